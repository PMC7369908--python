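"""Calibration of LIE scaling factors against experimental affinities.

The two LIE coefficients (alpha, beta) are fitted by no-intercept least
squares of the experimental binding free energies on the per-ligand
(dV_vdw, dV_ele) pairs:

    minimise  sum_i (dG_exp,i - alpha * dV_vdw,i - beta * dV_ele,i)^2

solved exactly through the 2x2 normal equations. No intercept is used: the
LIE functional form has none, and a free offset would absorb part of the
binding signal into an unphysical constant. Ligands without an experimental
affinity are excluded from the fit but still receive predictions.

Model quality is reported as the squared Pearson correlation between
predicted and experimental values, for both the literature parameterization
("model 1", alpha 0.181 with chemistry-dependent beta) and the fitted one
("model 2").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .affinity import ExperimentalAffinity
from .lie import (
    LITERATURE_ALPHA,
    EnergyDelta,
    LIEParameters,
    assign_beta,
    lie_binding_energy,
)

__all__ = [
    "CalibrationResult",
    "InsufficientDataError",
    "CollinearityError",
    "UndefinedRSquaredError",
    "fit_parameters",
    "coefficient_of_determination",
    "leave_one_out",
    "calibrate",
    "build_report",
    "read_report",
]

#: fail on near-singular normal matrices instead of silently regularizing
CONDITION_LIMIT = 1e12


class InsufficientDataError(ValueError):
    """Fewer overlapping ligands than parameters to fit."""


class CollinearityError(ValueError):
    """The two energy-difference columns are (numerically) collinear."""


class UndefinedRSquaredError(ValueError):
    """Pearson correlation is undefined (zero variance or too few points)."""


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted LIE parameters plus per-ligand predictions and fit quality."""

    alpha: float
    beta: float
    r2_model1: float
    r2_model2: float
    predictions_model1: dict[str, float]
    predictions_model2: dict[str, float]
    residuals: dict[str, float]  # dG_exp - model-2 prediction, fitted ligands only
    n_ligands: int
    loo_rmse: float | None = None

    def __post_init__(self) -> None:
        for r2 in (self.r2_model1, self.r2_model2):
            if not (0.0 <= r2 <= 1.0 + 1e-12):
                raise ValueError(f"r^2 out of range: {r2}")
        if self.n_ligands < 2:
            raise ValueError("calibration needs at least 2 ligands")


def _design(deltas, exps):
    """Overlap deltas with experimental affinities; return (ids, X, y)."""
    exp_by_id = {e.ligand_id: e.dG_exp for e in exps}
    rows = [(d.ligand_id, d.dV_vdw, d.dV_ele) for d in deltas if d.ligand_id in exp_by_id]
    ids = [r[0] for r in rows]
    X = np.array([[r[1], r[2]] for r in rows], dtype=float).reshape(-1, 2)
    y = np.array([exp_by_id[i] for i in ids], dtype=float)
    return ids, X, y


def fit_parameters(deltas, exps) -> tuple[float, float]:
    """No-intercept least-squares (alpha, beta) over the overlapping ligands.

    Raises
    ------
    InsufficientDataError
        With fewer than 2 ligands present in both collections.
    CollinearityError
        If the 2x2 normal matrix has condition number above ``CONDITION_LIMIT``.
    """
    ids, X, y = _design(deltas, exps)
    if len(ids) < 2:
        raise InsufficientDataError(
            f"need >= 2 ligands with both energy differences and experimental "
            f"affinities, got {len(ids)}"
        )
    gram = X.T @ X
    if np.linalg.cond(gram) > CONDITION_LIMIT:
        raise CollinearityError("dV_vdw and dV_ele columns are collinear; fit is unstable")
    alpha, beta = np.linalg.solve(gram, X.T @ y)
    return float(alpha), float(beta)


def coefficient_of_determination(pred: dict[str, float], exp: dict[str, float]) -> float:
    """Squared Pearson correlation between paired predictions and observations.

    Pairs on ligand_id; requires >= 3 common ligands and nonzero variance in
    both vectors. Note r^2 of a correlation is invariant under sign flips and
    affine maps of either vector — it measures linear association, not
    absolute agreement.
    """
    common = sorted(set(pred) & set(exp))
    if len(common) < 3:
        raise UndefinedRSquaredError(f"need >= 3 paired values, got {len(common)}")
    p = np.array([pred[k] for k in common], dtype=float)
    e = np.array([exp[k] for k in common], dtype=float)
    if p.std() == 0 or e.std() == 0:
        raise UndefinedRSquaredError("zero variance in predictions or observations")
    r = np.corrcoef(p, e)[0, 1]
    return float(r * r)


def leave_one_out(deltas, exps) -> tuple[dict[str, float], float]:
    """Per-ligand held-out predictions and their RMSE.

    Each overlapping ligand is predicted from (alpha, beta) refitted on the
    remaining ligands — a cheap robustness check on the calibration.
    """
    ids, X, y = _design(deltas, exps)
    if len(ids) < 3:
        raise InsufficientDataError(
            f"leave-one-out needs >= 3 overlapping ligands, got {len(ids)}"
        )
    exp_by_id = {e.ligand_id: e for e in exps}
    preds: dict[str, float] = {}
    for i, lig in enumerate(ids):
        rest_deltas = [d for d in deltas if d.ligand_id != lig]
        rest_exps = [e for e in exps if e.ligand_id != lig]
        a, b = fit_parameters(rest_deltas, rest_exps)
        preds[lig] = a * X[i, 0] + b * X[i, 1]
    errors = np.array([preds[lig] - exp_by_id[lig].dG_exp for lig in ids])
    return preds, float(np.sqrt(np.mean(errors**2)))


def calibrate(
    deltas,
    exps,
    ligands=None,
    beta_scheme: dict | None = None,
    with_loo: bool = False,
) -> CalibrationResult:
    """Full calibration: fit (alpha, beta), predict under both models, score.

    ``ligands`` (LigandRecord collection) supplies the chemistry descriptors
    for the model-1 per-ligand beta; without it, model 1 falls back to the
    polyhydroxyl class for every ligand.
    """
    alpha, beta = fit_parameters(deltas, exps)
    fitted = LIEParameters(alpha, beta, source="fitted")
    lig_by_id = {l.ligand_id: l for l in (ligands or [])}

    pred1: dict[str, float] = {}
    pred2: dict[str, float] = {}
    for d in deltas:
        if d.ligand_id in lig_by_id:
            b1 = assign_beta(lig_by_id[d.ligand_id], beta_scheme)
        else:
            b1 = 0.33
        params1 = LIEParameters(LITERATURE_ALPHA, b1, source="literature")
        pred1[d.ligand_id] = lie_binding_energy(d, params1).dG
        pred2[d.ligand_id] = lie_binding_energy(d, fitted).dG

    exp_map = {e.ligand_id: e.dG_exp for e in exps}
    r2_1 = coefficient_of_determination(pred1, exp_map)
    r2_2 = coefficient_of_determination(pred2, exp_map)
    residuals = {k: exp_map[k] - pred2[k] for k in pred2 if k in exp_map}

    loo_rmse = None
    if with_loo:
        _, loo_rmse = leave_one_out(deltas, exps)

    return CalibrationResult(
        alpha=alpha,
        beta=beta,
        r2_model1=r2_1,
        r2_model2=r2_2,
        predictions_model1=pred1,
        predictions_model2=pred2,
        residuals=residuals,
        n_ligands=len(residuals),
        loo_rmse=loo_rmse,
    )


def build_report(result: CalibrationResult, exps, path: str) -> None:
    """Serialize a calibration (parameters, r^2 values, scatter points) to JSON."""
    if not result.predictions_model2:
        raise ValueError("calibration has no predictions to report")
    exp_map = {e.ligand_id: e.dG_exp for e in exps}
    points = [
        {
            "ligand_id": lig,
            "dG_exp": exp_map[lig],
            "dG_model1": result.predictions_model1.get(lig),
            "dG_model2": result.predictions_model2[lig],
        }
        for lig in sorted(result.predictions_model2)
        if lig in exp_map
    ]
    payload = {
        "alpha": result.alpha,
        "beta": result.beta,
        "r2_model1": result.r2_model1,
        "r2_model2": result.r2_model2,
        "n_ligands": result.n_ligands,
        "loo_rmse": result.loo_rmse,
        "points": points,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
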