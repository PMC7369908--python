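"""The linear interaction energy (LIE) binding free energy estimator.

LIE estimates the absolute binding free energy of a ligand from two
end-point molecular dynamics ensembles — the ligand bound in the solvated
protein and the ligand free in solvent — as a weighted sum of the changes in
its average interaction energies with the surroundings:

    dG_LIE = alpha * (<V_vdw>_bound - <V_vdw>_free)
           + beta  * (<V_ele>_bound - <V_ele>_free)

alpha scales the non-polar (van der Waals) term; beta scales the polar
(electrostatic) term and conventionally depends on the ligand's chemistry.
Two parameterizations are supported: the literature scheme (alpha = 0.181
with beta in {0.50, 0.43, 0.37, 0.33} chosen per ligand) and externally
supplied values, e.g. from :mod:`tyrlie.calibration`.

Uncertainties propagate in quadrature assuming independent components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .affinity import LigandRecord
from .energy_io import EnergySummary

__all__ = [
    "LITERATURE_ALPHA",
    "LIEParameters",
    "EnergyDelta",
    "LIEResult",
    "DescriptorError",
    "assign_beta",
    "literature_parameters",
    "lie_binding_energy",
    "compute_delta",
]

LITERATURE_ALPHA = 0.181

#: beta classes of the standard chemistry-dependent scheme
BETA_CHARGED = 0.50
BETA_NO_HYDROXYL = 0.43
BETA_ONE_HYDROXYL = 0.37
BETA_POLYHYDROXYL = 0.33


class DescriptorError(ValueError):
    """Ligand lacks the descriptors needed to choose beta."""


@dataclass(frozen=True)
class LIEParameters:
    alpha: float
    beta: float
    source: str = "user"  # "literature" | "fitted" | "user"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("LIE scaling factors must be non-negative")
        if self.source not in ("literature", "fitted", "user"):
            raise ValueError(f"unknown parameter source {self.source!r}")


@dataclass(frozen=True)
class EnergyDelta:
    """Bound-minus-free average interaction energies for one ligand (kcal/mol)."""

    ligand_id: str
    dV_vdw: float
    dV_ele: float
    dV_vdw_sem: float = 0.0
    dV_ele_sem: float = 0.0

    def __post_init__(self) -> None:
        if self.dV_vdw_sem < 0 or self.dV_ele_sem < 0:
            raise ValueError("sems must be non-negative")
        if not (math.isfinite(self.dV_vdw) and math.isfinite(self.dV_ele)):
            raise ValueError("energy differences must be finite")


@dataclass(frozen=True)
class LIEResult:
    ligand_id: str
    dG: float
    dG_sem: float
    parameters: LIEParameters

    def __post_init__(self) -> None:
        if not math.isfinite(self.dG):
            raise ValueError("dG must be finite")
        if self.dG_sem < 0:
            raise ValueError("dG_sem must be non-negative")


def assign_beta(ligand: LigandRecord, scheme: dict | None = None) -> float:
    """Electrostatic scaling factor for a ligand under the standard scheme.

    Resolution order: a per-ligand override (from ``scheme["overrides"]``
    or the ligand's own ``beta_override`` field), then the chemistry rule —
    charged ligands 0.50; 0 hydroxyls 0.43; 1 hydroxyl 0.37; >= 2 hydroxyls
    0.33. Overrides exist because some ligands (zwitterionic amino-acid
    substrates, hydroxy-acids) are assigned a class in the source
    parameterization that no simple hydroxyl count reproduces.
    """
    overrides = (scheme or {}).get("overrides", {})
    if ligand.ligand_id in overrides:
        return float(overrides[ligand.ligand_id])
    if ligand.beta_override is not None:
        return float(ligand.beta_override)
    if ligand.charge_class == "charged":
        return BETA_CHARGED
    if ligand.hydroxyl_count == 0:
        return BETA_NO_HYDROXYL
    if ligand.hydroxyl_count == 1:
        return BETA_ONE_HYDROXYL
    return BETA_POLYHYDROXYL


def literature_parameters(ligand: LigandRecord, scheme: dict | None = None) -> LIEParameters:
    """Literature alpha with the chemistry-dependent beta for this ligand."""
    return LIEParameters(LITERATURE_ALPHA, assign_beta(ligand, scheme), source="literature")


def lie_binding_energy(delta: EnergyDelta, params: LIEParameters) -> LIEResult:
    """Evaluate the LIE estimator on one ligand's energy differences."""
    dG = params.alpha * delta.dV_vdw + params.beta * delta.dV_ele
    dG_sem = math.hypot(params.alpha * delta.dV_vdw_sem, params.beta * delta.dV_ele_sem)
    return LIEResult(delta.ligand_id, dG, dG_sem, params)


def compute_delta(
    bound_ele: EnergySummary,
    bound_vdw: EnergySummary,
    free_ele: EnergySummary,
    free_vdw: EnergySummary,
    ligand_id: str,
) -> EnergyDelta:
    """Bound-minus-free differences with quadrature-propagated sems."""
    return EnergyDelta(
        ligand_id=ligand_id,
        dV_vdw=bound_vdw.mean - free_vdw.mean,
        dV_ele=bound_ele.mean - free_ele.mean,
        dV_vdw_sem=math.hypot(bound_vdw.sem, free_vdw.sem),
        dV_ele_sem=math.hypot(bound_ele.sem, free_ele.sem),
    )
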