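"""Synthetic molecular-dynamics-like inputs for the whole pipeline.

Real inputs to a LIE analysis are interaction-energy time series saved
during MD production runs, and coordinate trajectories of the metal site.
This module generates statistically faithful stand-ins for both, so every
stage of the package runs and is testable without any simulation engine or
download:

* Interaction-energy series are stationary Gaussian AR(1) processes.
  Energies saved every few dozen MD steps are strongly autocorrelated, and
  AR(1) is the simplest process reproducing that, with the lag-1
  autocorrelation ``phi`` defaulting to 0.9.
* Metal-site trajectories displace each coordination partner along its
  metal-partner direction so the distance is exactly N(mean, sd)
  distributed, plus a small angular jitter of the direction; the recovered
  distance statistics therefore match their targets.

The module also ships the study's reference tables as packaged fixtures:
per-ligand interaction-energy differences with published LIE and
experimental binding free energies, ligand chemistry descriptors with
measured inhibition/dissociation constants, metal-coordination distance
statistics, and per-ion electrostatic contributions.

All generators use numpy's default PCG64 generator and are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

import biotite.structure as struc

from .affinity import LigandRecord, convert_units
from .energy_io import EnergyTimeSeries
from .lie import EnergyDelta

__all__ = [
    "SeriesSpec",
    "SiteTrajectorySpec",
    "StationarityError",
    "gen_energy_series",
    "gen_bound_free_pair",
    "gen_site_trajectory",
    "table4_fixture",
    "deltas_from_frame",
    "ligands_from_frame",
    "reference_table",
    "ligand_table",
    "coordination_reference",
    "ion_contribution_reference",
    "site_trajectory_spec_from_reference",
    "toy_site_structure",
    "DEFAULT_FREE_MEANS",
    "DEFAULT_NOISE",
]

#: default free-state mean interaction energies (kcal/mol); only the
#: bound-minus-free difference matters for LIE, so these set an arbitrary but
#: realistic solvation baseline for a small polar ligand in water
DEFAULT_FREE_MEANS = {"electrostatic": -6.76, "vdw": -8.0}

#: default fluctuation model for generated energy series
DEFAULT_NOISE = {"sd_ele": 1.0, "sd_vdw": 0.5, "phi": 0.9, "n_frames": 2000, "dt": 2.0}


class StationarityError(ValueError):
    """AR(1) coefficient outside [0, 1)."""


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for one AR(1) interaction-energy series."""

    ligand_id: str
    state: str
    component: str
    group: str = "surroundings"
    mean: float = 0.0  # kcal/mol
    sd: float = 1.0  # kcal/mol, stationary standard deviation
    ar1_phi: float = 0.9
    n_frames: int = 2000
    dt: float = 2.0  # ps between saved frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= self.ar1_phi < 1.0):
            raise StationarityError(f"ar1_phi must be in [0, 1), got {self.ar1_phi}")


@dataclass(frozen=True)
class SiteTrajectorySpec:
    """Recipe for a synthetic metal-site coordinate trajectory.

    partners: (label, unit direction from the metal, target mean distance,
    target distance sd) per coordination partner.
    """

    metal_label: str
    metal_position: np.ndarray
    partners: list[tuple[str, np.ndarray, float, float]]
    n_frames: int = 2000
    seed: int = 0
    angular_jitter: float = 0.03  # rad, direction wobble per frame

    def __post_init__(self) -> None:
        for label, _, mean, sd in self.partners:
            if mean <= 0:
                raise ValueError(f"partner {label}: target mean distance must be positive")
            if sd < 0:
                raise ValueError(f"partner {label}: target sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def gen_energy_series(spec: SeriesSpec) -> EnergyTimeSeries:
    """Stationary Gaussian AR(1) series: v_t = mean + phi*(v_{t-1}-mean) + eps_t.

    eps_t ~ N(0, sd^2 * (1 - phi^2)), and v_0 is drawn from the stationary
    distribution N(mean, sd^2), so the whole series is stationary from the
    first frame. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    values = np.empty(n)
    if spec.sd == 0.0:
        values.fill(spec.mean)
    else:
        innov_sd = spec.sd * np.sqrt(1.0 - spec.ar1_phi**2)
        x = rng.normal(0.0, spec.sd)
        values[0] = spec.mean + x
        for t in range(1, n):
            x = spec.ar1_phi * x + rng.normal(0.0, innov_sd)
            values[t] = spec.mean + x
    times = np.arange(n, dtype=float) * spec.dt
    return EnergyTimeSeries(spec.ligand_id, spec.state, spec.component, spec.group, times, values)


def gen_bound_free_pair(
    delta: EnergyDelta,
    free_means: dict | None = None,
    noise: dict | None = None,
    seed: int = 0,
) -> list[EnergyTimeSeries]:
    """Four series (bound/free x electrostatic/vdw) realising one EnergyDelta.

    The population means of bound and free differ by exactly dV per
    component, so the full pipeline (block averaging, difference, LIE)
    recovers the fixture within its propagated uncertainty. Sub-seeds are
    derived deterministically from ``seed``.
    """
    free_means = {**DEFAULT_FREE_MEANS, **(free_means or {})}
    noise = {**DEFAULT_NOISE, **(noise or {})}
    seeds = np.random.SeedSequence(seed).generate_state(4)
    out = []
    dv = {"electrostatic": delta.dV_ele, "vdw": delta.dV_vdw}
    sd = {"electrostatic": noise["sd_ele"], "vdw": noise["sd_vdw"]}
    k = 0
    for component in ("electrostatic", "vdw"):
        for state in ("bound", "free"):
            mean = free_means[component] + (dv[component] if state == "bound" else 0.0)
            out.append(
                gen_energy_series(
                    SeriesSpec(
                        ligand_id=delta.ligand_id,
                        state=state,
                        component=component,
                        mean=mean,
                        sd=sd[component],
                        ar1_phi=noise["phi"],
                        n_frames=int(noise["n_frames"]),
                        dt=noise["dt"],
                        seed=int(seeds[k] % 2**31),
                    )
                )
            )
            k += 1
    return out


def gen_site_trajectory(spec: SiteTrajectorySpec) -> pd.DataFrame:
    """Frame table (frame, atom_label, x, y, z) for a fluctuating metal site.

    Each partner's metal distance is drawn i.i.d. N(target mean, target sd)
    per frame; its direction wobbles by a small random rotation so frames are
    not collinear. The metal itself stays fixed, so recovered distance
    statistics match the targets exactly in distribution.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    metal = np.asarray(spec.metal_position, dtype=float)
    for f in range(spec.n_frames):
        rows.append((f, spec.metal_label, *metal))
    for label, direction, mean, sd in spec.partners:
        d0 = np.asarray(direction, dtype=float)
        nrm = np.linalg.norm(d0)
        if nrm < 1e-12:
            raise ValueError(f"partner {label}: zero direction vector")
        d0 = d0 / nrm
        dists = rng.normal(mean, sd, size=spec.n_frames) if sd > 0 else np.full(spec.n_frames, mean)
        if spec.angular_jitter > 0 and sd > 0:
            wobble = rng.normal(0.0, spec.angular_jitter, size=(spec.n_frames, 3))
            dirs = d0[None, :] + wobble
            dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        else:
            dirs = np.tile(d0, (spec.n_frames, 1))
        pos = metal[None, :] + dists[:, None] * dirs
        for f in range(spec.n_frames):
            rows.append((f, label, *pos[f]))
    df = pd.DataFrame(rows, columns=["frame", "atom_label", "x", "y", "z"])
    return df.sort_values(["frame", "atom_label"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# packaged reference fixtures
# ---------------------------------------------------------------------------

def _read_data(name: str) -> pd.DataFrame:
    with resources.files("tyrlie.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def reference_table() -> pd.DataFrame:
    """Published per-ligand energy differences and binding free energies."""
    return _read_data("interaction_deltas.csv")


def ligand_table() -> pd.DataFrame:
    """Ligand chemistry descriptors and measured affinity constants."""
    return _read_data("ligands.csv")


def coordination_reference() -> pd.DataFrame:
    """Crystal and MD-averaged metal-partner distances for the binuclear site."""
    return _read_data("coordination_reference.csv")


def ion_contribution_reference() -> pd.DataFrame:
    """Per-ligand mean Cu-ligand distances and electrostatic energies."""
    return _read_data("ion_contributions.csv")


def deltas_from_frame(df: pd.DataFrame) -> dict[str, EnergyDelta]:
    """EnergyDelta records from a deltas table (ligand_id,dV_vdw,dV_ele[,sems])."""
    deltas = {}
    for _, row in df.iterrows():
        deltas[row["ligand_id"]] = EnergyDelta(
            ligand_id=row["ligand_id"],
            dV_vdw=float(row["dV_vdw"]),
            dV_ele=float(row["dV_ele"]),
            dV_vdw_sem=float(row.get("dV_vdw_sem", 0.0) or 0.0),
            dV_ele_sem=float(row.get("dV_ele_sem", 0.0) or 0.0),
        )
    return deltas


def ligands_from_frame(df: pd.DataFrame) -> dict[str, LigandRecord]:
    """LigandRecord objects from a ligand descriptor table."""
    ligands = {}
    for _, row in df.iterrows():
        has_ki = pd.notna(row["Ki_value"])
        ligands[row["ligand_id"]] = LigandRecord(
            ligand_id=row["ligand_id"],
            name=row["name"],
            hydroxyl_count=int(row["hydroxyl_count"]),
            charge_class=row["charge_class"],
            Ki=convert_units(float(row["Ki_value"]), str(row["Ki_units"])) if has_ki else None,
            Ki_kind=str(row["Ki_kind"]) if has_ki else "none",
            beta_override=float(row["beta_override"]) if pd.notna(row["beta_override"]) else None,
        )
    return ligands


def table4_fixture() -> tuple[dict[str, EnergyDelta], dict[str, LigandRecord]]:
    """The nine-ligand study fixture: energy deltas plus ligand records.

    Energy differences carry the published uncertainties; ligands without a
    measured constant have Ki None and are excluded from experimental
    comparisons downstream.
    """
    return deltas_from_frame(reference_table()), ligands_from_frame(ligand_table())


_OCTAHEDRAL_DIRECTIONS = {
    "equatorial": [np.array(v, float) for v in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0))],
    "axial": [np.array(v, float) for v in ((0, 0, 1), (0, 0, -1))],
}


def site_trajectory_spec_from_reference(
    ion: str, n_frames: int = 2000, seed: int = 0
) -> SiteTrajectorySpec:
    """Trajectory spec targeting the reference coordination statistics of one ion.

    Partners are laid out on an ideal octahedron (axial partners along +/-z)
    with their target mean/sd taken from the packaged reference table.
    """
    ref = coordination_reference()
    sub = ref[ref["ion"] == ion]
    if sub.empty:
        raise ValueError(f"unknown ion {ion!r}; expected one of {sorted(set(ref['ion']))}")
    slots = {"equatorial": 0, "axial": 0}
    partners = []
    for _, row in sub.iterrows():
        role = row["role"]
        direction = _OCTAHEDRAL_DIRECTIONS[role][slots[role] % len(_OCTAHEDRAL_DIRECTIONS[role])]
        slots[role] += 1
        partners.append(
            (f"{row['residue']}_{row['atom']}", direction, float(row["sim_mean"]), float(row["sim_sd"]))
        )
    return SiteTrajectorySpec(
        metal_label=ion,
        metal_position=np.zeros(3),
        partners=partners,
        n_frames=n_frames,
        seed=seed,
    )


def toy_site_structure(binuclear: bool = True) -> struc.AtomArray:
    """Synthetic minimal Cu coordination site as a biotite AtomArray.

    Each Cu ion carries three histidine NE2 nitrogens at 2.1 angstrom and
    three water oxygens at 2.2 angstrom in an octahedral arrangement — the
    His3 + water coordination motif of a type-3 copper centre. With
    ``binuclear=True`` a second, independently coordinated Cu sits 4.2
    angstrom away, mimicking a coupled binuclear site.
    """
    def octa(avoid_plus_x: bool) -> np.ndarray:
        # octahedral directions, with the arm pointing at the partner ion
        # tilted away so the two coordination spheres do not bridge
        tilted = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        dirs = [
            -tilted if avoid_plus_x else tilted,
            (0, 1, 0), (0, 0, 1), (0, -1, 0), (0, 0, -1),
            (-1, 0, 0) if avoid_plus_x else (1, 0, 0),
        ]
        return np.array([np.asarray(d, float) for d in dirs])

    def one_site(center, res_offset, avoid_plus_x):
        dirs = octa(avoid_plus_x)
        atoms = [("CU", "CU", "CU", res_offset, center, True)]
        for i in range(3):
            pos = center + 2.1 * dirs[i]
            atoms.append(("NE2", "HIS", "N", res_offset + 1 + i, pos, False))
        for i in range(3):
            pos = center + 2.2 * dirs[3 + i]
            atoms.append(("O", "HOH", "O", res_offset + 4 + i, pos, True))
        return atoms

    records = one_site(np.zeros(3), 1, avoid_plus_x=True)
    if binuclear:
        records += one_site(np.array([4.2, 0.0, 0.0]), 101, avoid_plus_x=False)
    n = len(records)
    arr = struc.AtomArray(n)
    arr.coord = np.array([r[4] for r in records])
    arr.atom_name = np.array([r[0] for r in records], dtype="U6")
    arr.res_name = np.array([r[1] for r in records], dtype="U5")
    arr.element = np.array([r[2] for r in records], dtype="U2")
    arr.res_id = np.array([r[3] for r in records], dtype=int)
    arr.chain_id = np.full(n, "A", dtype="U4")
    arr.hetero = np.array([r[5] for r in records], dtype=bool)
    return arr
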