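"""Per-residue and per-ion decomposition of bound-state interaction energies.

Averaging the ligand's electrostatic and van der Waals interaction energy
with each surrounding residue (and each active-site metal ion) over the
bound-state trajectory highlights which contacts drive binding. This is a
presentation of mean interaction energies only: there is no rigorous
decomposition of a free energy into additive per-residue terms, so the
numbers rank binding determinants but are not themselves free energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .energy_io import EnergyTimeSeries, block_average

__all__ = [
    "ResidueProfile",
    "IonContribution",
    "StructureError",
    "residue_profile",
    "top_contributors",
    "ion_contributions",
    "write_profile",
]

ION_LABELS = ("Cu_A", "Cu_B")


class StructureError(ValueError):
    """Expected group (e.g. a metal ion) missing from a profile."""


@dataclass(frozen=True)
class ResidueProfile:
    """Mean per-group interaction energies for one bound ligand (kcal/mol).

    entries maps residue/ion label -> dict with keys mean_ele, mean_vdw,
    sem_ele, sem_vdw; insertion order follows first appearance in the input.
    """

    ligand_id: str
    entries: dict[str, dict[str, float]]


@dataclass(frozen=True)
class IonContribution:
    ligand_id: str
    ion_label: str
    V_ele: float  # kcal/mol
    mean_distance: float  # angstrom

    def __post_init__(self) -> None:
        if self.ion_label not in ION_LABELS:
            raise StructureError(f"unknown ion label {self.ion_label!r}")
        if self.mean_distance <= 0:
            raise ValueError("mean_distance must be positive")


def residue_profile(
    series: list[EnergyTimeSeries],
    n_blocks: int = 5,
    t_start: float | None = None,
    t_end: float | None = None,
) -> ResidueProfile:
    """Time-average each per-group series of a bound-state decomposition.

    All series must share one ligand_id and state "bound". Only groups with
    both an electrostatic and a van der Waals series are profiled.
    """
    if not series:
        raise ValueError("no series given")
    ligand_ids = {s.ligand_id for s in series}
    if len(ligand_ids) != 1:
        raise ValueError(f"series mix ligand_ids {sorted(ligand_ids)}")
    if any(s.state != "bound" for s in series):
        raise ValueError("residue decomposition applies to bound-state series only")
    ligand_id = series[0].ligand_id

    by_group: dict[str, dict[str, EnergyTimeSeries]] = {}
    for s in series:
        by_group.setdefault(s.group, {})[s.component] = s

    entries: dict[str, dict[str, float]] = {}
    for group, comps in by_group.items():
        if "electrostatic" not in comps or "vdw" not in comps:
            continue
        ele = block_average(comps["electrostatic"], n_blocks, t_start, t_end)
        vdw = block_average(comps["vdw"], n_blocks, t_start, t_end)
        entries[group] = {
            "mean_ele": ele.mean,
            "mean_vdw": vdw.mean,
            "sem_ele": ele.sem,
            "sem_vdw": vdw.sem,
        }
    return ResidueProfile(ligand_id=ligand_id, entries=entries)


def top_contributors(
    profile: ResidueProfile, n: int, component: str = "electrostatic"
) -> tuple[list[tuple[str, float]], bool]:
    """The n most attractive groups by mean interaction energy.

    Sorted ascending (most negative, i.e. strongest attraction, first); ties
    broken lexicographically by label. Returns (ranking, truncated) where
    truncated is True when n exceeded the number of groups and the full
    ranking was returned instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    key = "mean_ele" if component == "electrostatic" else "mean_vdw"
    if component not in ("electrostatic", "vdw"):
        raise ValueError(f"unknown component {component!r}")
    ranked = sorted(profile.entries.items(), key=lambda kv: (kv[1][key], kv[0]))
    truncated = n > len(ranked)
    return [(label, vals[key]) for label, vals in ranked[:n]], truncated


def ion_contributions(
    profile: ResidueProfile, distances: dict[str, float]
) -> list[IonContribution]:
    """Pair each Cu ion's mean electrostatic energy with its ligand distance.

    ``distances`` maps ion label -> mean ligand-ion distance in angstrom.
    Both active-site ions must be present in the profile.
    """
    out = []
    for ion in ION_LABELS:
        if ion not in profile.entries:
            raise StructureError(f"profile for {profile.ligand_id} lacks ion group {ion}")
        if ion not in distances:
            raise StructureError(f"no ligand-{ion} distance supplied")
        out.append(
            IonContribution(
                ligand_id=profile.ligand_id,
                ion_label=ion,
                V_ele=profile.entries[ion]["mean_ele"],
                mean_distance=distances[ion],
            )
        )
    return out


def write_profile(profile: ResidueProfile, path: str) -> None:
    """Write a profile as delimited text (residue,mean_ele,mean_vdw,sem_ele,sem_vdw)."""
    rows = [
        (label, v["mean_ele"], v["mean_vdw"], v["sem_ele"], v["sem_vdw"])
        for label, v in profile.entries.items()
    ]
    df = pd.DataFrame(rows, columns=["residue", "mean_ele", "mean_vdw", "sem_ele", "sem_vdw"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "# mean ligand-residue interaction energies (kcal/mol); "
            "not a rigorous free-energy decomposition\n"
        )
        df.to_csv(fh, index=False, float_format="%.6f")
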