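"""Experimental binding affinities from inhibition/dissociation constants.

A measured inhibition constant K_i (or dissociation constant K_d) in molar
units converts to a binding free energy via

    dG_exp = R * T * ln(K)

with R = 1.987204e-3 kcal/(mol K). K < 1 M gives a negative (favourable)
free energy. Dissociation constants are treated identically: both are
equilibrium constants for the unbound state on the molar standard state.

The default temperature is 298.15 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_KCAL",
    "DEFAULT_TEMPERATURE",
    "LigandRecord",
    "ExperimentalAffinity",
    "UnitError",
    "convert_units",
    "delta_g_from_ki",
    "experimental_affinities",
]

R_KCAL = 1.987204e-3  # gas constant, kcal/(mol K)
DEFAULT_TEMPERATURE = 298.15  # K

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


class UnitError(ValueError):
    """Unrecognised concentration unit."""


@dataclass(frozen=True)
class LigandRecord:
    """Identity, chemistry descriptors and measured affinity of one ligand.

    hydroxyl_count and charge_class drive the chemistry-dependent choice of
    the LIE electrostatic scaling factor; Ki (molar) is the measured
    inhibition or dissociation constant, absent for ligands without a
    published value.
    """

    ligand_id: str
    name: str
    hydroxyl_count: int
    charge_class: str  # "neutral" | "charged"
    Ki: float | None = None
    Ki_kind: str = "none"  # "Ki" | "Kd" | "none"
    beta_override: float | None = None

    def __post_init__(self) -> None:
        if self.hydroxyl_count < 0:
            raise ValueError("hydroxyl_count must be >= 0")
        if self.charge_class not in ("neutral", "charged"):
            raise ValueError(f"unknown charge_class {self.charge_class!r}")
        if self.Ki is not None and self.Ki <= 0:
            raise ValueError("Ki must be positive when present")
        if self.Ki_kind not in ("Ki", "Kd", "none"):
            raise ValueError(f"unknown Ki_kind {self.Ki_kind!r}")
        if (self.Ki is None) != (self.Ki_kind == "none"):
            raise ValueError("Ki and Ki_kind must be present or absent together")


@dataclass(frozen=True)
class ExperimentalAffinity:
    ligand_id: str
    dG_exp: float  # kcal/mol
    temperature: float  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def convert_units(value: float, units: str) -> float:
    """Convert a concentration to molar by exact power-of-ten scaling.

    Recognised units: M, mM, uM (also µM), nM.
    """
    try:
        scale = _UNIT_SCALE[units]
    except KeyError:
        raise UnitError(f"unknown concentration unit {units!r}") from None
    return value * scale


def delta_g_from_ki(Ki: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy R*T*ln(Ki) in kcal/mol, Ki in molar."""
    if Ki <= 0:
        raise ValueError(f"Ki must be positive, got {Ki}")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return R_KCAL * T * math.log(Ki)


def experimental_affinities(
    ligands, T: float = DEFAULT_TEMPERATURE
) -> list[ExperimentalAffinity]:
    """Convert every ligand with a measured constant; skip the rest."""
    out = []
    for lig in ligands:
        if lig.Ki is None:
            continue
        out.append(ExperimentalAffinity(lig.ligand_id, delta_g_from_ki(lig.Ki, T), T))
    return out
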