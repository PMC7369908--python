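"""Reading, writing and summarising ligand-surrounding interaction-energy
time series.

The on-disk dialect is plain delimited text (comma or tab, auto-detected),
UTF-8, ``#`` comments, with required columns
``ligand_id,state,component,group,time_ps,energy_kcal``. One file may hold
many series; a series is identified by the tuple
``(ligand_id, state, component, group)`` where ``group`` is either
``"surroundings"`` for the ligand-total interaction energy or a residue/ion
label (``His208``, ``Cu_A``, ...) for a decomposed term.

Uncertainties on time averages are estimated by block averaging: the frames
are split into contiguous blocks and the standard error of the block means
is reported. This is the standard treatment for autocorrelated molecular
dynamics series, where the naive i.i.d. standard error would be far too
optimistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnergyTimeSeries",
    "EnergySummary",
    "EnergyFormatError",
    "EnergyParseError",
    "EnergyValidationError",
    "read_energy_table",
    "write_energy_table",
    "block_average",
    "write_summary_table",
    "read_summary_table",
]

REQUIRED_COLUMNS = ("ligand_id", "state", "component", "group", "time_ps", "energy_kcal")

STATES = ("bound", "free")
COMPONENTS = ("electrostatic", "vdw")


class EnergyFormatError(ValueError):
    """Malformed header or unsupported file layout."""


class EnergyParseError(ValueError):
    """A cell failed to parse as the declared type."""


class EnergyValidationError(ValueError):
    """Parsed data violates a series invariant (e.g. duplicate time points)."""


@dataclass(frozen=True)
class EnergyTimeSeries:
    """Per-frame interaction energies for one (state, component, group) identity.

    times are in ps and strictly increasing; values are in kcal/mol.
    """

    ligand_id: str
    state: str
    component: str
    group: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.state not in STATES:
            raise EnergyValidationError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.component not in COMPONENTS:
            raise EnergyValidationError(
                f"unknown component {self.component!r}; expected one of {COMPONENTS}"
            )
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise EnergyValidationError("times and values must be 1-D and of equal length")
        if len(times) < 1:
            raise EnergyValidationError("a series needs at least one frame")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(times)):
            raise EnergyValidationError("times and values must be finite")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise EnergyValidationError("times must be strictly increasing")

    @property
    def identity(self) -> tuple[str, str, str, str]:
        return (self.ligand_id, self.state, self.component, self.group)

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def window(self, t_start: float | None = None, t_end: float | None = None) -> "EnergyTimeSeries":
        """Restrict to frames with t_start <= time <= t_end (inclusive)."""
        mask = np.ones(len(self.times), dtype=bool)
        if t_start is not None:
            mask &= self.times >= t_start
        if t_end is not None:
            mask &= self.times <= t_end
        if not mask.any():
            raise EnergyValidationError(
                f"window [{t_start}, {t_end}] selects no frames of series {self.identity}"
            )
        return EnergyTimeSeries(
            self.ligand_id, self.state, self.component, self.group,
            self.times[mask], self.values[mask],
        )


@dataclass(frozen=True)
class EnergySummary:
    """Block-averaged mean of a series with its standard error (kcal/mol)."""

    mean: float
    sem: float
    n_frames: int
    n_blocks: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise EnergyValidationError("sem must be non-negative")
        if self.n_blocks < 1:
            raise EnergyValidationError("n_blocks must be >= 1")
        if self.n_frames < self.n_blocks:
            raise EnergyValidationError("n_frames must be >= n_blocks")


def _detect_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                return "\t" if "\t" in line else ","
    raise EnergyFormatError(f"{path}: no header line found")


def read_energy_table(path: str, dialect: dict | None = None) -> list[EnergyTimeSeries]:
    """Read an energy table into one series per unique identity tuple.

    Parameters
    ----------
    path:
        Delimited-text file in the dialect described in the module docstring.
    dialect:
        Optional overrides; recognised key: ``"delimiter"``.

    Raises
    ------
    EnergyFormatError
        If a required column is missing.
    EnergyParseError
        If a time or energy cell is non-numeric or NaN (reported with its
        1-based line number).
    EnergyValidationError
        On duplicate (identity, time) rows.
    """
    delim = (dialect or {}).get("delimiter") or _detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delim, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EnergyFormatError(f"{path}: empty file") from None

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EnergyFormatError(f"{path}: missing required column(s) {', '.join(missing)}")

    # Map data rows back to physical line numbers for parse-error reporting.
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = [
        i + 1
        for i, line in enumerate(lines)
        if line.strip() and not line.lstrip().startswith("#")
    ][1:]  # first non-comment line is the header

    for col in ("time_ps", "energy_kcal"):
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            lineno = data_lines[row] if row < len(data_lines) else row + 2
            raise EnergyParseError(
                f"{path}:{lineno}: non-numeric {col} value {raw.iloc[row]!r}"
            )
        df[col] = parsed

    dupes = df.duplicated(subset=["ligand_id", "state", "component", "group", "time_ps"])
    if dupes.any():
        row = df[dupes].iloc[0]
        raise EnergyValidationError(
            f"{path}: duplicate time point {row['time_ps']} for series "
            f"({row['ligand_id']}, {row['state']}, {row['component']}, {row['group']})"
        )

    series = []
    for (lig, state, comp, group), sub in df.groupby(
        ["ligand_id", "state", "component", "group"], sort=False
    ):
        sub = sub.sort_values("time_ps", kind="stable")
        series.append(
            EnergyTimeSeries(
                str(lig), str(state), str(comp), str(group),
                sub["time_ps"].to_numpy(float), sub["energy_kcal"].to_numpy(float),
            )
        )
    return series


def write_energy_table(series: Iterable[EnergyTimeSeries], path: str) -> None:
    """Write series to the delimited dialect read by :func:`read_energy_table`."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "ligand_id": s.ligand_id,
                    "state": s.state,
                    "component": s.component,
                    "group": s.group,
                    "time_ps": s.times,
                    "energy_kcal": s.values,
                }
            )
        )
    if not frames:
        raise EnergyValidationError("nothing to write: empty series collection")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def block_average(
    series: EnergyTimeSeries,
    n_blocks: int = 5,
    t_start: float | None = None,
    t_end: float | None = None,
) -> EnergySummary:
    """Grand mean and block-averaged standard error of a series.

    The frames (optionally restricted to ``[t_start, t_end]``) are split into
    ``n_blocks`` contiguous, near-equal blocks. The reported mean is the grand
    mean over all frames; the sem is the sample standard deviation of the
    block means divided by sqrt(n_blocks). With ``n_blocks=1`` the spread of a
    single block mean is undefined, so sem 0.0 is returned and a warning is
    issued.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if t_start is not None or t_end is not None:
        series = series.window(t_start, t_end)
    values = series.values
    if n_blocks > len(values):
        raise ValueError(
            f"n_blocks={n_blocks} exceeds the {len(values)} frames available"
        )
    mean = float(values.mean())
    if n_blocks == 1:
        warnings.warn(
            "block_average with n_blocks=1 cannot estimate an uncertainty; sem set to 0",
            UserWarning,
            stacklevel=2,
        )
        return EnergySummary(mean=mean, sem=0.0, n_frames=len(values), n_blocks=1)
    block_means = np.array([b.mean() for b in np.array_split(values, n_blocks)])
    sem = float(block_means.std(ddof=1) / np.sqrt(n_blocks))
    return EnergySummary(mean=mean, sem=sem, n_frames=len(values), n_blocks=n_blocks)


_SUMMARY_COLUMNS = ("ligand_id", "state", "component", "group", "mean", "sem", "n_frames", "n_blocks")


def write_summary_table(
    summaries: Sequence[tuple[tuple[str, str, str, str], EnergySummary]], path: str
) -> None:
    """Write (identity, summary) pairs as delimited text.

    Floats are written with 6 decimal places; a write -> read -> write cycle
    is byte-stable.
    """
    if not summaries:
        raise EnergyValidationError("nothing to write: empty summary collection")
    rows = []
    for (lig, state, comp, group), s in summaries:
        rows.append((lig, state, comp, group, s.mean, s.sem, s.n_frames, s.n_blocks))
    df = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_summary_table(path: str) -> list[tuple[tuple[str, str, str, str], EnergySummary]]:
    """Inverse of :func:`write_summary_table`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise EnergyFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        identity = (str(row["ligand_id"]), str(row["state"]), str(row["component"]), str(row["group"]))
        out.append(
            (
                identity,
                EnergySummary(
                    mean=float(row["mean"]),
                    sem=float(row["sem"]),
                    n_frames=int(row["n_frames"]),
                    n_blocks=int(row["n_blocks"]),
                ),
            )
        )
    return out
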