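"""Octahedral dummy-atom model for active-site Cu2+ ions.

Divalent copper in a classical force field is poorly served by a bare +2
point charge: coordination geometry collapses or distorts, and two nearby
ions repel excessively. The dummy-cation construction spreads the +2 charge
over a small core plus six massless charged particles arranged as an
octahedron around it. A d9 ion like Cu2+ is Jahn-Teller active, so the
octahedron is distorted: the two axial dummies sit farther from the core
than the four equatorial ones, reproducing the elongated axial
metal-partner distances seen in crystal structures and simulations.

This module builds such a model at every Cu site detected in a PDB
structure, writes the augmented structure back out, and provides the
geometric validation used on coordinate trajectories: per-partner
coordination-distance statistics, an axial/equatorial elongation ratio, and
radial distribution functions around the ion.

Charges and core-dummy distances are configuration parameters (see
``data/dummy_params.yaml``); every invariant enforced here — total charge
exactly +2.0 e, axial >= equatorial distance, exact class distances,
orthogonal equatorial arms — holds for any parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "MetalSite",
    "DummyModel",
    "CoordinationStats",
    "RDFResult",
    "GeometryError",
    "OrientationError",
    "FrameError",
    "SelectionError",
    "default_dummy_params",
    "read_structure",
    "save_structure",
    "detect_metal_sites",
    "build_dummy_model",
    "write_structure_with_dummies",
    "read_frame_table",
    "write_frame_table",
    "coordination_distances",
    "jahn_teller_score",
    "radial_distribution",
]

WATER_RES_NAMES = {"HOH", "WAT", "TIP3", "TIP", "SPC", "SOL"}

DUMMY_ATOM_NAMES = ("DE1", "DE2", "DE3", "DE4", "DA1", "DA2")


class GeometryError(ValueError):
    """Too few coordinating atoms to orient a dummy model."""


class OrientationError(ValueError):
    """Degenerate (collinear) coordination; no unique frame exists."""


class FrameError(ValueError):
    """A trajectory frame lacks a required atom."""


class SelectionError(ValueError):
    """An atom selection matched nothing."""


@dataclass(frozen=True)
class MetalSite:
    """One Cu ion and its inner coordination sphere.

    coordinating_atoms holds (residue_label, atom_name, position, cls) tuples
    sorted by distance from the metal; cls is "protein" or "water".
    """

    metal_label: str
    metal_position: np.ndarray
    coordinating_atoms: list[tuple[str, str, np.ndarray, str]]

    def partner_distances(self) -> dict[str, float]:
        return {
            f"{res}_{atom}": float(np.linalg.norm(pos - self.metal_position))
            for res, atom, pos, _ in self.coordinating_atoms
        }


@dataclass(frozen=True)
class DummyModel:
    """Cu2+ core plus six dummy particles in a distorted octahedron."""

    core_position: np.ndarray
    core_charge: float
    eq_charge: float
    ax_charge: float
    eq_distance: float
    ax_distance: float
    dummy_positions: np.ndarray  # (6, 3): 4 equatorial then 2 axial
    axis: np.ndarray  # unit vector

    def __post_init__(self) -> None:
        total = self.core_charge + 4 * self.eq_charge + 2 * self.ax_charge
        if abs(total - 2.0) > 1e-12:
            raise ValueError(f"total site charge must be +2.0 e, got {total}")
        if self.ax_distance < self.eq_distance:
            raise ValueError("axial distance must be >= equatorial (Jahn-Teller elongation)")
        rel = self.dummy_positions - self.core_position
        dist = np.linalg.norm(rel, axis=1)
        expect = np.array([self.eq_distance] * 4 + [self.ax_distance] * 2)
        if not np.allclose(dist, expect, atol=1e-9):
            raise ValueError("dummy distances deviate from their class values")
        # the four equatorial arms must form two orthogonal (+/-) pairs
        eq = rel[:4] / self.eq_distance
        if not (
            np.allclose(eq[0], -eq[1], atol=1e-9)
            and np.allclose(eq[2], -eq[3], atol=1e-9)
            and abs(eq[0] @ eq[2]) < 1e-9
        ):
            raise ValueError("equatorial dummies are not pairwise orthogonal")

    @property
    def total_charge(self) -> float:
        return self.core_charge + 4 * self.eq_charge + 2 * self.ax_charge


@dataclass(frozen=True)
class CoordinationStats:
    """Per-partner mean/sd of the metal-partner distance over a trajectory."""

    per_partner: dict[str, tuple[float, float]]
    n_frames: int


@dataclass(frozen=True)
class RDFResult:
    r_centers: np.ndarray
    g: np.ndarray
    n_frames: int

    @property
    def first_peak(self) -> float:
        """Location of the global maximum of g(r)."""
        return float(self.r_centers[int(np.argmax(self.g))])


def default_dummy_params() -> dict:
    """Packaged placeholder charges/distances satisfying the model invariants."""
    with resources.files("tyrlie.data").joinpath("dummy_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def read_structure(path: str) -> struc.AtomArray:
    """First model of a PDB file as a biotite AtomArray."""
    return PDBFile.read(path).get_structure(model=1)


def save_structure(structure: struc.AtomArray, path: str) -> None:
    pdb = PDBFile()
    pdb.set_structure(structure)
    pdb.write(path)


def detect_metal_sites(structure: struc.AtomArray, cutoff: float = 3.0) -> list[MetalSite]:
    """Find every Cu ion and its coordinating His nitrogens and water oxygens.

    Coordination partners are side-chain N atoms of histidine (ND1/NE2) and
    water O atoms within ``cutoff`` angstrom of the metal, sorted by distance.
    A structure without copper yields an empty list.
    """
    is_cu = np.char.upper(structure.element.astype("U4")) == "CU"
    sites = []
    for cu in structure[is_cu]:
        partners = []
        for atom in structure:
            if str(atom.element).upper() == "CU":
                continue
            res_name = str(atom.res_name).strip()
            atom_name = str(atom.atom_name).strip()
            if res_name == "HIS" and atom_name in ("ND1", "NE2"):
                cls = "protein"
            elif res_name in WATER_RES_NAMES and str(atom.element).upper() == "O":
                cls = "water"
            else:
                continue
            d = float(np.linalg.norm(atom.coord - cu.coord))
            if d <= cutoff:
                label = f"{res_name.capitalize()}{atom.res_id}"
                partners.append((d, label, atom_name, np.array(atom.coord, float), cls))
        partners.sort(key=lambda t: (t[0], t[1], t[2]))
        sites.append(
            MetalSite(
                metal_label=f"CU_{cu.res_id}",
                metal_position=np.array(cu.coord, dtype=float),
                coordinating_atoms=[(l, a, p, c) for _, l, a, p, c in partners],
            )
        )
    return sites


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Any right-handed pair (u, v) spanning the plane orthogonal to axis."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def build_dummy_model(
    site: MetalSite,
    params: dict | None = None,
    axial_partner: str | None = None,
) -> DummyModel:
    """Place six dummy particles around a metal site.

    The axial direction points at the coordinating partner with the largest
    metal distance — the Jahn-Teller-elongated contact — unless
    ``axial_partner`` names one explicitly (``"<residue_label>_<atom_name>"``).
    The two axial dummies sit along +/- this axis; the four equatorial
    dummies lie in the orthogonal plane, rotated so their fourfold direction
    set best aligns (circular-mean sense) with the azimuths of the remaining
    coordinating atoms.
    """
    params = params or default_dummy_params()
    atoms = site.coordinating_atoms
    if len(atoms) < 3:
        raise GeometryError(
            f"site {site.metal_label} has {len(atoms)} coordinating atoms; >= 3 needed"
        )
    directions = np.array([p - site.metal_position for _, _, p, _ in atoms])
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms < 1e-9):
        raise OrientationError("a coordinating atom coincides with the metal")
    unit = directions / norms[:, None]
    if np.linalg.matrix_rank(unit, tol=1e-6) < 2:
        raise OrientationError(f"coordination of {site.metal_label} is collinear")

    labels = [f"{res}_{atom}" for res, atom, _, _ in atoms]
    if axial_partner is not None:
        if axial_partner not in labels:
            raise GeometryError(f"axial partner {axial_partner!r} not coordinated to the site")
        i_ax = labels.index(axial_partner)
    else:
        i_ax = int(np.argmax(norms))
    axis = unit[i_ax]

    u, v = _orthonormal_frame(axis)
    # fourfold circular mean of the remaining partners' azimuths; invariant
    # under the 90-degree symmetry of the equatorial arms and under rigid
    # motions of the whole site
    s = c = 0.0
    for j in range(len(atoms)):
        if j == i_ax:
            continue
        x, y = unit[j] @ u, unit[j] @ v
        if np.hypot(x, y) < 1e-9:
            continue
        phi = np.arctan2(y, x)
        s += np.sin(4 * phi)
        c += np.cos(4 * phi)
    theta = 0.0 if (s == 0.0 and c == 0.0) else float(np.arctan2(s, c)) / 4.0

    e1 = np.cos(theta) * u + np.sin(theta) * v
    e2 = np.cross(axis, e1)
    eq_d = float(params["eq_distance"])
    ax_d = float(params["ax_distance"])
    dummy_positions = site.metal_position + np.vstack(
        [eq_d * e1, -eq_d * e1, eq_d * e2, -eq_d * e2, ax_d * axis, -ax_d * axis]
    )
    return DummyModel(
        core_position=site.metal_position,
        core_charge=float(params["core_charge"]),
        eq_charge=float(params["eq_charge"]),
        ax_charge=float(params["ax_charge"]),
        eq_distance=eq_d,
        ax_distance=ax_d,
        dummy_positions=dummy_positions,
        axis=axis,
    )


def write_structure_with_dummies(
    structure: struc.AtomArray, models: list[DummyModel]
) -> struc.AtomArray:
    """Append HETATM records for each dummy model (CU core + DE1-DE4, DA1-DA2).

    Each model becomes one new hetero residue "CUD" on chain "D" with a fresh
    residue id; the original records are preserved unchanged.
    """
    if not models:
        raise ValueError("no dummy models given")
    existing = {
        (str(rn).strip(), str(an).strip())
        for rn, an in zip(structure.res_name, structure.atom_name)
    }
    for name in DUMMY_ATOM_NAMES:
        if ("CUD", name) in existing:
            raise ValueError(f"atom name collision: structure already has CUD/{name}")

    next_res_id = int(structure.res_id.max()) + 1 if len(structure) else 1
    pieces = [structure]
    for k, model in enumerate(models):
        n = 7
        arr = struc.AtomArray(n)
        arr.coord = np.vstack([model.core_position[None, :], model.dummy_positions])
        arr.chain_id = np.full(n, "D", dtype="U4")
        arr.res_id = np.full(n, next_res_id + k, dtype=int)
        arr.res_name = np.full(n, "CUD", dtype="U5")
        arr.atom_name = np.array(("CU",) + DUMMY_ATOM_NAMES, dtype="U6")
        arr.element = np.array(["CU"] + ["D"] * 6, dtype="U2")
        arr.hetero = np.ones(n, dtype=bool)
        if "occupancy" in structure.get_annotation_categories():
            arr.set_annotation("occupancy", np.ones(n))
        if "b_factor" in structure.get_annotation_categories():
            arr.set_annotation("b_factor", np.zeros(n))
        pieces.append(arr)
    return struc.concatenate(pieces)


# ---------------------------------------------------------------------------
# trajectory analysis (frame table: columns frame, atom_label, x, y, z)
# ---------------------------------------------------------------------------

def read_frame_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("frame", "atom_label", "x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trajectory column(s) {', '.join(missing)}")
    return df


def write_frame_table(frames: pd.DataFrame, path: str) -> None:
    frames.to_csv(path, index=False, float_format="%.4f")


def _coords_by_label(frames: pd.DataFrame, label: str) -> np.ndarray:
    """(n_frames, 3) coordinates of one atom, validated frame by frame."""
    sub = frames[frames["atom_label"] == label]
    if sub.empty:
        raise SelectionError(f"atom {label!r} not present in the trajectory")
    n_frames = int(frames["frame"].max()) + 1
    if len(sub) != n_frames:
        present = set(sub["frame"])
        missing = next(i for i in range(n_frames) if i not in present)
        raise FrameError(f"atom {label!r} missing from frame {missing}")
    sub = sub.sort_values("frame", kind="stable")
    return sub[["x", "y", "z"]].to_numpy(float)


def coordination_distances(
    frames: pd.DataFrame, metal_label: str, partners: list[str]
) -> CoordinationStats:
    """Mean and sd of the metal-partner distance for each named partner."""
    metal = _coords_by_label(frames, metal_label)
    per_partner = {}
    for label in partners:
        pos = _coords_by_label(frames, label)
        d = np.linalg.norm(pos - metal, axis=1)
        per_partner[label] = (float(d.mean()), float(d.std(ddof=1)) if len(d) > 1 else 0.0)
    return CoordinationStats(per_partner=per_partner, n_frames=len(metal))


def jahn_teller_score(
    stats: CoordinationStats,
    axial_partners: list[str] | str,
    equatorial_partners: list[str],
) -> float:
    """Axial elongation ratio: mean axial distance / mean equatorial distance.

    Values above 1 indicate the tetragonal (Jahn-Teller) distortion of the
    octahedron; a perfect octahedron scores exactly 1.
    """
    if isinstance(axial_partners, str):
        axial_partners = [axial_partners]
    if not axial_partners or not equatorial_partners:
        raise ValueError("axial and equatorial partner sets must be non-empty")
    for label in list(axial_partners) + list(equatorial_partners):
        if label not in stats.per_partner:
            raise KeyError(f"partner {label!r} not in the coordination statistics")
    ax = np.mean([stats.per_partner[l][0] for l in axial_partners])
    eq = np.mean([stats.per_partner[l][0] for l in equatorial_partners])
    return float(ax / eq)


def radial_distribution(
    frames: pd.DataFrame,
    center_label: str,
    species_labels: list[str],
    r_max: float = 6.0,
    n_bins: int = 60,
) -> RDFResult:
    """Radial distribution function g(r) of selected atoms around a center.

    Distances from the center to every selected atom are histogrammed over
    all frames and normalised by the spherical-shell volume and the mean
    number density of the selected species inside the r_max sphere. The
    normalisation assumes a non-periodic (droplet-style) system; for ideal
    uniformly distributed atoms g(r) -> 1.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if not species_labels:
        raise SelectionError("empty species selection")
    center = _coords_by_label(frames, center_label)
    n_frames = len(center)
    dists = []
    for label in species_labels:
        pos = _coords_by_label(frames, label)
        dists.append(np.linalg.norm(pos - center, axis=1))
    d = np.concatenate(dists)  # n_frames * n_species distances
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    mean_counts = counts / n_frames
    n_inside = float(np.sum(d <= r_max)) / n_frames
    if n_inside == 0:
        raise SelectionError(f"no selected atoms within r_max={r_max} of {center_label!r}")
    rho = n_inside / (4.0 / 3.0 * np.pi * r_max**3)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = mean_counts / (shell_vol * rho)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r_centers=centers, g=g, n_frames=n_frames)
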