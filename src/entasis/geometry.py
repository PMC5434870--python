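"""Internal coordinates, the τ4 index, Kabsch superposition and summaries.

The coordination-site statistics mirror how metalloprotein trajectory
tables are usually reported: per-frame internal coordinates averaged over
the simulation, with the root-mean-square fluctuation about the mean in
parentheses. Angular quantities use circular statistics so a dihedral
oscillating across the ±180° seam averages to 180°, not 0°.

Two averaging conventions coexist deliberately:

* :func:`geometry_summary` computes statistics of per-frame internal
  coordinates (the table convention);
* :func:`ensemble_average_structure` averages superposed Cartesian
  coordinates and is meant for the strain-energy workflow, where a single
  representative geometry is evaluated on a potential-energy surface.

τ4 on a fluctuating site differs between the two conventions; both are
exposed and neither is privileged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, TrajectoryError
from .structure_io import Structure, Trajectory, select_atoms

__all__ = [
    "InternalCoordinateSpec",
    "internal_coordinate",
    "tau4",
    "kabsch_superpose",
    "rmsd_series",
    "ensemble_average_structure",
    "geometry_summary",
    "circular_mean_deg",
    "circular_rms_deg",
]

CoordKind = Literal["distance", "angle", "dihedral", "improper"]

_ARITY = {"distance": 2, "angle": 3, "dihedral": 4, "improper": 4}
# atoms closer than this are treated as coincident
_COINCIDENT_TOL = 1e-8


@dataclass(frozen=True)
class InternalCoordinateSpec:
    """One row of a geometry summary: a labelled distance/angle/torsion.

    ``atom_refs`` are resolved per frame via :meth:`Structure.index_of`
    (indices, unique names, or (name, resnum, chain) tuples). An improper
    torsion is evaluated with the dihedral formula on the four atoms in the
    given order; the distinction is retained as metadata because tables
    list impropers separately.
    """

    kind: CoordKind
    atom_refs: tuple
    label: str

    def __post_init__(self) -> None:
        if self.kind not in _ARITY:
            raise ValueError(f"unknown internal-coordinate kind {self.kind!r}")
        refs = tuple(self.atom_refs)
        object.__setattr__(self, "atom_refs", refs)
        if len(refs) != _ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} needs {_ARITY[self.kind]} atoms, got {len(refs)}"
            )
        if len(set(refs)) != len(refs):
            raise ValueError(f"atom references must be distinct: {refs}")

    @property
    def is_angular(self) -> bool:
        return self.kind != "distance"


def _positions(frame: Structure, spec: InternalCoordinateSpec) -> np.ndarray:
    idx = [frame.index_of(r) for r in spec.atom_refs]
    return frame.coords[idx]


def internal_coordinate(frame: Structure, spec: InternalCoordinateSpec) -> float:
    """Evaluate one internal coordinate on one frame (Å or degrees).

    Distances are non-negative; angles lie in [0°, 180°]; dihedrals and
    impropers are signed in (−180°, 180°] with the right-hand (IUPAC,
    cis = 0°) convention.
    """
    p = _positions(frame, spec)
    if spec.kind == "distance":
        return float(np.linalg.norm(p[1] - p[0]))
    if spec.kind == "angle":
        return _angle_deg(p[0], p[1], p[2])
    return _dihedral_deg(p[0], p[1], p[2], p[3])


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _COINCIDENT_TOL or nv < _COINCIDENT_TOL:
        raise DegenerateGeometryError("coincident atoms in angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _dihedral_deg(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    if np.linalg.norm(b2) < _COINCIDENT_TOL:
        raise DegenerateGeometryError("coincident central atoms in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COINCIDENT_TOL or np.linalg.norm(n2) < _COINCIDENT_TOL:
        raise DegenerateGeometryError("collinear atoms make dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 to +180 so the range is (-180, 180]
    if ang <= -180.0 + 1e-12:
        ang += 360.0
    return float(ang)


# --------------------------------------------------------------------------
# tau4
# --------------------------------------------------------------------------

def tau4(angles_deg: Sequence[float]) -> float:
    """Four-coordinate geometry index τ4 = (360° − (α + β)) / 141°.

    α and β are the two largest coordination angles (multiset selection:
    a tied maximum counts twice). τ4 is 0 for a square-planar site (two
    180° trans angles) and 1 for an ideal tetrahedron (all angles
    109.47°); intermediate values flag distorted four-coordination.
    """
    angles = [float(a) for a in angles_deg]
    if len(angles) < 2:
        raise ValueError("tau4 needs at least two coordination angles")
    for a in angles:
        if not 0.0 < a <= 180.0:
            raise ValueError(f"coordination angle {a} outside (0, 180] degrees")
    largest = sorted(angles, reverse=True)[:2]
    return (360.0 - sum(largest)) / 141.0


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

def _subset_coords(structure: Structure, subset) -> np.ndarray:
    if subset is None:
        return structure.coords
    return select_atoms(structure, subset).coords


def kabsch_superpose(mobile: Structure, reference: Structure,
                     subset=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with ``rotation`` a proper
    (det = +1) 3×3 matrix such that ``coords @ rotation.T + translation``
    maps mobile onto reference with the least-squares minimum RMSD over
    the subset. Unweighted (no masses).
    """
    x = _subset_coords(mobile, subset)
    y = _subset_coords(reference, subset)
    if x.shape != y.shape:
        raise TrajectoryError(
            f"subset sizes differ: {x.shape[0]} vs {y.shape[0]} atoms"
        )
    n = x.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # collinearity: fewer than 2 significant principal axes
    sv = np.linalg.svd(x0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("collinear subset: rotation underdetermined")

    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    diff = x0 @ rot.T - y0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rot, trans, rmsd


def apply_rigid(structure: Structure, rotation: np.ndarray,
                translation: np.ndarray) -> Structure:
    """Return the structure transformed by a rotation + translation."""
    return Structure(structure.atoms,
                     structure.coords @ rotation.T + translation)


def rmsd_series(trajectory: Trajectory, reference_index: int = 0,
                subset=None) -> np.ndarray:
    """Minimum RMSD of every frame to the frame at ``reference_index`` (Å)."""
    if not 0 <= reference_index < len(trajectory):
        raise TrajectoryError(f"reference index {reference_index} out of range")
    ref = trajectory.frames[reference_index]
    return np.array([
        kabsch_superpose(f, ref, subset)[2] for f in trajectory.frames
    ])


def ensemble_average_structure(trajectory: Trajectory, subset=None) -> Structure:
    """Superpose every frame onto frame 0 over ``subset``, then average.

    Single-pass and deterministic: the superposition target is frame 0,
    not an iteratively refined mean structure. The rigid transform fitted
    on the subset is applied to the whole frame before averaging.
    """
    ref = trajectory.frames[0]
    acc = np.zeros_like(ref.coords)
    for frame in trajectory.frames:
        rot, trans, _ = kabsch_superpose(frame, ref, subset)
        acc += frame.coords @ rot.T + trans
    return Structure(ref.atoms, acc / len(trajectory))


# --------------------------------------------------------------------------
# circular statistics and summaries
# --------------------------------------------------------------------------

def circular_mean_deg(values_deg: np.ndarray) -> float:
    """Circular mean mapped to (−180°, 180°]."""
    rad = np.radians(np.asarray(values_deg, dtype=float))
    mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    if mean <= -180.0 + 1e-12:
        mean += 360.0
    return float(mean)


def _wrap_deg(delta: np.ndarray) -> np.ndarray:
    """Wrap angular differences into (−180, 180]."""
    return (np.asarray(delta) + 180.0) % 360.0 - 180.0


def circular_rms_deg(values_deg: np.ndarray) -> float:
    """Population RMS deviation about the circular mean, in degrees."""
    mean = circular_mean_deg(values_deg)
    dev = _wrap_deg(np.asarray(values_deg, dtype=float) - mean)
    return float(np.sqrt(np.mean(dev ** 2)))


def geometry_summary(trajectory: Trajectory,
                     specs: Sequence[InternalCoordinateSpec]) -> pd.DataFrame:
    """Tables-style statistics of internal coordinates over a trajectory.

    For distances: arithmetic mean and population RMS deviation. For
    angles/dihedrals/impropers: circular mean (degrees, in (−180, 180])
    and circular RMS deviation. Columns: label, kind, mean, rms, n.
    """
    rows = []
    for spec in specs:
        vals = np.array([internal_coordinate(f, spec) for f in trajectory.frames])
        if spec.is_angular:
            mean = circular_mean_deg(vals)
            rms = circular_rms_deg(vals)
        else:
            mean = float(vals.mean())
            rms = float(np.sqrt(np.mean((vals - mean) ** 2)))
        rows.append({"label": spec.label, "kind": spec.kind,
                     "mean": mean, "rms": rms, "n": len(vals)})
    return pd.DataFrame(rows, columns=["label", "kind", "mean", "rms", "n"])
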