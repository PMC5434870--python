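"""Structures, trajectories and energy-gap tables.

This module owns the three container types the pipeline passes around —
:class:`Structure`, :class:`Trajectory` and :class:`GapSeries` — plus the
readers/writers for the plain-text formats they travel in (PDB, XYZ, TSV).

Conventions: coordinates are Å, energies kcal/mol, times ps. Atom order is
the identity key across trajectory frames; names are never re-matched,
because simulation outputs preserve order.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    OrderingError,
    ParseError,
    SchemaError,
    SelectionError,
    TrajectoryError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "GapSeries",
    "read_pdb",
    "read_xyz_trajectory",
    "read_energy_table",
    "select_atoms",
    "write_table",
    "write_pdb",
    "write_xyz_trajectory",
]

STATE_LABELS = ("oxidized", "reduced")


# --------------------------------------------------------------------------
# container types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom's identity; coordinates live on the owning Structure."""

    name: str
    element: str
    residue_name: str = "UNK"
    residue_number: int = 1
    chain: str = "A"

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity key, unique within a structure."""
        return (self.name, self.residue_number, self.chain)


@dataclass
class Structure:
    """A single conformation: named atoms with Cartesian coordinates in Å."""

    atoms: list[Atom]
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.atoms) == 0:
            raise EmptyInputError("structure has no atoms")
        if self.coords.shape != (len(self.atoms), 3):
            raise TrajectoryError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ParseError("non-finite coordinate in structure")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise TrajectoryError(f"duplicate atom identifier {dup} in structure")

    def __len__(self) -> int:
        return len(self.atoms)

    def index_of(self, ref) -> int:
        """Resolve an atom reference to its index.

        A reference may be an integer index, a unique atom name, or a
        ``(name, residue_number, chain)`` tuple.
        """
        from .errors import LookupError_

        if isinstance(ref, (int, np.integer)):
            if not 0 <= ref < len(self.atoms):
                raise LookupError_(f"atom index {ref} out of range")
            return int(ref)
        if isinstance(ref, str):
            hits = [i for i, a in enumerate(self.atoms) if a.name == ref]
            if len(hits) != 1:
                raise LookupError_(
                    f"atom name {ref!r} matched {len(hits)} atoms (need exactly 1)"
                )
            return hits[0]
        if isinstance(ref, tuple) and len(ref) == 3:
            key = (str(ref[0]), int(ref[1]), str(ref[2]))
            hits = [i for i, a in enumerate(self.atoms) if a.key == key]
            if len(hits) != 1:
                raise LookupError_(f"atom key {key} matched {len(hits)} atoms")
            return hits[0]
        raise LookupError_(f"unsupported atom reference {ref!r}")

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = list(indices)
        return Structure([self.atoms[i] for i in idx], self.coords[idx])


@dataclass
class Trajectory:
    """Ordered frames over an identical atom set, with optional times in ps."""

    frames: list[Structure]
    times: np.ndarray | None = None  # ps, strictly increasing

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise EmptyInputError("trajectory has no frames")
        ref_keys = [a.key for a in self.frames[0].atoms]
        for i, fr in enumerate(self.frames[1:], start=1):
            if [a.key for a in fr.atoms] != ref_keys:
                raise TrajectoryError(
                    f"frame {i} atom set differs from frame 0 "
                    f"({len(fr)} vs {len(ref_keys)} atoms or reordered)"
                )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.frames):
                raise TrajectoryError(
                    f"{len(self.times)} timestamps for {len(self.frames)} frames"
                )
            if np.any(np.diff(self.times) <= 0):
                raise OrderingError("trajectory times not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    def coords_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class GapSeries:
    """Per-frame two-state energies and the vertical gap ΔE = E_ox − E_red.

    ``state`` records which potential-energy surface generated the sampled
    configurations (the ensemble), not which energy is reported: both state
    energies are evaluated at every frame.
    """

    times: np.ndarray  # ps
    delta_e: np.ndarray  # kcal/mol
    state: str
    e_ox: np.ndarray | None = None
    e_red: np.ndarray | None = None

    def __post_init__(self) -> None:
        from .errors import StateLabelError

        self.times = np.asarray(self.times, dtype=float)
        self.delta_e = np.asarray(self.delta_e, dtype=float)
        if self.state not in STATE_LABELS:
            raise StateLabelError(
                f"state must be one of {STATE_LABELS}, got {self.state!r}"
            )
        if self.times.shape != self.delta_e.shape or self.times.ndim != 1:
            raise SchemaError("times and delta_e must be equal-length 1-D arrays")
        if len(self.times) == 0:
            raise EmptyInputError("gap series has no frames")
        if np.any(np.diff(self.times) <= 0):
            raise OrderingError("gap-series times not strictly increasing")
        for name in ("e_ox", "e_red"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                setattr(self, name, arr)
                if arr.shape != self.times.shape:
                    raise SchemaError(f"{name} length does not match times")
        if self.e_ox is not None and self.e_red is not None:
            if not np.allclose(self.delta_e, self.e_ox - self.e_red, atol=1e-9):
                raise SchemaError("delta_e inconsistent with e_ox - e_red")

    def __len__(self) -> int:
        return len(self.times)

    def to_records(self) -> list[dict]:
        rows = []
        for i in range(len(self)):
            row: dict = {"time": self.times[i]}
            if self.e_ox is not None:
                row["e_ox"] = self.e_ox[i]
            if self.e_red is not None:
                row["e_red"] = self.e_red[i]
            row["delta_e"] = self.delta_e[i]
            row["state"] = self.state
            rows.append(row)
        return rows


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    """PDB element heuristic for files lacking columns 77-78.

    Leading digits are stripped (e.g. ``1HB``); a two-letter element is
    assumed only when the name starts in column 13 with a recognised
    two-letter symbol, otherwise the first letter is the element.
    """
    name = atom_name.strip()
    name = name.lstrip("0123456789")
    if not name:
        return "X"
    two = name[:2].capitalize()
    if two in {"Cu", "Fe", "Zn", "Mn", "Mg", "Na", "Cl", "Br", "Se", "Ca", "Ni", "Co"}:
        return two
    return name[0].upper()


def read_pdb(stream: TextIO | str) -> list[Structure]:
    """Parse PDB text into one :class:`Structure` per MODEL.

    Fixed-column parsing of ATOM/HETATM records only (name 13-16,
    resName 18-20, chainID 22, resSeq 23-26, x/y/z 31-38/39-46/47-54);
    MODEL/ENDMDL delimit frames, every other record type is ignored.
    Alternate locations other than blank or 'A' are skipped with a warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    models: list[tuple[list[Atom], list[list[float]]]] = []
    atoms: list[Atom] = []
    xyz: list[list[float]] = []
    in_model = False
    saw_model_record = False

    def flush() -> None:
        nonlocal atoms, xyz
        if atoms:
            models.append((atoms, xyz))
        atoms, xyz = [], []

    for lineno, raw in enumerate(stream, start=1):
        rec = raw[:6].strip()
        if rec == "MODEL":
            saw_model_record = True
            flush()
            in_model = True
            continue
        if rec == "ENDMDL":
            flush()
            in_model = False
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        line = raw.rstrip("\n")
        if len(line) < 54:
            raise ParseError(f"line {lineno}: ATOM record shorter than 54 columns")
        altloc = line[16] if len(line) > 16 else " "
        if altloc not in (" ", "A"):
            warnings.warn(
                f"line {lineno}: skipping alternate location {altloc!r}",
                stacklevel=2,
            )
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed coordinate field") from exc
        name = line[12:16].strip()
        res_name = line[17:20].strip() or "UNK"
        chain = line[21].strip() or "A"
        try:
            res_num = int(line[22:26])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed residue number") from exc
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(name)
        atoms.append(Atom(name, element.capitalize(), res_name, res_num, chain))
        xyz.append([x, y, z])

    flush()
    if not models:
        raise EmptyInputError("no ATOM/HETATM records found")
    if saw_model_record and in_model:
        warnings.warn("final MODEL not closed by ENDMDL", stacklevel=2)
    return [Structure(a, np.array(c)) for a, c in models]


def write_pdb(structures: Structure | Sequence[Structure], stream: TextIO) -> None:
    """Write one or more structures as (multi-MODEL) PDB text."""
    if isinstance(structures, Structure):
        structures = [structures]
    multi = len(structures) > 1
    for imodel, s in enumerate(structures, start=1):
        if multi:
            stream.write(f"MODEL {imodel:>8d}\n")
        for serial, (atom, pos) in enumerate(zip(s.atoms, s.coords), start=1):
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            stream.write(
                f"ATOM  {serial:>5d} {name:<4.4s} {atom.residue_name:<3.3s} "
                f"{atom.chain:1.1s}{atom.residue_number:>4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2.2s}\n"
            )
        if multi:
            stream.write("ENDMDL\n")
    stream.write("END\n")


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------

def read_xyz_trajectory(stream: TextIO | str) -> Trajectory:
    """Read a concatenated-frame XYZ file into a Trajectory.

    Element symbols become atom names; residue metadata is synthesized
    (each atom gets its index as residue number so identity keys stay
    unique).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    frames: list[Structure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected atom count") from exc
        body = lines[i + 2 : i + 2 + count]
        if len(body) < count:
            raise ParseError(
                f"frame starting at line {i + 1}: header says {count} atoms "
                f"but only {len(body)} coordinate lines present"
            )
        atoms, xyz = [], []
        for j, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + j}: expected 'element x y z'")
            try:
                pos = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"line {i + 3 + j}: malformed coordinate") from exc
            atoms.append(Atom(parts[0], parts[0].capitalize(), "UNK", j + 1, "A"))
            xyz.append(pos)
        frames.append(Structure(atoms, np.array(xyz)))
        i += 2 + count
    if not frames:
        raise EmptyInputError("no XYZ frames found")
    return Trajectory(frames)


def write_xyz_trajectory(trajectory: Trajectory, stream: TextIO,
                         precision: int = 6) -> None:
    for k, frame in enumerate(trajectory.frames):
        stream.write(f"{len(frame)}\n")
        t = "" if trajectory.times is None else f" t={trajectory.times[k]:g} ps"
        stream.write(f"frame {k}{t}\n")
        for atom, pos in zip(frame.atoms, frame.coords):
            stream.write(
                f"{atom.element:<3s} {pos[0]:.{precision}f} "
                f"{pos[1]:.{precision}f} {pos[2]:.{precision}f}\n"
            )


# --------------------------------------------------------------------------
# energy tables
# --------------------------------------------------------------------------

def read_energy_table(stream: TextIO | str, state: str | None = None) -> GapSeries:
    """Read a TSV/CSV two-state energy table into a :class:`GapSeries`.

    Accepts either (time, e_ox, e_red) or (time, delta_e) column layouts,
    with '#' comment lines permitted. The sampled-state label comes from a
    ``state`` column (which must be single-valued) or the ``state`` argument.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        df = pd.read_csv(stream, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError("energy table is empty") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "time" not in df.columns:
        raise SchemaError("energy table needs a 'time' column")
    if len(df) == 0:
        raise EmptyInputError("energy table has a header but no rows")

    numeric_cols = ["time"] + [c for c in ("e_ox", "e_red", "delta_e")
                               if c in df.columns]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ParseError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = converted

    times = df["time"].to_numpy()
    if np.any(np.diff(times) <= 0):
        raise OrderingError("times not strictly increasing in energy table")

    if "state" in df.columns:
        labels = set(df["state"].astype(str).str.strip())
        if len(labels) != 1:
            raise SchemaError(f"state column carries multiple labels: {labels}")
        state = labels.pop()
    if state is None:
        raise SchemaError("no state column and no state label supplied")

    e_ox = df["e_ox"].to_numpy() if "e_ox" in df.columns else None
    e_red = df["e_red"].to_numpy() if "e_red" in df.columns else None
    if "delta_e" in df.columns:
        delta = df["delta_e"].to_numpy()
    elif e_ox is not None and e_red is not None:
        delta = e_ox - e_red
    else:
        raise SchemaError("need either delta_e or both e_ox and e_red columns")
    return GapSeries(times=times, delta_e=delta, state=state, e_ox=e_ox, e_red=e_red)


def write_table(rows: Iterable[Mapping], stream: TextIO, precision: int = 6,
                columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as TSV with a header.

    Floats are rendered with ``precision`` significant digits; the output
    round-trips through :func:`read_energy_table` / ``pandas.read_csv``.
    An empty record list still produces a header when ``columns`` is given.
    """
    rows = list(rows)
    if not rows:
        if columns:
            stream.write("\t".join(columns) + "\n")
            return
        raise SchemaError("no records and no column list to write a header from")
    keys = list(rows[0].keys())
    for i, r in enumerate(rows):
        if list(r.keys()) != keys:
            raise SchemaError(f"record {i} fields {list(r.keys())} != {keys}")
    if columns is not None and list(columns) != keys:
        raise SchemaError("explicit column list does not match record fields")

    def fmt(v) -> str:
        if isinstance(v, (float, np.floating)):
            return f"{v:.{precision}g}"
        return str(v)

    stream.write("\t".join(keys) + "\n")
    for r in rows:
        stream.write("\t".join(fmt(r[k]) for k in keys) + "\n")


# --------------------------------------------------------------------------
# atom selection
# --------------------------------------------------------------------------

_SELECTION_KEYS = {"residue_numbers", "residue_names", "atom_names",
                   "exclude_elements"}


def select_atoms(structure: Structure, spec: Mapping | None) -> Structure:
    """Select a subset of atoms by conjunction of simple criteria.

    ``spec`` maps any of ``residue_numbers``, ``residue_names``,
    ``atom_names`` (inclusion lists, AND-ed together) and
    ``exclude_elements`` to lists. ``None`` or an empty mapping selects
    everything. Source order is preserved; an empty result is allowed but
    raises a warning.
    """
    if spec is None:
        spec = {}
    if not isinstance(spec, Mapping):
        raise SelectionError(f"selection spec must be a mapping, got {type(spec)}")
    unknown = set(spec) - _SELECTION_KEYS
    if unknown:
        raise SelectionError(f"unknown selection keys {sorted(unknown)}; "
                             f"allowed: {sorted(_SELECTION_KEYS)}")
    for key, value in spec.items():
        if isinstance(value, (str, bytes)) or not isinstance(value, Iterable):
            raise SelectionError(f"selection key {key!r} must map to a list")

    res_nums = {int(v) for v in spec.get("residue_numbers", [])} or None
    res_names = {str(v).upper() for v in spec.get("residue_names", [])} or None
    atom_names = {str(v).upper() for v in spec.get("atom_names", [])} or None
    excl = {str(v).capitalize() for v in spec.get("exclude_elements", [])}

    keep = []
    for i, a in enumerate(structure.atoms):
        if res_nums is not None and a.residue_number not in res_nums:
            continue
        if res_names is not None and a.residue_name.upper() not in res_names:
            continue
        if atom_names is not None and a.name.upper() not in atom_names:
            continue
        if a.element.capitalize() in excl:
            continue
        keep.append(i)
    if not keep:
        warnings.warn("atom selection matched no atoms", stacklevel=2)
        return _empty_subset(structure)
    return structure.subset(keep)


def _empty_subset(structure: Structure) -> Structure:
    """An empty selection result; bypasses the non-empty invariant on purpose."""
    s = Structure.__new__(Structure)
    s.atoms = []
    s.coords = np.empty((0, 3))
    return s


def select_trajectory(trajectory: Trajectory, spec: Mapping | None) -> Trajectory:
    """Apply the same atom selection to every frame."""
    if spec is None or not spec:
        return trajectory
    idx = [trajectory.frames[0].index_of(a.key)
           for a in select_atoms(trajectory.frames[0], spec).atoms]
    if not idx:
        raise SelectionError("selection matched no atoms in trajectory")
    return Trajectory([f.subset(idx) for f in trajectory.frames],
                      trajectory.times)
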