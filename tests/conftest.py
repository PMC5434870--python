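import numpy as np
import pytest

from entasis.structure_io import Atom, Structure, Trajectory


@pytest.fixture
def square_structure() -> Structure:
    """Five heavy atoms: one central, four in a plane (non-collinear)."""
    atoms = [
        Atom("CU", "Cu", "CU", 100, "A"),
        Atom("SG", "S", "CYS", 87, "A"),
        Atom("SD", "S", "MET", 95, "A"),
        Atom("ND1", "N", "HIS", 37, "A"),
        Atom("ND2", "N", "HIS", 90, "A"),
    ]
    coords = np.array([
        [0.0, 0.0, 0.0],
        [2.0, 0.0, 0.0],
        [0.0, 2.0, 0.0],
        [-2.0, 0.0, 0.5],
        [0.0, -2.0, 0.5],
    ])
    return Structure(atoms, coords)


@pytest.fixture
def pdb_text() -> str:
    """Two-MODEL PDB with three atoms each; fixed-column formatted."""

    def atom_line(serial, name, res, chain, resnum, x, y, z, element):
        pad_name = name if len(name) >= 4 else f" {name:<3s}"
        return (f"ATOM  {serial:>5d} {pad_name:<4s} {res:<3s} {chain}"
                f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {element:>2s}")

    lines = ["HEADER    SYNTHETIC TEST STRUCTURE", "MODEL        1"]
    lines += [
        atom_line(1, "CU", "CU", "A", 100, 1.000, 2.000, 3.000, "CU"),
        atom_line(2, "SG", "CYS", "A", 87, 2.500, 0.000, 0.000, "S"),
        atom_line(3, "ND1", "HIS", "A", 37, 0.000, 2.500, 0.000, "N"),
        "ENDMDL",
        "MODEL        2",
        atom_line(1, "CU", "CU", "A", 100, 1.100, 2.100, 3.100, "CU"),
        atom_line(2, "SG", "CYS", "A", 87, 2.600, 0.100, 0.000, "S"),
        atom_line(3, "ND1", "HIS", "A", 37, 0.100, 2.600, 0.000, "N"),
        "ENDMDL",
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def constant_trajectory(structure: Structure, n: int) -> Trajectory:
    return Trajectory([Structure(structure.atoms, structure.coords.copy())
                       for _ in range(n)],
                      times=np.arange(1, n + 1, dtype=float))
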