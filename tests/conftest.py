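"""Shared fixtures: hand-written PDB texts and small structure builders."""

from __future__ import annotations

import numpy as np
import pytest

from oligotopo.structio import StructureModel


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz,
    occ: float = 1.00,
    altloc: str = " ",
    element: str | None = None,
    record: str = "ATOM",
) -> str:
    x, y, z = xyz
    element = element or name[0]
    return (
        f"{record:<6}{serial:>5} {name:^4}{altloc}{resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}"
    )


@pytest.fixture
def two_atom_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "N", "GLY", "A", 1, (0.0, 0.0, 0.0), element="N"),
        pdb_atom_line(2, "CA", "GLY", "A", 1, (1.5, 0.0, 0.0), element="C"),
        "END",
    ]
    path = tmp_path / "two_atom.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def multimodel_pdb(tmp_path):
    """Three MODEL blocks, same two atoms, shifted per model."""
    lines = []
    for m in range(1, 4):
        lines.append(f"MODEL {m:>8}")
        lines.append(pdb_atom_line(1, "CA", "GLY", "A", 1, (float(m), 0.0, 0.0)))
        lines.append(pdb_atom_line(2, "CA", "GLY", "A", 2, (float(m), 3.8, 0.0)))
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "multi.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One atom with altlocs A (occ 0.40) and B (occ 0.60), plus a plain atom."""
    lines = [
        pdb_atom_line(1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0), occ=0.40, altloc="A"),
        pdb_atom_line(2, "CA", "GLY", "A", 1, (9.0, 0.0, 0.0), occ=0.60, altloc="B"),
        pdb_atom_line(3, "CA", "GLY", "A", 2, (3.8, 0.0, 0.0)),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def water_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0)),
        pdb_atom_line(2, "O", "HOH", "A", 101, (5.0, 5.0, 5.0), element="O", record="HETATM"),
        "END",
    ]
    path = tmp_path / "water.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_model(coords, chains=None, atom_names=None, radii=None, resnums=None, elements=None):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    chains = chains if chains is not None else ["A"] * n
    atom_names = atom_names if atom_names is not None else ["CA"] * n
    radii = radii if radii is not None else [1.87] * n
    resnums = resnums if resnums is not None else list(range(1, n + 1))
    elements = elements if elements is not None else ["C"] * n
    return StructureModel(
        chain_ids=chains,
        residue_numbers=resnums,
        residue_names=["GLY"] * n,
        atom_names=atom_names,
        elements=elements,
        coords=coords,
        vdw_radii=radii,
    )


@pytest.fixture
def single_atom_model():
    return make_model([[0.0, 0.0, 0.0]], radii=[1.7])


@pytest.fixture
def trimer_model():
    """Three 4-residue chains, well separated."""
    base = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]], float)
    coords = np.concatenate([base + [0, 0, 0], base + [0, 30, 0], base + [0, 60, 0]])
    return make_model(
        coords,
        chains=["A"] * 4 + ["B"] * 4 + ["C"] * 4,
        resnums=[1, 2, 3, 4] * 3,
    )
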