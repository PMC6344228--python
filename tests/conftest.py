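"""Shared fixtures: tiny hand-written coordinate files and toy builders."""

from __future__ import annotations

import numpy as np
import pytest

from kinland.structure import AtomRecord, StructureModel, write_pdb

# Two-atom fixture with exact, hand-chosen coordinates.
TINY_PDB = """\
ATOM      1  N   ALA A   1      11.104  13.207   2.100  1.00 10.00           N
ATOM      2  CA  ALA A   1      12.560  13.300   2.000  1.00 10.00           C
END
"""

# Altloc fixture: CA has A (occ 0.6) and B (occ 0.4); CB has a 0.5/0.5 tie.
ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.60 10.00           C
ATOM      3  CA BALA A   1       1.100   0.000   0.000  0.40 10.00           C
ATOM      4  CB AALA A   1       2.000   0.000   0.000  0.50 10.00           C
ATOM      5  CB BALA A   1       2.100   0.000   0.000  0.50 10.00           C
END
"""

# Hydrogen + ligand fixture.
HET_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.400   0.000   0.000  1.00 10.00           C
ATOM      3  HA  ALA A   1       1.400   1.000   0.000  1.00 10.00           H
HETATM    4  C1  LIG A 900       5.000   5.000   5.000  1.00 10.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture
def het_pdb(tmp_path):
    path = tmp_path / "het.pdb"
    path.write_text(HET_PDB)
    return path


def make_chain(
    n_residues: int = 100,
    chain_id: str = "A",
    start: int = 1,
    resname: str = "ALA",
    spacing: float = 3.8,
    sequence: str | None = None,
) -> StructureModel:
    """Straight synthetic chain, one N/CA/C/O/CB residue every ``spacing`` Å.

    A slight helical twist keeps the Cα trace non-collinear so Kabsch
    superposition is well defined.
    """
    three = {
        "A": "ALA", "G": "GLY", "L": "LEU", "V": "VAL", "F": "PHE",
        "Y": "TYR", "E": "GLU", "K": "LYS", "S": "SER", "T": "THR",
    }
    atoms = []
    for i in range(n_residues):
        resnum = start + i
        name3 = three[sequence[i]] if sequence else resname
        angle = 0.35 * i
        base = np.array([
            i * spacing, 2.0 * np.cos(angle), 2.0 * np.sin(angle)
        ])
        for atom_name, element, off in [
            ("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.0, 0.4, 0.0)),
            ("C", "C", (2.0, 0.0, 0.3)), ("O", "O", (2.0, -1.0, 0.0)),
            ("CB", "C", (1.0, 1.4, 0.9)),
        ]:
            pos = np.round(base + np.asarray(off), 3)
            atoms.append(AtomRecord(
                chain_id=chain_id, residue_number=resnum, insertion_code="",
                residue_name=name3, atom_name=atom_name, element=element,
                position=tuple(float(v) for v in pos),
            ))
    return StructureModel(
        identifier="chain", atoms=atoms, chain_roles={chain_id: "kinase"}
    )


def drop_residues(model: StructureModel, residues: set[int]) -> StructureModel:
    atoms = [a for a in model.atoms if a.residue_number not in residues]
    return StructureModel(model.identifier, atoms, dict(model.chain_roles))


def renumber(model: StructureModel, offset: int) -> StructureModel:
    from dataclasses import replace

    atoms = [replace(a, residue_number=a.residue_number + offset)
             for a in model.atoms]
    return StructureModel(model.identifier, atoms, dict(model.chain_roles))


@pytest.fixture
def straight_chain():
    return make_chain(100)


def write_model(model: StructureModel, tmp_path, name: str):
    path = tmp_path / name
    write_pdb(model, path)
    return path
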