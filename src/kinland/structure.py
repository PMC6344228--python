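"""Macromolecular coordinate model and I/O.

Coordinates are read with :mod:`gemmi` (PDB and mmCIF dialects) into a flat,
ordered list of :class:`AtomRecord`. Author residue numbering is preserved
throughout — it is the convention in which every kinase element (P loop,
activation segment, spines ...) is defined. No coordinate transformation is
applied on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    ConfigurationError,
    EmptySelectionError,
    StructureParseError,
    UnknownFormatError,
)

logger = logging.getLogger(__name__)

#: Chain role vocabulary used by the pipeline.
CHAIN_ROLES = ("kinase", "cyclin", "cks", "ligand", "other")

# Standard amino acids, for role guessing and sequence extraction.
_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y",
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy- or hydrogen-atom site, in author numbering."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, number, insertion code) — sorts by number then icode."""
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class StructureModel:
    """An ordered heavy-atom coordinate set with chain role annotations."""

    identifier: str
    atoms: list[AtomRecord]
    chain_roles: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def kinase_chain_id(self) -> str:
        """First chain (by chain-id sort order) annotated with role 'kinase'."""
        kin = sorted(c for c, r in self.chain_roles.items() if r == "kinase")
        if not kin:
            raise ConfigurationError(
                f"{self.identifier}: no chain has role 'kinase'"
            )
        return kin[0]

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        """Copy of the model with positions replaced (same atom order)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, position=(float(x), float(y), float(z)))
            for a, (x, y, z) in zip(self.atoms, xyz)
        ]
        return StructureModel(self.identifier, atoms, dict(self.chain_roles))


def _guess_roles(atoms: Sequence[AtomRecord]) -> dict[str, str]:
    """Longest polypeptide chain → kinase; pure-hetero chains → ligand."""
    by_chain: dict[str, list[AtomRecord]] = {}
    for a in atoms:
        by_chain.setdefault(a.chain_id, []).append(a)
    roles: dict[str, str] = {}
    best_chain, best_len = None, -1
    for cid, chain_atoms in by_chain.items():
        resnums = {a.residue_key for a in chain_atoms if not a.is_hetero}
        if not resnums:
            roles[cid] = "ligand"
            continue
        roles[cid] = "other"
        if len(resnums) > best_len:
            best_chain, best_len = cid, len(resnums)
    if best_chain is not None:
        roles[best_chain] = "kinase"
    return roles


def read_structure(
    path: str | Path,
    format: str = "auto",
    chain_roles: Mapping[str, str] | None = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records of the first model are returned, author numbering
    preserved, coordinates untouched. If ``chain_roles`` is not given, the
    longest polypeptide chain is annotated as the kinase.
    """
    path = Path(path)
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise UnknownFormatError(f"unknown coordinate format: {format!r}")
    if not path.exists():
        raise StructureParseError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for atom in res:
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        residue_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        altloc=atom.altloc.strip("\x00 ") if atom.altloc else "",
                        is_hetero=het,
                    )
                )
    ident = st.name or path.stem
    roles = dict(chain_roles) if chain_roles else _guess_roles(atoms)
    logger.info("read %s: %d atoms, chains %s", path, len(atoms), sorted(roles))
    return StructureModel(identifier=ident, atoms=atoms, chain_roles=roles)


def standardize(model: StructureModel) -> StructureModel:
    """Standard filtering: drop hydrogens and collapse altlocs.

    Keeps, per atom site, the altloc with highest occupancy (ties broken by
    lexicographically first altloc identifier). Crystal structures in scope
    carry no hydrogens, but the filter is enforced for uniformity.
    """
    heavy = [a for a in model.atoms if a.element.upper() not in ("H", "D")]
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in heavy:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name,
               a.atom_name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        elif (a.occupancy, _altloc_rank(a.altloc)) > (
            cur.occupancy, _altloc_rank(cur.altloc)
        ):
            best[key] = a
    atoms = [best[k] for k in order]
    logger.info(
        "standardize %s: %d atoms in, %d out",
        model.identifier, len(model.atoms), len(atoms),
    )
    return StructureModel(model.identifier, atoms, dict(model.chain_roles))


def _altloc_rank(altloc: str):
    # Higher rank wins; lexicographically first altloc must win ties,
    # so rank decreases with the character.
    return tuple(-ord(c) for c in altloc) if altloc else (1,)


def select_atoms(
    model: StructureModel,
    chain: str | None = None,
    residues=None,
    heavy_only: bool = False,
    exclude_hetero: bool = False,
) -> StructureModel:
    """Subset a model, order preserved.

    ``residues`` may be anything supporting ``in`` on integer residue
    numbers (a set, a :class:`kinland.elements.ResidueSet`, a range ...).
    Raises :class:`EmptySelectionError` when nothing matches.
    """
    if chain is not None and chain not in model.chain_ids():
        raise ConfigurationError(
            f"chain {chain!r} not present in {model.identifier} "
            f"(has {model.chain_ids()})"
        )
    if residues is not None and not hasattr(residues, "__contains__"):
        residues = set(residues)
    out = []
    for a in model.atoms:
        if chain is not None and a.chain_id != chain:
            continue
        if residues is not None and a.residue_number not in residues:
            continue
        if heavy_only and a.element.upper() in ("H", "D"):
            continue
        if exclude_hetero and a.is_hetero:
            continue
        out.append(a)
    if not out:
        raise EmptySelectionError(
            f"selection matched no atoms in {model.identifier}"
        )
    logger.debug("select_atoms: %d in, %d out", len(model.atoms), len(out))
    return StructureModel(model.identifier, out, dict(model.chain_roles))


def residue_sequence(
    model: StructureModel, chain: str
) -> list[tuple[tuple[str, int, str], str, str]]:
    """Ordered unique residues of a chain: (residue_key, resname, one-letter).

    Unknown residue names map to 'X'. Hetero residues are skipped.
    """
    seen: dict[tuple, str] = {}
    for a in model.atoms:
        if a.chain_id != chain or a.is_hetero:
            continue
        seen.setdefault(a.residue_key, a.residue_name)
    return [(key, name, _AA3.get(name, "X")) for key, name in seen.items()]


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(model: StructureModel, path: str | Path | None = None) -> str:
    """Serialize to PDB text (standard field widths); optionally write a file."""
    lines = []
    serial = 0
    for a in model.atoms:
        serial += 1
        record = "HETATM" if a.is_hetero else "ATOM  "
        x, y, z = a.position
        lines.append(
            f"{record}{serial:>5} {_format_atom_name(a.atom_name, a.element)}"
            f"{a.altloc or ' ':1}{a.residue_name:>3} {a.chain_id[:1]:1}"
            f"{a.residue_number:>4}{a.insertion_code or ' ':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
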