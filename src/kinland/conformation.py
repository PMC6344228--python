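"""Conformational metrics for kinase structures.

Implements the four structural statistics used to compare cyclin-free and
cyclin-bound kinase states:

* least-squares rigid-body superposition (Kabsch) of paired kinase chains,
  with sequence-based Cα pairing;
* an inter-lobe atomic contact census at a strict distance cutoff;
* assembly assessment of the regulatory (R) and catalytic (C) hydrophobic
  spines from consecutive side-chain minimum distances;
* classification of the P-loop tyrosine as "tucked-in" (inside the ATP
  pocket) or "popped-out" (coordinating the activation-segment glutamate).

All metrics operate on heavy atoms of the kinase chain only; waters,
ligands and partner chains (cyclin, Cks) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.spatial import cKDTree

from .elements import ElementMap
from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    IncompatibleCensusError,
    InsufficientPairingError,
)
from .structure import StructureModel, residue_sequence, select_atoms

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

ResidueKey = tuple[str, int, str]


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Rigid-body fit of a moving structure onto a fixed one.

    ``rotation`` and ``translation`` map moving coordinates onto the fixed
    frame: x_fit = rotation @ x_moving + translation.
    """

    rmsd: float
    n_pairs: int
    rotation: np.ndarray
    translation: np.ndarray
    pairing: list[tuple[ResidueKey, ResidueKey]]
    atom_set: str = "calpha"

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def pair_calphas(
    fixed: StructureModel, moving: StructureModel
) -> list[tuple[ResidueKey, ResidueKey]]:
    """One-to-one residue pairing of the two kinase chains.

    Pairs follow a global sequence alignment (match +1, mismatch 0,
    gap −1), not author numbering, so renumbered chains pair correctly.
    Only pairs in which both residues carry a Cα are retained.
    """
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    seq_f = residue_sequence(fixed, fixed.kinase_chain_id())
    seq_m = residue_sequence(moving, moving.kinase_chain_id())
    if not seq_f or not seq_m:
        raise InsufficientPairingError("a kinase chain has no residues")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(
        "".join(s for _, _, s in seq_f), "".join(s for _, _, s in seq_m)
    )[0]

    has_ca_f = _residues_with_ca(fixed)
    has_ca_m = _residues_with_ca(moving)
    for (fs, fe), (ms, me) in zip(*aln.aligned):
        for i, j in zip(range(fs, fe), range(ms, me)):
            key_f, key_m = seq_f[i][0], seq_m[j][0]
            if key_f in has_ca_f and key_m in has_ca_m:
                pairs.append((key_f, key_m))
    if len(pairs) < 3:
        raise InsufficientPairingError(
            f"only {len(pairs)} residue pairs with Calpha atoms"
        )
    return pairs


def _residues_with_ca(model: StructureModel) -> set[ResidueKey]:
    return {
        a.residue_key for a in model.atoms
        if a.atom_name == "CA" and not a.is_hetero
    }


def _atom_lookup(model: StructureModel) -> dict[tuple, np.ndarray]:
    return {
        (a.residue_key, a.atom_name): np.asarray(a.position)
        for a in model.atoms
        if not a.is_hetero and a.element.upper() not in ("H", "D")
    }


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimising ||R q + t − p||.

    Reflection solutions are rejected by flipping the sign of the smallest
    singular direction, so ``det(R) = +1`` always.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    for X in (P0, Q0):
        sv = np.linalg.svd(X, compute_uv=False)
        if len(sv) < 2 or sv[1] < 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError(
                "point set is (near-)collinear; rotation is not unique"
            )
    C = Q0.T @ P0
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    return R, t


def superpose(
    fixed: StructureModel,
    moving: StructureModel,
    pairing: Sequence[tuple[ResidueKey, ResidueKey]] | None = None,
    atom_set: str = "calpha",
) -> SuperpositionResult:
    """Least-squares rigid superposition over paired residues.

    ``atom_set='calpha'`` (default) uses one Cα per pair — the global
    superposition convention; ``'all_heavy'`` uses every heavy atom name
    common to both residues of a pair.
    """
    if pairing is None:
        pairing = pair_calphas(fixed, moving)
    if len(pairing) < 3:
        raise InsufficientPairingError(f"{len(pairing)} pairs; need >= 3")
    if atom_set not in ("calpha", "all_heavy"):
        raise ConfigurationError(f"unknown atom_set {atom_set!r}")

    lut_f, lut_m = _atom_lookup(fixed), _atom_lookup(moving)
    P, Q = [], []
    for key_f, key_m in pairing:
        if atom_set == "calpha":
            names: Iterable[str] = ("CA",)
        else:
            names_f = {n for (k, n) in lut_f if k == key_f}
            names_m = {n for (k, n) in lut_m if k == key_m}
            names = sorted(names_f & names_m)
        for name in names:
            if (key_f, name) in lut_f and (key_m, name) in lut_m:
                P.append(lut_f[(key_f, name)])
                Q.append(lut_m[(key_m, name)])
    P, Q = np.array(P), np.array(Q)
    if len(P) < 3:
        raise InsufficientPairingError(f"{len(P)} matched atoms; need >= 3")
    R, t = kabsch(P, Q)
    diff = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return SuperpositionResult(
        rmsd=rmsd, n_pairs=len(P), rotation=R, translation=t,
        pairing=list(pairing), atom_set=atom_set,
    )


# ---------------------------------------------------------------------------
# contact census
# ---------------------------------------------------------------------------

@dataclass
class ContactCensusResult:
    """Census of inter-lobe heavy-atom contacts under a strict cutoff."""

    cutoff: float
    mode: str
    total_contacts: int
    per_element_contacts: dict[tuple[str, str], int]
    contact_list: list[tuple]  # (atom_a, atom_b, distance)
    state: str = ""

    def check(self) -> None:
        assert self.total_contacts == len(self.contact_list)
        assert all(d < self.cutoff for _, _, d in self.contact_list)
        assert sum(self.per_element_contacts.values()) == self.total_contacts


def _census_atoms(
    model: StructureModel, element_map: ElementMap, mode: str, chain: str | None
) -> tuple[list, list[tuple[str, str]]]:
    """Kinase-chain heavy atoms with (side, element) labels; unlabelled dropped."""
    chain = chain or model.kinase_chain_id()
    kin = select_atoms(model, chain=chain, heavy_only=True, exclude_hetero=True)
    if mode == "lobe_vs_lobe":
        labelled_elements = {
            "n_lobe": ("N", element_map.n_lobe),
            "c_lobe": ("C", element_map.c_lobe),
        }
    elif mode == "element_pairs":
        labelled_elements = {
            name: (side, rs)
            for name, (side, rs) in element_map.census_elements().items()
        }
    else:
        raise ConfigurationError(f"unknown census mode {mode!r}")

    atoms, labels = [], []
    counts = {name: 0 for name in labelled_elements}
    for a in kin.atoms:
        for name, (side, rs) in labelled_elements.items():
            if a.residue_number in rs:
                atoms.append(a)
                labels.append((side, name))
                counts[name] += 1
                break
    for name, n in counts.items():
        if n == 0:
            warnings.warn(
                f"element {name!r} has no atoms in {model.identifier}",
                stacklevel=3,
            )
    return atoms, labels


def contact_census(
    model: StructureModel,
    element_map: ElementMap,
    cutoff: float = 4.0,
    mode: str = "lobe_vs_lobe",
    chain: str | None = None,
    state: str = "",
) -> ContactCensusResult:
    """Count unordered heavy-atom pairs bridging the two lobes.

    A contact is a pair (a, b) with a in an N-lobe element, b in a C-lobe
    element and distance strictly below ``cutoff`` (the boundary convention
    is "< cutoff", so a pair at exactly the cutoff does not count).
    Intra-lobe and intra-element pairs are never counted. Neighbour search
    uses a k-d tree but equals the all-pairs result exactly.
    """
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    atoms, labels = _census_atoms(model, element_map, mode, chain)
    per: dict[tuple[str, str], int] = {}
    contact_list: list[tuple] = []
    if atoms:
        xyz = np.array([a.position for a in atoms])
        tree = cKDTree(xyz)
        for i, j in sorted(tree.query_pairs(cutoff)):
            (side_i, el_i), (side_j, el_j) = labels[i], labels[j]
            if side_i == side_j:
                continue
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d >= cutoff:
                continue
            # orient the pair N-side first for stable per-element keys
            if side_i == "N":
                key, pair = (el_i, el_j), (atoms[i], atoms[j], d)
            else:
                key, pair = (el_j, el_i), (atoms[j], atoms[i], d)
            per[key] = per.get(key, 0) + 1
            contact_list.append(pair)
    result = ContactCensusResult(
        cutoff=cutoff, mode=mode, total_contacts=len(contact_list),
        per_element_contacts=per, contact_list=contact_list, state=state,
    )
    result.check()
    return result


# ---------------------------------------------------------------------------
# hydrophobic spines
# ---------------------------------------------------------------------------

@dataclass
class SpineAssessment:
    """Assembly state of a hydrophobic spine.

    ``residue_gaps[i]`` is the minimum side-chain heavy-atom distance
    between consecutive spine residues i and i+1 (inf when a residue lacks
    side-chain atoms); a link is broken iff its gap exceeds the threshold.
    """

    spine: str
    residues: list[int]
    residue_gaps: list[float]
    link_threshold: float
    broken_links: list[tuple[int, int]]

    @property
    def assembled(self) -> bool:
        return not self.broken_links


def assess_spine(
    model: StructureModel,
    element_map: ElementMap,
    spine: str = "R",
    link_threshold: float = 4.5,
    chain: str | None = None,
) -> SpineAssessment:
    """Minimum consecutive side-chain distances along the R- or C-spine."""
    spine = spine.upper()
    if spine == "R":
        residues = list(element_map.r_spine_residues)
    elif spine == "C":
        residues = list(element_map.c_spine_residues)
    else:
        raise ConfigurationError(f"spine must be 'R' or 'C', got {spine!r}")
    if len(residues) < 2:
        raise ConfigurationError("spine needs at least two residues")
    chain = chain or model.kinase_chain_id()

    side_chains: dict[int, np.ndarray] = {}
    for resnum in residues:
        coords = [
            a.position for a in model.atoms
            if a.chain_id == chain and a.residue_number == resnum
            and not a.is_hetero and a.element.upper() not in ("H", "D")
            and a.atom_name not in BACKBONE_ATOMS
        ]
        if coords:
            side_chains[resnum] = np.array(coords)
        else:
            warnings.warn(
                f"spine residue {resnum} has no side-chain heavy atoms "
                f"in {model.identifier}; link marked broken", stacklevel=2,
            )

    gaps: list[float] = []
    broken: list[tuple[int, int]] = []
    for a, b in zip(residues, residues[1:]):
        if a in side_chains and b in side_chains:
            diffs = side_chains[a][:, None, :] - side_chains[b][None, :, :]
            gap = float(np.sqrt((diffs ** 2).sum(axis=2)).min())
        else:
            gap = float("inf")
        gaps.append(gap)
        if gap > link_threshold:
            broken.append((a, b))
    return SpineAssessment(
        spine=spine, residues=residues, residue_gaps=gaps,
        link_threshold=link_threshold, broken_links=broken,
    )


# ---------------------------------------------------------------------------
# P-loop tyrosine pose
# ---------------------------------------------------------------------------

@dataclass
class PloopClass:
    """Pose of the P-loop tyrosine hydroxyl.

    popped_out: the hydroxyl sits closer to the activation-segment
    glutamate carboxylate than to the ATP-pocket reference and within the
    coordination threshold. tucked_in: it sits in the pocket. Anything
    ambiguous is indeterminate.
    """

    label: str
    d_pocket: float
    d_glu: float
    reason: str = ""


def classify_ploop(
    model: StructureModel,
    element_map: ElementMap,
    coordination_threshold: float = 3.5,
    pocket_threshold: float = 6.0,
    chain: str | None = None,
) -> PloopClass:
    """Classify the P-loop tyrosine as tucked_in / popped_out / indeterminate.

    The pocket reference is the centroid of the gatekeeper side-chain heavy
    atoms and the hinge-residue Cα atoms — ligand-independent, so apo
    structures classify too.
    """
    chain = chain or model.kinase_chain_id()

    def chain_atoms(resnum: int):
        return [
            a for a in model.atoms
            if a.chain_id == chain and a.residue_number == resnum
            and not a.is_hetero and a.element.upper() not in ("H", "D")
        ]

    tyr_oh = [a for a in chain_atoms(element_map.ploop_tyrosine)
              if a.atom_name == "OH"]
    glu_oxy = [a for a in chain_atoms(element_map.activation_glutamate)
               if a.atom_name in ("OE1", "OE2")]
    pocket_pts = [np.asarray(a.position)
                  for a in chain_atoms(element_map.gatekeeper)
                  if a.atom_name not in BACKBONE_ATOMS]
    for resnum in element_map.hinge:
        pocket_pts += [np.asarray(a.position) for a in chain_atoms(resnum)
                       if a.atom_name == "CA"]

    nan = float("nan")
    if not tyr_oh:
        return PloopClass("indeterminate", nan, nan,
                          "P-loop tyrosine hydroxyl (OH) missing")
    if not glu_oxy:
        return PloopClass("indeterminate", nan, nan,
                          "activation glutamate carboxylate (OE1/OE2) missing")
    if not pocket_pts:
        return PloopClass("indeterminate", nan, nan,
                          "pocket reference atoms missing")

    oh = np.asarray(tyr_oh[0].position)
    d_pocket = float(np.linalg.norm(oh - np.mean(pocket_pts, axis=0)))
    d_glu = float(min(np.linalg.norm(oh - np.asarray(a.position))
                      for a in glu_oxy))
    if d_glu < d_pocket and d_glu < coordination_threshold:
        label = "popped_out"
    elif d_pocket < d_glu and d_pocket < pocket_threshold:
        label = "tucked_in"
    else:
        label = "indeterminate"
    return PloopClass(label, d_pocket, d_glu)


# ---------------------------------------------------------------------------
# state comparison
# ---------------------------------------------------------------------------

@dataclass
class StateComparison:
    """Contact censuses ranked by total, minimum state(s) flagged."""

    table: pd.DataFrame
    minimal_states: list[str]
    unique_minimum: bool


def compare_states(
    censuses: Mapping[str, ContactCensusResult]
    | Sequence[tuple[str, ContactCensusResult]],
) -> StateComparison:
    """Rank labelled censuses by total contacts (ascending).

    All censuses must share one cutoff. Ties are reported: with several
    minimal states ``unique_minimum`` is False and all are flagged.
    The ranking is invariant to the input order.
    """
    items = list(censuses.items()) if isinstance(censuses, Mapping) \
        else list(censuses)
    if len(items) < 2:
        raise IncompatibleCensusError("need at least two censuses to compare")
    cutoffs = {c.cutoff for _, c in items}
    if len(cutoffs) != 1:
        raise IncompatibleCensusError(
            f"censuses use different cutoffs: {sorted(cutoffs)}"
        )
    rows = sorted(
        ({"state": s, "total_contacts": c.total_contacts} for s, c in items),
        key=lambda r: (r["total_contacts"], r["state"]),
    )
    least = rows[0]["total_contacts"]
    for r in rows:
        r["is_minimum"] = r["total_contacts"] == least
    minimal = [r["state"] for r in rows if r["is_minimum"]]
    table = pd.DataFrame(rows).reset_index(drop=True)
    return StateComparison(
        table=table, minimal_states=minimal, unique_minimum=len(minimal) == 1
    )
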