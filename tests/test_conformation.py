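"""Superposition, contact census, spine and P-loop metrics vs brute force."""

import numpy as np
import pytest

from kinland.conformation import (
    assess_spine,
    classify_ploop,
    compare_states,
    contact_census,
    kabsch,
    pair_calphas,
    superpose,
)
from kinland.elements import ElementMap, ResidueSet, default_element_map
from kinland.errors import (
    ConfigurationError,
    DegenerateGeometryError,
    IncompatibleCensusError,
    InsufficientPairingError,
)
from kinland.structure import AtomRecord, StructureModel
from kinland.synth import gen_rigid_copy, toy_element_map

from .conftest import drop_residues, make_chain, renumber

# 50-residue non-repetitive sequence over a 10-letter alphabet, chosen so
# the internal-deletion alignment below is unambiguous.
SEQ50 = "AGLVFYEKSTGAVLYFKEST" "LAGYVEFSKT" "VGALFYEKTS" "YAGLVFESKT"


def random_lobe_map(n_max: int = 5000) -> ElementMap:
    """Element map for random clouds: residues 1..n are N-lobe, n+1.. C-lobe."""
    return ElementMap(
        kinase="RND",
        n_lobe=ResidueSet([(1, n_max)]),
        c_lobe=ResidueSet([(n_max + 1, 2 * n_max)]),
        hinge=ResidueSet([(2 * n_max + 1, 2 * n_max + 2)]),
        p_loop=ResidueSet([(1, 2)]),
        c_helix=ResidueSet([(3, 4)]),
        activation_segment=ResidueSet([(n_max + 1, n_max + 2)]),
        beta_sheet_base=ResidueSet([(5, 6)]),
    )


def random_cloud(n: int, seed: int, box: float = 15.0,
                 n_max: int = 5000) -> StructureModel:
    """n atoms at uniform positions, each its own residue, random lobe label."""
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(0.0, box, size=(n, 3))
    side = rng.integers(0, 2, size=n)  # 0 = N-lobe, 1 = C-lobe
    atoms = [
        AtomRecord(
            chain_id="A",
            residue_number=int(i + 1 + side[i] * n_max),
            insertion_code="", residue_name="ALA", atom_name="CB",
            element="C", position=tuple(np.round(xyz[i], 3)),
        )
        for i in range(n)
    ]
    return StructureModel("cloud", atoms, {"A": "kinase"})


def brute_force_contacts(model: StructureModel, emap: ElementMap,
                         cutoff: float) -> int:
    atoms = [a for a in model.atoms if not a.is_hetero]
    total = 0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            in_n = (a.residue_number in emap.n_lobe,
                    b.residue_number in emap.n_lobe)
            in_c = (a.residue_number in emap.c_lobe,
                    b.residue_number in emap.c_lobe)
            if not ((in_n[0] and in_c[1]) or (in_c[0] and in_n[1])):
                continue
            d = np.linalg.norm(np.subtract(a.position, b.position))
            if d < cutoff:
                total += 1
    return total


class TestPairing:
    def test_identical_chains(self):
        fixed = make_chain(50, sequence=SEQ50)
        pairs = pair_calphas(fixed, fixed)
        assert len(pairs) == 50
        assert all(a == b for a, b in pairs)

    def test_internal_deletion_skipped(self):
        fixed = make_chain(50, sequence=SEQ50)
        moving = drop_residues(fixed, set(range(20, 25)))
        pairs = pair_calphas(fixed, moving)
        assert len(pairs) == 45
        fixed_nums = {f[1] for f, m in pairs}
        assert fixed_nums == set(range(1, 51)) - set(range(20, 25))
        # surviving residues pair with their own numbers
        assert all(f[1] == m[1] for f, m in pairs)

    def test_pairing_follows_sequence_not_numbering(self):
        fixed = make_chain(50, sequence=SEQ50)
        moving = renumber(fixed, 200)
        pairs = pair_calphas(fixed, moving)
        assert len(pairs) == 50
        assert all(m[1] == f[1] + 200 for f, m in pairs)

    def test_too_few_pairs(self):
        fixed = make_chain(2)
        with pytest.raises(InsufficientPairingError):
            pair_calphas(fixed, fixed)


class TestSuperpose:
    def test_self_superposition(self, straight_chain):
        res = superpose(straight_chain, straight_chain)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, straight_chain, seed):
        rng = np.random.default_rng(seed)
        copy, _ = gen_rigid_copy(
            straight_chain,
            angles_deg=tuple(rng.uniform(-180, 180, 3)),
            translation=tuple(rng.uniform(-20, 20, 3)),
        )
        res = superpose(straight_chain, copy)
        assert res.rmsd < 1e-8
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-6

    def test_planar_toy_matches_grid_search(self):
        """Kabsch equals an exhaustive 1-D rotation scan on planar points."""
        P = np.array([[0.0, 0, 0], [3, 0, 0], [3, 2, 0], [0, 2.5, 0]])
        rng = np.random.default_rng(5)
        Q = P + rng.normal(0, 0.4, size=P.shape)
        Q[:, 2] = 0.0

        P0 = P - P.mean(axis=0)
        Q0 = Q - Q.mean(axis=0)
        thetas = np.arange(0.0, 2 * np.pi, 1e-4)
        cos, sin = np.cos(thetas), np.sin(thetas)
        # rotate Q0 about z by every theta and score
        x = cos[:, None] * Q0[:, 0] - sin[:, None] * Q0[:, 1]
        y = sin[:, None] * Q0[:, 0] + cos[:, None] * Q0[:, 1]
        sq = (x - P0[:, 0]) ** 2 + (y - P0[:, 1]) ** 2
        grid_rmsd = np.sqrt(sq.mean(axis=1)).min()

        R, t = kabsch(P, Q)
        fit_rmsd = np.sqrt(((Q @ R.T + t - P) ** 2).sum(axis=1).mean())
        assert fit_rmsd == pytest.approx(grid_rmsd, abs=1e-4)

    def test_collinear_is_degenerate(self):
        P = np.array([[float(i), 0, 0] for i in range(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch(P, P)

    def test_no_reflection(self):
        """A mirrored point set still yields a proper rotation."""
        rng = np.random.default_rng(3)
        P = rng.normal(size=(10, 3))
        Q = P * np.array([1.0, 1.0, -1.0])
        R, _ = kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


class TestContactCensus:
    def test_single_contact(self):
        emap = random_lobe_map()
        atoms = [
            AtomRecord("A", 1, "", "ALA", "CB", "C", (0.0, 0.0, 0.0)),
            AtomRecord("A", 5001, "", "ALA", "CB", "C", (3.5, 0.0, 0.0)),
        ]
        model = StructureModel("two", atoms, {"A": "kinase"})
        census = contact_census(model, emap, cutoff=4.0)
        assert census.total_contacts == 1
        assert census.contact_list[0][2] == pytest.approx(3.5)

    def test_cutoff_is_strict(self):
        """A pair at exactly the cutoff does not count (< convention)."""
        emap = random_lobe_map()
        atoms = [
            AtomRecord("A", 1, "", "ALA", "CB", "C", (0.0, 0.0, 0.0)),
            AtomRecord("A", 5001, "", "ALA", "CB", "C", (4.0, 0.0, 0.0)),
        ]
        model = StructureModel("two", atoms, {"A": "kinase"})
        assert contact_census(model, emap, cutoff=4.0).total_contacts == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        emap = random_lobe_map()
        model = random_cloud(200, seed)
        census = contact_census(model, emap, cutoff=4.0)
        assert census.total_contacts == brute_force_contacts(model, emap, 4.0)

    def test_monotone_in_cutoff(self):
        emap = random_lobe_map()
        model = random_cloud(150, 11)
        totals = [
            contact_census(model, emap, cutoff=c).total_contacts
            for c in (2.0, 3.0, 4.0, 6.0, 8.0)
        ]
        assert totals == sorted(totals)

    def test_empty_element_warns_not_errors(self):
        model = random_cloud(20, 0)
        with pytest.warns(UserWarning, match="no atoms"):
            census = contact_census(model, random_lobe_map(),
                                    mode="element_pairs")
        assert census.total_contacts == 0

    def test_invalid_cutoff(self):
        with pytest.raises(ConfigurationError):
            contact_census(random_cloud(5, 0), random_lobe_map(), cutoff=-1.0)


def spine_stack(gaps: list[float]) -> StructureModel:
    """Residues 1..n along x, consecutive CB side-chain distances = gaps."""
    atoms = []
    x = 0.0
    for i, resnum in enumerate(range(1, len(gaps) + 2)):
        atoms.append(AtomRecord("A", resnum, "", "LEU", "CA", "C",
                                (x, 5.0, 0.0)))
        atoms.append(AtomRecord("A", resnum, "", "LEU", "CB", "C",
                                (x, 0.0, 0.0)))
        if i < len(gaps):
            x += gaps[i]
    return StructureModel("spine", atoms, {"A": "kinase"})


def spine_map(residues: list[int]) -> ElementMap:
    return toy_element_map().with_overrides({"r_spine_residues": residues})


class TestSpines:
    def test_assembled_stack(self):
        model = spine_stack([3.8, 3.8, 3.8])
        a = assess_spine(model, spine_map([1, 2, 3, 4]), spine="R",
                         link_threshold=4.5)
        assert a.assembled
        assert a.residue_gaps == pytest.approx([3.8, 3.8, 3.8])

    def test_one_displaced_residue_breaks_one_link(self):
        model = spine_stack([3.8, 7.0, 3.8])
        a = assess_spine(model, spine_map([1, 2, 3, 4]), spine="R",
                         link_threshold=4.5)
        assert not a.assembled
        assert a.broken_links == [(2, 3)]

    def test_gaps_match_exhaustive_minimum(self):
        rng = np.random.default_rng(4)
        residues = [1, 2, 3]
        atoms = []
        for resnum in residues:
            for k in range(4):
                pos = tuple(np.round(rng.uniform(0, 8, 3), 3))
                atoms.append(AtomRecord("A", resnum, "", "LEU",
                                        f"CD{k}" if k else "CB", "C", pos))
        model = StructureModel("rand", atoms, {"A": "kinase"})
        a = assess_spine(model, spine_map(residues), spine="R",
                         link_threshold=4.5)
        for (r1, r2), gap in zip(zip(residues, residues[1:]), a.residue_gaps):
            pts1 = [x.position for x in atoms if x.residue_number == r1]
            pts2 = [x.position for x in atoms if x.residue_number == r2]
            expect = min(
                np.linalg.norm(np.subtract(p, q)) for p in pts1 for q in pts2
            )
            assert gap == pytest.approx(expect)

    def test_assembled_monotone_in_threshold(self):
        model = spine_stack([3.8, 4.6, 4.0])
        emap = spine_map([1, 2, 3, 4])
        flags = [
            assess_spine(model, emap, spine="R", link_threshold=t).assembled
            for t in (3.0, 4.0, 4.7, 6.0)
        ]
        assert flags == sorted(flags)  # False before True, never back

    def test_missing_side_chain_breaks_link(self):
        model = spine_stack([3.8, 3.8])
        model.atoms = [a for a in model.atoms
                       if not (a.residue_number == 2 and a.atom_name == "CB")]
        with pytest.warns(UserWarning, match="no side-chain"):
            a = assess_spine(model, spine_map([1, 2, 3]), spine="R",
                             link_threshold=4.5)
        assert not a.assembled
        assert len(a.broken_links) == 2

    def test_short_spine_config_error(self):
        with pytest.raises(ConfigurationError):
            assess_spine(spine_stack([3.8]), spine_map([1]), spine="R")


def ploop_model(oh_pos, glu_pos=(20.0, 0.0, 0.0)) -> StructureModel:
    """Minimal CDK1-like chain: pocket atoms at origin, Y15 OH placeable."""
    atoms = [
        # gatekeeper F80 side chain defines the pocket reference with the
        # hinge CA atoms, all near the origin
        AtomRecord("A", 80, "", "PHE", "CZ", "C", (0.0, 0.0, 0.0)),
        AtomRecord("A", 81, "", "GLU", "CA", "C", (0.0, 0.0, 0.0)),
        AtomRecord("A", 82, "", "LEU", "CA", "C", (0.0, 0.0, 0.0)),
        AtomRecord("A", 83, "", "LEU", "CA", "C", (0.0, 0.0, 0.0)),
        AtomRecord("A", 84, "", "ALA", "CA", "C", (0.0, 0.0, 0.0)),
        AtomRecord("A", 15, "", "TYR", "OH", "O", tuple(map(float, oh_pos))),
        AtomRecord("A", 163, "", "GLU", "OE1", "O",
                   tuple(map(float, glu_pos))),
        AtomRecord("A", 163, "", "GLU", "OE2", "O",
                   tuple(np.add(glu_pos, (0.5, 0.5, 0.0)))),
    ]
    return StructureModel("ploop", atoms, {"A": "kinase"})


class TestPloop:
    def test_popped_out(self):
        # hydroxyl 2.8 A from the glutamate carboxylate, 17 A from pocket
        model = ploop_model(oh_pos=(17.2, 0.0, 0.0), glu_pos=(20.0, 0.0, 0.0))
        c = classify_ploop(model, default_element_map("CDK1"))
        assert c.label == "popped_out"
        assert c.d_glu == pytest.approx(2.8)

    def test_tucked_in(self):
        model = ploop_model(oh_pos=(0.0, 0.0, 0.0), glu_pos=(15.0, 0.0, 0.0))
        c = classify_ploop(model, default_element_map("CDK1"))
        assert c.label == "tucked_in"
        assert c.d_pocket == pytest.approx(0.0)

    def test_indeterminate_when_both_far(self):
        model = ploop_model(oh_pos=(9.0, 0.0, 0.0), glu_pos=(17.0, 0.0, 0.0))
        c = classify_ploop(model, default_element_map("CDK1"))
        assert c.label == "indeterminate"

    def test_missing_hydroxyl_is_indeterminate(self):
        model = ploop_model(oh_pos=(0.0, 0.0, 0.0))
        model.atoms = [a for a in model.atoms if a.atom_name != "OH"]
        c = classify_ploop(model, default_element_map("CDK1"))
        assert c.label == "indeterminate"
        assert "hydroxyl" in c.reason

    def test_label_stable_under_rigid_motion(self):
        model = ploop_model(oh_pos=(17.2, 0.0, 0.0))
        moved, _ = gen_rigid_copy(model, angles_deg=(30, -60, 110),
                                  translation=(8, -4, 12))
        emap = default_element_map("CDK1")
        assert classify_ploop(moved, emap).label == \
            classify_ploop(model, emap).label


class TestCompareStates:
    def make(self, total: int):
        from kinland.conformation import ContactCensusResult
        return ContactCensusResult(
            cutoff=4.0, mode="lobe_vs_lobe", total_contacts=total,
            per_element_contacts={("n_lobe", "c_lobe"): total},
            contact_list=[(None, None, 3.0)] * total,
        )

    def test_minimum_flagged(self):
        censuses = {
            "CDK1-cyclin B": self.make(133), "CDK2-cyclin A": self.make(145),
            "CDK1": self.make(104), "CDK2": self.make(141),
        }
        cmp = compare_states(censuses)
        assert cmp.table.iloc[0]["state"] == "CDK1"
        assert cmp.minimal_states == ["CDK1"]
        assert cmp.unique_minimum
        assert list(cmp.table["total_contacts"]) == [104, 133, 141, 145]

    def test_tie_reported(self):
        cmp = compare_states({"a": self.make(10), "b": self.make(10)})
        assert not cmp.unique_minimum
        assert cmp.minimal_states == ["a", "b"]

    def test_order_invariance(self):
        items = [("x", self.make(7)), ("y", self.make(3)), ("z", self.make(9))]
        fwd = compare_states(items).table
        rev = compare_states(items[::-1]).table
        assert fwd.equals(rev)

    def test_mixed_cutoffs_rejected(self):
        a = self.make(5)
        b = self.make(6)
        b.cutoff = 5.0
        with pytest.raises(IncompatibleCensusError):
            compare_states({"a": a, "b": b})
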