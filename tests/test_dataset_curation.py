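import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemescan.dataset_curation import (BACKGROUND_SET_CRITERIA, CullEntry,
                                       FilterCriteria, HEME_SET_CRITERIA,
                                       filter_structures, find_apo_candidates,
                                       greedy_cull, pairwise_identity,
                                       validate_apo_pocket)
from hemescan.synthetic_data import make_identity_family

from conftest import assemble, make_atom, make_residue


def xray(sid, resolution, r_value):
    res = make_residue("A", 1, "ALA", [make_atom("CA", "C", [0, 0, 0])])
    return assemble([res], [], structure_id=sid, resolution=resolution,
                    r_value=r_value, experiment="X-RAY DIFFRACTION")


class TestFilterStructures:
    def test_inclusive_boundaries(self):
        kept = filter_structures([xray("OK", 3.0, 0.30)], HEME_SET_CRITERIA)
        assert [s.structure_id for s in kept] == ["OK"]

    def test_resolution_above_cutoff_excluded(self):
        assert filter_structures([xray("BAD", 3.1, 0.2)], HEME_SET_CRITERIA) == []

    def test_background_criteria_stricter(self):
        s = xray("MID", 2.8, 0.25)
        assert filter_structures([s], HEME_SET_CRITERIA) == [s]
        assert filter_structures([s], BACKGROUND_SET_CRITERIA) == []

    def test_missing_metadata_excluded(self):
        res = make_residue("A", 1, "ALA", [make_atom("CA", "C", [0, 0, 0])])
        s = assemble([res], [], structure_id="NOMETA")
        assert filter_structures([s], HEME_SET_CRITERIA) == []

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            FilterCriteria(max_resolution=-1)
        with pytest.raises(ValueError):
            FilterCriteria(max_r_value=1.5)


class TestPairwiseIdentity:
    def test_identical(self):
        a = pairwise_identity("MKVLATT", "MKVLATT")
        assert a.identity == 1.0 and a.coverage == 1.0

    def test_hand_countable(self):
        assert pairwise_identity("AAAA", "AATA").identity == pytest.approx(0.75)

    def test_fragment_coverage(self):
        a = pairwise_identity("MKVLATTGELIR", "VLATT")
        assert a.identity == 1.0
        assert a.coverage == 1.0  # aligned columns / shorter length

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "AAA")

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10 ** 6))
    def test_identity_matches_column_recount(self, seed):
        rng = np.random.default_rng(seed)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aa, rng.integers(10, 60)))
        b = "".join(rng.choice(aa, rng.integers(10, 60)))
        aln = pairwise_identity(a, b)
        n_match = sum(1 for i, j in aln.aligned_positions if a[i] == b[j])
        n_cols = len(aln.aligned_positions)
        assert aln.identity == pytest.approx(n_match / n_cols if n_cols else 0.0)


class TestGreedyCull:
    def test_three_chain_worked_example(self):
        """A~B ≈30%, A~C ≈10%, B~C low, cutoff 25%, priority A>B>C → {A,C}."""
        seqs, realized = make_identity_family(100, (0.30, 0.10), seed=9)
        assert realized[0, 1] == pytest.approx(0.30, abs=0.02)
        assert realized[0, 2] == pytest.approx(0.10, abs=0.02)
        assert realized[1, 2] < 0.25
        entries = [CullEntry("A", seqs[0], 1.0), CullEntry("B", seqs[1], 2.0),
                   CullEntry("C", seqs[2], 3.0)]
        kept = greedy_cull(entries, 0.25)
        assert [e.chain_id for e in kept] == ["A", "C"]

    def test_identical_chains_keep_higher_priority(self):
        entries = [CullEntry("LOW", "MKVATT", 2.5), CullEntry("HI", "MKVATT", 1.2)]
        kept = greedy_cull(entries, 0.25)
        assert [e.chain_id for e in kept] == ["HI"]

    def test_empty_input(self):
        assert greedy_cull([], 0.25) == []

    def test_determinism(self):
        seqs, _ = make_identity_family(60, (0.5, 0.2, 0.1), seed=3)
        entries = [CullEntry(f"C{i}", s, float(i)) for i, s in enumerate(seqs)]
        k1 = greedy_cull(list(entries), 0.25)
        k2 = greedy_cull(list(reversed(entries)), 0.25)
        assert [e.chain_id for e in k1] == [e.chain_id for e in k2]

    @pytest.mark.parametrize("seed", range(6))
    def test_cull_soundness(self, seed):
        rng = np.random.default_rng(seed)
        targets = tuple(rng.uniform(0.05, 0.95, size=4))
        seqs, _ = make_identity_family(80, targets, seed=seed)
        entries = [CullEntry(f"C{i}", s, float(i)) for i, s in enumerate(seqs)]
        kept = greedy_cull(entries, 0.25)
        assert kept, "at least the top-priority chain is kept"
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                ident = pairwise_identity(kept[i].sequence,
                                          kept[j].sequence).identity
                assert ident < 0.25


class TestApoCandidates:
    def setup_method(self):
        self.seqs, _ = make_identity_family(100, (0.94, 0.89), seed=21)
        self.holo = [("HOLO:A", self.seqs[0])]

    def test_identity_thresholds(self):
        cands = [("APO94:A", self.seqs[1], set()),
                 ("APO89:A", self.seqs[2], set())]
        pairs = find_apo_candidates(self.holo, cands, {"HEM", "HEC"})
        assert [p.apo_id for p in pairs] == ["APO94:A"]
        assert pairs[0].identity >= 0.90 and pairs[0].coverage >= 0.95

    def test_heme_like_ligand_rejected(self):
        cands = [("HASHEME:A", self.seqs[0], {"HNI"})]
        assert find_apo_candidates(self.holo, cands, {"HEM", "HEC", "HNI"}) == []
        assert len(find_apo_candidates(self.holo, cands, {"HEM", "HEC"})) == 1


class TestValidateApoPocket:
    def apo_with(self, hetero):
        residues = [make_residue("A", i + 1, "ALA",
                                 [make_atom("CA", "C", [3.8 * i, 0, 0]),
                                  make_atom("CB", "C", [3.8 * i, 1.5, 0])])
                    for i in range(5)]
        return assemble(residues, hetero, structure_id="APO")

    def pocket(self):
        return [("A", "2"), ("A", "3")]

    def test_no_hetero_groups_clear(self):
        assert validate_apo_pocket(self.apo_with([]), self.pocket()) is True

    def test_nearby_glycerol_blocks(self):
        gol = make_residue("A", 900, "GOL",
                           [make_atom("C1", "C", [3.8, 3.0, 0])], hetero=True)
        assert validate_apo_pocket(self.apo_with([gol]), self.pocket()) is False

    def test_distant_ligand_clear(self):
        gol = make_residue("A", 900, "GOL",
                           [make_atom("C1", "C", [50, 50, 50])], hetero=True)
        assert validate_apo_pocket(self.apo_with([gol]), self.pocket()) is True

    def test_water_ignored(self):
        wat = make_residue("A", 901, "HOH",
                           [make_atom("O", "O", [3.8, 2.5, 0])], hetero=True)
        assert validate_apo_pocket(self.apo_with([wat]), self.pocket()) is True
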