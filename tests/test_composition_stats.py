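import numpy as np
import pytest

from hemescan.composition_stats import (AMINO_ACIDS, FrequencyProfile,
                                        classify_rsa, fold_class_summary,
                                        load_max_accessibility,
                                        profile_chi_square, relative_profile,
                                        residue_frequencies, site_frequencies,
                                        ss_state)
from hemescan.contact_analysis import AxialLigand, ContactRecord

from conftest import make_atom, make_residue

HEME_ID = ("TST", "X", "501")


def contact(chain, pos, resname, dist=4.0):
    res = make_residue(chain, pos, resname, [make_atom("CB", "C", [0, 0, 0])])
    return ContactRecord(residue=res, heme_id=HEME_ID, min_distance=dist,
                         n_atom_pairs_within_cutoff=1)


def axial_of(rec):
    return AxialLigand(residue=rec.residue, heme_id=HEME_ID,
                       donor_atom="NE2", donor_element="N", distance=2.1)


class TestResidueFrequencies:
    def test_single_letter(self):
        p = residue_frequencies(["AAAA"])
        assert p.freqs[AMINO_ACIDS.index("A")] == 1.0
        assert p.n_total == 4

    def test_pooling(self):
        p = residue_frequencies(["ACDE", "ACDE"])
        for aa in "ACDE":
            assert p.freqs[AMINO_ACIDS.index(aa)] == pytest.approx(0.25)

    def test_unknown_letters_ignored(self):
        p = residue_frequencies(["AXXA"])
        assert p.n_total == 2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            residue_frequencies([])

    def test_uniform_sampling_within_binomial_bound(self):
        """1000 uniform random sequences: every frequency within 3σ of 1/20."""
        rng = np.random.default_rng(42)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 60)) for _ in range(1000)]
        p = residue_frequencies(seqs)
        n = p.n_total
        sigma = np.sqrt(0.05 * 0.95 / n)
        assert np.all(np.abs(p.freqs - 0.05) < 3.5 * sigma)


class TestSiteFrequencies:
    def setup_method(self):
        self.his = [contact("A", i, "HIS") for i in (1, 2, 3)]
        self.phe = [contact("A", 9, "PHE")]
        self.axial = [axial_of(c) for c in self.his]

    def test_exclude_axial_removes_ligands(self):
        p = site_frequencies(self.his + self.phe, exclude_axial=True,
                             axial=self.axial)
        assert p.freqs[AMINO_ACIDS.index("F")] == 1.0

    def test_include_axial(self):
        p = site_frequencies(self.his + self.phe, exclude_axial=False)
        assert p.freqs[AMINO_ACIDS.index("H")] == pytest.approx(0.75)

    def test_distinct_residue_counting(self):
        doubled = self.phe + [contact("A", 9, "PHE")]  # same residue, 2 hemes
        assert site_frequencies(doubled).n_total == 1
        assert site_frequencies(doubled, distinct=False).n_total == 2

    def test_exclusion_never_increases_counts(self):
        full = site_frequencies(self.his + self.phe)
        reduced = site_frequencies(self.his + self.phe, exclude_axial=True,
                                   axial=self.axial)
        assert np.all(reduced.counts <= full.counts)


class TestRelativeProfile:
    def test_identity(self):
        p = residue_frequencies(["ACDEFGHIKL"])
        r = relative_profile(p, p)
        defined = ~np.isnan(r.ratios)
        assert np.allclose(r.ratios[defined], 1.0)

    def test_eightfold_cysteine_enrichment(self):
        """Site C at 16% against a 2% background gives an 8-fold ratio —
        the heme-c cysteine scenario."""
        counts_bg = np.zeros(20, int)
        counts_bg[AMINO_ACIDS.index("C")] = 2
        counts_bg[AMINO_ACIDS.index("A")] = 98
        counts_site = np.zeros(20, int)
        counts_site[AMINO_ACIDS.index("C")] = 16
        counts_site[AMINO_ACIDS.index("A")] = 84
        r = relative_profile(FrequencyProfile(AMINO_ACIDS, counts_site),
                             FrequencyProfile(AMINO_ACIDS, counts_bg))
        assert r.ratio("C") == pytest.approx(8.0)

    def test_axial_exclusion_drops_his_to_zero(self):
        his = [contact("A", i, "HIS") for i in (1, 2)]
        axial = [axial_of(c) for c in his]
        phe = [contact("A", 9, "PHE")]
        bg = residue_frequencies(["HF" * 50])
        with_ax = relative_profile(site_frequencies(his + phe), bg)
        without = relative_profile(
            site_frequencies(his + phe, exclude_axial=True, axial=axial), bg)
        assert with_ax.ratio("H") > 1.0
        assert without.ratio("H") == 0.0

    def test_zero_background_flagged(self):
        bg = residue_frequencies(["ACDE"])
        site = residue_frequencies(["WWWW"])
        r = relative_profile(site, bg)
        assert "W" in r.undefined
        assert np.isnan(r.ratio("W"))


class TestSsState:
    @pytest.mark.parametrize("code,state", [
        ("H", "helix"), ("G", "helix"), ("I", "helix"),
        ("E", "strand"), ("B", "strand"),
        ("T", "coil"), ("S", "coil"), (" ", "coil")])
    def test_three_state_mapping(self, code, state):
        assert ss_state(code) == state


class TestClassifyRsa:
    def setup_method(self):
        self.table = load_max_accessibility()

    def test_boundaries(self):
        m = self.table["ALA"]
        assert classify_rsa(0.07 * m, "ALA", self.table).label == "buried"
        assert classify_rsa(0.20 * m, "ALA", self.table).label == "intermediate"
        assert classify_rsa(0.37 * m, "ALA", self.table).label == "intermediate"
        assert classify_rsa(0.50 * m, "ALA", self.table).label == "exposed"

    def test_rsa_capped_at_one(self):
        cls = classify_rsa(2 * self.table["GLY"], "GLY", self.table)
        assert cls.rsa == 1.0 and cls.label == "exposed"

    def test_unknown_residue_raises(self):
        with pytest.raises(KeyError):
            classify_rsa(10.0, "XYZ", self.table)

    def test_classes_partition_unit_interval(self):
        m = self.table["VAL"]
        for acc in np.linspace(0, m, 101):
            cls = classify_rsa(acc, "VAL", self.table)
            eps = 1e-9
            expected = ("buried" if cls.rsa <= 0.07 + eps
                        else "intermediate" if cls.rsa <= 0.37 + eps
                        else "exposed")
            assert cls.label == expected


class TestChiSquare:
    def test_identical_profiles(self):
        p = residue_frequencies(["ACDEFG" * 10])
        stat, df, pval = profile_chi_square(p, p)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = residue_frequencies(["A" * 1000 + "C"])
        b = residue_frequencies(["D" * 1000 + "C"])
        stat, df, pval = profile_chi_square(a, b)
        assert pval < 1e-6

    def test_empty_profile_raises(self):
        empty = FrequencyProfile(AMINO_ACIDS, np.zeros(20, int))
        full = residue_frequencies(["ACDE"])
        with pytest.raises(ValueError):
            profile_chi_square(empty, full)


class TestFoldCensus:
    def test_class_counts_sum_to_total(self):
        s = fold_class_summary()
        assert sum(s["class_counts"].values()) == s["n_annotated_chains"]
        assert 0 < s["all_alpha_fraction"] < 1
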