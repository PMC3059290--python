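import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hemescan.contact_analysis import (classify_binding_chains,
                                       count_hemes_per_chain,
                                       find_axial_ligands, find_heme_groups,
                                       find_interacting_residues,
                                       find_nonresidue_coordinators)
from hemescan.synthetic_data import (FixtureSpec, make_binding_fixture,
                                     transform_structure)

from conftest import assemble, bare_heme, make_atom, make_residue


def brute_force_contacts(heme_res, structure, cutoff=4.5):
    """All-pairs heavy-atom scan — the oracle for the k-d tree path."""
    heme_xyz = np.array([a.coords for a in heme_res.heavy_atoms()])
    keys = set()
    for res in structure.protein_residues():
        for a in res.heavy_atoms():
            if np.min(np.linalg.norm(heme_xyz - a.coords, axis=1)) <= cutoff:
                keys.add(res.key())
                break
    return keys


class TestFindHemeGroups:
    def test_five_hemes_found(self):
        hemes = [bare_heme(center=(20 * i, 0, 0), pos=str(500 + i))
                 for i in range(5)]
        s = assemble([make_residue("A", 1, "ALA",
                                   [make_atom("CA", "C", [0, 50, 0])])], hemes)
        assert len(find_heme_groups(s)) == 5

    def test_no_hetero_groups(self):
        s = assemble([make_residue("A", 1, "ALA",
                                   [make_atom("CA", "C", [0, 0, 0])])], [])
        assert find_heme_groups(s) == []

    def test_heme_without_iron_skipped_with_warning(self):
        broken = bare_heme()
        broken.atoms = [a for a in broken.atoms if a.element != "FE"]
        s = assemble([make_residue("A", 1, "ALA",
                                   [make_atom("CA", "C", [0, 0, 0])])], [broken])
        with pytest.warns(UserWarning, match="no FE"):
            assert find_heme_groups(s) == []

    def test_heme_type_codes(self):
        hec = bare_heme(pos="600")
        hec.name = "HEC"
        s = assemble([make_residue("A", 1, "ALA",
                                   [make_atom("CA", "C", [0, 30, 0])])],
                     [bare_heme(), hec])
        types = sorted(h.heme_type for h in find_heme_groups(s))
        assert types == ["b", "c"]


class TestAxialLigands:
    @pytest.mark.parametrize("dist,expected", [(2.1, True), (3.0, True),
                                               (3.5, False)])
    def test_cutoff_is_inclusive(self, dist, expected):
        his = make_residue("A", 5, "HIS", [
            make_atom("NE2", "N", [0, 0, dist]),
            make_atom("CA", "C", [0, 0, dist + 3])])
        s = assemble([his], [bare_heme()])
        ligs = find_axial_ligands(find_heme_groups(s)[0], s)
        assert bool(ligs) is expected
        if ligs:
            assert ligs[0].donor_atom == "NE2"
            assert ligs[0].distance == pytest.approx(dist)

    def test_met_sulfur_at_boundary(self):
        met = make_residue("A", 5, "MET", [
            make_atom("SD", "S", [0, 0, 3.0]),
            make_atom("CA", "C", [0, 0, 6.0])])
        s = assemble([met], [bare_heme()])
        ligs = find_axial_ligands(find_heme_groups(s)[0], s)
        assert len(ligs) == 1 and ligs[0].donor_element == "S"

    def test_carbon_never_a_donor(self):
        res = make_residue("A", 5, "ALA", [make_atom("CB", "C", [0, 0, 2.0])])
        s = assemble([res], [bare_heme()])
        assert find_axial_ligands(find_heme_groups(s)[0], s) == []

    def test_nonresidue_coordinator_reported_separately(self):
        imd = make_residue("B", 900, "IMD",
                           [make_atom("N1", "N", [0, 0, 2.2])], hetero=True)
        res = make_residue("A", 5, "ALA", [make_atom("CB", "C", [8, 8, 8])])
        s = assemble([res], [bare_heme(), imd])
        h = find_heme_groups(s)[0]
        assert find_axial_ligands(h, s) == []
        coords = find_nonresidue_coordinators(h, s)
        assert len(coords) == 1 and coords[0].group.name == "IMD"


class TestInteractingResidues:
    def test_hydrogen_contacts_excluded(self):
        res = make_residue("A", 1, "SER", [
            make_atom("HG", "H", [2.05 + 1.0, 0, 0]),   # 1 Å from NA: hydrogen
            make_atom("OG", "O", [2.05 + 9.0, 0, 0])])  # far heavy atom
        s = assemble([res], [bare_heme()])
        assert find_interacting_residues(find_heme_groups(s)[0], s) == []

    def test_boundary_inclusive(self):
        # exactly 4.5 Å from the iron at the origin (exactly representable)
        res = make_residue("A", 1, "ALA",
                           [make_atom("CB", "C", [0, 0, 4.5])])
        s = assemble([res], [bare_heme()])
        recs = find_interacting_residues(find_heme_groups(s)[0], s)
        assert len(recs) == 1
        assert recs[0].min_distance == pytest.approx(4.5)

    def test_twelve_residues_at_four_angstroms(self):
        s, truth = make_binding_fixture(FixtureSpec(
            seed=11, n_contacts=12, contact_distance=4.0))
        h = find_heme_groups(s)[0]
        recs = find_interacting_residues(h, s)
        assert len(recs) == 12
        assert {r.residue.key() for r in recs} == truth["contact_keys"]
        assert {r.residue.key() for r in recs} == brute_force_contacts(
            h.residue, s)

    @pytest.mark.parametrize("seed", range(12))
    def test_kdtree_matches_all_pairs_oracle(self, seed):
        s, _ = make_binding_fixture(FixtureSpec(
            seed=100 + seed, n_contacts=8 + seed % 5, with_axial=seed % 2 == 0,
            contact_distance=3.0 + 0.1 * seed))
        h = find_heme_groups(s)[0]
        fast = {r.residue.key() for r in find_interacting_residues(h, s)}
        assert fast == brute_force_contacts(h.residue, s)

    @pytest.mark.parametrize("seed", range(8))
    def test_axial_subset_of_contacts(self, seed):
        s, _ = make_binding_fixture(FixtureSpec(
            seed=200 + seed, n_contacts=6, with_axial=True))
        h = find_heme_groups(s)[0]
        axial = {l.residue.key() for l in find_axial_ligands(h, s)}
        contacts = {r.residue.key() for r in find_interacting_residues(h, s)}
        assert axial and axial <= contacts


class TestBindingClassification:
    @pytest.mark.parametrize("n,axial,binding,reason", [
        (3, True, True, "axial"),
        (10, False, True, "contacts"),
        (9, False, False, "none"),
    ])
    def test_binding_rules(self, n, axial, binding, reason):
        s, _ = make_binding_fixture(FixtureSpec(
            seed=7 + n, n_contacts=n, with_axial=axial))
        v = classify_binding_chains(s)
        assert len(v) == 1
        assert v[0].is_binding is binding and v[0].reason == reason

    def test_out_of_range_contacts_not_counted(self):
        s, _ = make_binding_fixture(FixtureSpec(
            seed=3, n_contacts=12, contact_distance=4.6))
        v = classify_binding_chains(s)
        assert v[0].n_contacts == 0 and not v[0].is_binding


class TestHemeCounting:
    def test_eight_hemes_one_chain(self):
        hemes, residues = [], []
        for i in range(8):
            c = np.array([25.0 * i, 0, 0])
            hemes.append(bare_heme(center=c, pos=str(500 + i)))
            residues.append(make_residue("A", i + 1, "ALA", [
                make_atom("CB", "C", c + [0, 4.3 + 4.0, 0])]))
        s = assemble(residues, hemes)
        assert count_hemes_per_chain(s) == {"A": 8}

    def test_shared_heme_counts_for_both_chains(self):
        heme = bare_heme()
        ra = make_residue("A", 1, "ALA", [make_atom("CB", "C", [4.3 + 4, 0, 0])])
        rb = make_residue("B", 1, "ALA", [make_atom("CB", "C", [-4.3 - 4, 0, 0])])
        rc = make_residue("C", 1, "ALA", [make_atom("CB", "C", [60, 60, 60])])
        s = assemble([ra, rb, rc], [heme])
        assert count_hemes_per_chain(s) == {"A": 1, "B": 1}


class TestRigidInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_transform_changes_nothing(self, seed):
        s, _ = make_binding_fixture(FixtureSpec(
            seed=300 + seed, n_contacts=10, with_axial=True))
        rng = np.random.default_rng(seed)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(0, 50, 3)
        s2 = transform_structure(s, R, t)
        v1, v2 = classify_binding_chains(s), classify_binding_chains(s2)
        assert v1 == v2
        h1 = find_heme_groups(s)[0]
        h2 = find_heme_groups(s2)[0]
        d1 = sorted(r.min_distance for r in find_interacting_residues(h1, s))
        d2 = sorted(r.min_distance for r in find_interacting_residues(h2, s2))
        np.testing.assert_allclose(d1, d2, atol=1e-6)
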