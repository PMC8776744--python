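"""Polar contacts and binding-pocket census."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gnmcompare.contacts import (
    POCKET_PRESETS,
    census_all_chains,
    find_polar_contacts,
    pocket_census,
)
from gnmcompare.structures import Atom
from gnmcompare.synthetic import make_pocket_scene
from conftest import SCENE_POCKET


def atom(name, element, xyz, resname="ALA", resnum=1, chain="A"):
    return Atom(name, element, tuple(map(float, xyz)), 10.0, 1.0, "",
                resname, resnum, "", chain)


class TestFindPolarContacts:
    def test_backbone_n_to_water_within_cutoff(self):
        n = atom("N", "N", (0, 0, 0))
        w = atom("O", "O", (2.9, 0, 0), resname="HOH", resnum=301, chain="S")
        (c,) = find_polar_contacts([n], [w], 3.6)
        assert c.kind == "protein-water"
        assert c.distance == pytest.approx(2.9)

    def test_carbon_is_not_polar(self):
        cb = atom("CB", "C", (0, 0, 0))
        w = atom("O", "O", (2.9, 0, 0), resname="HOH", resnum=301, chain="S")
        assert find_polar_contacts([cb], [w], 3.6) == []

    def test_pair_beyond_cutoff_excluded(self):
        a = atom("N", "N", (0, 0, 0))
        b = atom("O", "O", (3.7, 0, 0), resnum=2)
        assert find_polar_contacts([a], [b], 3.6) == []

    def test_intra_residue_pairs_excluded(self):
        a = atom("N", "N", (0, 0, 0), resnum=5)
        b = atom("O", "O", (2.5, 0, 0), resnum=5)
        assert find_polar_contacts([a], [b], 3.6) == []

    def test_overlapping_selections_deduplicated(self):
        a = atom("N", "N", (0, 0, 0), resnum=1)
        b = atom("O", "O", (3.0, 0, 0), resnum=2)
        contacts = find_polar_contacts([a, b], [a, b], 3.6)
        assert len(contacts) == 1

    def test_adjacent_backbone_flag(self):
        o_i = atom("O", "O", (0, 0, 0), resnum=10)
        n_next = atom("N", "N", (2.3, 1.0, 0), resnum=11)
        assert len(find_polar_contacts([o_i], [n_next], 3.6)) == 1
        assert find_polar_contacts([o_i], [n_next], 3.6,
                                   include_adjacent_backbone=False) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_all_pairs_scan(self, seed):
        rng = np.random.default_rng(seed)
        atoms = []
        for i in range(120):
            el = ("N", "O", "C")[i % 3]
            atoms.append(atom(f"X{i}", el, rng.uniform(0, 25, 3),
                              resnum=i, chain="A"))
        sel_a, sel_b = atoms[:60], atoms[40:]
        fast = find_polar_contacts(sel_a, sel_b, 3.6)

        def short(key):  # Atom.key -> (chain, resname, resnum, name)
            return (key[0], key[1], key[2], key[4])

        brute = set()
        for a in sel_a:
            for b in sel_b:
                if a.key == b.key or a.residue_key == b.residue_key:
                    continue
                if not (a.is_polar and b.is_polar):
                    continue
                if np.linalg.norm(a.xyz - b.xyz) <= 3.6:
                    brute.add(frozenset((short(a.key), short(b.key))))
        assert {frozenset((c.atom_a, c.atom_b)) for c in fast} == brute


class TestPocketCensus:
    def test_scene_counts_match_construction(self, pocket_scene):
        c = pocket_census(pocket_scene, "A", SCENE_POCKET)
        assert c.n_waters == 3
        assert c.n_polar_interactions == 3
        assert all(k.kind == "protein-water" for k in c.contacts)

    def test_no_near_waters_means_zero(self):
        scene = make_pocket_scene(0, 3.0, 3, 4.5, seed=2)
        c = pocket_census(scene, "A", SCENE_POCKET)
        assert c.n_waters == 0 and c.n_polar_interactions == 0

    @pytest.mark.parametrize("n_near", [2, 4])
    def test_scaling_with_near_water_count(self, n_near):
        scene = make_pocket_scene(n_near, 3.0, 1, 4.5, seed=3)
        c = pocket_census(scene, "A", SCENE_POCKET)
        assert c.n_waters == n_near
        assert c.n_polar_interactions == n_near

    def test_counts_invariant_under_rigid_transform(self, pocket_scene):
        r = Rotation.random(random_state=4).as_matrix()
        moved = pocket_scene.transformed(r, np.array([5.0, -3.0, 11.0]))
        c0 = pocket_census(pocket_scene, "A", SCENE_POCKET)
        c1 = pocket_census(moved, "A", SCENE_POCKET)
        assert (c0.n_waters, c0.n_polar_interactions) == \
            (c1.n_waters, c1.n_polar_interactions)

    def test_cutoff_monotonicity(self):
        for seed in range(4):
            scene = make_pocket_scene(3, 3.0, 2, 4.5, seed=seed)
            prev_w = prev_p = -1
            for cutoff in (3.0, 3.6, 4.6, 6.0):
                c = pocket_census(scene, "A", SCENE_POCKET, cutoff=cutoff)
                assert c.n_waters >= prev_w
                assert c.n_polar_interactions >= prev_p
                prev_w, prev_p = c.n_waters, c.n_polar_interactions

    def test_water_count_bounded_by_total_waters(self, pocket_scene):
        c = pocket_census(pocket_scene, "A", SCENE_POCKET, cutoff=8.0)
        assert c.n_waters <= len(pocket_scene.waters)
        assert c.n_polar_interactions >= c.n_waters

    def test_presets_are_exposed(self):
        assert set(POCKET_PRESETS) == {"canonical8", "compact7"}
        assert ("THR", 90) in POCKET_PRESETS["canonical8"]
        assert ("SER", 27) in POCKET_PRESETS["compact7"]


class TestCensusAllChains:
    def test_identical_chains_identical_censuses(self, tetramer):
        st, _ = tetramer
        censuses = census_all_chains(st, [("ALA", 30), ("ALA", 31)])
        counts = {(c.n_waters, c.n_polar_interactions) for c in censuses}
        assert len(censuses) == 4
        assert len(counts) == 1  # no waters anywhere -> all equal

    def test_ordered_by_chain_id(self, tetramer):
        st, _ = tetramer
        censuses = census_all_chains(st, [("ALA", 30)])
        assert [c.chain for c in censuses] == sorted(st.chain_ids)

    def test_deleting_one_chains_waters(self, pocket_scene):
        import copy

        both = copy.deepcopy(pocket_scene)
        both.chains.append(copy.deepcopy(both.chains[0]))
        both.chains[1].id = "B"
        shift = np.array([60.0, 0, 0])
        for res in both.chains[1].residues:
            res.atoms = [a.__class__(**{**a.__dict__, "chain_id": "B",
                                        "coords": tuple(a.xyz + shift)})
                         for a in res.atoms]
        censuses = census_all_chains(both, SCENE_POCKET)
        by_chain = {c.chain: c for c in censuses}
        assert by_chain["A"].n_waters == 3
        assert by_chain["B"].n_waters == 0  # its pocket has no waters nearby
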