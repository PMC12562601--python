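"""Interface descriptors: SASA/BSA, H-bonds, salt bridges, stacking, MHP."""

import math

import numpy as np
import pytest

from conftest import grid_sasa, random_rigid_motion
from ifscreen import synthgen
from ifscreen.descriptors import (ContactRecord, InteractionGeometry,
                                  InterfaceDescriptor, buried_surface_area,
                                  describe_interface, detect_hbonds,
                                  detect_ionic, detect_stacking,
                                  enumerate_contacts, mhp_complementarity,
                                  sasa)
from ifscreen.structmodel import Atom, Residue, StructureModel

GEOM = InteractionGeometry()


def single_atoms(*entries, chain="A"):
    """Structure of isolated atoms: entries are (name, element, res, xyz)."""
    atoms, residues, coords = [], [], []
    for i, (name, element, res_name, xyz) in enumerate(entries):
        atoms.append(Atom(name, element))
        residues.append(Residue(chain, i + 1, "", res_name, i, i + 1))
        coords.append(xyz)
    return StructureModel(atoms, residues, np.asarray(coords, float)[None])


def two_partner_atoms(name_a, el_a, res_a, name_b, el_b, res_b, dist):
    a = single_atoms((name_a, el_a, res_a, (0.0, 0.0, 0.0)))
    b = single_atoms((name_b, el_b, res_b, (dist, 0.0, 0.0)), chain="B")
    return a, b


def residue_with(res_name, atom_specs, chain="A", seq=1):
    atoms = [Atom(n, e) for n, e, _ in atom_specs]
    coords = np.asarray([xyz for _, _, xyz in atom_specs], float)
    return StructureModel(atoms, [Residue(chain, seq, "", res_name, 0,
                                          len(atoms))], coords[None])


class TestSasa:
    def test_isolated_atom_is_analytic_sphere(self):
        st = single_atoms(("C1", "C", "HPB", (0, 0, 0)))
        exact = 4 * math.pi * (1.70 + GEOM.sasa_probe) ** 2
        assert sasa(st, GEOM).sum() == pytest.approx(exact, rel=0.01)

    def test_separated_atoms_add(self):
        st = single_atoms(("C1", "C", "HPB", (0, 0, 0)),
                          ("C1", "C", "HPB", (50, 0, 0)))
        exact = 2 * 4 * math.pi * (1.70 + GEOM.sasa_probe) ** 2
        assert sasa(st, GEOM).sum() == pytest.approx(exact, rel=0.01)

    def test_matches_dense_grid_oracle(self):
        """Shrake-Rupley areas agree with an independent numeric oracle."""
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 6, (10, 3))
        entries = [("C1", "C", "HPB", tuple(p)) for p in pts]
        st = single_atoms(*entries)
        mine = sasa(st, GEOM).sum()
        oracle = grid_sasa(st.coords[0], st.radii(), GEOM.sasa_probe,
                           n_samples=20000, seed=1).sum()
        assert mine == pytest.approx(oracle, rel=0.02)

    def test_total_stable_under_point_doubling(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 5, (8, 3))
        st = single_atoms(*[("C1", "C", "HPB", tuple(p)) for p in pts])
        a = sasa(st, InteractionGeometry(sasa_points=480)).sum()
        b = sasa(st, InteractionGeometry(sasa_points=960)).sum()
        assert a == pytest.approx(b, rel=0.02)


class TestBsa:
    def test_far_partners_zero(self):
        a, b = two_partner_atoms("C1", "C", "HPB", "C1", "C", "HPB", 50.0)
        assert buried_surface_area(a, b, GEOM) == 0.0

    def test_two_sphere_contact_matches_cap_closed_form(self):
        d = 2.5
        a, b = two_partner_atoms("C1", "C", "HPB", "C1", "C", "HPB", d)
        R = 1.70 + GEOM.sasa_probe
        h = R - d / 2
        exact = 2 * (2 * math.pi * R * h)
        assert buried_surface_area(a, b, GEOM) == pytest.approx(exact, rel=0.03)

    def test_planted_interface_hits_construction_target(self):
        toy = synthgen.make_toy_complex(hbond_pairs=0, ionic_pairs=0,
                                        target_bsa=3000, seed=2)
        bsa = buried_surface_area(toy.receptor, toy.ligand, GEOM)
        assert bsa == pytest.approx(toy.truth["bsa_analytic"], rel=0.05)

    def test_symmetry(self):
        toy = synthgen.make_toy_complex(hbond_pairs=2, ionic_pairs=1, seed=3)
        ab = buried_surface_area(toy.receptor, toy.ligand, GEOM)
        ba = buried_surface_area(toy.ligand, toy.receptor, GEOM)
        assert ab == ba

    def test_clash_raises(self):
        a, b = two_partner_atoms("C1", "C", "HPB", "C1", "C", "HPB", 0.2)
        with pytest.raises(ValueError, match="clash"):
            buried_surface_area(a, b, GEOM)

    def test_translating_apart_never_increases_descriptors(self):
        toy = synthgen.make_toy_complex(hbond_pairs=2, ionic_pairs=2,
                                        bsa_pairs=5, seed=6)
        prev = None
        for shift in (0.0, 2.0, 5.0, 12.0):
            lig = toy.ligand
            moved = StructureModel(lig.atoms, lig.residues,
                                   lig.coords - np.array([0, shift, 0]))
            d = describe_interface(toy.receptor, moved, GEOM)
            if prev is not None:
                assert d.bsa <= prev.bsa + 1e-6
                assert d.n_hbonds <= prev.n_hbonds
                assert d.n_ionic <= prev.n_ionic
            prev = d


class TestHbonds:
    def test_canonical_pair_detected_and_long_pair_not(self):
        don = residue_with("ALA", [("N", "N", (0, 0, 0))])
        acc = residue_with("ALA", [("O", "O", (2.9, 0, 0))], chain="B")
        assert len(detect_hbonds(don, acc, GEOM)) == 1
        far = residue_with("ALA", [("O", "O", (4.2, 0, 0))], chain="B")
        assert detect_hbonds(don, far, GEOM) == []

    def test_angle_criterion_applies_with_hydrogens(self):
        # donor N with H pointing away from the acceptor: angle ~70° -> reject
        don = residue_with("ALA", [("N", "N", (0, 0, 0)),
                                   ("H", "H", (-0.5, 0.87, 0))])
        acc = residue_with("ALA", [("O", "O", (2.9, 0, 0))], chain="B")
        assert detect_hbonds(don, acc, GEOM) == []
        # H pointing toward the acceptor: near-linear -> accept
        don2 = residue_with("ALA", [("N", "N", (0, 0, 0)),
                                    ("H", "H", (1.0, 0, 0))])
        found = detect_hbonds(don2, acc, GEOM)
        assert len(found) == 1 and found[0].angle > 170

    def test_planted_count_exact(self, toy_hb_ionic):
        toy = toy_hb_ionic
        hb = detect_hbonds(toy.receptor, toy.ligand, GEOM)
        # 3 pure H-bond pairs + 2 salt bridges that are also H-bonded
        assert len(hb) == toy.truth["n_hbond_pairs"] == 5


class TestIonic:
    def test_arg_asp_bridge_and_distance_cutoff(self):
        pos = residue_with("ARG", [("NH1", "N", (0, 0, 0))])
        neg = residue_with("ASP", [("OD1", "O", (3.0, 0, 0))], chain="B")
        assert len(detect_ionic(pos, neg, GEOM)) == 1
        pos2 = residue_with("LYS", [("NZ", "N", (0, 0, 0))])
        neg2 = residue_with("GLU", [("OE1", "O", (5.5, 0, 0))], chain="B")
        assert detect_ionic(pos2, neg2, GEOM) == []

    def test_loop_ii_pairs_recovered_from_planted_geometry(self):
        """R32/R34 to D170/D171 planted bridges come back as named pairs."""
        pairs = [synthgen.PlantedPair("I", 32, 170, "ARG", "ASP", "-"),
                 synthgen.PlantedPair("I", 34, 171, "ARG", "ASP", "-")]
        toy = synthgen.make_toy_complex(hbond_pairs=0, ionic_pairs=pairs,
                                        seed=4)
        bridges = detect_ionic(toy.receptor, toy.ligand, GEOM)
        named = {(b.positive_res[1], b.negative_res[1]) for b in bridges}
        assert named == {(32, 170), (34, 171)}

    def test_dedup_one_bridge_per_residue_pair(self):
        pos = residue_with("ARG", [("NH1", "N", (0, 0, 0)),
                                   ("NH2", "N", (0, 1.0, 0))])
        neg = residue_with("ASP", [("OD1", "O", (3.0, 0, 0)),
                                   ("OD2", "O", (3.0, 1.0, 0))], chain="B")
        assert len(detect_ionic(pos, neg, GEOM)) == 1


class TestStacking:
    @staticmethod
    def ring(res_name, center, tilt_deg=0.0, chain="A", seq=1):
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        c = np.asarray(center, float)
        t = math.radians(tilt_deg)
        specs = []
        for k in range(6):
            a = k * math.pi / 3
            v = np.array([math.cos(a), 0.0, math.sin(a)]) * 1.39
            # tilt about x rotates the ring normal away from +y
            v = np.array([v[0], -math.sin(t) * v[2], math.cos(t) * v[2]])
            specs.append((names[k], "C", tuple(c + v)))
        return residue_with(res_name, specs, chain=chain, seq=seq)

    def test_parallel_rings_detected(self):
        a = self.ring("TYR", (0, 0, 0))
        b = self.ring("PHE", (0, 4.0, 0), tilt_deg=5, chain="B")
        found = detect_stacking(a, b, GEOM)
        assert len(found) == 1 and found[0].interplanar_angle < 30

    def test_distant_rings_not_detected(self):
        a = self.ring("TYR", (0, 0, 0))
        b = self.ring("PHE", (0, 8.0, 0), chain="B")
        assert detect_stacking(a, b, GEOM) == []

    def test_t_shaped_band_semantics(self):
        a = self.ring("TYR", (0, 0, 0))
        b = self.ring("PHE", (0, 5.0, 0), tilt_deg=85, chain="B")
        assert len(detect_stacking(a, b, GEOM)) == 1
        no_t = InteractionGeometry(stacking_angle_bands=((0.0, 30.0),))
        assert detect_stacking(a, b, no_t) == []


class TestMhp:
    def test_uniform_sign_constructions(self):
        agree = synthgen.make_toy_complex(hbond_pairs=0, ionic_pairs=0,
                                          mhp_agree_pairs=5, seed=1)
        assert mhp_complementarity(agree.receptor, agree.ligand, GEOM) == 1.0
        disagree = synthgen.make_toy_complex(hbond_pairs=0, ionic_pairs=0,
                                             mhp_disagree_pairs=5, seed=1)
        assert mhp_complementarity(disagree.receptor, disagree.ligand,
                                   GEOM) == 0.0

    def test_planted_60_40_mix(self):
        toy = synthgen.make_toy_complex(hbond_pairs=0, ionic_pairs=0,
                                        mhp_agree_pairs=6,
                                        mhp_disagree_pairs=4, seed=2)
        score = mhp_complementarity(toy.receptor, toy.ligand, GEOM)
        assert score == pytest.approx(0.6, abs=0.03)

    def test_undefined_for_far_partners(self):
        a, b = two_partner_atoms("C1", "C", "HPB", "C1", "C", "HPB", 50.0)
        with pytest.warns(UserWarning, match="undefined"):
            assert mhp_complementarity(a, b, GEOM) is None


class TestDescribeInterface:
    def test_far_partners_all_zero(self):
        a, b = two_partner_atoms("C1", "C", "HPB", "C1", "C", "HPB", 50.0)
        with pytest.warns(UserWarning):
            d = describe_interface(a, b, GEOM)
        assert (d.bsa, d.n_hbonds, d.n_ionic, d.n_stacking) == (0.0, 0, 0, 0)
        assert d.mhp_score is None

    def test_counts_equal_detector_outputs(self, toy_hb_ionic):
        toy = toy_hb_ionic
        d = describe_interface(toy.receptor, toy.ligand, GEOM)
        assert d.n_hbonds == len(detect_hbonds(toy.receptor, toy.ligand, GEOM))
        assert d.n_ionic == len(detect_ionic(toy.receptor, toy.ligand, GEOM))
        assert d.n_stacking == len(
            detect_stacking(toy.receptor, toy.ligand, GEOM))

    def test_rigid_motion_invariance(self, toy_hb_ionic):
        toy = toy_hb_ionic
        rot, trans = random_rigid_motion(12)
        rec = StructureModel(toy.receptor.atoms, toy.receptor.residues,
                             toy.receptor.coords @ rot.T + trans)
        lig = StructureModel(toy.ligand.atoms, toy.ligand.residues,
                             toy.ligand.coords @ rot.T + trans)
        d0 = describe_interface(toy.receptor, toy.ligand, GEOM)
        d1 = describe_interface(rec, lig, GEOM)
        assert d1.n_hbonds == d0.n_hbonds
        assert d1.n_ionic == d0.n_ionic
        assert d1.n_stacking == d0.n_stacking
        assert d1.bsa == pytest.approx(d0.bsa, rel=0.02)

    def test_descriptor_validation(self):
        with pytest.raises(ValueError):
            InterfaceDescriptor(-1.0, 0, 0, 0.5)
        with pytest.raises(ValueError):
            InterfaceDescriptor(0.0, 0, 0, 1.5)


class TestEnumerateContacts:
    def test_planted_k61_d193_ionic_plus_h(self):
        pairs = [synthgen.PlantedPair("I", 61, 193, "LYS", "ASP", "+")]
        toy = synthgen.make_toy_complex(hbond_pairs=0, ionic_pairs=pairs,
                                        seed=5)
        recs = enumerate_contacts(toy.receptor, toy.ligand, GEOM,
                                  toy.partition)
        assert len(recs) == 1
        c = recs[0]
        assert c.ligand_label == "K61"
        assert c.receptor_residue[1] == 193 and c.receptor_role == "+"
        assert c.kinds == frozenset({"H", "I"})

    def test_no_interactions_empty(self):
        a = residue_with("ALA", [("CB", "C", (0, 0, 0))])
        b = residue_with("ALA", [("CB", "C", (30, 0, 0))], chain="B")
        assert enumerate_contacts(a, b, GEOM, {"A": "+"}) == []

    def test_glycan_partner_flagged_with_parent(self):
        rec = residue_with("MAN", [("O3", "O", (0, 0, 0))], chain="P", seq=601)
        lig = residue_with("SER", [("OG", "O", (2.9, 0, 0))], chain="L")
        recs = enumerate_contacts(rec, lig, GEOM, {"P": "+"},
                                  glycan_parents={("P", 601): 143})
        assert len(recs) == 1
        assert recs[0].partner_is_glycan and recs[0].glycan_parent == 143
        assert recs[0].receptor_label == "MAN(N143)(+)"

    def test_unpartitioned_chain_raises(self, toy_hb_ionic):
        toy = toy_hb_ionic
        with pytest.raises(ValueError, match="role"):
            enumerate_contacts(toy.receptor, toy.ligand, GEOM, {})

    def test_recovers_exact_planted_pairs(self, toy_hb_ionic):
        toy = toy_hb_ionic
        recs = enumerate_contacts(toy.receptor, toy.ligand, GEOM,
                                  toy.partition)
        got = {(c.ligand_residue, c.receptor_residue, c.kinds) for c in recs}
        want = {(c.ligand_residue, c.receptor_residue, c.kinds)
                for c in toy.truth_contacts}
        assert got == want
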