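"""Geometric interaction detectors, His524 classes and pose filtering."""

import numpy as np
import pytest

from hydroqsar.fixtures import ToyComplexSpec, make_toy_complex
from hydroqsar.pharmacophore import (
    CLOSED,
    MOVED_BACK,
    OPEN,
    UNKNOWN,
    FeatureHit,
    GeometricCriteria,
    HBondGroup,
    RingDescriptor,
    check_aring_arrangement,
    classify_his524,
    count_internal_hbonds,
    detect_features,
    detect_hbond,
    detect_pi_stack,
    detect_salt_bridge,
    ligand_length,
    pose_his524_filter,
)
from hydroqsar.structure_model import AtomRecord, MolecularStructure
from tests.conftest import mol_from_smiles, random_rotation

CRIT = GeometricCriteria()


def chain(coords, elements=None):
    elements = elements or ["C"] * len(coords)
    atoms = [AtomRecord(serial=k + 1, element=el, coords=xyz)
             for k, (el, xyz) in enumerate(zip(elements, coords))]
    st = MolecularStructure(atoms=atoms)
    st.bonds = [(i, i + 1, 1) for i in range(len(atoms) - 1)]
    return st


class TestHbond:
    def test_linear_short_bond_hits(self):
        donor = HBondGroup(heavy=[0, 0, 0], hydrogens=[[0.96, 0, 0]])
        acceptor = HBondGroup(heavy=[2.8, 0, 0])
        hit = detect_hbond(donor, acceptor, CRIT)
        assert hit is not None
        assert hit.measured["distance"] == pytest.approx(2.8)
        assert hit.measured["angle"] == pytest.approx(180.0)

    def test_long_distance_misses(self):
        donor = HBondGroup(heavy=[0, 0, 0], hydrogens=[[0.96, 0, 0]])
        acceptor = HBondGroup(heavy=[5.0, 0, 0])
        assert detect_hbond(donor, acceptor, CRIT) is None

    def test_bent_angle_misses(self):
        # direct angle computation: acceptor placed so the D-H...A angle is
        # 100 degrees, below the 120-degree cutoff
        h = np.array([0.96, 0, 0])
        direction = np.array([np.cos(np.deg2rad(80)),
                              np.sin(np.deg2rad(80)), 0.0])
        acc_pos = h + 2.2 * direction
        u = np.array([0, 0, 0]) - h
        v = acc_pos - h
        ang = np.degrees(np.arccos(u @ v / np.linalg.norm(u)
                                   / np.linalg.norm(v)))
        assert ang == pytest.approx(100.0, abs=1e-9)
        donor = HBondGroup(heavy=[0, 0, 0], hydrogens=[h])
        assert detect_hbond(donor, HBondGroup(heavy=acc_pos), CRIT) is None

    def test_donor_without_hydrogen_warns(self):
        donor = HBondGroup(heavy=[0, 0, 0])
        with pytest.warns(UserWarning):
            assert detect_hbond(donor, HBondGroup(heavy=[2.8, 0, 0]),
                                CRIT) is None

    def test_geometry_only_depends_on_positions(self):
        # storage order of the hydrogens never changes the result
        donor1 = HBondGroup(heavy=[0, 0, 0],
                            hydrogens=[[0.96, 0, 0], [-0.3, 0.9, 0]])
        donor2 = HBondGroup(heavy=[0, 0, 0],
                            hydrogens=[[-0.3, 0.9, 0], [0.96, 0, 0]])
        acc = HBondGroup(heavy=[2.8, 0, 0])
        h1 = detect_hbond(donor1, acc, CRIT)
        h2 = detect_hbond(donor2, acc, CRIT)
        assert h1.measured == h2.measured


class TestSaltBridge:
    def _asp(self, od1):
        from hydroqsar.structure_model import PocketResidue

        atoms = [AtomRecord(1, "C", np.asarray(od1) + [0, 1.2, 0],
                            name="CG"),
                 AtomRecord(2, "O", od1, name="OD1"),
                 AtomRecord(3, "O", np.asarray(od1) + [1.1, 1.0, 0],
                            name="OD2")]
        return PocketResidue("ASP", "A", 351, atoms)

    def _amine_ligand(self, n_pos):
        # propylamine-like: C-C-C-N with hydrogens on N
        st = chain([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], list(n_pos)],
                   ["C", "C", "C", "N"])
        h = AtomRecord(5, "H", np.asarray(n_pos) + [0.5, 0.8, 0])
        st.atoms.append(h)
        st.bonds.append((3, 4, 1))
        return st

    def test_close_amine_hits(self):
        lig = self._amine_ligand([4.5, 0, 0])
        hit = detect_salt_bridge(lig, self._asp([4.5, 3.5, 0]), CRIT)
        assert hit is not None
        assert hit.measured["distance"] == pytest.approx(3.5)

    def test_far_amine_misses(self):
        lig = self._amine_ligand([4.5, 0, 0])
        assert detect_salt_bridge(lig, self._asp([4.5, 6.0, 0]), CRIT) is None

    def test_amide_nitrogen_not_basic(self):
        # functional-group perception: amide N adjacent to C=O is excluded
        st = chain([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], ["C", "C", "N"])
        o = AtomRecord(4, "O", [1.5, 1.2, 0])
        st.atoms.append(o)
        st.bonds.append((1, 3, 2))  # carbonyl
        asp = self._asp([3.0, 3.0, 0])
        assert detect_salt_bridge(st, asp, CRIT) is None

    def test_non_acidic_residue_rejected(self):
        from hydroqsar.structure_model import PocketResidue

        ser = PocketResidue("SER", "A", 100,
                            [AtomRecord(1, "O", [0, 0, 0], name="OG")])
        lig = self._amine_ligand([0, 3, 0])
        with pytest.raises(ValueError):
            detect_salt_bridge(lig, ser, CRIT)


class TestPiStack:
    def _ring(self, centroid, normal):
        return RingDescriptor(member_atoms=[0, 1, 2, 3, 4, 5],
                              centroid=np.asarray(centroid, float),
                              normal=np.asarray(normal, float))

    def test_perpendicular_close_hits(self):
        hit = detect_pi_stack(self._ring([0, 0, 0], [0, 0, 1]),
                              self._ring([5, 0, 0], [1, 0, 0]), CRIT)
        assert hit is not None
        assert hit.measured["interplanar_angle"] == pytest.approx(90.0)

    def test_parallel_rings_miss_t_window(self):
        assert detect_pi_stack(self._ring([0, 0, 0], [0, 0, 1]),
                               self._ring([4, 0, 0], [0, 0, 1]),
                               CRIT) is None

    def test_tilted_within_window(self):
        # 75-degree interplanar angle at 4.8 A: inside the (60, 90) window
        n2 = [np.sin(np.deg2rad(75)), 0, np.cos(np.deg2rad(75))]
        hit = detect_pi_stack(self._ring([0, 0, 0], [0, 0, 1]),
                              self._ring([4.8, 0, 0], n2), CRIT)
        assert hit is not None
        assert hit.measured["interplanar_angle"] == pytest.approx(75.0)

    def test_non_ring_rejected(self):
        bad = RingDescriptor(member_atoms=[0], centroid=np.zeros(3),
                             normal=np.array([0, 0, 1.0]))
        with pytest.raises(ValueError):
            detect_pi_stack(bad, self._ring([4, 0, 0], [1, 0, 0]), CRIT)


class TestInternalHbonds:
    def test_ethane_has_none(self):
        assert count_internal_hbonds(mol_from_smiles("CC"), CRIT) == 0

    def _oracle(self, lig):
        # exhaustive enumeration: every (O/N donor with H, O/N acceptor)
        # pair >= 4 bonds apart meeting distance + angle criteria
        import networkx as nx

        g = lig.graph()
        n = 0
        for d in range(len(lig.atoms)):
            if lig.atoms[d].element not in ("O", "N"):
                continue
            hs = [k for k in lig.neighbors(d) if lig.atoms[k].element == "H"]
            if not hs:
                continue
            for a in range(len(lig.atoms)):
                if a == d or lig.atoms[a].element not in ("O", "N"):
                    continue
                try:
                    if nx.shortest_path_length(g, d, a) < 4:
                        continue
                except nx.NetworkXNoPath:
                    pass
                dd = np.linalg.norm(lig.atoms[d].coords - lig.atoms[a].coords)
                if dd > CRIT.hbond_max_dist:
                    continue
                for h in hs:
                    u = lig.atoms[d].coords - lig.atoms[h].coords
                    v = lig.atoms[a].coords - lig.atoms[h].coords
                    ang = np.degrees(np.arccos(
                        np.clip(u @ v / np.linalg.norm(u)
                                / np.linalg.norm(v), -1, 1)))
                    if ang >= CRIT.hbond_min_angle:
                        n += 1
                        break
        return n

    def test_planted_motif_counts_one(self):
        from hydroqsar.fixtures import make_ligand

        lig, _ = make_ligand("phenol", internal_hb=True)
        assert count_internal_hbonds(lig, CRIT) == self._oracle(lig) == 1

    def test_two_independent_motifs(self):
        from hydroqsar.fixtures import make_ligand

        one, _ = make_ligand("phenol", internal_hb=True)
        # duplicate the whole molecule far away: counts add
        two = one.copy()
        shifted = one.copy()
        shifted.set_coords(shifted.coords + np.array([40.0, 0, 0]))
        offset = len(two.atoms)
        two.atoms.extend(shifted.atoms)
        two.bonds.extend([(i + offset, j + offset, o)
                          for i, j, o in shifted.bonds])
        assert count_internal_hbonds(two, CRIT) == self._oracle(two) == 2

    def test_short_separation_excluded(self):
        # catechol-like: adjacent hydroxyls are only 3 bonds apart
        lig = mol_from_smiles("Oc1ccccc1O")
        assert count_internal_hbonds(lig, CRIT) == self._oracle(lig)


class TestLigandLength:
    def test_two_atoms(self):
        st = chain([[0, 0, 0], [3, 0, 0]])
        assert ligand_length(st) == pytest.approx(3.0)

    def test_collinear_chain(self):
        st = chain([[0, 0, 0], [2, 0, 0], [5, 0, 0]])
        assert ligand_length(st) == pytest.approx(5.0)

    def test_matches_brute_force(self, e2_like_complex):
        lig = e2_like_complex.ligand
        heavy = lig.heavy_indices()
        xyz = lig.coords[heavy]
        oracle = max(np.linalg.norm(xyz[i] - xyz[j])
                     for i in range(len(xyz)) for j in range(i))
        assert ligand_length(lig) == pytest.approx(oracle, abs=1e-12)

    def test_hydrogens_ignored(self):
        st = chain([[0, 0, 0], [2, 0, 0], [10, 0, 0]], ["C", "C", "H"])
        assert ligand_length(st) == pytest.approx(2.0)


class TestAringArrangement:
    def _phe(self, centroid, normal=(0, 1, 0)):
        return RingDescriptor(member_atoms=list(range(6)),
                              centroid=np.asarray(centroid, float),
                              normal=np.asarray(normal, float))

    def test_posed_ligand_passes(self, e2_like_complex):
        ring_centroid = np.mean(
            [e2_like_complex.ligand.atoms[i].coords
             for i in e2_like_complex.ligand.rings[0]], axis=0)
        phe = self._phe(ring_centroid + [0, 0, 5.0])
        assert check_aring_arrangement(e2_like_complex.ligand, phe,
                                       criteria=CRIT)

    def test_translated_ligand_fails(self, e2_like_complex):
        lig = e2_like_complex.ligand.copy()
        ring_centroid = np.mean([lig.atoms[i].coords
                                 for i in lig.rings[0]], axis=0)
        phe = self._phe(ring_centroid + [0, 0, 5.0])
        lig.transform(np.eye(3), np.array([8.0, 0, 0]))
        assert not check_aring_arrangement(lig, phe, criteria=CRIT)

    def test_boundary_distance_inclusive(self, e2_like_complex):
        lig = e2_like_complex.ligand
        ring_centroid = np.mean([lig.atoms[i].coords
                                 for i in lig.rings[0]], axis=0)
        phe = self._phe(ring_centroid
                        + [0, 0, CRIT.ring_centroid_max_dist])
        assert check_aring_arrangement(lig, phe, criteria=CRIT)

    def test_no_aromatic_ring_fails(self):
        st = chain([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]])
        assert not check_aring_arrangement(st, self._phe([0, 0, 5]),
                                           criteria=CRIT)


class TestHis524Classification:
    @pytest.mark.parametrize("cls", [CLOSED, MOVED_BACK, OPEN])
    def test_constructed_classes(self, cls):
        cmplx = make_toy_complex(ToyComplexSpec(his524_class=cls))
        assert classify_his524(cmplx.pocket, CRIT) == cls

    def test_missing_his_unknown(self):
        cmplx = make_toy_complex(ToyComplexSpec())
        pocket = [r for r in cmplx.pocket if r.res_name != "HIS"]
        assert classify_his524(pocket, CRIT) == UNKNOWN

    def test_missing_side_chain_unknown(self):
        cmplx = make_toy_complex(ToyComplexSpec())
        for r in cmplx.pocket:
            if r.res_name == "HIS":
                r.atoms = [a for a in r.atoms if a.element != "N"]
        assert classify_his524(cmplx.pocket, CRIT) == UNKNOWN

    def test_rigid_invariance(self):
        cmplx = make_toy_complex(ToyComplexSpec(his524_class=MOVED_BACK))
        before = classify_his524(cmplx.pocket, CRIT)
        cmplx.transform(random_rotation(9), np.array([3.0, -1.0, 7.0]))
        assert classify_his524(cmplx.pocket, CRIT) == before


class TestPoseFilter:
    def _hits(self, *features):
        return [FeatureHit(feature=f, partner="x") for f in features]

    def test_closed_with_both_bonds_passes(self, e2_like_complex):
        lig = e2_like_complex.ligand
        assert pose_his524_filter(lig, CLOSED,
                                  self._hits("hb_E353", "hb_H524"), CRIT)

    def test_missing_hb1_fails_every_class(self, e2_like_complex):
        lig = e2_like_complex.ligand
        for cls in (CLOSED, MOVED_BACK, OPEN):
            assert not pose_his524_filter(lig, cls,
                                          self._hits("hb_H524"), CRIT)

    def test_closed_diol_requires_hb2(self, e2_like_complex):
        # the e2-like ligand has its second hydroxyl 11 A from the phenol,
        # so on a closed receptor HB2 is mandatory
        lig = e2_like_complex.ligand
        assert not pose_his524_filter(lig, CLOSED,
                                      self._hits("hb_E353"), CRIT)

    def test_moved_back_no_hb2_needed(self, e2_like_complex):
        lig = e2_like_complex.ligand
        assert pose_his524_filter(lig, MOVED_BACK,
                                  self._hits("hb_E353"), CRIT)

    def test_open_requires_long_ligand(self, e2_like_complex):
        long_lig = make_toy_complex(
            ToyComplexSpec(ligand_template="amine_tail",
                           his524_class=OPEN)).ligand
        assert ligand_length(long_lig) > CRIT.length_open_threshold
        assert pose_his524_filter(long_lig, OPEN,
                                  self._hits("hb_E353"), CRIT)
        short_lig = make_toy_complex(
            ToyComplexSpec(ligand_template="phenol")).ligand
        assert not pose_his524_filter(short_lig, OPEN,
                                      self._hits("hb_E353"), CRIT)


class TestFeatureScan:
    def test_hits_self_consistent(self, e2_like_complex):
        for hit in detect_features(e2_like_complex, CRIT):
            if "distance" in hit.measured:
                if hit.feature == "salt_bridge_D351":
                    assert hit.measured["distance"] <= CRIT.saltbridge_max_dist
                elif hit.feature.startswith("hb_"):
                    assert hit.measured["distance"] <= CRIT.hbond_max_dist
                    assert hit.measured["angle"] >= CRIT.hbond_min_angle
                elif hit.feature == "pistack_F404":
                    assert (hit.measured["distance"]
                            <= CRIT.ring_centroid_max_dist)

    def test_rigid_invariance_of_scan(self, e2_like_complex):
        before = sorted(h.feature for h in detect_features(e2_like_complex,
                                                           CRIT))
        e2_like_complex.transform(random_rotation(4),
                                  np.array([-2.0, 5.0, 1.0]))
        after = sorted(h.feature for h in detect_features(e2_like_complex,
                                                          CRIT))
        assert before == after
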