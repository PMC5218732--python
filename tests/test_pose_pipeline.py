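"""Pose RMSD, consensus clustering, ranking and receptor selection."""

import numpy as np
import pytest

from hydroqsar.fixtures import ToyComplexSpec, make_pose_set, make_toy_complex
from hydroqsar.pose_pipeline import (
    ClusterConfig,
    DockedPose,
    ReceptorLibraryEntry,
    brute_force_candidates,
    candidate_clusters,
    cluster_poses,
    heavy_atom_rmsd,
    load_poses,
    rank_candidates,
    select_receptors,
    tanimoto,
    topo_fingerprint,
)
from tests.conftest import mol_from_smiles


def shifted(mol, offset):
    st = mol.copy()
    st.set_coords(st.coords + np.asarray(offset, float))
    return st


@pytest.fixture(scope="module")
def base_ligand():
    return make_toy_complex(ToyComplexSpec()).ligand


class TestRmsd:
    def test_identical_is_zero(self, base_ligand):
        assert heavy_atom_rmsd(base_ligand, base_ligand.copy()) == 0.0

    def test_uniform_translation_closed_form(self, base_ligand):
        moved = shifted(base_ligand, [1.0, 0, 0])
        assert heavy_atom_rmsd(base_ligand, moved,
                               symmetry_aware=False) == pytest.approx(1.0)
        # symmetry minimization can never make it worse than the identity
        assert heavy_atom_rmsd(base_ligand, moved) <= 1.0 + 1e-12

    def test_benzene_flip_symmetry(self, benzene_structure):
        flipped = benzene_structure.copy()
        center = flipped.coords.mean(axis=0)
        R = np.diag([1.0, -1.0, -1.0])  # 180-degree rotation about x
        flipped.set_coords((flipped.coords - center) @ R.T + center)
        plain = heavy_atom_rmsd(benzene_structure, flipped,
                                symmetry_aware=False)
        sym = heavy_atom_rmsd(benzene_structure, flipped,
                              symmetry_aware=True)
        assert plain > 0.5
        assert sym == pytest.approx(0.0, abs=0.2)

    def test_graph_mismatch_rejected(self, base_ligand):
        other = mol_from_smiles("CCO")
        with pytest.raises(ValueError):
            heavy_atom_rmsd(base_ligand, other)


class TestClustering:
    def _poses(self, mols):
        return [DockedPose(run_index=i, conformer=m)
                for i, m in enumerate(mols)]

    def test_identical_poses_one_candidate(self, base_ligand):
        poses = self._poses([base_ligand.copy() for _ in range(10)])
        clusters = cluster_poses(poses, ClusterConfig())
        cands = candidate_clusters(clusters)
        assert len(clusters) == 1
        assert len(cands) == 1
        assert cands[0].count == 10

    def test_scattered_poses_no_candidates(self, base_ligand):
        poses = self._poses([shifted(base_ligand, [5.0 * i, 0, 0])
                             for i in range(10)])
        clusters = cluster_poses(poses, ClusterConfig())
        assert len(clusters) == 10
        assert candidate_clusters(clusters) == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_poses([], ClusterConfig())

    def test_members_within_threshold_of_leader(self, base_ligand):
        rng = np.random.default_rng(2)
        poses = self._poses([shifted(base_ligand, rng.normal(0, 0.6, 3))
                             for _ in range(12)])
        cfg = ClusterConfig(symmetry_aware=False)
        for cl in cluster_poses(poses, cfg):
            for m in cl.members:
                assert heavy_atom_rmsd(m, cl.representative,
                                       False) < cfg.rmsd_threshold

    def test_candidate_existence_matches_oracle(self):
        # seeded random fixtures of <= 8 poses with docking-like geometry
        # (binding sites separated by much more than the RMSD threshold,
        # tight within-site jitter): greedy clustering finds a consensus
        # candidate exactly when the exhaustive leader oracle says one exists
        small = mol_from_smiles("CCO")
        cfg = ClusterConfig(symmetry_aware=False)
        for seed in range(300):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 9))
            centers = [np.array([6.0 * k, 0.0, 0.0]) for k in range(3)]
            poses = []
            for i in range(n):
                c = centers[int(rng.integers(3))]
                offset = rng.normal(size=3)
                offset *= 0.25 * rng.random() / np.linalg.norm(offset)
                poses.append(DockedPose(run_index=i,
                                        conformer=shifted(small, c + offset)))
            greedy = bool(candidate_clusters(cluster_poses(poses, cfg), cfg))
            oracle = brute_force_candidates(poses, cfg)
            assert greedy == oracle

    def test_greedy_never_invents_candidates(self):
        # adversarial geometry (sites closer than the threshold allows):
        # greedy may split a borderline consensus but must never report a
        # candidate the exhaustive oracle rejects
        small = mol_from_smiles("CCO")
        cfg = ClusterConfig(symmetry_aware=False)
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            n = int(rng.integers(3, 9))
            poses = [DockedPose(run_index=i,
                                conformer=shifted(small,
                                                  rng.uniform(-1.5, 1.5, 3)))
                     for i in range(n)]
            greedy = bool(candidate_clusters(cluster_poses(poses, cfg), cfg))
            if greedy:
                assert brute_force_candidates(poses, cfg)

    def test_order_permutation_invariant_candidates(self, base_ligand):
        rng = np.random.default_rng(7)
        poses = []
        for i in range(9):
            poses.append(DockedPose(
                run_index=i,
                conformer=shifted(base_ligand,
                                  [0.1 * (i % 3), 0, 6.0 * (i // 3)]),
                engine_score=float(rng.normal(-8, 1))))
        counts1 = sorted(c.count for c in cluster_poses(poses))
        perm = [poses[i] for i in rng.permutation(9)]
        counts2 = sorted(c.count for c in cluster_poses(perm))
        assert counts1 == counts2


class TestPlantedPoseSets:
    def test_planted_multiplicities_recovered(self, base_ligand):
        poses, labels = make_pose_set(base_ligand, n_runs=10, n_per_run=1,
                                      cluster_plan=[(0.2, 5), (0.2, 3),
                                                    (0.2, 2)], seed=1)
        clusters = cluster_poses(poses, ClusterConfig())
        cands = candidate_clusters(clusters)
        assert sorted(c.count for c in clusters) == [2, 3, 5]
        assert sorted(c.count for c in cands) == [3, 5]

    def test_large_jitter_fragments(self, base_ligand):
        cfg = ClusterConfig()
        poses, _ = make_pose_set(base_ligand, 10, 1,
                                 cluster_plan=[(2.0, 8)], seed=3)
        cands = candidate_clusters(cluster_poses(poses, cfg), cfg)
        # fragmentation may reduce the candidate count but consensus never
        # exceeds the plan, and the oracle agrees about existence
        assert len(cands) <= 1 or sum(c.count for c in cands) <= 8
        if cands:
            assert brute_force_candidates(poses, cfg)

    def test_pdbqt_ingestion_rebuilds_hydrogens(self, tmp_path):
        # PDBQT poses carry heavy atoms only (engine merges non-polar H);
        # ingestion must rebuild hydrogens to the template's valences
        template = mol_from_smiles("CCO")
        heavy = template.heavy_indices()
        lines = ["MODEL 1"]
        for k, i in enumerate(heavy):
            a = template.atoms[i]
            x, y, z = a.coords
            lines.append(
                f"ATOM  {k+1:>5d}  {a.element:<3s}LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00    "
                f"+0.000 {a.element:<2s}")
        lines.append("ENDMDL")
        path = tmp_path / "run0.pdbqt"
        path.write_text("\n".join(lines) + "\n")
        poses = load_poses([path], template)
        assert len(poses) == 1
        conf = poses[0].conformer
        assert [conf.atoms[i].element for i in conf.heavy_indices()] \
            == [template.atoms[i].element for i in heavy]
        # valence completion: every carbon regains its hydrogens
        n_h = sum(1 for a in conf.atoms if a.element == "H")
        carbons_h = sum(
            1 for i, a in enumerate(template.atoms) if a.element == "H"
            and any(template.atoms[n].element == "C"
                    for n in template.neighbors(i)))
        assert n_h >= carbons_h

    def test_graph_mismatch_reports_file(self, tmp_path, base_ligand):
        from rdkit import Chem

        from hydroqsar.structure_model import to_rdkit

        path = tmp_path / "bad.sdf"
        w = Chem.SDWriter(str(path))
        w.write(to_rdkit(mol_from_smiles("CCO")))
        w.close()
        with pytest.raises(ValueError, match="bad.sdf"):
            load_poses([path], base_ligand)

    def test_pose_files_round_trip(self, base_ligand, tmp_path):
        make_pose_set(base_ligand, n_runs=4, n_per_run=2,
                      cluster_plan=[(0.15, 5), (0.15, 3)], seed=5,
                      out_dir=tmp_path)
        files = sorted(tmp_path.glob("run*.sdf"))
        assert len(files) == 4
        poses = load_poses(files, base_ligand)
        assert len(poses) == 8
        cands = candidate_clusters(cluster_poses(poses, ClusterConfig()))
        assert sorted(c.count for c in cands) == [3, 5]


class TestRanking:
    def _receptor(self):
        return make_toy_complex(ToyComplexSpec(
            feature_switches=frozenset({"HB_E353", "HB_H524"})))

    def test_single_candidate_rank_one(self):
        rec = self._receptor()
        poses = [DockedPose(run_index=i, conformer=rec.ligand.copy())
                 for i in range(5)]
        ranked = rank_candidates(cluster_poses(poses), rec)
        assert len(ranked) == 1
        assert ranked[0].rank == 1
        assert ranked[0].passed_filter

    def test_bad_pose_filtered_out(self):
        rec = self._receptor()
        good = [DockedPose(run_index=i, conformer=rec.ligand.copy(),
                           engine_score=-9.0) for i in range(4)]
        # displaced pose: loses the Glu353 bond (HB1) -> dropped
        bad_conf = shifted(rec.ligand, [20.0, 0, 0])
        bad = [DockedPose(run_index=4 + i, conformer=bad_conf.copy(),
                          engine_score=-7.0) for i in range(4)]
        ranked = rank_candidates(cluster_poses(good + bad), rec)
        passed = [r for r in ranked if r.passed_filter]
        failed = [r for r in ranked if not r.passed_filter]
        assert len(passed) == 1 and len(failed) == 1
        assert passed[0].rank == 1 and failed[0].rank == 0

    def test_rank_order_matches_recomputed_predictions(self):
        rec = self._receptor()
        ranked = rank_candidates(cluster_poses(
            [DockedPose(run_index=i, conformer=rec.ligand.copy())
             for i in range(6)]), rec)
        scores = [r.prediction.log_rba for r in ranked if r.passed_filter]
        assert scores == sorted(scores, reverse=True)

    def test_all_filtered_is_ni_outcome(self):
        rec = self._receptor()
        bad_conf = shifted(rec.ligand, [20.0, 0, 0])
        poses = [DockedPose(run_index=i, conformer=bad_conf.copy())
                 for i in range(5)]
        with pytest.warns(UserWarning):
            ranked = rank_candidates(cluster_poses(poses), rec)
        assert all(not r.passed_filter for r in ranked)


class TestSimilarity:
    def test_identical_molecules_identical_bits(self):
        a = topo_fingerprint(mol_from_smiles("CCO"))
        b = topo_fingerprint(mol_from_smiles("CCO", seed=99))
        assert np.array_equal(a, b)
        assert tanimoto(a, b) == 1.0

    def test_different_molecules_differ(self):
        a = topo_fingerprint(mol_from_smiles("C"))
        b = topo_fingerprint(mol_from_smiles("CCCCCCCCCC"))
        assert not np.array_equal(a, b)

    def test_permutation_stable(self):
        from rdkit import Chem

        from hydroqsar.structure_model import from_rdkit, to_rdkit

        base = mol_from_smiles("CC(C)c1ccc(O)cc1")
        ref = topo_fingerprint(base)
        rd = to_rdkit(base)
        rng = np.random.default_rng(0)
        for _ in range(20):
            order = list(rng.permutation(rd.GetNumAtoms()))
            shuffled = Chem.RenumberAtoms(rd, [int(i) for i in order])
            assert np.array_equal(topo_fingerprint(from_rdkit(shuffled)),
                                  ref)

    def test_tanimoto_values(self):
        a = np.zeros(8, bool)
        b = np.zeros(8, bool)
        a[[1, 2, 3]] = True
        b[[2, 3, 4]] = True
        assert tanimoto(a, b) == pytest.approx(0.5)  # 2 / 4
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, np.zeros(8, bool)) == 0.0
        assert tanimoto(np.zeros(8, bool), np.zeros(8, bool)) == 1.0
        with pytest.raises(ValueError):
            tanimoto(a, np.zeros(4, bool))


class TestReceptorSelection:
    def _entry(self, smiles, label, cls):
        cmplx = make_toy_complex(ToyComplexSpec())
        cmplx.receptor_label = label
        return ReceptorLibraryEntry(receptor=cmplx,
                                    cocrystal_ligand=mol_from_smiles(smiles),
                                    receptor_class=cls)

    def test_identity_match_wins(self):
        lib = [self._entry("c1ccccc1O", "rec_phenol", "closed"),
               self._entry("CCCCCCCC", "rec_octane", "closed"),
               self._entry("CCO", "rec_ethanol", "moved_back"),
               self._entry("c1ccccc1", "rec_benzene", "open")]
        chosen = select_receptors(mol_from_smiles("c1ccccc1O"), lib)
        assert chosen["closed"].receptor.receptor_label == "rec_phenol"

    def test_single_entry_classes(self):
        lib = [self._entry("CCO", "a", "closed"),
               self._entry("CCC", "b", "moved_back"),
               self._entry("CCN", "c", "open")]
        chosen = select_receptors(mol_from_smiles("c1ccccc1O"), lib)
        assert {cls: e.receptor.receptor_label
                for cls, e in chosen.items()} == {"closed": "a",
                                                  "moved_back": "b",
                                                  "open": "c"}

    def test_matches_brute_force_argmax(self):
        smiles = ["CCO", "CCCO", "c1ccccc1", "c1ccccc1O", "CC(C)C", "CCCCC"]
        lib = [self._entry(s, f"rec{i}", cls)
               for i, (s, cls) in enumerate(zip(
                   smiles, ["closed", "closed", "moved_back", "moved_back",
                            "open", "open"]))]
        query = mol_from_smiles("CCCCO")
        qfp = topo_fingerprint(query)
        chosen = select_receptors(query, lib)
        for cls in ("closed", "moved_back", "open"):
            entries = [e for e in lib if e.receptor_class == cls]
            sims = [tanimoto(qfp, topo_fingerprint(e.cocrystal_ligand))
                    for e in entries]
            best = entries[int(np.argmax(sims))]
            assert chosen[cls].receptor.receptor_label \
                == best.receptor.receptor_label

    def test_missing_class_warns(self):
        lib = [self._entry("CCO", "a", "closed")]
        with pytest.warns(UserWarning):
            chosen = select_receptors(mol_from_smiles("CCO"), lib)
        assert set(chosen) == {"closed"}
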