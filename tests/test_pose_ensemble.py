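"""Pose post-processing: embedding, dual selection, MDCOM, complexes, ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bindkit.datatypes import Embedding, PlantedPoseSpec, PoseEnsemble, Structure, Topology
from bindkit.pose_ensemble import (
    build_complexes,
    common_frame,
    kde_select,
    mdcom,
    pca_embed,
    pose_centers_of_mass,
    rank_rescoring,
    score_select,
    select_poses,
)
from bindkit.synthetic_data import (
    _random_rotation,
    default_ligand_template,
    gen_pose_ensemble,
)


def _mini_ensemble(coords, scores=None, snapshot_ids=None):
    n, m = coords.shape[:2]
    return PoseEnsemble(
        element=np.full(m, "C", dtype="U4"),
        atom_name=np.array([f"C{i+1}" for i in range(m)], dtype="U6"),
        coords=coords,
        scores=np.zeros(n) if scores is None else np.asarray(scores, float),
        provenance=pd.DataFrame({
            "snapshot_id": np.zeros(n, int) if snapshot_ids is None else snapshot_ids,
            "conformer_id": np.arange(n),
            "epimer": ["alpha"] * n,
        }),
    )


def _snapshot(coords):
    n = coords.shape[0]
    topo = Topology(element=np.full(n, "C", dtype="U4"),
                    atom_name=np.full(n, "CA", dtype="U6"),
                    res_id=np.arange(1, n + 1),
                    res_name=np.full(n, "GLY", dtype="U4"),
                    chain=np.full(n, "A", dtype="U2"))
    return Structure(topo, coords)


class TestCommonFrame:
    def test_single_snapshot_is_identity(self, rng):
        coords = rng.standard_normal((5, 4, 3))
        ens = _mini_ensemble(coords)
        snap = _snapshot(rng.standard_normal((10, 3)) * 8)
        out = common_frame({0: snap}, ens, np.arange(10))
        assert np.allclose(out.coords, coords, atol=1e-10)

    def test_known_rotation_recovered(self, rng):
        base = rng.standard_normal((12, 3)) * 8
        R = _random_rotation(rng)
        t = np.array([3.0, -2.0, 5.0])
        snaps = {0: _snapshot(base), 1: _snapshot(base @ R.T + t)}
        # one pose rigidly attached to each snapshot at the same local site
        site = base[:4] + 1.0
        ens = _mini_ensemble(np.stack([site, site @ R.T + t]),
                             snapshot_ids=np.array([0, 1]))
        out = common_frame(snaps, ens, np.arange(12))
        # after projection both poses coincide in the reference frame
        assert np.allclose(out.coords[0], out.coords[1], atol=1e-8)

    def test_rigid_projection_preserves_internal_distances(self, rng):
        base = rng.standard_normal((12, 3)) * 8
        R = _random_rotation(rng)
        snaps = {0: _snapshot(base), 1: _snapshot(base @ R.T)}
        coords = rng.standard_normal((6, 5, 3))
        ens = _mini_ensemble(coords, snapshot_ids=np.array([0, 1] * 3))
        out = common_frame(snaps, ens, np.arange(12))
        for k in range(6):
            d_in = np.linalg.norm(coords[k][:, None] - coords[k][None, :], axis=2)
            d_out = np.linalg.norm(out.coords[k][:, None] - out.coords[k][None, :], axis=2)
            assert np.allclose(d_in, d_out, atol=1e-8)

    def test_missing_snapshot_errors_with_ids(self, rng):
        ens = _mini_ensemble(rng.standard_normal((2, 4, 3)),
                             snapshot_ids=np.array([0, 7]))
        with pytest.raises(KeyError, match="7"):
            common_frame({0: _snapshot(rng.standard_normal((10, 3)))},
                         ens, np.arange(10))


class TestPCA:
    def test_identical_poses_degenerate_with_warning(self):
        coords = np.tile(np.arange(12.0).reshape(4, 3), (5, 1, 1))
        with pytest.warns(UserWarning):
            emb = pca_embed(_mini_ensemble(coords))
        assert emb.explained_variance == (0.0, 0.0)
        assert np.allclose(emb.points, 0.0)

    def test_two_rigid_clusters_separated_on_pc1(self):
        base = np.arange(12.0).reshape(4, 3)
        shift = np.array([10.0, 0, 0])
        coords = np.stack([base] * 10 + [base + shift] * 10)
        emb = pca_embed(_mini_ensemble(coords))
        pc1 = emb.points[:, 0]
        assert abs(pc1[:10].mean() - pc1[10:].mean()) > 15.0  # 10 A over 4 atoms -> 20 in 3N space
        # deterministic sign convention: first nonzero loading positive
        nz = emb.components[0][np.abs(emb.components[0]) > 1e-12]
        assert nz[0] > 0

    def test_matches_brute_force_covariance_eigendecomposition(self, rng):
        coords = rng.standard_normal((30, 6, 3)) * 3
        ens = _mini_ensemble(coords)
        emb = pca_embed(ens)
        X = coords.reshape(30, -1)
        C = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        frac = eig[:2] / eig.sum()
        assert emb.explained_variance[0] == pytest.approx(frac[0], rel=1e-9)
        assert emb.explained_variance[1] == pytest.approx(frac[1], rel=1e-9)

    def test_matches_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        coords = rng.standard_normal((40, 5, 3)) * 2
        emb = pca_embed(_mini_ensemble(coords))
        ref = sklearn.PCA(n_components=2).fit(coords.reshape(40, -1))
        assert np.allclose(np.abs(emb.points),
                           np.abs(ref.transform(coords.reshape(40, -1))), atol=1e-8)


class TestKDESelect:
    def test_k_equals_n_selects_all(self, rng):
        pts = rng.standard_normal((15, 2))
        emb = Embedding(points=pts, explained_variance=(0.6, 0.4),
                        mean_vector=np.zeros(4), components=np.zeros((2, 4)))
        idx, _ = kde_select(emb, k=15)
        assert sorted(idx.tolist()) == list(range(15))

    def test_k_above_n_rejected(self, rng):
        emb = Embedding(points=rng.standard_normal((5, 2)),
                        explained_variance=(0.6, 0.4),
                        mean_vector=np.zeros(4), components=np.zeros((2, 4)))
        with pytest.raises(ValueError):
            kde_select(emb, k=6)

    def test_selected_points_sit_at_planted_modes(self):
        # two tight modes far apart (>> 8 scalar bandwidths): taking one pose
        # per density mode must land within one bandwidth of a planted mode
        # in >= 95% of seeds
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 60
            pts = np.concatenate([0.3 * r.standard_normal((n // 2, 2)),
                                  0.3 * r.standard_normal((n // 2, 2)) + [12.0, 0.0]])
            bw = pts.std(axis=0, ddof=1) * n ** (-1 / 6)
            h = float(np.sqrt(bw[0] * bw[1]))
            assert 12.0 > 8 * h
            emb = Embedding(points=pts, explained_variance=(0.9, 0.1),
                            mean_vector=np.zeros(4), components=np.zeros((2, 4)))
            idx, _ = kde_select(emb, k=2)
            sel = pts[idx]
            d0 = np.linalg.norm(sel - [0.0, 0.0], axis=1)
            d1 = np.linalg.norm(sel - [12.0, 0.0], axis=1)
            if np.all(np.minimum(d0, d1) <= h):
                hits += 1
        assert hits >= 95

    def test_deterministic_given_identical_input(self, two_cluster_ensemble):
        ens, _ = two_cluster_ensemble
        emb = pca_embed(ens)
        a, _ = kde_select(emb, 10)
        b, _ = kde_select(emb, 10)
        assert np.array_equal(a, b)


class TestScoreSelect:
    def test_distinct_scores_pick_k_smallest(self, rng):
        scores = rng.permutation(20).astype(float)
        ens = _mini_ensemble(rng.standard_normal((20, 3, 3)), scores=scores)
        idx = score_select(ens, 5)
        assert sorted(scores[idx]) == sorted(scores)[:5]

    def test_equal_scores_fall_back_to_provenance_order(self, rng):
        ens = _mini_ensemble(rng.standard_normal((10, 3, 3)), scores=np.zeros(10))
        assert np.array_equal(score_select(ens, 4), np.arange(4))

    def test_better_scoring_cluster_dominates_selection(self, two_cluster_ensemble):
        # cluster 0 scores -8 +/- 0.5, cluster 1 scores -6 +/- 0.5 (3-4 sigma)
        ens, truth = two_cluster_ensemble
        idx = score_select(ens, 10)
        assert np.sum(truth.cluster_of[idx] == 0) >= 8


class TestMDCOM:
    def test_identical_poses_give_zero(self):
        coords = np.tile(np.arange(9.0).reshape(3, 3), (4, 1, 1))
        assert mdcom(_mini_ensemble(coords), [0, 1, 2, 3]) == 0.0

    def test_two_poses_separated_4A(self):
        base = np.arange(9.0).reshape(3, 3)
        coords = np.stack([base, base + [4.0, 0, 0]])
        assert mdcom(_mini_ensemble(coords), [0, 1]) == pytest.approx(4.0, rel=1e-12)

    def test_matches_brute_force_pair_mean(self, two_cluster_ensemble):
        ens, _ = two_cluster_ensemble
        idx = np.arange(25)
        coms = pose_centers_of_mass(ens)[idx]
        pairs = [np.linalg.norm(coms[i] - coms[j])
                 for i, j in itertools.combinations(range(25), 2)]
        assert mdcom(ens, idx) == pytest.approx(np.mean(pairs), rel=1e-12)

    def test_invariant_under_global_rigid_transform(self, two_cluster_ensemble, rng):
        ens, _ = two_cluster_ensemble
        idx = np.arange(30)
        before = mdcom(ens, idx)
        R = _random_rotation(rng)
        moved = PoseEnsemble(element=ens.element, atom_name=ens.atom_name,
                             coords=ens.coords @ R.T + np.array([5.0, -3.0, 2.0]),
                             scores=ens.scores, provenance=ens.provenance)
        assert mdcom(moved, idx) == pytest.approx(before, rel=1e-9)

    def test_tight_cluster_far_below_split_selection(self, two_cluster_spec):
        ens, truth = gen_pose_ensemble(two_cluster_spec, seed=5)
        tight = np.nonzero(truth.cluster_of == 0)[0][:10]
        split = np.concatenate([np.nonzero(truth.cluster_of == 0)[0][:5],
                                np.nonzero(truth.cluster_of == 1)[0][:5]])
        assert mdcom(ens, tight) < 2.0
        assert mdcom(ens, split) > 4.0

    def test_fewer_than_two_indices_rejected(self, two_cluster_ensemble):
        with pytest.raises(ValueError):
            mdcom(two_cluster_ensemble[0], [3])


class TestSelectPoses:
    def test_convergent_vs_divergent_diagnostic(self, two_cluster_spec):
        # both routes favor cluster 0 -> union MDCOM well below the 10 A
        # inter-cluster distance (the convergent case)
        ens, truth = gen_pose_ensemble(two_cluster_spec, seed=3)
        sel = select_poses(ens)
        assert sel.union_indices.size <= 20
        assert sel.mdcom < 10.0

        # flip the score model so score favors the far cluster while density
        # still favors the big one: union MDCOM approaches the separation
        spec = PlantedPoseSpec(
            centers=two_cluster_spec.centers, spread=[0.5, 0.5], counts=[120, 80],
            ligand_template=default_ligand_template(),
            score_model=[(-6.0, 0.2), (-8.0, 0.2)],
        )
        ens2, _ = gen_pose_ensemble(spec, seed=3)
        sel2 = select_poses(ens2)
        assert sel2.mdcom > sel.mdcom
        assert sel2.mdcom > 3.0

    def test_fully_overlapping_selections_collapse(self, rng):
        # 10 poses, both routes must pick all of them
        coords = rng.standard_normal((10, 4, 3))
        ens = _mini_ensemble(coords, scores=np.arange(10.0))
        sel = select_poses(ens, k_score=10, k_kde=10)
        assert sel.union_indices.size == 10
        assert sel.overlap_fraction == 1.0


class TestComplexes:
    def test_atom_counts_and_coordinates_conserved(self, rng):
        ens = _mini_ensemble(rng.standard_normal((6, 5, 3)) * 4)
        snap = _snapshot(rng.standard_normal((20, 3)) * 10)
        cxs = build_complexes({0: snap}, ens,
                              np.arange(5), ligand_chain="L")
        assert len(cxs) == 5
        for k, cx in enumerate(cxs):
            assert cx.topology.n_atoms == 20 + ens.n_atoms
            assert np.array_equal(cx.coords[:20], snap.coords)
            assert np.array_equal(cx.coords[20:], ens.coords[k])
            assert set(cx.topology.chain[20:]) == {"L"}
            assert set(cx.topology.res_name[20:]) == {"PUN"}

    def test_empty_selection_is_clean_noop(self, rng):
        ens = _mini_ensemble(rng.standard_normal((4, 3, 3)))
        snap = _snapshot(rng.standard_normal((8, 3)))
        assert build_complexes({0: snap}, ens, []) == []

    def test_ligand_chain_collision_rejected(self, rng):
        ens = _mini_ensemble(rng.standard_normal((4, 3, 3)))
        snap = _snapshot(rng.standard_normal((8, 3)))
        with pytest.raises(ValueError, match="chain"):
            build_complexes({0: snap}, ens, [0], ligand_chain="A")


class TestRescoring:
    def test_printed_energy_gap(self):
        table = pd.DataFrame({"pose_id": ["A", "B"],
                              "energy_kcal_mol": [-56.8, -45.8]})
        best, gap = rank_rescoring(table)
        assert best == "A"
        assert gap == pytest.approx(11.0, abs=1e-12)

    def test_single_row_gap_is_sentinel(self):
        best, gap = rank_rescoring(pd.DataFrame({"pose_id": [3],
                                                 "energy_kcal_mol": [-40.0]}))
        assert best == 3 and np.isinf(gap)

    def test_invariant_under_all_row_permutations(self):
        rows = list(zip("ABCD", [-50.0, -42.5, -61.3, -55.1]))
        ref = rank_rescoring(pd.DataFrame(rows, columns=["pose_id", "energy_kcal_mol"]))
        for perm in itertools.permutations(rows):
            table = pd.DataFrame(perm, columns=["pose_id", "energy_kcal_mol"])
            assert rank_rescoring(table) == ref

    def test_duplicate_ids_rejected(self):
        table = pd.DataFrame({"pose_id": ["A", "A"], "energy_kcal_mol": [-1.0, -2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            rank_rescoring(table)
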