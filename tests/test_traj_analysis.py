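"""Trajectory statistics: Kabsch, RMSD/RMSF, SASA, distances, sampling."""

import numpy as np
import pytest
from scipy.integrate import trapezoid

from bindkit.datatypes import SeriesResult, Topology, Trajectory
from bindkit.synthetic_data import _random_rotation
from bindkit.traj_analysis import (
    density_profile,
    min_distance_brute,
    min_distance_series,
    rmsd_series,
    rmsf,
    sample_snapshots,
    sasa_series,
    shrake_rupley_sasa,
    superpose,
)
from conftest import chain_indices


def _toy_traj(frames, atom_name="CA"):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    topo = Topology(element=np.full(n, "C", dtype="U4"),
                    atom_name=np.full(n, atom_name, dtype="U6"),
                    res_id=np.arange(1, n + 1),
                    res_name=np.full(n, "GLY", dtype="U4"),
                    chain=np.full(n, "A", dtype="U2"))
    return Trajectory(topology=topo, frames=frames)


class TestSuperpose:
    def test_identical_coordinates_identity_transform(self, rng):
        x = rng.standard_normal((10, 3)) * 5
        R, t, r = superpose(x, x)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0.0, atol=1e-12)

    def test_known_rotation_recovered(self, rng):
        x = rng.standard_normal((20, 3)) * 5
        R_true = _random_rotation(rng)
        y = x @ R_true.T + np.array([1.0, -2.0, 0.5])
        R, t, r = superpose(x, y)
        assert r < 1e-10
        assert np.allclose(R, R_true, atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_optimal_among_random_rotations(self, rng):
        x = rng.standard_normal((15, 3)) * 4
        y = x + rng.standard_normal((15, 3)) * 0.8
        _, _, best = superpose(x, y)
        cy = y - y.mean(axis=0)
        cx = x - x.mean(axis=0)
        for _ in range(500):
            R = _random_rotation(rng)
            r = np.sqrt(np.mean(np.sum((cx @ R.T - cy) ** 2, axis=1)))
            assert best <= r + 1e-12

    def test_collinear_selection_rejected(self):
        x = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose(x, x + 1.0)


class TestRMSDSeries:
    def test_reference_frame_has_zero_rmsd(self, hinge_traj):
        s = rmsd_series(hinge_traj, 0)
        assert s.values[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_body_motion_is_invisible(self, rng):
        base = rng.standard_normal((12, 3)) * 6
        frames = [base]
        for _ in range(9):
            R = _random_rotation(rng)
            frames.append(base @ R.T + rng.standard_normal(3) * 10)
        s = rmsd_series(_toy_traj(np.stack(frames)), 0)
        assert np.all(s.values < 1e-8)

    def test_hinge_rmsd_increases_when_fit_on_fixed_domain(self, hinge_traj_clean):
        t = hinge_traj_clean
        A = chain_indices(t, "A")
        s = rmsd_series(t, 0, selection=np.arange(t.topology.n_atoms),
                        fit_selection=A)
        assert s.values[-1] > s.values[1] > 0


class TestDensityProfile:
    def test_integrates_to_one(self, rng):
        s = SeriesResult(values=rng.normal(3.0, 0.5, 400), metric="rmsd")
        grid, dens = density_profile(s)
        assert trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_series_gives_two_modes(self, rng):
        vals = np.concatenate([rng.normal(2.0, 0.1, 200), rng.normal(8.0, 0.1, 200)])
        grid, dens = density_profile(SeriesResult(values=vals, metric="rmsd"))
        # compare against a coarse histogram oracle
        hist, edges = np.histogram(vals, bins=30, density=True)
        top2 = np.sort(edges[:-1][np.argsort(hist)[-2:]] + np.diff(edges)[0] / 2)
        interior = np.arange(1, dens.size - 1)
        peaks = interior[(dens[interior] > dens[interior - 1])
                         & (dens[interior] > dens[interior + 1])]
        modes = np.sort(grid[peaks[np.argsort(dens[peaks])[-2:]]])
        assert np.allclose(modes, top2, atol=0.5)

    def test_constant_series_warns_and_peaks_at_value(self):
        s = SeriesResult(values=np.full(50, 4.2), metric="rmsd")
        with pytest.warns(UserWarning):
            grid, dens = density_profile(s)
        assert grid[np.argmax(dens)] == pytest.approx(4.2, abs=1e-3)


class TestRMSF:
    def test_static_trajectory_gives_zero(self, rng):
        base = rng.standard_normal((8, 3)) * 5
        t = _toy_traj(np.tile(base, (6, 1, 1)))
        _, values = rmsf(t)
        assert np.allclose(values, 0.0, atol=1e-10)

    def test_planted_isotropic_jitter_matches_sigma_sqrt3(self, rng):
        # one mobile residue with sd sigma among anchored ones: RMSF = sigma*sqrt(3)
        sigma = 0.4
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [4, 4, 4],
                         [8, 4, 0], [4, 8, 0], [0, 4, 8]], dtype=float)
        frames = np.tile(base, (2000, 1, 1))
        frames[:, 4, :] += sigma * rng.standard_normal((2000, 3))
        t = _toy_traj(frames)
        _, values = rmsf(t, selection=np.array([0, 1, 2, 3, 5, 6, 7]))
        assert values[4] == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_mobile_domain_exceeds_fixed_domain(self, hinge_traj):
        t = hinge_traj
        A = chain_indices(t, "A")
        _, values = rmsf(t, selection=A)
        n_a = A.size
        assert values[n_a:].mean() > 3 * values[:n_a].mean()


class TestSASA:
    def test_isolated_atom_matches_analytic_sphere(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array(["C"]))
        assert area[0] == pytest.approx(4 * np.pi * (1.70 + 1.40) ** 2, rel=0.01)

    def test_caged_atom_is_fully_buried(self):
        # octahedral cage of carbons 2 A away blocks every direction
        center = np.zeros((1, 3))
        cage = 2.0 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                               [0, 0, 1], [0, 0, -1]], dtype=float)
        coords = np.vstack([center, cage])
        areas = shrake_rupley_sasa(coords, np.array(["C"] * 7))
        assert areas[0] == 0.0

    def test_partition_consistency(self, hinge_traj_clean):
        # per-residue SASA sums to the whole-molecule value
        t = hinge_traj_clean
        frame = 0
        per_atom = shrake_rupley_sasa(t.frames[frame], t.topology.element,
                                      n_points=240)
        total = per_atom.sum()
        by_residue = sum(
            per_atom[t.topology.res_id == rid].sum()
            for rid in np.unique(t.topology.res_id))
        assert by_residue == pytest.approx(total, rel=1e-12)

    def test_agrees_with_biotite_reference(self, rng):
        biotite_struc = pytest.importorskip("biotite.structure")
        coords = rng.standard_normal((15, 3)) * 3.0
        elements = np.array(["C", "N", "O"] * 5)
        mine = shrake_rupley_sasa(coords, elements, n_points=960)
        arr = biotite_struc.AtomArray(15)
        arr.coord = coords.astype(np.float32)
        arr.element = elements
        arr.chain_id = np.full(15, "A")
        arr.res_id = np.arange(1, 16)
        arr.res_name = np.full(15, "GLY")
        arr.atom_name = np.array([f"X{i}" for i in range(15)])
        radii = {"C": 1.70, "N": 1.55, "O": 1.52}
        ref = biotite_struc.sasa(arr, probe_radius=1.4, point_number=960,
                                 vdw_radii=np.array([radii[e] for e in elements]))
        assert np.allclose(mine, ref, rtol=0.05, atol=0.5)

    def test_unknown_element_is_rejected_by_name(self):
        with pytest.raises(ValueError, match="Xx"):
            shrake_rupley_sasa(np.zeros((1, 3)), np.array(["Xx"]))


class TestMinDistance:
    def test_overlapping_selections_rejected(self, hinge_traj_clean):
        with pytest.raises(ValueError, match="overlap"):
            min_distance_series(hinge_traj_clean, np.array([0, 1]), np.array([1, 2]))

    def test_planted_closest_pair(self):
        frame = np.array([[0, 0, 0], [50, 0, 0], [7.3, 0, 0], [60, 0, 0]], float)
        t = _toy_traj(frame[None])
        s = min_distance_series(t, np.array([0, 1]), np.array([2, 3]))
        assert s.values[0] == pytest.approx(7.3, rel=1e-12)

    def test_grid_equals_brute_force_on_random_frames(self, rng):
        for _ in range(100):
            frames = rng.standard_normal((1, 14, 3)) * 6
            t = _toy_traj(frames)
            a, b = np.arange(7), np.arange(7, 14)
            grid = min_distance_series(t, a, b, method="grid").values[0]
            brute = min_distance_brute(frames[0][a], frames[0][b])
            assert grid == brute


class TestSampling:
    def test_n_equals_frames_returns_all(self, hinge_traj_clean):
        idx = sample_snapshots(hinge_traj_clean, hinge_traj_clean.n_frames)
        assert np.array_equal(idx, np.arange(hinge_traj_clean.n_frames))

    def test_stride_indices_are_arithmetic(self, rng):
        t = _toy_traj(rng.standard_normal((600, 4, 3)))
        idx = sample_snapshots(t, 60, "stride")
        assert np.array_equal(idx, np.arange(0, 600, 10))

    def test_requested_count_unique_sorted(self, hinge_traj):
        idx = sample_snapshots(hinge_traj, 30, "rmsd-spread")
        assert idx.size == 30
        assert np.array_equal(idx, np.unique(idx))
        again = sample_snapshots(hinge_traj, 30, "rmsd-spread")
        assert np.array_equal(idx, again)

    def test_oversampling_rejected(self, hinge_traj):
        with pytest.raises(ValueError):
            sample_snapshots(hinge_traj, hinge_traj.n_frames + 1)


class TestRigidInvariance:
    def test_all_metrics_invariant_under_global_transform(self, hinge_traj, rng):
        t = hinge_traj
        R = _random_rotation(rng)
        shift = np.array([7.0, -4.0, 11.0])
        moved = Trajectory(topology=t.topology, frames=t.frames @ R.T + shift)
        A, B = chain_indices(t, "A"), chain_indices(t, "B")

        assert np.allclose(rmsd_series(t, 0, selection=A).values,
                           rmsd_series(moved, 0, selection=A).values, atol=1e-8)
        assert np.allclose(rmsf(t, selection=A)[1], rmsf(moved, selection=A)[1],
                           atol=1e-8)
        assert np.allclose(min_distance_series(t, A, B).values,
                           min_distance_series(moved, A, B).values, atol=1e-8)
        # SASA is quadrature-based, so rotation invariance holds to the
        # point-set resolution rather than exactly
        sub = Trajectory(topology=t.topology, frames=t.frames[::8])
        sub_moved = Trajectory(topology=t.topology, frames=moved.frames[::8])
        probe = np.array([t.probe_index])
        assert np.allclose(sasa_series(sub, probe, n_points=960).values,
                           sasa_series(sub_moved, probe, n_points=960).values,
                           rtol=0.02, atol=1.0)
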