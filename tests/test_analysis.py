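"""Observable estimators: windowed diffusion, regime labels, contacts,
clusters, density, shape, coalescence and the border curve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condmd import analysis
from condmd.analysis import (DiffusionSeries, TrajectoryTooShortError,
                             border_curve, classify_regime, coalescence_time,
                             deceleration_time_bracket, diffusion_time_real_units,
                             msd_windowed, shape_metrics, strong_contacts)
from condmd.builders import make_synthetic_fixtures
from condmd.model import BeadRole
from condmd.trajectory import Trajectory


def _series(times, Ds):
    times = np.asarray(times, dtype=float)
    Ds = np.asarray(Ds, dtype=float)
    spans = np.gradient(times)
    return DiffusionSeries(times, Ds, spans, np.full_like(times, 4.0))


class TestMsdWindowed:
    def test_windows_satisfy_displacement_rule(self):
        traj = make_synthetic_fixtures(
            "brownian_walkers", {"D_true": 0.5, "n_walkers": 400,
                                 "n_frames": 200, "dt_frame": 1.0}, seed=0)
        s = msd_windowed(traj, displacement_factor=4.0)
        assert np.all(s.displacement_check >= 4.0)
        assert np.all(np.diff(s.window_centers) > 0)

    @pytest.mark.parametrize("D_true", [0.02, 0.5, 2.0])
    def test_recovers_ground_truth_across_decades(self, D_true):
        traj = make_synthetic_fixtures(
            "brownian_walkers", {"D_true": D_true, "n_walkers": 1200,
                                 "n_frames": 160,
                                 "dt_frame": 4.0 / (6.0 * D_true)}, seed=7)
        s = msd_windowed(traj)
        assert np.mean(s.D_values) == pytest.approx(D_true, rel=0.05)

    def test_frozen_trajectory_raises(self):
        pos = np.zeros((30, 50, 3)) + 5.0
        traj = Trajectory(np.arange(30.0), pos, np.array([100.0] * 3),
                          np.full(50, 2, np.int8), 1)
        with pytest.raises(TrajectoryTooShortError):
            msd_windowed(traj)

    def test_frozen_trajectory_partial_bound(self):
        rng = np.random.default_rng(0)
        pos = 5.0 + 0.01 * rng.normal(size=(30, 50, 3)).cumsum(axis=0)
        traj = Trajectory(np.arange(30.0), pos, np.array([100.0] * 3),
                          np.full(50, 2, np.int8), 1)
        s = msd_windowed(traj, allow_partial=True)
        assert s.partial_last
        assert s.D_values[-1] < 1e-3


class TestClassifyRegime:
    def test_constant_series_above_threshold_is_liquid(self):
        lab = classify_regime(_series([10, 20, 30, 40], [2e-3] * 4), 2e-4)
        assert lab.label == "liquid" and lab.onset_time is None

    def test_decaying_series_crossing_is_ageing_with_onset(self):
        t = np.linspace(100, 3000, 25)
        D = 1e-2 * np.exp(-t / 400.0)  # crosses 2e-4 at t ~ 1565
        lab = classify_regime(_series(t, D), 2e-4)
        assert lab.label == "ageing"
        t_expect = 400.0 * np.log(1e-2 / 2e-4)
        assert lab.onset_time == pytest.approx(t_expect, abs=t[1] - t[0])

    def test_decaying_series_without_crossing_is_extrapolated_ageing(self):
        t = np.array([50.0, 150.0, 400.0, 1000.0])
        D = np.array([5e-3, 2e-3, 8e-4, 3e-4])  # still falling, above 2e-4
        lab = classify_regime(_series(t, D), 2e-4)
        assert lab.label == "ageing" and lab.extrapolated

    def test_noisy_plateau_is_liquid(self):
        rng = np.random.default_rng(1)
        D = 1e-3 * (1.0 + 0.05 * rng.normal(size=6))
        lab = classify_regime(_series(np.linspace(10, 60, 6), D), 2e-4)
        assert lab.label == "liquid"


def brute_contacts(wrapped, box, roles, chain_len, cutoff):
    """All-pairs reference for strong-contact counting."""
    n = len(roles)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if i // chain_len == j // chain_len:
                continue
            pair = {int(roles[i]), int(roles[j])}
            if pair != {int(BeadRole.STICKER_A), int(BeadRole.STICKER_B)}:
                continue
            d = wrapped[i] - wrapped[j]
            d -= box * np.rint(d / box)
            if np.dot(d, d) < cutoff * cutoff:
                count += 1
    return count


class TestStrongContacts:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_chains, L = 6, 8
        box = np.array([6.0, 7.0, 8.0])
        pos = rng.uniform(0, 1, (n_chains * L, 3)) * box
        roles = rng.integers(0, 3, n_chains * L).astype(np.int8)
        n, _, pairs = strong_contacts(pos, box, roles, L, 1.5)
        assert n == brute_contacts(pos, box, roles, L, 1.5)

    def test_homotypic_pairs_never_strong(self):
        # two A stickers 1.1 sigma apart on different chains
        box = np.array([50.0] * 3)
        pos = np.array([[10.0, 10, 10], [11.1, 10, 10]])
        roles = np.array([0, 0], dtype=np.int8)
        n, _, _ = strong_contacts(pos, box, roles, 1, 1.5)
        assert n == 0

    def test_intra_chain_pairs_excluded(self):
        box = np.array([50.0] * 3)
        pos = np.array([[10.0, 10, 10], [11.1, 10, 10]])
        roles = np.array([0, 1], dtype=np.int8)  # A and B on the SAME chain
        n, _, _ = strong_contacts(pos, box, roles, 2, 1.5)
        assert n == 0

    def test_cutoff_definition(self):
        traj = make_synthetic_fixtures("contact_toy", {"r_contact": 1.1})
        n_lo, _, _ = strong_contacts(traj.wrapped(0), traj.box, traj.roles,
                                     traj.chain_len, 1.0)
        assert n_lo == 0


class TestClusters:
    @pytest.mark.parametrize("seed", range(4))
    def test_chain_clusters_match_networkx(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        n_chains, L = 8, 5
        box = np.array([10.0] * 3)
        pos = rng.uniform(0, 1, (n_chains * L, 3)) * box
        labels, sizes = analysis.chain_clusters(pos, box, L, 1.5)
        g = nx.Graph()
        g.add_nodes_from(range(n_chains))
        for i in range(n_chains * L):
            for j in range(i + 1, n_chains * L):
                if i // L == j // L:
                    continue
                d = pos[i] - pos[j]
                d -= box * np.rint(d / box)
                if np.dot(d, d) < 1.5 ** 2:
                    g.add_edge(i // L, j // L)
        ref_sizes = sorted((len(c) for c in nx.connected_components(g)),
                           reverse=True)
        assert list(sizes) == ref_sizes

    def test_cluster_spanning_periodic_boundary_unwraps(self):
        # compact blob centered on a box corner
        rng = np.random.default_rng(3)
        box = np.array([20.0] * 3)
        pts = rng.normal(0.0, 1.0, (200, 3))  # near the origin/corner
        w = np.mod(pts, box)
        idx = analysis.largest_cluster_beads(w, box, 1, 1.5)
        unwrapped = analysis.unwrap_cluster(w, box, idx, 1.5)
        spread = unwrapped.max(axis=0) - unwrapped.min(axis=0)
        assert np.all(spread < 12.0)  # no box-length splits remain


class TestShapeMetrics:
    def test_kappa2_in_unit_interval_and_rigid_motion_invariant(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.normal(size=(60, 3)) * rng.uniform(0.1, 3.0, 3)
            m = shape_metrics(pts)
            assert 0.0 <= m.kappa2 <= 1.0
            rot = Rotation.random(random_state=rng).as_matrix()
            moved = pts @ rot.T + rng.uniform(-50, 50, 3)
            assert shape_metrics(moved).kappa2 == pytest.approx(m.kappa2,
                                                                abs=1e-9)

    def test_planar_disc_matches_direct_tensor(self):
        rng = np.random.default_rng(8)
        pts = np.column_stack([rng.normal(size=(500, 2)), np.zeros(500)])
        m = shape_metrics(pts)
        d = pts - pts.mean(axis=0)
        gyr = sum(np.outer(v, v) for v in d) / len(d)
        lam = np.sort(np.linalg.eigvalsh(gyr))
        assert m.asphericity == pytest.approx(lam[2] - 0.5 * (lam[0] + lam[1]),
                                              rel=1e-9)

    def test_degenerate_inputs_flagged(self):
        assert shape_metrics(np.zeros((3, 3))).reduced_rank
        assert shape_metrics(np.zeros((10, 3))).relative_shape_anisotropy == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_kappa2_bounds_property(self, seed):
        pts = np.random.default_rng(seed).normal(size=(12, 3))
        assert 0.0 <= shape_metrics(pts).kappa2 <= 1.0


class TestCoalescence:
    def test_static_pair_is_censored(self):
        traj = make_synthetic_fixtures("two_spheres_merging",
                                       {"merge_frame": 500, "n_frames": 60},
                                       seed=1)
        res = coalescence_time(traj, sphericity_tol=0.02)
        assert res.censored and res.status == "censored"

    def test_stride_invariance_below_dwell(self):
        traj = make_synthetic_fixtures("two_spheres_merging",
                                       {"merge_frame": 80, "n_frames": 120},
                                       seed=2)
        r1 = coalescence_time(traj, sphericity_tol=0.02)
        r2 = coalescence_time(traj.slice_frames(stride=2), sphericity_tol=0.02)
        assert abs(r1.tau_c - r2.tau_c) <= 2.0

    def test_initially_two_clusters(self):
        traj = make_synthetic_fixtures("two_spheres_merging",
                                       {"merge_frame": 80, "n_frames": 120},
                                       seed=3)
        res = coalescence_time(traj, sphericity_tol=0.02)
        assert res.cluster_count_series[0] == 2


class TestBorderCurve:
    def test_constructed_crossings(self):
        t = np.linspace(100, 5000, 40)
        series = {
            5.25: _series(t, 1e-2 * np.exp(-t / 150.0)),  # crosses early
            5.5: _series(t, 1e-2 * np.exp(-t / 80.0)),    # crosses earlier
            5.0: _series(t, np.full_like(t, 2e-3)),       # liquid, excluded
        }
        pts = border_curve(series, 2e-4)
        assert [e for e, _ in pts] == [5.25, 5.5]
        onsets = {e: o for e, o in pts}
        assert onsets[5.5] < onsets[5.25]  # stronger binding arrests sooner

    def test_single_point_curve(self):
        t = np.linspace(100, 3000, 30)
        pts = border_curve({6.0: _series(t, 1e-2 * np.exp(-t / 100.0))}, 2e-4)
        assert len(pts) == 1


class TestRealUnits:
    def test_five_micron_crossing_time(self):
        assert diffusion_time_real_units(1.0, 5.0) == pytest.approx(25.0 / 6.0)

    def test_zero_distance(self):
        assert diffusion_time_real_units(1.0, 0.0) == 0.0

    def test_deceleration_bracket_minutes_to_hour(self):
        t1 = diffusion_time_real_units(1.0, 5.0)
        lo, hi = deceleration_time_bracket(t1, 2.0, 3.0)
        assert lo == pytest.approx(416.7, rel=1e-3)   # ~ 7 minutes
        assert hi == pytest.approx(4166.7, rel=1e-3)  # ~ 1.2 hours
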