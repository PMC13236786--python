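import numpy as np
import pandas as pd
import pytest

from gazecnn.attribution import (
    AttributionTensor,
    explain,
    global_importance,
    kde_heatmap,
    max_shap_vs_rt,
    polar_time_histogram,
    rotate_point,
    silverman_bandwidth,
)
from gazecnn.network import GazeNet, NetworkConfig


def toy_config(**kw):
    base = dict(
        in_channels=2,
        conv_features=3,
        kernel_size=3,
        dropout_p=0.0,
        pool_size=2,
        pool_stride=2,
        hidden_sizes=(4,),
        n_classes=3,
        input_length=12,
    )
    base.update(kw)
    return NetworkConfig(**base)


class TestExplain:
    def test_constant_zero_model_gives_zero_contributions(self):
        net = GazeNet.init(toy_config(), seed=0)
        for k in net.params:
            net.params[k][:] = 0.0
        rng = np.random.default_rng(0)
        a = explain(net, rng.normal(size=(5, 2, 12)), rng.normal(size=(3, 2, 12)))
        np.testing.assert_array_equal(a.values, 0.0)

    def test_linear_surrogate_matches_closed_form_shapley(self):
        """With unit pooling and a bias shift keeping every ReLU in its linear
        region, the network is affine and the contribution of input cell i for
        class c must equal J_ci * (x_i - background mean_i)."""
        net = GazeNet.init(toy_config(pool_size=1, pool_stride=1), seed=3)
        net.params["bc"][:] = 1e4  # every pre-activation strictly positive
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(6, 2, 12))
        q = rng.normal(size=(4, 2, 12))
        a = explain(net, bg, q)
        # Jacobian of the affine map by finite differences
        x0 = np.zeros((1, 2, 12))
        f0 = net.forward(x0)[0]
        J = np.empty((2, 12, net.config.n_classes))
        for c in range(2):
            for t in range(12):
                xp = x0.copy()
                xp[0, c, t] = 1.0
                J[c, t] = net.forward(xp)[0] - f0
        expected = (q - bg.mean(axis=0))[..., None] * J[None]
        np.testing.assert_allclose(a.values, expected, atol=1e-6)

    def test_additivity_on_random_nonlinear_model(self):
        net = GazeNet.init(toy_config(), seed=7)
        rng = np.random.default_rng(8)
        a = explain(net, rng.normal(size=(10, 2, 12)), rng.normal(size=(20, 2, 12)))
        # per trial and class, contributions must sum to logit - baseline
        totals = a.values.sum(axis=(1, 2))
        np.testing.assert_allclose(totals, a.query_outputs - a.baseline_outputs, atol=1e-9)

    def test_explain_is_deterministic(self):
        net = GazeNet.init(toy_config(), seed=1)
        rng = np.random.default_rng(2)
        bg, q = rng.normal(size=(5, 2, 12)), rng.normal(size=(3, 2, 12))
        a1, a2 = explain(net, bg, q), explain(net, bg, q)
        np.testing.assert_array_equal(a1.values, a2.values)


class TestGlobalImportance:
    def _tensor(self, values):
        return AttributionTensor(
            values=values,
            baseline_outputs=np.zeros(values.shape[3]),
            query_outputs=values.sum(axis=(1, 2)),
            trial_order=list(range(values.shape[0])),
        )

    def test_single_entry_spreads_over_12_cells(self):
        vals = np.zeros((1, 2, 30, 6))
        vals[0, 0, 17, 3] = 12.0
        gi = global_importance(self._tensor(vals))
        assert gi.values[0, 17] == pytest.approx(1.0)  # 12 / (2 features x 6 classes)
        assert gi.argmax_sample[0] == 17

    def test_all_zero_tensor_ties_to_sample_zero(self):
        gi = global_importance(self._tensor(np.zeros((2, 2, 10, 6))))
        np.testing.assert_array_equal(gi.values, 0.0)
        np.testing.assert_array_equal(gi.argmax_sample, [0, 0])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(4, 2, 25, 6))
        gi = global_importance(self._tensor(vals))
        for tr in range(4):
            for smp in range(25):
                cells = [abs(vals[tr, f, smp, c]) for f in range(2) for c in range(6)]
                assert gi.values[tr, smp] == pytest.approx(np.mean(cells))

    def test_argmax_gaze_reads_query_trace(self):
        vals = np.zeros((1, 2, 10, 6))
        vals[0, 1, 4, 0] = 1.0
        q = np.arange(20, dtype=float).reshape(1, 2, 10)
        gi = global_importance(self._tensor(vals), queries=q)
        np.testing.assert_array_equal(gi.argmax_gaze[0], [q[0, 0, 4], q[0, 1, 4]])


class TestMaxShapVsRt:
    def _gi(self, argmax):
        from gazecnn.attribution import GlobalImportance

        n = len(argmax)
        return GlobalImportance(
            values=np.zeros((n, 600)),
            argmax_sample=np.asarray(argmax),
            argmax_gaze=np.zeros((n, 2)),
            trial_order=list(range(n)),
        )

    def test_sample_index_converts_to_milliseconds(self):
        trials = pd.DataFrame(
            {"participant_id": ["p1"], "trial_index": [1], "rt_ms": [400.0]}
        )
        out = max_shap_vs_rt(self._gi([100]), trials)
        assert out.loc[0, "argmax_time_ms"] == 200.0
        assert not out.loc[0, "after_response"]

    def test_peak_in_padded_tail_is_flagged(self):
        trials = pd.DataFrame(
            {"participant_id": ["p1"], "trial_index": [1], "rt_ms": [400.0]}
        )
        out = max_shap_vs_rt(self._gi([300]), trials)  # 600 ms > 400 ms RT
        assert bool(out.loc[0, "after_response"])


class TestRotation:
    def test_zero_rotation_is_identity(self, geometry):
        x, y = rotate_point(100.0, 200.0, geometry, 60.0, 60.0)
        assert (x, y) == (100.0, 200.0)

    def test_center_is_fixed_point(self, geometry):
        x, y = rotate_point(geometry.center_x, geometry.center_y, geometry, 0.0, 123.0)
        assert (x, y) == pytest.approx((geometry.center_x, geometry.center_y))

    def test_quarter_turn_in_screen_coordinates(self, geometry):
        # +90 deg counterclockwise (math frame) moves a rightward point upward,
        # i.e. to smaller screen y
        x, y = rotate_point(geometry.center_x + 50, geometry.center_y, geometry, 0.0, 90.0)
        assert x == pytest.approx(geometry.center_x, abs=1e-9)
        assert y == pytest.approx(geometry.center_y - 50, abs=1e-9)

    def test_rotation_preserves_pairwise_distances(self, geometry):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1400, size=(30, 2))
        rx, ry = rotate_point(pts[:, 0], pts[:, 1], geometry, 30.0, 250.0)
        rot = np.column_stack([rx, ry])
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        d1 = np.linalg.norm(rot[:, None] - rot[None], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-8)


class TestSilverman:
    def test_64_points_with_sd_10_give_bandwidth_5(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(64, 2))
        pts = (pts - pts.mean(0)) / pts.std(0, ddof=1) * 10.0  # exact sd 10 per axis
        assert silverman_bandwidth(pts) == pytest.approx(10 * 64 ** (-1 / 6))
        assert silverman_bandwidth(pts) == pytest.approx(5.0)

    def test_scale_equivariance(self):
        pts = np.random.default_rng(2).normal(size=(40, 2))
        assert silverman_bandwidth(3.5 * pts) == pytest.approx(3.5 * silverman_bandwidth(pts))

    def test_more_points_shrink_bandwidth(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(200, 2))
        assert silverman_bandwidth(pts) > silverman_bandwidth(np.vstack([pts, pts]))

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            silverman_bandwidth(np.zeros((10, 2)))


class TestKde:
    def test_single_point_peaks_at_its_cell(self):
        grid = kde_heatmap(np.array([[1000.0, 700.0]]), h=30.0)
        iy, ix = np.unravel_index(grid.density.argmax(), grid.density.shape)
        assert abs(grid.xs[ix] - 1000.0) <= 5.0
        assert abs(grid.ys[iy] - 700.0) <= 5.0
        assert grid.density.max() == 1.0

    def test_two_distant_points_give_equal_peaks(self):
        grid = kde_heatmap(np.array([[800.0, 700.0], [1800.0, 700.0]]), h=25.0)
        left = grid.density[:, grid.xs < 1280].max()
        right = grid.density[:, grid.xs >= 1280].max()
        assert left == pytest.approx(right, rel=1e-9)

    def test_pre_normalisation_mass_integrates_to_one(self):
        rng = np.random.default_rng(4)
        pts = rng.normal([1280, 720], 150, size=(100, 2))
        grid = kde_heatmap(pts, h=25.0, resolution=10.0)
        assert grid.raw_integral == pytest.approx(1.0, abs=0.02)


class TestPolarHistogram:
    def test_aligned_points_fill_single_bin(self, geometry):
        pts = np.tile(geometry.location_coords()[0], (7, 1))
        out = polar_time_histogram(pts, np.arange(7.0), geometry, n_bins=6)
        assert out["count"].sum() == 7
        assert (out["count"] > 0).sum() == 1

    def test_counts_conserve_non_center_points(self, geometry):
        rng = np.random.default_rng(5)
        pts = rng.normal([1280, 720], 300, size=(40, 2))
        out = polar_time_histogram(pts, np.zeros(40), geometry, n_bins=12)
        assert out["count"].sum() == 40

    def test_center_points_excluded_with_warning(self, geometry):
        pts = np.array([[geometry.center_x, geometry.center_y], [1500.0, 720.0]])
        with pytest.warns(RuntimeWarning):
            out = polar_time_histogram(pts, np.array([10.0, 20.0]), geometry, n_bins=6)
        assert out["count"].sum() == 1

    def test_capture_then_correction_orders_bin_times(self, geometry):
        """Early peaks near the aligned distractor, late peaks opposite it."""
        rng = np.random.default_rng(6)
        near = geometry.location_coords()[0] + rng.normal(0, 20, size=(30, 2))
        opposite = geometry.location_coords()[3] + rng.normal(0, 20, size=(30, 2))
        pts = np.vstack([near, opposite])
        times = np.concatenate([rng.uniform(200, 400, 30), rng.uniform(600, 900, 30)])
        out = polar_time_histogram(pts, times, geometry, n_bins=6)
        t_near = out.loc[out["angle_deg"] == 0.0, "mean_time_ms"].item()
        t_far = out.loc[out["angle_deg"] == 180.0, "mean_time_ms"].item()
        assert t_near < t_far
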