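"""GTWR: kernels, local fits, cross-validation, and its limiting models."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vegdrivers.gtwr import (GTWRConfig, PanelDataset, coefficient_summary,
                             fit_gtwr, fit_local_wls, kernel_weight,
                             loocv_score, select_bandwidth, st_distance,
                             st_distance_matrix)
from vegdrivers.synthetic import (PredictorSpec, SyntheticPanelConfig,
                                  generate_panel)


class TestDistance:
    def test_euclidean_3_4_5(self):
        assert st_distance((0, 0, 2000), (3, 4, 2000), tau=1.0) == pytest.approx(5.0)

    def test_temporal_scaling(self):
        # sqrt(tau * dt^2) with tau=4, dt=2
        assert st_distance((0, 0, 2000), (0, 0, 2002), tau=4.0) == pytest.approx(4.0)

    def test_identity_and_symmetry(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert st_distance(a, a, tau=2.0) == 0.0
        assert st_distance(a, b, 2.0) == pytest.approx(st_distance(b, a, 2.0))

    def test_matrix_agrees_with_pairwise(self, rng):
        pts = rng.normal(size=(8, 3))
        D = st_distance_matrix(pts, tau=0.5)
        for i in range(8):
            for j in range(8):
                assert D[i, j] == pytest.approx(st_distance(pts[i], pts[j], 0.5))

    def test_tau_zero_ignores_time(self):
        assert st_distance((1, 1, 1900), (1, 1, 2100), tau=0.0) == 0.0


class TestKernel:
    def test_self_weight_is_one(self):
        assert kernel_weight(0.0, 10.0, "gaussian") == 1.0
        assert kernel_weight(0.0, 10.0, "bisquare") == 1.0

    def test_gaussian_at_bandwidth(self):
        assert kernel_weight(10.0, 10.0, "gaussian") == pytest.approx(np.exp(-1))

    def test_bisquare_compact_support(self):
        assert kernel_weight(10.0, 10.0, "bisquare") == 0.0
        assert kernel_weight(15.0, 10.0, "bisquare") == 0.0
        assert kernel_weight(5.0, 10.0, "bisquare") == pytest.approx((1 - 0.25) ** 2)

    def test_nonincreasing_in_distance(self):
        d = np.linspace(0, 30, 100)
        for k in ("gaussian", "bisquare"):
            w = kernel_weight(d, 12.0, k)
            assert (np.diff(w) <= 1e-15).all()

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            kernel_weight(1.0, 0.0)


class TestLocalWLS:
    def test_exact_line(self):
        X = np.array([[1, 0], [1, 1], [1, 2]], dtype=float)
        y = np.array([1.0, 3.0, 5.0])
        beta, flagged = fit_local_wls(X, y, np.ones(3))
        np.testing.assert_allclose(beta, [1.0, 2.0], atol=1e-12)
        assert not flagged

    def test_zero_weight_excludes_outlier(self):
        X = np.array([[1, 0], [1, 1], [1, 2], [1, 3]], dtype=float)
        y = np.array([1.0, 3.0, 5.0, 500.0])
        beta, _ = fit_local_wls(X, y, np.array([1, 1, 1, 0.0]))
        np.testing.assert_allclose(beta, [1.0, 2.0], atol=1e-10)

    def test_duplicate_columns_trigger_ridge_flag(self):
        x = np.arange(5.0)
        X = np.column_stack([np.ones(5), x, x])
        beta, flagged = fit_local_wls(X, 2 * x + 1, np.ones(5))
        assert flagged
        assert np.all(np.isfinite(beta))


def _const_beta_panel(noise_sd=0.0, seed=3, n_units=10, years=(2000, 2009)):
    cfg = SyntheticPanelConfig(
        n_units=n_units, years=years, domain=(200.0, 150.0),
        predictors=(PredictorSpec("a", surface=(0.8, 0, 0, 0)),
                    PredictorSpec("b", surface=(-0.5, 0, 0, 0))),
        intercept_surface=(2.0, 0, 0, 0), noise_sd=noise_sd, seed=seed)
    return generate_panel(cfg)


class TestLOOCV:
    def test_matches_bruteforce_deletion(self, small_panel):
        panel, _ = small_panel
        sub = PanelDataset(panel.frame.iloc[:20].reset_index(drop=True), panel.predictors)
        cfg = GTWRConfig(tau=4.0)
        b = 60.0
        score = loocv_score(sub, cfg, b)
        X = sub.design()
        y = sub.y()
        D = st_distance_matrix(sub.points(), cfg.tau)
        W = kernel_weight(D, b, cfg.kernel)
        total = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i   # literally delete record i
            Xi, yi, wi = X[keep], y[keep], W[i, keep]
            beta = np.linalg.solve(Xi.T @ (Xi * wi[:, None]), (Xi * wi[:, None]).T @ yi)
            total += (y[i] - X[i] @ beta) ** 2
        assert score == pytest.approx(total, abs=1e-10)

    def test_global_line_scores_zero_at_huge_bandwidth(self):
        panel, _ = _const_beta_panel(noise_sd=0.0)
        score = loocv_score(panel, GTWRConfig(tau=1.0), bandwidth=1e9)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_single_candidate_grid_returned(self):
        panel, _ = _const_beta_panel(noise_sd=0.01)
        cfg = GTWRConfig(tau=1.0, bandwidth_grid=(77.0,))
        assert select_bandwidth(panel, cfg) == 77.0

    @pytest.mark.parametrize("seed", [3, 8, 21])
    def test_constant_coefficients_prefer_large_bandwidth(self, seed):
        # enough records that the CV curve's expectation dominates its noise
        panel, _ = _const_beta_panel(noise_sd=0.02, seed=seed, n_units=20,
                                     years=(2000, 2019))
        cfg = GTWRConfig(tau=1.0, bandwidth_grid=(5.0, 50.0, 500.0))
        sel = select_bandwidth(panel, cfg)
        assert sel > 450.0  # oversmoothing is optimal when coefficients are constant


class TestFitGtwr:
    def test_exact_global_model_is_fixed_point_at_any_bandwidth(self):
        panel, truth = _const_beta_panel(noise_sd=0.0)
        D = st_distance_matrix(panel.points(), 1.0)
        diam = D.max()
        for frac in (0.1, 1.0, 10.0):
            res = fit_gtwr(panel, GTWRConfig(tau=1.0, bandwidth=frac * diam))
            np.testing.assert_allclose(res.frame["beta_a"], 0.8, atol=1e-6)
            np.testing.assert_allclose(res.frame["beta_b"], -0.5, atol=1e-6)
            np.testing.assert_allclose(res.frame["beta_0"], 2.0, atol=1e-6)

    def test_huge_bandwidth_reduces_to_global_ols(self, small_panel):
        panel, _ = small_panel
        D = st_distance_matrix(panel.points(), 1.0)
        res = fit_gtwr(panel, GTWRConfig(tau=1.0, bandwidth=1e6 * D.max()))
        X = panel.design()
        ols = np.linalg.lstsq(X, panel.y(), rcond=None)[0]
        betas = res.frame[["beta_0", "beta_a", "beta_b"]].to_numpy()
        assert np.abs(betas - ols).max() < 1e-8

    def test_tau_zero_single_year_reproduces_pure_spatial_gwr(self, rng):
        # independent oracle: explicit per-point weighted normal equations
        n = 25
        frame = pd.DataFrame({
            "unit_id": [f"U{i:03d}" for i in range(n)],
            "x_km": rng.uniform(0, 100, n), "y_km": rng.uniform(0, 80, n),
            "year": 2005,
            "a": rng.normal(size=n), "b": rng.normal(size=n)})
        frame["response"] = 1 + 0.02 * frame.x_km * frame.a - 0.5 * frame.b \
            + rng.normal(0, 0.05, n)
        panel = PanelDataset(frame, ["a", "b"])
        bw = 30.0
        res = fit_gtwr(panel, GTWRConfig(tau=0.0, bandwidth=bw))
        X = panel.design()
        y = panel.y()
        pts = panel.points()
        for i in range(n):
            d2 = (pts[:, 0] - pts[i, 0]) ** 2 + (pts[:, 1] - pts[i, 1]) ** 2
            w = np.exp(-d2 / bw**2)
            beta = np.linalg.solve(X.T @ (X * w[:, None]), (X * w[:, None]).T @ y)
            got = res.frame.loc[i, ["beta_0", "beta_a", "beta_b"]].to_numpy(dtype=float)
            np.testing.assert_allclose(got, beta, atol=1e-9)

    def test_residual_identity_and_r2(self, small_panel):
        panel, _ = small_panel
        res = fit_gtwr(panel, GTWRConfig(tau=1.0, bandwidth=80.0))
        np.testing.assert_allclose(res.frame["residual"],
                                   panel.y() - res.frame["fitted"], atol=1e-12)
        assert 0.0 < res.r2 <= 1.0

    def test_deterministic_bytes(self, small_panel):
        panel, _ = small_panel
        cfg = GTWRConfig(tau=4.0, bandwidth_grid=(30.0, 90.0))
        a = fit_gtwr(panel, cfg)
        b = fit_gtwr(panel, cfg)
        assert a.frame.to_csv() == b.frame.to_csv()
        assert a.bandwidth == b.bandwidth

    def test_tiny_bandwidth_fails_with_advice(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(RuntimeError, match="bandwidth"):
            fit_gtwr(panel, GTWRConfig(tau=1.0, bandwidth=1e-4))

    def test_aicc_criterion_selects_a_finite_bandwidth(self):
        panel, _ = _const_beta_panel(noise_sd=0.05)
        cfg = GTWRConfig(tau=1.0, criterion="aicc", bandwidth_grid=(20.0, 100.0, 400.0))
        res = fit_gtwr(panel, cfg)
        assert np.isfinite(res.aicc)
        assert res.bandwidth >= 20.0


class TestSummary:
    def _result(self, small_panel):
        panel, _ = small_panel
        return fit_gtwr(panel, GTWRConfig(tau=1.0, bandwidth=80.0))

    def test_identical_betas_collapse_quartiles(self):
        panel, _ = _const_beta_panel(noise_sd=0.0)
        res = fit_gtwr(panel, GTWRConfig(tau=1.0, bandwidth=1e5))
        summary = coefficient_summary(res, "year")
        for col in ("beta_a_25q", "beta_a_50q", "beta_a_75q"):
            np.testing.assert_allclose(summary[col], 0.8, atol=1e-6)

    def test_unit_grouping_average_identity(self, small_panel):
        res = self._result(small_panel)
        by_unit = coefficient_summary(res, "unit")
        # each unit has the same number of years, so the double average
        # equals the global mean
        assert by_unit["beta_a"].mean() == pytest.approx(res.frame["beta_a"].mean())

    def test_median_is_order_statistic(self):
        frame = pd.DataFrame({
            "unit_id": [f"U{i}" for i in range(5)], "year": 2000,
            "beta_0": 0.0, "beta_a": [5.0, 1.0, 4.0, 2.0, 3.0],
            "fitted": 0.0, "residual": 0.0, "local_r2": 1.0, "flagged": False})
        from vegdrivers.gtwr import GTWRResult
        res = GTWRResult(frame, ["a"], 1.0, 0.0, 0.0, 1.0, 1.0, 1.0, GTWRConfig(tau=1.0))
        summary = coefficient_summary(res, "year")
        assert summary["beta_a_50q"].iloc[0] == 3.0
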