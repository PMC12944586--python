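"""q-statistic against brute-force variance decomposition and its invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegdrivers.geodetector import (Stratification, discretize,
                                    factor_detector_table, q_significance,
                                    q_statistic, stars)


def brute_force_q(y, labels):
    """Direct group-variance decomposition with population variances."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    ssw = sum(len(y[labels == h]) * np.var(y[labels == h])
              for h in np.unique(labels))
    return 1.0 - ssw / (len(y) * np.var(y))


class TestQ:
    def test_hand_computed_decomposition(self):
        # SSW = 0.5 + 4.5, SST = 14 -> q = 9/14
        res = q_statistic([1, 2, 3, 6], Stratification([1, 1, 2, 2], 2))
        assert res.q == pytest.approx(9 / 14, abs=1e-12)
        assert res.ssw == pytest.approx(5.0)
        assert res.sst == pytest.approx(14.0)

    def test_single_stratum_gives_zero(self):
        res = q_statistic([1.0, 2.0, 5.0], Stratification([1, 1, 1], 1))
        assert res.q == 0.0

    def test_perfect_separation_gives_one(self):
        res = q_statistic([1, 1, 2, 2], Stratification([1, 1, 2, 2], 2))
        assert res.q == 1.0

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 50))
            L = int(rng.integers(2, 7))
            labels = rng.integers(1, L + 1, n)
            labels[:L] = np.arange(1, L + 1)  # ensure every stratum occupied
            y = rng.normal(size=n)
            res = q_statistic(y, Stratification(labels, L))
            assert res.q == pytest.approx(brute_force_q(y, labels), abs=1e-12)
            assert 0.0 <= res.q <= 1.0
            assert sum(res.n_h.values()) == n

    def test_additivity_ssw_plus_ssb_equals_sst(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            labels = rng.integers(1, 4, n)
            labels[:3] = [1, 2, 3]
            y = rng.normal(size=n)
            res = q_statistic(y, Stratification(labels, 3))
            ybar = y.mean()
            ssb = sum(cnt * (y[labels == h].mean() - ybar) ** 2
                      for h, cnt in res.n_h.items())
            assert res.ssw + ssb == pytest.approx(res.sst, rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(a=st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-10, 10), seed=st.integers(0, 50))
    def test_affine_invariance(self, a, b, seed):
        r = np.random.default_rng(seed)
        y = r.normal(size=20)
        labels = r.integers(1, 4, 20)
        labels[:3] = [1, 2, 3]
        s = Stratification(labels, 3)
        assert q_statistic(a * y + b, s).q == pytest.approx(q_statistic(y, s).q,
                                                            abs=1e-9)

    def test_refinement_never_decreases_q(self, rng):
        for _ in range(30):
            y = rng.normal(size=30)
            labels = rng.integers(1, 4, 30)
            labels[:3] = [1, 2, 3]
            q0 = q_statistic(y, Stratification(labels, 3)).q
            # split stratum 1 arbitrarily into strata 1 and 4
            refined = labels.copy()
            members = np.flatnonzero(refined == 1)
            refined[members[: len(members) // 2]] = 4
            if len(np.unique(refined)) == 4:
                q1 = q_statistic(y, Stratification(refined, 4)).q
                assert q1 >= q0 - 1e-12

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            q_statistic([2.0, 2.0, 2.0], Stratification([1, 1, 2], 2))


class TestDiscretize:
    def test_median_split(self):
        s = discretize([1, 2, 3, 4], 2, "quantile")
        assert s.labels.tolist() == [1, 1, 2, 2]

    def test_tie_at_break_goes_to_lower_stratum(self):
        s = discretize([1.0, 2.0, 2.0, 4.0], 2, "quantile")
        assert s.labels[1] == s.labels[2] == 1

    def test_constant_collapses_to_one_stratum(self):
        s = discretize([5.0] * 6, 3)
        assert s.L == 1

    def test_saturated_stratification_explains_everything(self, rng):
        y = rng.normal(size=6)
        s = Stratification(np.arange(1, 7), 6)
        assert q_statistic(y, s).q == pytest.approx(1.0)

    def test_equal_interval_bins(self):
        s = discretize([0.0, 0.4, 0.6, 1.0], 2, "equal_interval")
        assert s.labels.tolist() == [1, 1, 2, 2]

    def test_jenks_matches_exhaustive_partition_search(self, rng):
        x = rng.normal(size=9)
        L = 3
        got = discretize(x, L, "jenks")

        def ssd(vals):
            return np.sum((vals - vals.mean()) ** 2)

        order = np.argsort(x)
        xs = x[order]
        best = np.inf
        for c1, c2 in itertools.combinations(range(1, 9), 2):
            cost = ssd(xs[:c1]) + ssd(xs[c1:c2]) + ssd(xs[c2:])
            best = min(best, cost)
        got_cost = sum(ssd(x[got.labels == h]) for h in range(1, got.L + 1))
        assert got_cost == pytest.approx(best, rel=1e-12)

    def test_jenks_finds_obvious_clusters(self):
        x = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 9.9, 10.0, 10.1])
        s = discretize(x, 3, "jenks")
        assert s.labels.tolist() == [1, 1, 1, 2, 2, 3, 3, 3]

    def test_invalid_L(self):
        with pytest.raises(ValueError):
            discretize([1.0, 2.0], 1)


class TestSignificance:
    def test_perfect_separation_is_significant(self):
        # N=12 so the null has C(12,6) = 924 label splits, only 2 reaching q=1
        y = np.repeat([1.0, 5.0], 6)
        s = Stratification(np.repeat([1, 2], 6), 2)
        p = q_significance(y, s, B=999, seed=0)
        assert p <= 0.05

    def test_single_stratum_p_is_one(self):
        y = np.array([1.0, 2.0, 3.0])
        assert q_significance(y, Stratification([1, 1, 1], 1)) == 1.0

    def test_small_B_rejected(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="B"):
            q_significance(y, Stratification([1, 1, 2, 2], 2), B=50)

    def test_noncentral_f_orders_effects(self, rng):
        y = rng.normal(size=60)
        strong = Stratification(1 + (y > np.median(y)).astype(int), 2)
        weak = Stratification(rng.integers(1, 3, 60), 2)
        p_strong = q_significance(y, strong, method="noncentral_f")
        p_weak = q_significance(y, weak, method="noncentral_f")
        assert 0.0 <= p_strong <= 1.0 and 0.0 <= p_weak <= 1.0
        assert p_strong < p_weak

    def test_seeded_reproducibility(self, rng):
        y = rng.normal(size=30)
        s = Stratification(rng.integers(1, 4, 30), 3)
        assert q_significance(y, s, B=199, seed=42) == \
            q_significance(y, s, B=199, seed=42)

    def test_stars_thresholds(self):
        assert stars(0.005) == "**"
        assert stars(0.03) == "*"
        assert stars(0.2) == ""
        assert stars(np.nan) == ""


class TestFactorTable:
    def _panel(self, rng, years=(2000, 2010), n=30):
        rows = []
        for yr in years:
            x = rng.normal(size=n)
            rows.append(pd.DataFrame({
                "unit_id": [f"U{i:03d}" for i in range(n)], "year": yr,
                "LAI": 2 * x + rng.normal(0, 0.3, n), "driver": x,
                "policy": np.nan if yr < 2005 else rng.uniform(0, 1, n)}))
        return pd.concat(rows, ignore_index=True)

    def test_single_cell_equals_q_statistic(self, rng):
        panel = self._panel(rng, years=(2000,))
        tab = factor_detector_table(panel, "LAI", ["driver"], [2000], L=4, B=199)
        sub = panel[panel.year == 2000]
        expect = q_statistic(sub["LAI"].to_numpy(),
                             discretize(sub["driver"].to_numpy(), 4)).q
        assert tab.loc["driver", (2000, "q")] == pytest.approx(expect)

    def test_missing_factor_year_is_missing_cell(self, rng):
        panel = self._panel(rng)
        tab = factor_detector_table(panel, "LAI", ["driver", "policy"],
                                    [2000, 2010], B=199)
        assert np.isnan(tab.loc["policy", (2000, "q")])
        assert tab.loc["policy", (2000, "stars")] == ""
        assert np.isfinite(tab.loc["policy", (2010, "q")])

    def test_self_explanation_monotone_in_L(self, rng):
        n = 60
        y = rng.normal(size=n)
        panel = pd.DataFrame({"unit_id": [f"U{i}" for i in range(n)],
                              "year": 2000, "LAI": y, "self": y})
        qs = [factor_detector_table(panel, "LAI", ["self"], [2000], L=L,
                                    B=199).loc["self", (2000, "q")]
              for L in (2, 4, 8)]
        assert qs[0] < qs[1] < qs[2]
        assert qs[2] > 0.8

    def test_duplicate_units_rejected(self, rng):
        panel = self._panel(rng, years=(2000,))
        dup = pd.concat([panel, panel.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            factor_detector_table(dup, "LAI", ["driver"], [2000], B=199)
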