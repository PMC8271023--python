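"""Survival statistics, multiple-testing correction, concordance and
forest-based importance."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mibitime import (
    bh_adjust,
    concordance_index,
    cox_fit,
    generate_survival,
    km_curve,
    logrank_test,
    rf_importance,
    survival_rf_shap,
    wilcoxon_ranksum,
)
from mibitime.shapley import exact_shapley


class TestKaplanMeier:
    def test_four_events_no_censoring(self):
        km = km_curve([1, 2, 3, 4], [True] * 4)
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[1] == pytest.approx(0.75)
        assert surv[2] == pytest.approx(0.5)
        assert surv[3] == pytest.approx(0.25)
        assert surv[4] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        km = km_curve([5, 7, 9], [False, False, False])
        assert (km["survival"] == 1.0).all()

    def test_mixed_censoring_hand_product_limit(self):
        # times 1, 2+, 3 → S = 1, 2/3, 2/3, 0
        km = km_curve([1, 2, 3], [True, False, True])
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[0] == 1.0
        assert surv[1] == pytest.approx(2 / 3)
        assert surv[2] == pytest.approx(2 / 3)
        assert surv[3] == pytest.approx(0.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1, 2], [True, True])


def hand_mantel_cox(times, events, groups):
    """Independent observed-minus-expected tabulation over event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [True] * 6
        res = logrank_test(times, events, [0, 0, 0, 1, 1, 1])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_hand_mantel_cox_table(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [True] * 6
        groups = [0, 0, 0, 1, 1, 1]
        res = logrank_test(times, events, groups)
        assert res.chi_square == pytest.approx(hand_mantel_cox(times, events, groups), rel=1e-9)

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [True, True], [0, 0])


class TestCox:
    def toy(self):
        return pd.DataFrame(
            {
                "time": [1.0, 2, 3, 4, 5, 6],
                "event": [1, 1, 1, 1, 1, 1],
                "x": [1.0, 0, 1, 0, 1, 0],
            }
        )

    def test_matches_brute_force_partial_likelihood(self):
        """MLE agrees with a direct scan of the written-out partial
        likelihood (distinct event times, so ties play no role)."""
        df = self.toy()
        order = np.argsort(df["time"].to_numpy())
        x = df["x"].to_numpy()[order]

        def neg_log_pl(beta):
            ll = 0.0
            for i in range(len(x)):
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[i:])))
            return -ll

        oracle = minimize_scalar(neg_log_pl, bounds=(-10, 10), method="bounded").x
        fit = cox_fit(df, "time", "event")
        assert fit.coef("x") == pytest.approx(oracle, abs=1e-4)
        assert fit.hazard_ratio("x") == pytest.approx(np.exp(fit.coef("x")), abs=1e-12)

    def test_constant_covariate_dropped(self):
        df = self.toy().assign(c=1.0)
        fit = cox_fit(df, "time", "event")
        assert "c" in fit.dropped
        assert "c" not in fit.summary.index

    def test_recovers_planted_log_hazard_ratio(self):
        """On simulated exponential survival with hazard ratio 3 the
        estimated log-HR lands within 3 standard errors of log 3."""
        rng = np.random.default_rng(2024)
        groups = np.array([0, 1] * 100)
        t, e = generate_survival(groups, 0.02, 3.0, 0.3, rng)
        df = pd.DataFrame({"time": t, "event": e.astype(int), "group": groups.astype(float)})
        fit = cox_fit(df, "time", "event")
        se = float(fit.summary.loc["group", "se"])
        assert abs(fit.coef("group") - np.log(3)) < 3 * se

    def test_categorical_reference_coding(self):
        df = self.toy().assign(arch=["cold", "mixed", "cold", "mixed", "cold", "mixed"])
        fit = cox_fit(df, "time", "event", categorical=("arch",))
        assert any("arch" in c for c in fit.summary.index)


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_order_invariant_and_rank_monotone(self, rng):
        p = rng.uniform(0.001, 1.0, 20)
        adj = bh_adjust(p)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])
        # adjusted values never cross below a smaller raw p's adjustment
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_values_bounded_and_dominate_raw(self, p):
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)


class TestWilcoxon:
    def test_identical_samples_p_near_one(self):
        z, p = wilcoxon_ranksum([1, 2, 3, 4], [1, 2, 3, 4])
        assert z == pytest.approx(0.0)
        assert p > 0.9

    def test_exact_enumeration_small_samples(self):
        """{1,2,3} vs {4,5,6}: 1 of the C(6,3)=20 rank splits is as extreme,
        so the two-sided exact p is 2/20 = 0.1."""
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.uniform(0, 1, 10)
        b = rng.uniform(0.2, 1.2, 12)
        z1, p1 = wilcoxon_ranksum(a, b)
        z2, p2 = wilcoxon_ranksum(np.exp(a), np.exp(b))
        assert z1 == pytest.approx(z2)
        assert p1 == pytest.approx(p2)


class TestConcordance:
    def test_perfect_ordering(self):
        assert concordance_index([1, 2, 3, 4], [True] * 4, [4, 3, 2, 1]) == 1.0

    def test_random_scores_expect_half(self, rng):
        times = rng.exponential(10, 50)
        events = np.ones(50, bool)
        cs = [
            concordance_index(times, events, rng.permutation(50)) for _ in range(200)
        ]
        assert np.mean(cs) == pytest.approx(0.5, abs=0.02)

    def test_hand_enumeration_with_censoring(self):
        # A(t=1,e), B(t=2,censored), C(t=3,e), D(t=4,e); risks 4,3,1,2
        # comparable pairs: (A,B),(A,C),(A,D) concordant; (C,D) discordant
        c = concordance_index([1, 2, 3, 4], [True, False, True, True], [4, 3, 1, 2])
        assert c == pytest.approx(3 / 4)


class TestRFImportance:
    def _data(self, rng, n=60):
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            {
                "signal": y + rng.normal(0, 0.05, n),
                "noise1": rng.normal(0, 1, n),
                "noise2": rng.normal(0, 1, n),
                "noise3": rng.normal(0, 1, n),
            }
        )
        return X, y

    def test_separating_feature_ranks_first(self, rng):
        X, y = self._data(rng)
        imp = rf_importance(X, y, seed=0, n_trees=100)
        assert imp.index[0] == "signal"
        assert imp["gini_importance_max1"].iloc[0] == 1.0

    def test_duplicated_feature_splits_importance(self, rng):
        X, y = self._data(rng)
        X["signal2"] = X["signal"]
        imp = rf_importance(X, y, seed=0, n_trees=200)["gini_importance"]
        assert imp["signal"] + imp["signal2"] > max(imp["noise1"], imp["noise2"], imp["noise3"])

    def test_label_permutation_destroys_concentration(self, rng):
        X, y = self._data(rng)
        informative = rf_importance(X, y, seed=0, n_trees=100)["gini_importance"].max()
        shuffled = rf_importance(X, rng.permutation(y), seed=0, n_trees=100)[
            "gini_importance"
        ].max()
        assert shuffled < informative

    def test_single_class_rejected(self, rng):
        X, _ = self._data(rng)
        with pytest.raises(ValueError):
            rf_importance(X, np.zeros(len(X)), seed=0)


class TestExactShapley:
    def test_linear_model_closed_form(self, rng):
        """For f(x)=2x0+x1, phi_j = coef_j (x_j − mean background_j)."""
        X = rng.normal(0, 1, size=(15, 3))
        f = lambda A: 2 * A[:, 0] + A[:, 1]
        phi, base = exact_shapley(f, X)
        np.testing.assert_allclose(phi[:, 0], 2 * (X[:, 0] - X[:, 0].mean()), atol=1e-10)
        np.testing.assert_allclose(phi[:, 1], X[:, 1] - X[:, 1].mean(), atol=1e-10)
        assert base == pytest.approx(f(X).mean())

    def test_unused_feature_gets_exact_zero(self, rng):
        X = rng.normal(0, 1, size=(10, 3))
        f = lambda A: A[:, 0] * A[:, 1]
        phi, _ = exact_shapley(f, X)
        np.testing.assert_array_equal(phi[:, 2], 0.0)

    def test_local_accuracy_nonlinear(self, rng):
        X = rng.normal(0, 1, size=(12, 4))
        f = lambda A: np.sin(A[:, 0]) * A[:, 1] + A[:, 2] ** 2
        phi, base = exact_shapley(f, X)
        np.testing.assert_allclose(phi.sum(axis=1) + base, f(X), atol=1e-8)


class TestSurvivalForestShap:
    def test_local_accuracy_and_importance(self, rng):
        n = 30
        groups = rng.integers(0, 2, n).astype(float)
        t, e = generate_survival(groups.astype(int), 0.02, 4.0, 0.2, rng)
        X = pd.DataFrame(
            {"group": groups, "noise": rng.normal(0, 1, n), "age": rng.normal(55, 10, n)}
        )
        res = survival_rf_shap(X, t, e, seed=5, n_trees=50)
        total = res.shap_values.sum(axis=1).to_numpy() + res.base_value
        # risk scores from the same forest the attributions explain
        np.testing.assert_allclose(total, res.risk_scores, atol=1e-6)
        assert set(res.mean_abs_shap.index) == {"group", "noise", "age"}
        assert 0.0 < res.c_index <= 1.0


class TestEmbedding:
    def test_shape_and_determinism(self, rng):
        from mibitime import embed_2d

        X = rng.normal(0, 1, size=(20, 6))
        a = embed_2d(X, seed=3)
        b = embed_2d(X, seed=3)
        assert a.shape == (20, 2)
        np.testing.assert_array_equal(a, b)
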