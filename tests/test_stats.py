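"""Binomial GLM, likelihood-ratio factor tests, Tukey comparisons, Spearman."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

from aviary_transect.stats import (
    ModelSpec,
    RankDeficiencyError,
    factor_test,
    fit_binomial_glm,
    method_correlation_matrix,
    spearman,
    tukey_pairwise,
)


def two_group_frame(levels=("a", "b"), reps=1):
    return pd.DataFrame({"g": [l for l in levels for _ in range(reps)]})


def grid_max_loglik(s, n, X, lo=-8.0, hi=8.0):
    """Brute-force maximization of the binomial log-likelihood over a zooming
    2-parameter grid.  Independent of the IRLS path."""
    assert X.shape[1] == 2
    s = np.asarray(s, float)
    n = np.asarray(n, float)
    centers = np.array([0.0, 0.0])
    half = (hi - lo) / 2.0
    best = -np.inf
    for _ in range(4):
        b0 = np.linspace(centers[0] - half, centers[0] + half, 161)
        b1 = np.linspace(centers[1] - half, centers[1] + half, 161)
        B0, B1 = np.meshgrid(b0, b1, indexing="ij")
        eta = (
            X[:, 0][:, None, None] * B0[None] + X[:, 1][:, None, None] * B1[None]
        )
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        ll = np.sum(
            s[:, None, None] * np.log(mu) + (n - s)[:, None, None] * np.log(1 - mu),
            axis=0,
        )
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = ll[i, j]
        centers = np.array([b0[i], b1[j]])
        half = 2.5 * (b0[1] - b0[0])
    return best


class TestGlmFit:
    def test_saturated_two_cell_model_is_closed_form(self):
        fit = fit_binomial_glm([10, 20], [100, 100], two_group_frame(),
                               ModelSpec("x", ("g",)))
        assert fit.converged and not fit.no_variation
        coefs = fit.coefficients
        assert coefs["intercept"] == pytest.approx(logit(0.10), abs=1e-7)
        assert coefs["g[b]"] == pytest.approx(logit(0.20) - logit(0.10), abs=1e-7)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_identical_groups_give_null_effect(self):
        fit = fit_binomial_glm([5, 5], [100, 100], two_group_frame(),
                               ModelSpec("x", ("g",)))
        assert fit.coefficients["g[b]"] == pytest.approx(0.0, abs=1e-8)
        ft = factor_test(fit, "g")
        assert ft.statistic == pytest.approx(0.0, abs=1e-8)
        assert ft.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_irls_optimum_matches_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        n_cells = rng.integers(2, 5)
        data = pd.DataFrame({"g": ["a", "b"] * 2})
        data = data.iloc[:n_cells].reset_index(drop=True)
        if data["g"].nunique() < 2:
            data.loc[n_cells - 1, "g"] = "b"
        n = rng.integers(30, 200, size=n_cells)
        p = rng.uniform(0.05, 0.6, size=n_cells)
        s = rng.binomial(n, p)
        s = np.clip(s, 1, n - 1)  # keep away from separation for the grid
        fit = fit_binomial_glm(s, n, data, ModelSpec("x", ("g",)))
        X = np.column_stack([np.ones(n_cells), (data["g"] == "b").astype(float)])
        assert fit.loglik == pytest.approx(grid_max_loglik(s, n, X), abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_reference_glm_implementation(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(100 + seed)
        data = pd.DataFrame({
            "flock": np.repeat(["f1", "f2", "f3"], 4),
            "kind": ["wall", "central"] * 6,
        })
        n = rng.integers(500, 3000, size=12)
        s = rng.binomial(n, rng.uniform(0.002, 0.02, size=12))
        s = np.maximum(s, 1)
        fit = fit_binomial_glm(s, n, data, ModelSpec("x", ("flock", "kind")))
        X = np.column_stack([
            np.ones(12),
            (data["flock"] == "f2").astype(float),
            (data["flock"] == "f3").astype(float),
            (data["kind"] == "wall").astype(float),
        ])
        ref = sm.GLM(np.column_stack([s, n - s]), X, family=sm.families.Binomial()).fit()
        assert fit.params == pytest.approx(ref.params, abs=1e-6)
        assert fit.deviance == pytest.approx(ref.deviance, abs=1e-6)

    def test_no_variation_response_is_not_fit(self):
        fit = fit_binomial_glm([0, 0], [100, 100], two_group_frame(),
                               ModelSpec("x", ("g",)))
        assert fit.no_variation and fit.params is None
        ft = factor_test(fit, "g")
        assert ft.flagged and ft.pvalue is None

    def test_separation_is_flagged(self):
        fit = fit_binomial_glm([0, 40], [500, 500], two_group_frame(),
                               ModelSpec("x", ("g",)))
        assert fit.converged
        assert any("g[b]" in nm or "intercept" in nm for nm in fit.separation)

    def test_aliased_factors_rejected(self):
        data = pd.DataFrame({"g": ["a", "b"], "h": ["x", "y"]})  # h aliases g
        with pytest.raises(RankDeficiencyError, match="aliased"):
            fit_binomial_glm([5, 10], [50, 50], data, ModelSpec("x", ("g", "h")))

    def test_single_level_factor_dropped_with_warning(self):
        data = pd.DataFrame({"g": ["a", "b"], "h": ["x", "x"]})
        with pytest.warns(UserWarning, match="single observed level"):
            fit = fit_binomial_glm([5, 10], [50, 50], data, ModelSpec("x", ("g", "h")))
        assert fit.dropped_factors == ["h"]


class TestFactorTest:
    def test_statistic_equals_twice_loglik_gap(self):
        s, n = [12, 30, 9, 15], [800, 900, 700, 850]
        data = pd.DataFrame({"flock": ["f1", "f1", "f2", "f2"],
                             "kind": ["wall", "central"] * 2})
        fit = fit_binomial_glm(s, n, data, ModelSpec("x", ("flock", "kind")))
        reduced = fit_binomial_glm(s, n, data, ModelSpec("x", ("kind",)))
        ft = factor_test(fit, "flock")
        assert ft.statistic == pytest.approx(2 * (fit.loglik - reduced.loglik), abs=1e-8)
        assert ft.df == 1

    def test_invariant_to_reference_level_choice(self):
        s, n = [12, 30, 9, 15], [800, 900, 700, 850]
        base = pd.DataFrame({"flock": ["f1", "f1", "f2", "f2"],
                             "kind": ["wall", "central"] * 2})
        pvals = set()
        for relabel in ({"f1": "aa", "f2": "zz"}, {"f1": "zz", "f2": "aa"}):
            data = base.assign(flock=base["flock"].map(relabel))
            fit = fit_binomial_glm(s, n, data, ModelSpec("x", ("flock", "kind")))
            pvals.add(round(factor_test(fit, "flock").pvalue, 12))
        assert len(pvals) == 1

    def test_strong_flock_contrast_is_detected(self):
        # prevalence 0.8% vs 0.03% at ~2000 birds per cell
        s, n = [16, 17, 1, 0], [2000, 2000, 2000, 2000]
        data = pd.DataFrame({"flock": ["f1", "f1", "f2", "f2"],
                             "kind": ["wall", "central"] * 2})
        fit = fit_binomial_glm(s, n, data, ModelSpec("x", ("flock", "kind")))
        assert factor_test(fit, "flock").pvalue < 0.001


class TestTukey:
    def fit_three_groups(self, s=(10, 20, 30), n=(200, 200, 200)):
        data = pd.DataFrame({"g": ["a", "b", "c"]})
        return fit_binomial_glm(list(s), list(n), data, ModelSpec("x", ("g",)))

    def test_two_levels_reduce_to_single_comparison(self):
        fit = fit_binomial_glm([10, 20], [100, 100], two_group_frame(),
                               ModelSpec("x", ("g",)))
        tk = tukey_pairwise(fit, "g")
        (c,) = tk.comparisons
        assert c.p_adjusted == pytest.approx(c.p_unadjusted, rel=1e-6)

    def test_equal_means_share_one_letter(self):
        fit = self.fit_three_groups(s=(15, 15, 15))
        tk = tukey_pairwise(fit, "g")
        assert set(tk.letters.values()) == {"a"}

    @pytest.mark.parametrize("seed", range(5))
    def test_adjusted_p_is_never_smaller_than_unadjusted(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 5))
        data = pd.DataFrame({"g": [f"g{i}" for i in range(k)] * 2})
        n = rng.integers(100, 500, size=2 * k)
        s = np.clip(rng.binomial(n, rng.uniform(0.05, 0.4, size=2 * k)), 1, None)
        fit = fit_binomial_glm(s, n, data, ModelSpec("x", ("g",)))
        tk = tukey_pairwise(fit, "g")
        for c in tk.comparisons:
            assert c.p_adjusted >= c.p_unadjusted - 1e-12

    def test_clearly_separated_means_get_distinct_letters(self):
        fit = self.fit_three_groups(s=(5, 60, 150), n=(300, 300, 300))
        tk = tukey_pairwise(fit, "g")
        assert len(set(tk.letters.values())) == 3


def naive_spearman_rho(x, y):
    """Brute-force oracle: average ranks assigned by explicit tie scanning,
    then the Pearson correlation of the ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_perfect_monotone_agreement(self):
        assert spearman([1, 5, 9, 11], [2, 3, 8, 20]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_tied_inputs_match_naive_ranking_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        x = rng.integers(0, 3, size=n).astype(float)
        y = rng.integers(0, 3, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert spearman(x, y).rho == pytest.approx(naive_spearman_rho(x, y), abs=1e-12)

    @given(
        st.lists(st.integers(-100, 100), min_size=4, max_size=10, unique=True),
    )
    def test_invariant_under_monotone_transforms(self, x):
        x = [float(v) for v in x]
        rng = np.random.default_rng(7)
        y = list(rng.random(len(x)))
        base = spearman(x, y).rho
        assert spearman([math.exp(v / 50) for v in x], y).rho == pytest.approx(base)
        assert spearman(x, [3 * v + 1 for v in y]).rho == pytest.approx(base)

    def test_zero_variance_is_flagged_not_raised(self):
        r = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert r.undefined and math.isnan(r.rho)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1.0, 2.0], [1.0, 2.0])


class TestMethodCorrelation:
    def test_identical_methods_correlate_perfectly(self):
        table = pd.DataFrame({
            "transect": [0.1, 0.4, 0.2, 0.8],
            "graded_a": [0.1, 0.4, 0.2, 0.8],
            "graded_b": [1.0, 4.0, 2.0, 8.0],
        }, index=["f1", "f2", "f3", "f4"])
        (m,) = method_correlation_matrix({"fl_head": table}).values()
        assert np.allclose(np.diag(m.rho), 1.0)
        assert m.rho.loc["transect", "graded_a"] == pytest.approx(1.0)
        assert m.rho.loc["transect", "graded_b"] == pytest.approx(1.0)

    def test_insufficient_flocks_omitted_with_reason(self):
        table = pd.DataFrame({
            "transect": [0.1, 0.4, 0.2],
            "graded": [0.2, np.nan, 0.1],
        }, index=["f1", "f2", "f3"])
        (m,) = method_correlation_matrix({"dirty": table}).values()
        assert math.isnan(m.rho.loc["transect", "graded"])
        assert any("2 flocks" in r for r in m.omitted)

    def test_stars_reflect_significance(self):
        rng = np.random.default_rng(3)
        x = rng.random(8)
        table = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, 8)})
        (m,) = method_correlation_matrix({"x": table}).values()
        assert m.stars().loc["a", "b"] in ("*", "**", "***")
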