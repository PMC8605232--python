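"""Binomial-logit models and correlations for welfare-indicator comparisons.

The field protocol compares indicator prevalences across flocks, observers,
transect types and vertical levels with fixed-factor binomial generalized
linear models on aggregated counts (successes out of trials per cell), and
relates the three scoring methods through tie-aware Spearman correlations of
flock-level prevalences.

The GLM is fit by iteratively reweighted least squares (IRLS) on the logit
link, with a per-iteration guarantee that the log-likelihood never decreases
(step-halving fallback).  Factor significance uses the likelihood-ratio
chi-square of the nested fit without that factor; pairwise comparisons of
factor least-squares means are adjusted with the Tukey studentized-range
distribution.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit

__all__ = [
    "ModelSpec",
    "GlmFit",
    "FactorTest",
    "PairwiseComparison",
    "TukeyResult",
    "SpearmanResult",
    "CorrelationMatrix",
    "RankDeficiencyError",
    "ConvergenceError",
    "fit_binomial_glm",
    "factor_test",
    "tukey_pairwise",
    "spearman",
    "method_correlation_matrix",
]

#: coefficients beyond this magnitude on the logit scale indicate separation
SEPARATION_LOGIT = 10.0


class RankDeficiencyError(ValueError):
    """Raised when the design matrix is rank deficient (aliased columns)."""


class ConvergenceError(RuntimeError):
    """Raised when IRLS fails to make monotone likelihood progress."""


@dataclass(frozen=True)
class ModelSpec:
    """What to model: a response indicator and the fixed factors.

    ``factors`` is an ordered subset of {flock, observer, transect_kind,
    vertical_level} (any categorical column works).  Treatment coding is used
    with the first level in sort order as reference; inference is invariant to
    that choice.
    """

    response: str
    factors: tuple[str, ...]
    score_level: int | None = None

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("ModelSpec requires at least one factor")


@dataclass
class GlmFit:
    """A fitted (or deliberately unfitted) binomial-logit model.

    When the response has no variation (all cells zero, or all saturated) the
    model is not fit: ``no_variation`` is set and every inferential field is
    ``None``.  ``separation`` lists coefficients whose magnitude exceeds 10 on
    the logit scale; contrasts involving them are not estimable.
    """

    spec: ModelSpec
    param_names: list[str]
    params: np.ndarray | None
    cov: np.ndarray | None
    deviance: float | None
    loglik: float | None
    df_resid: int | None
    converged: bool
    n_iter: int
    no_variation: bool
    separation: list[str]
    factor_levels: dict[str, list[str]]
    dropped_factors: list[str]
    successes: np.ndarray
    trials: np.ndarray
    data: pd.DataFrame
    fitted_p: np.ndarray | None

    @property
    def coefficients(self) -> dict[str, float] | None:
        if self.params is None:
            return None
        return dict(zip(self.param_names, self.params.tolist()))


@dataclass(frozen=True)
class FactorTest:
    """Likelihood-ratio test of one fixed factor."""

    factor: str
    statistic: float | None
    df: int | None
    pvalue: float | None
    flagged: bool = False
    reason: str | None = None


@dataclass(frozen=True)
class PairwiseComparison:
    """Tukey-adjusted difference of two factor least-squares means."""

    level_a: str
    level_b: str
    estimate: float  # logit-scale difference a - b
    se: float
    p_adjusted: float
    p_unadjusted: float


@dataclass(frozen=True)
class TukeyResult:
    factor: str
    comparisons: tuple[PairwiseComparison, ...]
    letters: dict[str, str]
    lsmeans_logit: dict[str, float]
    lsmeans_response: dict[str, float]
    excluded_levels: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    undefined: bool = False
    reason: str | None = None


def _binom_loglik(s: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    """Binomial log-likelihood without the combinatorial constant."""
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(s * np.log(mu) + (n - s) * np.log(1 - mu)))


def _saturated_loglik(s: np.ndarray, n: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(s > 0, s * np.log(s / n), 0.0)
        t2 = np.where(n - s > 0, (n - s) * np.log((n - s) / n), 0.0)
    return float(np.sum(t1 + t2))


def _build_design(
    data: pd.DataFrame, factors: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, list[str]], list[str]]:
    """Treatment-coded design matrix; drops factors with < 2 observed levels."""
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    levels: dict[str, list[str]] = {}
    dropped: list[str] = []
    for f in factors:
        if f not in data.columns:
            raise KeyError(f"factor column {f!r} missing from data")
        lv = sorted(data[f].astype(str).unique())
        if len(lv) < 2:
            warnings.warn(
                f"factor {f!r} has a single observed level {lv}; dropped from model",
                stacklevel=3,
            )
            dropped.append(f)
            continue
        levels[f] = lv
        col = data[f].astype(str).to_numpy()
        for l in lv[1:]:
            cols.append((col == l).astype(float))
            names.append(f"{f}[{l}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns; aliased: {aliased}"
        )
    return X, names, levels, dropped


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy left-to-right detection of linearly dependent columns."""
    aliased = []
    kept: list[np.ndarray] = []
    for j in range(X.shape[1]):
        if not kept:
            kept.append(X[:, j])
            continue
        B = np.column_stack(kept)
        resid = X[:, j] - B @ np.linalg.lstsq(B, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            aliased.append(names[j])
        else:
            kept.append(X[:, j])
    return aliased


def fit_binomial_glm(
    successes: Sequence[int] | np.ndarray,
    trials: Sequence[int] | np.ndarray,
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Fit a fixed-factor binomial GLM with logit link by IRLS.

    ``successes[i]`` of ``trials[i]`` birds in cell ``i`` show the indicator;
    ``data`` carries one row per cell with the factor columns of ``spec``.
    Convergence is declared when the largest coefficient change drops below
    ``tol``.  The log-likelihood is asserted non-decreasing at every
    iteration (with step-halving when a raw IRLS step overshoots).

    A response with no variation (no affected birds anywhere, or every bird
    affected) is not fit; the returned fit carries ``no_variation=True`` and
    should be reported descriptively.
    """
    s = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    if s.shape != n.shape or s.ndim != 1:
        raise ValueError("successes and trials must be equal-length 1-d arrays")
    if len(s) != len(data):
        raise ValueError("data must have one row per cell")
    if np.any(s < 0) or np.any(n <= 0) or np.any(s > n):
        raise ValueError("need 0 <= successes <= trials and trials > 0 in every cell")

    X, names, levels, dropped = _build_design(data, spec.factors)

    if s.sum() == 0 or np.all(s == n):
        return GlmFit(
            spec=spec, param_names=names, params=None, cov=None, deviance=None,
            loglik=None, df_resid=None, converged=False, n_iter=0,
            no_variation=True, separation=[], factor_levels=levels,
            dropped_factors=dropped, successes=s, trials=n, data=data,
            fitted_p=None,
        )

    p = X.shape[1]
    # start from the empirically smoothed per-cell rates
    mu = (s + 0.5) / (n + 1.0)
    eta = logit(mu)
    beta = np.zeros(p)
    ll = _binom_loglik(s, n, expit(X @ beta))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        w = n * mu * (1 - mu)
        z = eta + (s / n - mu) / (mu * (1 - mu))
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        # step-halving keeps the log-likelihood monotone
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            ll_new = _binom_loglik(s, n, expit(X @ cand))
            if ll_new >= ll - 1e-10:
                break
            step /= 2.0
        else:
            raise ConvergenceError("IRLS could not make monotone likelihood progress")
        assert ll_new >= ll - 1e-10, "log-likelihood decreased within an IRLS iteration"
        delta = np.max(np.abs(cand - beta))
        ll_gain = ll_new - ll
        beta, ll = cand, ll_new
        eta = X @ beta
        # coefficient convergence, or a likelihood plateau (the latter occurs
        # under separation, where coefficients drift but the fit is done)
        if delta < tol or ll_gain < 1e-12:
            converged = True
            break

    mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    w = n * mu * (1 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    deviance = 2.0 * (_saturated_loglik(s, n) - ll)
    separation = [nm for nm, b in zip(names, beta) if abs(b) > SEPARATION_LOGIT]
    return GlmFit(
        spec=spec, param_names=names, params=beta, cov=cov,
        deviance=max(deviance, 0.0), loglik=ll, df_resid=len(s) - p,
        converged=converged, n_iter=it, no_variation=False,
        separation=separation, factor_levels=levels, dropped_factors=dropped,
        successes=s, trials=n, data=data, fitted_p=mu,
    )


def factor_test(fit: GlmFit, factor: str) -> FactorTest:
    """Likelihood-ratio chi-square test of one fixed factor.

    The statistic is the deviance difference between the fit without the
    factor and the full fit — identically ``2 * (loglik_full - loglik_reduced)``
    — on ``levels - 1`` degrees of freedom.
    """
    if factor not in fit.spec.factors:
        raise KeyError(f"factor {factor!r} not in model spec {fit.spec.factors}")
    if fit.no_variation:
        return FactorTest(factor, None, None, None, flagged=True,
                          reason="response has no variation; not fit")
    if not fit.converged:
        return FactorTest(factor, None, None, None, flagged=True,
                          reason="full model did not converge")
    if factor in fit.dropped_factors:
        return FactorTest(factor, None, None, None, flagged=True,
                          reason="factor has a single observed level")

    remaining = tuple(f for f in fit.spec.factors if f != factor)
    if remaining:
        reduced = fit_binomial_glm(
            fit.successes, fit.trials, fit.data,
            ModelSpec(fit.spec.response, remaining, fit.spec.score_level),
        )
        if not reduced.converged:
            return FactorTest(factor, None, None, None, flagged=True,
                              reason="reduced model did not converge")
        ll_reduced = reduced.loglik
    else:
        # intercept-only null: closed form at the pooled rate
        mu0 = fit.successes.sum() / fit.trials.sum()
        ll_reduced = _binom_loglik(fit.successes, fit.trials,
                                   np.full_like(fit.trials, mu0, dtype=float))
    stat = max(2.0 * (fit.loglik - ll_reduced), 0.0)
    df = len(fit.factor_levels[factor]) - 1
    return FactorTest(factor, stat, df, float(sps.chi2.sf(stat, df)))


def _lsmean_contrasts(fit: GlmFit, factor: str) -> dict[str, np.ndarray]:
    """Contrast vector per factor level: own effect plus the balanced average
    of every other factor's effects (equal weight per level)."""
    contrasts = {}
    idx = {nm: i for i, nm in enumerate(fit.param_names)}
    for level in fit.factor_levels[factor]:
        c = np.zeros(len(fit.param_names))
        c[idx["intercept"]] = 1.0
        nm = f"{factor}[{level}]"
        if nm in idx:  # reference level has no column
            c[idx[nm]] = 1.0
        for other, lvs in fit.factor_levels.items():
            if other == factor:
                continue
            for l in lvs[1:]:
                c[idx[f"{other}[{l}]"]] = 1.0 / len(lvs)
        contrasts[level] = c
    return contrasts


def tukey_pairwise(fit: GlmFit, factor: str, alpha: float = 0.05) -> TukeyResult:
    """All pairwise LS-mean differences of a factor, Tukey adjusted.

    Differences are on the logit scale.  Adjusted P values come from the
    studentized-range distribution with the residual degrees of freedom of
    the cell-level fit (normal approximation when the fit is saturated).
    Levels whose coefficients show separation are excluded as non-estimable.
    A compact letter display is built greedily from the sorted LS-means:
    levels sharing a letter are not significantly different at ``alpha``.
    """
    if fit.no_variation or fit.params is None:
        raise ValueError("cannot compare levels of an unfitted (no-variation) model")
    if not fit.converged:
        raise ValueError("fit did not converge")
    if factor not in fit.factor_levels:
        raise KeyError(f"factor {factor!r} not in fitted model")

    levels = list(fit.factor_levels[factor])
    excluded = tuple(
        l for l in levels if f"{factor}[{l}]" in fit.separation
    )
    levels = [l for l in levels if l not in excluded]
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 estimable levels")

    k = len(levels)
    df = fit.df_resid if fit.df_resid and fit.df_resid > 0 else None
    if df is None:
        warnings.warn(
            "no residual degrees of freedom; using the normal approximation",
            stacklevel=2,
        )
    contrasts = _lsmean_contrasts(fit, factor)
    lsmeans = {l: float(contrasts[l] @ fit.params) for l in levels}

    comparisons = []
    padj_lookup: dict[frozenset[str], float] = {}
    for a, b in itertools.combinations(levels, 2):
        c = contrasts[a] - contrasts[b]
        est = float(c @ fit.params)
        se = float(math.sqrt(c @ fit.cov @ c))
        tstat = abs(est) / se
        q = tstat * math.sqrt(2.0)
        dfq = df if df is not None else 1e7
        p_adj = float(np.clip(sps.studentized_range.sf(q, k, dfq), 0.0, 1.0))
        if df is not None:
            p_un = float(2.0 * sps.t.sf(tstat, df))
        else:
            p_un = float(2.0 * sps.norm.sf(tstat))
        comparisons.append(PairwiseComparison(a, b, est, se, p_adj, p_un))
        padj_lookup[frozenset((a, b))] = p_adj

    letters = _compact_letters(levels, lsmeans, padj_lookup, alpha)
    return TukeyResult(
        factor=factor,
        comparisons=tuple(comparisons),
        letters=letters,
        lsmeans_logit=lsmeans,
        lsmeans_response={l: float(expit(m)) for l, m in lsmeans.items()},
        excluded_levels=excluded,
    )


def _compact_letters(
    levels: list[str],
    lsmeans: Mapping[str, float],
    padj: Mapping[frozenset[str], float],
    alpha: float,
) -> dict[str, str]:
    """Greedy insertion: walk levels by descending LS-mean (ties by name) and
    add each to every existing group it is non-significant with; open a new
    group otherwise.  Levels with different letter sets differ at ``alpha``."""
    order = sorted(levels, key=lambda l: (-lsmeans[l], l))
    groups: list[list[str]] = []
    for lvl in order:
        placed = False
        for g in groups:
            if all(padj[frozenset((lvl, m))] > alpha for m in g):
                g.append(lvl)
                placed = True
        if not placed:
            groups.append([lvl])
    letters = {l: "" for l in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for l in g:
            letters[l] += letter
    return {l: "".join(sorted(letters[l])) for l in levels}


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Tie-aware Spearman rank correlation with a t-approximation P value.

    Average ranks are assigned to ties; rho is the Pearson correlation of the
    ranks, and P comes from the t distribution with n-2 degrees of freedom.
    Pairs with a missing value in either vector are deleted first.  A vector
    with zero rank variance leaves rho undefined (flagged, not raised).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), n, undefined=True,
                              reason="zero rank variance in one input")
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), n)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise method agreement for one indicator: symmetric rho matrix with
    unit diagonal, matching P values, and omitted pairs with reasons."""

    indicator: str
    rho: pd.DataFrame
    pvalue: pd.DataFrame
    omitted: tuple[str, ...] = ()

    def stars(self) -> pd.DataFrame:
        """Significance stars at 0.05 / 0.01 / 0.001."""
        def star(p: float) -> str:
            if not np.isfinite(p):
                return ""
            return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        return self.pvalue.map(star)


def method_correlation_matrix(
    flock_values: Mapping[str, pd.DataFrame],
) -> dict[str, CorrelationMatrix]:
    """Spearman agreement between scoring methods, per mapped indicator.

    ``flock_values[indicator]`` is a table with one row per flock and one
    column per method, holding that method's flock-level prevalence of the
    (mapped) indicator.  Each method pair needs at least 3 flocks with both
    values; pairs with fewer are omitted with a reason and reported as NaN.
    The diagonal is exactly 1.
    """
    out = {}
    for indicator, table in flock_values.items():
        methods = list(table.columns)
        rho = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
        pv = pd.DataFrame(np.full((len(methods),) * 2, np.nan), index=methods, columns=methods)
        omitted = []
        for a, b in itertools.combinations(methods, 2):
            pair = table[[a, b]].dropna()
            if len(pair) < 3:
                omitted.append(f"{indicator}: {a} vs {b} has {len(pair)} flocks (< 3)")
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                continue
            r = spearman(pair[a], pair[b])
            if r.undefined:
                omitted.append(f"{indicator}: {a} vs {b} undefined ({r.reason})")
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                continue
            rho.loc[a, b] = rho.loc[b, a] = r.rho
            pv.loc[a, b] = pv.loc[b, a] = r.pvalue
        out[indicator] = CorrelationMatrix(indicator, rho, pv, tuple(omitted))
    return out
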