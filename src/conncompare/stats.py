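"""Between-group inference for connectome metrics.

AUC differences are tested with a label-permutation test (default 2,000
iterations, two-tailed, with the +1/(n+1) finite-sample correction so p is
never zero). Weighted-network metrics are compared with an ordinary linear
model including network density as a covariate, testing the group term by
the two-model F statistic. Subjects whose networks lack small-world
organization (sigma <= 1) can be excluded before single-density contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .density import auc_over_window
from .io import DensityWindow, MetricCurve, ValidationError

logger = logging.getLogger("conncompare")


@dataclass
class PermutationResult:
    """Outcome of a two-tailed group-label permutation test."""

    observed: float
    null_distribution: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def summary(self) -> str:
        return (f"observed diff = {self.observed:+.4g}, "
                f"p = {self.p_value:.4f} ({self.n_perm} permutations)")


@dataclass
class GlmResult:
    """Group effect from y ~ 1 + group + density (OLS)."""

    f_statistic: float
    p_value: float
    params: np.ndarray  # (intercept, group, density)
    df_resid: int

    def summary(self) -> str:
        b0, b1, b2 = self.params
        return (f"F(1, {self.df_resid}) = {self.f_statistic:.3f}, "
                f"p = {self.p_value:.4f}; "
                f"coef: intercept={b0:.4g}, group={b1:.4g}, density={b2:.4g}")


def _perm_pvalue(observed: float, null: np.ndarray) -> float:
    # tolerance so resamples identical to the observed assignment are not
    # missed through summation-order rounding
    tol = 1e-12 * max(1.0, abs(observed))
    exceed = np.count_nonzero(np.abs(null) >= abs(observed) - tol)
    return (exceed + 1) / (null.size + 1)


def permutation_test_means(
    vals_a: np.ndarray,
    vals_b: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
    exact: bool = False,
) -> PermutationResult:
    """Two-tailed permutation test on the difference of group means.

    ``exact=True`` enumerates every group-label assignment instead of
    Monte-Carlo resampling (feasible for small cohorts: 4v4 has C(8,4)=70
    splits); the exact p is then #{|diff*| >= |diff|} / n_splits, with the
    observed assignment counted among the splits.
    """
    vals_a = np.asarray(vals_a, dtype=float)
    vals_b = np.asarray(vals_b, dtype=float)
    if vals_a.size < 2 or vals_b.size < 2:
        raise ValidationError("need at least 2 subjects per group")
    pooled = np.concatenate([vals_a, vals_b])
    n_a = vals_a.size
    n = pooled.size
    observed = vals_a.mean() - vals_b.mean()
    if exact:
        splits = list(combinations(range(n), n_a))
        null = np.empty(len(splits))
        for i, idx_a in enumerate(splits):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            null[i] = pooled[mask].mean() - pooled[~mask].mean()
        p = np.count_nonzero(np.abs(null) >= np.abs(observed) - 1e-12) / null.size
        return PermutationResult(float(observed), null, float(p),
                                 null.size, seed)
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[:n_a].mean() - perm[n_a:].mean()
    return PermutationResult(float(observed), null,
                             _perm_pvalue(observed, null), n_perm, seed)


def auc_permutation_test(
    curves_a: list[MetricCurve],
    curves_b: list[MetricCurve],
    window: DensityWindow,
    n_perm: int = 2000,
    seed: int = 0,
    exact: bool = False,
) -> PermutationResult:
    """Permutation test on the group difference in metric AUC over a window.

    Each subject is reduced to one AUC before labels are shuffled, so the
    within-subject dependence across densities is preserved under the null.
    """
    auc_a = np.array([auc_over_window(c, window) for c in curves_a])
    auc_b = np.array([auc_over_window(c, window) for c in curves_b])
    return permutation_test_means(auc_a, auc_b, n_perm=n_perm, seed=seed,
                                  exact=exact)


def glm_group_test(
    values: np.ndarray,
    groups: np.ndarray,
    densities: np.ndarray,
) -> GlmResult:
    """Density-covaried group contrast for weighted-network metrics.

    Fits y = b0 + b1*group + b2*density by OLS and tests b1 = 0 with the
    partial F statistic F = ((RSS_reduced - RSS_full)/1) / (RSS_full/df).
    ``groups`` may be 0/1 codes or two string labels (coded in order of
    first appearance).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    d = np.asarray(densities, dtype=float)
    if g.dtype.kind not in "biuf":
        labels = list(dict.fromkeys(g.tolist()))
        if len(labels) != 2:
            raise ValidationError(f"need exactly two groups, got {labels}")
        g = np.array([labels.index(x) for x in g], dtype=float)
    g = g.astype(float)
    if y.size != g.size or y.size != d.size:
        raise ValidationError("values, groups, densities must align")
    if np.ptp(d) == 0:
        logger.warning("density covariate is constant; dropping it")
        x_full = sm.add_constant(g, has_constant="add")
        x_red = np.ones((y.size, 1))
    else:
        x_full = sm.add_constant(np.column_stack([g, d]), has_constant="add")
        x_red = sm.add_constant(d, has_constant="add")
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValidationError("design matrix is singular "
                              "(density collinear with group?)")
    full = sm.OLS(y, x_full).fit()
    reduced = sm.OLS(y, x_red).fit()
    params = np.asarray(full.params, dtype=float)
    if params.size == 2:  # constant density dropped: no density coefficient
        params = np.append(params, 0.0)
    df = int(full.df_resid)
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")
    rss_full = float(full.ssr)
    rss_red = float(reduced.ssr)
    if rss_full == 0:
        f_stat = np.inf
        p = 0.0
    else:
        f_stat = (rss_red - rss_full) / (rss_full / df)
        p = float(sps.f.sf(f_stat, 1, df))
    return GlmResult(float(f_stat), p, params, df)


def two_sample_t(
    vals_a: np.ndarray,
    vals_b: np.ndarray,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided independent-samples t test (pooled variance by default)."""
    vals_a = np.asarray(vals_a, dtype=float)
    vals_b = np.asarray(vals_b, dtype=float)
    if vals_a.size < 2 or vals_b.size < 2:
        raise ValidationError("need at least 2 subjects per group")
    if equal_var and vals_a.var(ddof=1) == 0 and vals_b.var(ddof=1) == 0:
        raise ValidationError("zero pooled variance: t undefined")
    res = sps.ttest_ind(vals_a, vals_b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ExclusionReport:
    included: dict[str, list[str]]
    excluded: dict[str, list[str]]


def small_world_filter(
    sigmas: dict[str, float],
    groups: dict[str, str],
) -> ExclusionReport:
    """Retain subjects with sigma strictly greater than 1.

    Mirrors the practice of excluding subjects whose connectome shows no
    small-world organization before single-density group contrasts. A group
    emptied by the exclusion is an error.
    """
    included: dict[str, list[str]] = {}
    excluded: dict[str, list[str]] = {}
    for sid, sigma in sigmas.items():
        grp = groups[sid]
        included.setdefault(grp, [])
        excluded.setdefault(grp, [])
        if sigma > 1:
            included[grp].append(sid)
        else:
            excluded[grp].append(sid)
            logger.info("excluding %s (group %s): sigma = %.3f <= 1",
                        sid, grp, sigma)
    for grp, ids in included.items():
        if not ids:
            raise ValidationError(
                f"group {grp!r} eliminated by small-world exclusion"
            )
    return ExclusionReport(included, excluded)
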