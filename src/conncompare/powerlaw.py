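"""Cumulative degree distributions and (truncated) power-law fitting.

Heavy-tailed degree distributions signal hub organization: a few regions
carry a disproportionate share of connections. The tail is modelled as a
power law p(x) ~ x^-alpha for x >= x_min, or an exponentially truncated
power law p(x) ~ x^-alpha * exp(-rate*x). Fitting follows the standard
maximum-likelihood recipe: alpha by MLE at each candidate x_min, x_min
chosen to minimize the Kolmogorov-Smirnov (KS) distance between the fitted
model and the empirical tail, and goodness of fit assessed by a
semi-parametric bootstrap (refit each resample; p = fraction of bootstrap
KS distances at least as large as the observed one).

Discrete data (integer degrees) use the Hurwitz-zeta normalization; node
strengths of weighted networks use the continuous formulation, because the
binary degree of a near-complete weighted graph is degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.integrate import quad

from .io import ValidationError
from .metrics import degrees, strengths

logger = logging.getLogger("conncompare")

MIN_TAIL = 10
ALPHA_BOUNDS = (1.000001, 12.0)


def cumulative_degree_distribution(
    matrix: np.ndarray, mode: str = "degree"
) -> tuple[np.ndarray, np.ndarray]:
    """Complementary cumulative distribution P(K >= k) of degrees/strengths.

    Returns the sorted unique values and P(K >= k) at each; the first
    probability is 1 and the sequence is non-increasing.
    """
    if not np.any(matrix):
        raise ValidationError("empty network has no degree distribution")
    vals = degrees(matrix) if mode == "degree" else strengths(matrix)
    uniq = np.unique(vals)
    ccdf = np.array([(vals >= u).mean() for u in uniq])
    return uniq, ccdf


# ---------------------------------------------------------------- pure power law

def _alpha_mle_continuous(tail: np.ndarray, xmin: float) -> float:
    return 1.0 + tail.size / np.log(tail / xmin).sum()


def _alpha_mle_discrete(tail: np.ndarray, xmin: float) -> float:
    logsum = np.log(tail).sum()
    n = tail.size

    def nll(alpha: float) -> float:
        return n * np.log(special.zeta(alpha, xmin)) + alpha * logsum

    res = optimize.minimize_scalar(nll, bounds=ALPHA_BOUNDS, method="bounded")
    return float(res.x)


def _model_cdf_power(x: np.ndarray, alpha: float, xmin: float,
                     discrete: bool) -> np.ndarray:
    if discrete:
        z0 = special.zeta(alpha, xmin)
        return 1.0 - special.zeta(alpha, np.floor(x) + 1) / z0
    return 1.0 - (x / xmin) ** (1.0 - alpha)


# ----------------------------------------------------- truncated power law

def _log_norm_truncated(alpha: float, rate: float, xmin: float,
                        discrete: bool) -> float:
    """log of the normalizing constant of x^-alpha * exp(-rate*x), x >= xmin."""
    if discrete:
        total, k = 0.0, float(xmin)
        while True:
            ks = np.arange(k, k + 4096)
            terms = np.exp(-alpha * np.log(ks) - rate * ks)
            total += terms.sum()
            if terms[-1] < 1e-17 * max(total, 1e-300) or k > 1e7:
                break
            k += 4096
        return np.log(max(total, 1e-300))
    val, _ = quad(lambda x: np.exp(-alpha * np.log(x) - rate * x),
                  xmin, np.inf, limit=200)
    return np.log(max(val, 1e-300))


def _fit_truncated(tail: np.ndarray, xmin: float,
                   discrete: bool) -> tuple[float, float]:
    n = tail.size
    logsum = np.log(tail).sum()
    xsum = tail.sum()

    def nll(theta):
        alpha, lograte = theta
        rate = np.exp(lograte)
        return (n * _log_norm_truncated(alpha, rate, xmin, discrete)
                + alpha * logsum + rate * xsum)

    best = None
    for a0, r0 in [(1.5, -3.0), (2.5, -2.0), (1.1, -1.0)]:
        res = optimize.minimize(nll, x0=[a0, r0], method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-7,
                                         "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    alpha, lograte = best.x
    return float(alpha), float(np.exp(lograte))


def _model_cdf_truncated(x: np.ndarray, alpha: float, rate: float,
                         xmin: float, discrete: bool) -> np.ndarray:
    logc = _log_norm_truncated(alpha, rate, xmin, discrete)
    if discrete:
        out = np.empty(len(np.atleast_1d(x)))
        xs = np.floor(np.atleast_1d(x)).astype(int)
        kmax = int(xs.max())
        ks = np.arange(int(xmin), kmax + 1)
        pmf = np.exp(-alpha * np.log(ks) - rate * ks - logc)
        cum = np.cumsum(pmf)
        for i, k in enumerate(xs):
            out[i] = cum[k - int(xmin)]
        return out
    xarr = np.atleast_1d(x).astype(float)
    return np.array([
        quad(lambda t: np.exp(-alpha * np.log(t) - rate * t - logc),
             xmin, xi, limit=200)[0]
        for xi in xarr
    ])


# ----------------------------------------------------------------- fitting

@dataclass
class PowerLawFit:
    """Maximum-likelihood tail fit of a (truncated) power law."""

    alpha: float
    xmin: float
    ks: float
    n_tail: int
    discrete: bool
    distribution: str = "power_law"
    rate: float | None = None  # exponential truncation rate, if fitted
    gof_p: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.ks <= 1:
            raise ValidationError(f"KS statistic out of [0,1]: {self.ks}")

    @property
    def alpha_se(self) -> float:
        """Asymptotic standard error of the exponent."""
        return (self.alpha - 1.0) / np.sqrt(self.n_tail)

    def summary(self) -> str:
        s = (f"{self.distribution}: alpha = {self.alpha:.3f} "
             f"(se {self.alpha_se:.3f}), xmin = {self.xmin:g}, "
             f"KS = {self.ks:.4f}, n_tail = {self.n_tail}")
        if self.rate is not None:
            s += f", rate = {self.rate:.4g}"
        if self.gof_p is not None:
            s += f", bootstrap GOF p = {self.gof_p:.3f}"
        return s


def _ks_statistic(tail: np.ndarray, cdf_model: np.ndarray,
                  discrete: bool) -> float:
    """KS distance between the empirical tail and the fitted model.

    Discrete data are heavily tied, so the distance is taken over unique
    values comparing step CDFs; continuous data use the usual two-sided
    empirical envelope.
    """
    tail = np.sort(tail)
    n = tail.size
    if discrete:
        uniq, last_idx = np.unique(tail, return_index=True)
        # empirical F(k) = fraction <= k: position after the last tie
        counts = np.searchsorted(tail, uniq, side="right")
        emp = counts / n
        uniq_cdf = cdf_model[np.searchsorted(tail, uniq, side="left")]
        return float(np.abs(emp - uniq_cdf).max())
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(np.maximum(np.abs(emp_hi - cdf_model),
                            np.abs(emp_lo - cdf_model)).max())


def _fit_at_xmin(values: np.ndarray, xmin: float, discrete: bool,
                 distribution: str) -> tuple[float, float | None, float]:
    tail = np.sort(values[values >= xmin])
    if distribution == "truncated_power_law":
        alpha, rate = _fit_truncated(tail, xmin, discrete)
        cdf = _model_cdf_truncated(tail, alpha, rate, xmin, discrete)
    else:
        alpha = (_alpha_mle_discrete(tail, xmin) if discrete
                 else _alpha_mle_continuous(tail, xmin))
        rate = None
        cdf = _model_cdf_power(tail, alpha, xmin, discrete)
    return alpha, rate, _ks_statistic(tail, cdf, discrete)


def fit_power_law(
    values: np.ndarray,
    discrete: bool | None = None,
    xmin: float | None = None,
    distribution: str = "power_law",
    n_boot: int = 0,
    seed: int = 0,
    min_tail: int = MIN_TAIL,
) -> PowerLawFit:
    """Fit a power-law (or exponentially truncated power-law) tail by MLE.

    When ``xmin`` is None it is chosen among the observed values to minimize
    the KS distance of the fitted model to the empirical tail, requiring at
    least ``min_tail`` tail observations. ``n_boot`` > 0 adds the
    semi-parametric bootstrap goodness-of-fit p (pure power law only).
    """
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size == 0:
        raise ValidationError("no positive values to fit")
    if np.unique(values).size == 1:
        raise ValidationError("all values identical: power-law fit undefined")
    if discrete is None:
        discrete = np.allclose(values, np.round(values))
    if discrete:
        values = np.round(values)
    if xmin is not None:
        if np.count_nonzero(values >= xmin) < min_tail:
            raise ValidationError(f"fewer than {min_tail} tail observations")
        candidates = [float(xmin)]
    else:
        uniq = np.unique(values)
        candidates = [float(u) for u in uniq
                      if np.count_nonzero(values >= u) >= min_tail]
        if not candidates:
            raise ValidationError(f"fewer than {min_tail} tail observations")
    best = None
    for xm in candidates:
        alpha, rate, ks = _fit_at_xmin(values, xm, discrete, distribution)
        if best is None or ks < best[3]:
            best = (xm, alpha, rate, ks)
    xm, alpha, rate, ks = best
    n_tail = int(np.count_nonzero(values >= xm))
    fit = PowerLawFit(alpha, xm, ks, n_tail, discrete, distribution, rate,
                      seed=seed)
    if n_boot > 0:
        fit.gof_p = _bootstrap_gof(values, fit, n_boot, seed,
                                   min_tail, xmin_fixed=xmin is not None)
    return fit


def rvs_power_law(alpha: float, xmin: float, size: int,
                  rng: np.random.Generator, discrete: bool = True) -> np.ndarray:
    """Exact samples from a (discrete or continuous) power law."""
    u = rng.random(size)
    if not discrete:
        return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))
    z0 = special.zeta(alpha, xmin)
    kmax = int(xmin) * 2
    while special.zeta(alpha, kmax + 1) / z0 > (1.0 - u.max()):
        kmax *= 2
        if kmax > 10**8:
            break
    ks = np.arange(int(xmin), kmax + 1)
    cdf = 1.0 - special.zeta(alpha, ks + 1) / z0
    idx = np.searchsorted(cdf, u, side="left")
    idx = np.clip(idx, 0, ks.size - 1)
    return ks[idx].astype(float)


def _bootstrap_gof(values: np.ndarray, fit: PowerLawFit, n_boot: int,
                   seed: int, min_tail: int, xmin_fixed: bool) -> float:
    """Semi-parametric bootstrap GOF p for a pure power-law fit."""
    rng = np.random.default_rng(seed)
    below = values[values < fit.xmin]
    n = values.size
    p_tail = fit.n_tail / n
    count = 0
    for _ in range(n_boot):
        tail_mask = rng.random(n) < p_tail
        n_t = int(tail_mask.sum())
        synth = np.empty(n)
        if below.size:
            synth[~tail_mask] = rng.choice(below, size=n - n_t, replace=True)
        else:
            tail_mask[:] = True
            n_t = n
        synth[tail_mask] = rvs_power_law(fit.alpha, fit.xmin, n_t, rng,
                                         fit.discrete)
        try:
            refit = fit_power_law(synth, discrete=fit.discrete,
                                  xmin=fit.xmin if xmin_fixed else None,
                                  min_tail=min(min_tail, max(2, n_t)))
        except ValidationError:
            continue
        if refit.ks >= fit.ks:
            count += 1
    return (count + 1) / (n_boot + 1)


def compare_fit_between_groups(
    fits_a: list[PowerLawFit],
    fits_b: list[PowerLawFit],
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test on subject-level KS goodness-of-fit statistics.

    The statistic is the difference of group-mean KS distances (larger KS =
    poorer power-law fit); group labels are shuffled; two-tailed p with the
    +1/(n+1) correction. Returns (observed difference, p).
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValidationError("need at least 2 subjects per group")
    ks_a = np.array([f.ks for f in fits_a])
    ks_b = np.array([f.ks for f in fits_b])
    pooled = np.concatenate([ks_a, ks_b])
    observed = ks_a.mean() - ks_b.mean()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[:ks_a.size].mean() - perm[ks_a.size:].mean()
    p = (np.count_nonzero(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1)
    return float(observed), float(p)
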