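"""Empirical tail distributions and maximum-likelihood fits.

Degree distributions are summarized with a three-parameter Weibull
(shape alpha, scale beta, location mu) and the fixed-point scores with a
log-normal. The Weibull location is profiled (grid plus local
refinement) because the joint MLE is ill-posed for shapes <= 1;
goodness of fit uses a parametric-bootstrap Kolmogorov-Smirnov test,
since the plain KS test is invalid with estimated parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

MIN_FIT_SIZE = 5


@dataclass
class DistFit:
    family: str  # "weibull3" or "lognormal"
    params: tuple[float, ...]  # (alpha, beta, mu) or (mu, sigma)
    loglik: float
    n: int
    gof_pvalue: float | None = None
    flagged: bool = False  # location hit its search boundary

    def frozen(self) -> stats.rv_continuous:
        """The fitted scipy distribution, for sampling and CDF evaluation."""
        if self.family == "weibull3":
            alpha, beta, mu = self.params
            return stats.weibull_min(alpha, loc=mu, scale=beta)
        mu, sigma = self.params
        return stats.lognorm(sigma, scale=np.exp(mu))


def ccdf(samples) -> list[tuple[float, float]]:
    """Empirical complementary CDF, ``P(X >= x)`` at each distinct value.

    Starts at 1 for the smallest value and is non-increasing.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    values, counts = np.unique(x, return_counts=True)
    # P(X >= v) = fraction of samples at or above v
    at_or_above = counts[::-1].cumsum()[::-1]
    return [(float(v), float(c) / x.size) for v, c in zip(values, at_or_above)]


def fit(
    samples,
    family: str,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> DistFit:
    """Maximum-likelihood fit of a named family.

    Parameters
    ----------
    samples : 1-d array, at least 5 non-identical values.
    family : {"lognormal", "weibull3"}
        Log-normal parameters are the closed-form (mu, sigma) of the log
        sample (1/n variance). The three-parameter Weibull is fitted by
        profile likelihood over the location, constrained strictly below
        the sample minimum.
    n_bootstrap : int
        Number of parametric-bootstrap KS replicates for the
        goodness-of-fit p-value (0 skips the test; 200 is the reporting
        default used by the CLI).
    seed : RNG seed for the bootstrap.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size < MIN_FIT_SIZE:
        raise ValueError(f"need at least {MIN_FIT_SIZE} samples, got {x.size}")
    if x[0] == x[-1]:
        raise ValueError("degenerate (constant) sample")
    if family == "lognormal":
        result = _fit_lognormal(x)
    elif family == "weibull3":
        result = _fit_weibull3(x)
    else:
        raise ValueError(f"unknown family {family!r}")
    if n_bootstrap > 0:
        result.gof_pvalue = _bootstrap_ks(x, result, n_bootstrap, seed)
    return result


def _fit_lognormal(x: np.ndarray) -> DistFit:
    if (x <= 0).any():
        raise ValueError("lognormal requires strictly positive samples")
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    loglik = float(stats.lognorm.logpdf(x, sigma, scale=np.exp(mu)).sum())
    return DistFit(family="lognormal", params=(mu, sigma), loglik=loglik, n=x.size)


def _weibull_loglik(x: np.ndarray, mu: float) -> tuple[float, float, float]:
    """Profile log-likelihood at fixed location; returns (ll, alpha, beta)."""
    shifted = x - mu
    alpha, _, beta = stats.weibull_min.fit(shifted, floc=0.0)
    ll = float(stats.weibull_min.logpdf(shifted, alpha, scale=beta).sum())
    return ll, alpha, beta


def _fit_weibull3(x: np.ndarray) -> DistFit:
    span = x[-1] - x[0]
    upper = x[0] - 1e-9 * max(span, 1.0)  # location strictly below the minimum
    lower = x[0] - 2.0 * span
    grid = np.linspace(lower, upper, 25)
    lls = [_weibull_loglik(x, mu)[0] for mu in grid]
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda mu: -_weibull_loglik(x, mu)[0], bounds=(lo, hi), method="bounded"
    )
    mu = float(res.x)
    ll, alpha, beta = _weibull_loglik(x, mu)
    tol = 1e-6 * max(span, 1.0)
    flagged = (mu - lower) < tol or (upper - mu) < tol
    return DistFit(
        family="weibull3",
        params=(float(alpha), float(beta), mu),
        loglik=ll,
        n=x.size,
        flagged=flagged,
    )


def _bootstrap_ks(x: np.ndarray, fitted: DistFit, n_bootstrap: int, seed: int) -> float:
    """Parametric-bootstrap KS p-value (add-one rule)."""
    frozen = fitted.frozen()
    observed = stats.kstest(x, frozen.cdf).statistic
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_bootstrap):
        sample = frozen.rvs(size=x.size, random_state=rng)
        refit = _fit_lognormal(np.sort(sample)) if fitted.family == "lognormal" else _fit_weibull3(np.sort(sample))
        stat = stats.kstest(sample, refit.frozen().cdf).statistic
        if stat >= observed:
            exceed += 1
    return (1 + exceed) / (n_bootstrap + 1)
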