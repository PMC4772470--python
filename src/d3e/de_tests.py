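"""Two-sample tests on per-gene count vectors.

Three tests share the null hypothesis that both samples are drawn from the
same distribution: the Cramér-von Mises criterion (rank-based, sensitive to
the whole shape of the ECDF difference), the two-sample Kolmogorov-Smirnov
test, and a parametric likelihood-ratio test under the Poisson-Beta bursting
model with a Monte-Carlo likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .pb_model import PBParams, pb_pmf_mc, _beta_draws

__all__ = [
    "TestResult",
    "cvm_statistic",
    "cvm_pvalue",
    "cvm_test",
    "ks_test",
    "pb_log_likelihood",
    "lr_test",
]

# An N-draw Monte-Carlo pmf estimate of zero only says the probability is
# below ~1/N, so log-likelihoods floor each pmf evaluation at 1/N: surprisal
# beyond the estimator's resolution is not credited to either model.  This
# also keeps the likelihood-ratio null distribution close to its chi-squared
# reference (unbounded surprisal from impossible-under-the-fit counts
# otherwise dominates the statistic's tail).


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n_x: int
    n_y: int


def _checked(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    return x


def cvm_statistic(x, y) -> float:
    """Two-sample Cramér-von Mises criterion T.

    With pooled-sample ranks q_i of the ordered first sample and s_j of the
    ordered second sample,

        U = N * sum_i (q_i - i)^2 + M * sum_j (s_j - j)^2
        T = U / (N M (N+M)) - (4 N M + 1) / (6 (N+M)).

    Tied values (pervasive for counts) receive midranks in the pooled
    ranking.  Symmetric in the two samples.
    """
    x, y = _checked(x), _checked(y)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled, method="average")
    q = np.sort(ranks[:n])
    s = np.sort(ranks[n:])
    i = np.arange(1, n + 1)
    j = np.arange(1, m + 1)
    u = n * np.sum((q - i) ** 2) + m * np.sum((s - j) ** 2)
    return float(u / (n * m * (n + m)) - (4.0 * n * m + 1.0) / (6.0 * (n + m)))


_CVM_TRUNCATION = 12.0
_CVM_TERMS = 100


def cvm_pvalue(t: float) -> float:
    """Asymptotic p-value of the Cramér-von Mises criterion.

    One minus the 100-term partial sum of the limiting-distribution series
    (binomial-coefficient weights and the modified Bessel function K_{1/4}).
    For T > 12 the series is numerically exhausted and the p-value is set to
    exactly 0; for T at or below the support minimum the p-value is 1.  The
    result is clamped to [0, 1].
    """
    if not np.isfinite(t):
        raise ValueError("T must be finite")
    if t > _CVM_TRUNCATION:
        return 0.0
    if t <= 0:
        return 1.0
    j = np.arange(_CVM_TERMS)
    # (-1)^j * C(-1/2, j) = Gamma(j + 1/2) / (Gamma(1/2) j!)
    log_coef = special.gammaln(j + 0.5) - special.gammaln(0.5) - special.gammaln(j + 1)
    z = (4 * j + 1) ** 2 / (16.0 * t)
    # exp(-z) K_{1/4}(z) = exp(-2z) * kve(1/4, z), stable for large z
    with np.errstate(over="ignore", under="ignore"):
        terms = np.exp(log_coef + 0.5 * np.log(4 * j + 1) - 2.0 * z) * special.kve(0.25, z)
    cdf = np.nansum(terms) / (math.pi * math.sqrt(t))
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def cvm_test(x, y) -> TestResult:
    """Cramér-von Mises two-sample test (statistic + asymptotic series p-value)."""
    t = cvm_statistic(x, y)
    return TestResult(t, cvm_pvalue(t), "cvm", len(np.ravel(x)), len(np.ravel(y)))


def ks_test(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test with the asymptotic p-value."""
    x, y = _checked(x), _checked(y)
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue), "ks", len(x), len(y))


def pb_log_likelihood(
    x,
    params: PBParams,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    c_draws: np.ndarray | None = None,
) -> float:
    """Monte-Carlo Poisson-Beta log-likelihood of a count vector.

    Uses one shared set of Beta draws for every observation, so the value is
    deterministic given the seed and additive over concatenated samples.
    Counts are rounded half-to-even (normalised data are real-valued); each
    pmf evaluation is floored at 1/N, the resolution of the N-draw estimate.
    """
    x = np.rint(_checked(x)).astype(np.int64)
    if np.any(x < 0):
        raise ValueError("negative counts")
    if c_draws is None:
        c_draws = _beta_draws(params, n_draws, seed)
    vals, counts = np.unique(x, return_counts=True)
    pm = pb_pmf_mc(params, vals, c_draws=c_draws)
    floor = 1.0 / max(len(c_draws), 2)
    return float(np.sum(counts * np.log(np.maximum(pm, floor))))


def lr_test(
    x_test,
    params_control: PBParams,
    params_test: PBParams,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
    df: int = 6,
) -> TestResult:
    """Likelihood-ratio test of the test-condition counts under the two fits.

    D = 2 (l(x | params_test) - l(x | params_control)), floored at 0, referred
    to a chi-squared distribution with ``df`` degrees of freedom.

    Under the null the statistic is the sum of an overfitting term (the test
    parameters were estimated on x_test itself) and an out-of-sample misfit
    term (the control parameters come from an independent, equally sized
    sample), each asymptotically chi-squared with 3 degrees of freedom —
    hence the default df of 6.

    The two Monte-Carlo likelihoods use common random numbers: one shared set
    of uniforms mapped through each parameter set's Beta quantile function,
    so most of the MC noise cancels in the difference.
    """
    x_test = _checked(x_test)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n_draws)
    ll = []
    for par in (params_control, params_test):
        c = special.betaincinv(par.alpha, par.beta, u)
        ll.append(pb_log_likelihood(x_test, par, c_draws=np.clip(c, 0.0, 1.0)))
    d = max(0.0, 2.0 * (ll[1] - ll[0]))
    p = float(stats.chi2.sf(d, df))
    return TestResult(d, p, "lr", len(x_test), len(x_test))
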