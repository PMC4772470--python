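"""Poisson-Beta parameter estimation: moments matching and Bayesian inference.

Moments matching inverts the first three factorial moments of the mixture in
closed form — fast, but degenerate whenever the sample looks Poisson (the
successive moment ratios r1, r2, r3 coincide) and prone to infeasible
(non-positive) estimates at small sample sizes.

The Bayesian route places independent Gamma(shape=1, scale) priors on
(alpha, beta, gamma) — scale 100 for the switching rates and scale max(x)
for the transcription rate — augments each cell with its latent promoter
activity c_i in (0, 1), and runs a blocked Gibbs sampler whose conditionals

    c_i     ~ Beta(c_i | alpha, beta) * Poisson(x_i | c_i gamma)
    alpha   ~ Gamma(alpha | 1, 100)  * prod_i Beta(c_i | alpha, beta)
    beta    ~ Gamma(beta  | 1, 100)  * prod_i Beta(c_i | alpha, beta)
    gamma   ~ Gamma(gamma | 1, max x) * prod_i Poisson(x_i | c_i gamma)

are each updated by univariate slice sampling (step-out with doubling,
shrinkage), on the log scale for the rates and the logit scale for the
activities.  The per-cell updates are conditionally independent and run
vectorised across cells.

`PoissonBetaModel` wraps both routes in a model/results pair: build the model
from a count vector, call ``fit``, read estimates and a ``summary()`` off the
results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .pb_model import PBParams, derived_quantities, pb_moments

__all__ = [
    "MomentDegeneracyError",
    "InfeasibleMomentsError",
    "PosteriorSamples",
    "factorial_moments",
    "moment_ratios",
    "estimate_mom",
    "mom_from_ratios",
    "estimate_bayes",
    "point_estimate",
    "PoissonBetaModel",
    "PoissonBetaResults",
]


class MomentDegeneracyError(ValueError):
    """Moment ratios are degenerate (Poisson-like sample or zero moment)."""


class InfeasibleMomentsError(ValueError):
    """Moment inversion produced a non-positive parameter estimate."""


def _as_counts(x) -> np.ndarray:
    """Round half-to-even to integers (normalised counts are real-valued)."""
    x = np.rint(np.asarray(x, dtype=float)).astype(np.int64).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(x < 0):
        raise ValueError("negative counts")
    return x


def factorial_moments(x, order: int = 3) -> tuple[float, ...]:
    """Sample factorial moments e_i = mean of X(X-1)...(X-i+1), i = 1..order."""
    if not 1 <= order <= 3:
        raise ValueError("order must be 1, 2 or 3")
    x = _as_counts(x).astype(float)
    out = []
    ff = x.copy()
    for i in range(order):
        if i:
            ff *= x - i
        out.append(float(ff.mean()))
    return tuple(out)


def moment_ratios(x) -> tuple[float, float, float]:
    """Successive ratios r_i = e_i / e_{i-1} (e_0 = 1) of the factorial moments."""
    e1, e2, e3 = factorial_moments(x, 3)
    if e1 == 0 or e2 == 0:
        raise MomentDegeneracyError("zero factorial moment; ratios undefined")
    return e1, e2 / e1, e3 / e2


_DEGENERATE_RTOL = 1e-12


def mom_from_ratios(r1: float, r2: float, r3: float) -> PBParams:
    """Invert the moment-ratio equations to (alpha, beta, gamma).

        alpha = 2 r1 (r3 - r2) / (r1 r2 - 2 r1 r3 + r2 r3)
        beta  = 2 (r2 - r1)(r1 - r3)(r3 - r2) / ((r1 r2 - 2 r1 r3 + r2 r3)(r1 - 2 r2 + r3))
        gamma = (-r1 r2 + 2 r1 r3 - r2 r3) / (r1 - 2 r2 + r3)

    Both denominators vanish in the Poisson limit r1 = r2 = r3, where the
    three parameters are not identifiable.
    """
    den1 = r1 * r2 - 2 * r1 * r3 + r2 * r3
    den2 = r1 - 2 * r2 + r3
    scale = max(abs(r1), abs(r2), abs(r3), 1.0)
    if abs(den1) < _DEGENERATE_RTOL * scale**2 or abs(den2) < _DEGENERATE_RTOL * scale:
        raise MomentDegeneracyError(
            "moment ratios are Poisson-degenerate; parameters not identifiable"
        )
    alpha = 2 * r1 * (r3 - r2) / den1
    beta = 2 * (r2 - r1) * (r1 - r3) * (r3 - r2) / (den1 * den2)
    gamma = -den1 / den2
    if not all(np.isfinite(v) and v > 0 for v in (alpha, beta, gamma)):
        raise InfeasibleMomentsError(
            f"moment inversion gave infeasible estimates ({alpha:.4g}, {beta:.4g}, {gamma:.4g})"
        )
    return PBParams(alpha, beta, gamma)


def estimate_mom(x) -> PBParams:
    """Method-of-moments fit of (alpha, beta, gamma) to a count vector."""
    return mom_from_ratios(*moment_ratios(x))


def plausible_fit(fit: PBParams, x) -> bool:
    """Can the fitted distribution plausibly generate its own sample?

    Counts are Poisson(c*gamma) with activity c <= 1, so the largest
    observed count should not exceed a generous Poisson upper envelope of
    gamma-hat.  Moment fits occasionally invert to a tiny gamma with an
    extreme duty cycle; those assign essentially zero probability to the
    data and wreck downstream likelihood ratios.
    """
    mx = float(np.max(np.rint(np.asarray(x, dtype=float))))
    return mx <= fit.gamma + 4.0 * np.sqrt(fit.gamma) + 3.0


# ---------------------------------------------------------------------------
# Slice sampling


def _slice_update(logf, x0: np.ndarray, rng: np.random.Generator, w=1.0,
                  max_steps: int = 200) -> np.ndarray:
    """One vectorised slice-sampling update of independent coordinates.

    ``logf`` maps an array like ``x0`` to elementwise log densities.  Each
    coordinate gets its own slice level, a step-out interval (initial width
    ``w``, scalar or per-coordinate, expanded in steps of ``w`` until both
    ends leave the slice) and a shrinkage loop.  Choosing ``w`` near the
    conditional's scale keeps the step-out short; any positive ``w`` leaves
    the update exact.
    """
    x0 = np.asarray(x0, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), x0.shape)
    logf = _finite_logf(logf)
    f0 = logf(x0)
    level = f0 - rng.exponential(size=x0.shape)
    left = x0 - w * rng.random(size=x0.shape)
    right = left + w
    for _ in range(max_steps):
        grow = logf(left) > level
        if not grow.any():
            break
        left = np.where(grow, left - w, left)
    for _ in range(max_steps):
        grow = logf(right) > level
        if not grow.any():
            break
        right = np.where(grow, right + w, right)
    x1 = x0.copy()
    active = np.ones(x0.shape, dtype=bool)
    for _ in range(max_steps):
        prop = left + rng.random(size=x0.shape) * (right - left)
        ok = logf(prop) >= level
        accept = active & ok
        x1 = np.where(accept, prop, x1)
        active &= ~ok
        if not active.any():
            break
        shrink_left = active & (prop < x0)
        left = np.where(shrink_left, prop, left)
        right = np.where(active & ~shrink_left, prop, right)
    return x1


@dataclass
class PosteriorSamples:
    """Kept draws of (alpha, beta, gamma) and the final latent activities."""

    draws: np.ndarray  # (n_kept, 3)
    latent_c: np.ndarray  # (n_cells,), final state
    n_burnin: int
    n_kept: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != 3:
            raise ValueError("draws must be (n_kept, 3)")
        if self.n_kept != len(self.draws):
            raise ValueError("n_kept must equal len(draws)")

    @property
    def alpha(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def beta(self) -> np.ndarray:
        return self.draws[:, 1]

    @property
    def gamma(self) -> np.ndarray:
        return self.draws[:, 2]


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _finite_logf(f):
    """Evaluate a log density, mapping overflow/NaN to -inf (rejected by the slicer)."""

    def wrapped(v):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            out = f(v)
        finite = np.isfinite(out)
        if finite.all():
            return out
        return np.where(finite, out, -np.inf)

    return wrapped


def estimate_bayes(
    x,
    n_iter: int = 3000,
    n_burnin: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    theta_alpha: float = 100.0,
    theta_beta: float = 100.0,
    theta_gamma: float | None = None,
    thin: int = 1,
) -> PosteriorSamples:
    """Blocked Gibbs sampler for the Poisson-Beta posterior.

    Priors are Gamma(shape 1, scale theta); ``theta_gamma`` defaults to
    ``max(x)`` (floored at 1 for an all-zero sample).  Reproducible under
    ``seed``; identical seeds give identical chains.
    """
    x = _as_counts(x)
    if n_iter <= n_burnin or n_burnin < 0:
        raise ValueError("need n_iter > n_burnin >= 0")
    n = len(x)
    xf = x.astype(float)
    if theta_gamma is None:
        theta_gamma = float(max(x.max(), 1))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    # state: log-rates and logit-activities
    alpha, beta = 1.0, 1.0
    gamma = max(float(x.mean()) * 2.0, 1.0)
    z = np.zeros(n)  # logit(c_i), start at c = 1/2

    def logf_z(zv):
        # Beta-Poisson conditional of c_i plus the logit-Jacobian c(1-c),
        # written directly in z via log sigma(z) = -softplus(-z) so the tails
        # stay exact (slopes alpha+x_i on the left, beta on the right) instead
        # of flattening to a clipped plateau
        log_c = -np.logaddexp(0.0, -zv)
        log_1mc = -np.logaddexp(0.0, zv)
        return (alpha + xf) * log_c + beta * log_1mc - gamma * np.exp(log_c)

    draws = np.empty(((n_iter - n_burnin - 1) // thin + 1, 3))
    kept = 0
    for sweep in range(n_iter):
        # logit-scale tail slopes of the c_i conditional: alpha + x_i on the
        # left, beta on the right; match the step-out width to the flattest
        # tail so interval expansion stays short (width only affects cost)
        w_z = min(2.0 + 2.0 / min(alpha, beta, 1.0), 1000.0)
        z = _slice_update(logf_z, z, rng, w=w_z)
        log_c = -np.logaddexp(0.0, -z)
        slc = float(np.sum(log_c))
        sl1c = float(-np.sum(np.logaddexp(0.0, z)))
        sc = float(np.sum(np.exp(log_c)))
        sx = float(np.sum(xf))

        def logf_la(w):
            a = np.exp(w)
            return (
                -a / theta_alpha
                + n * (gammaln(a + beta) - gammaln(a))
                + (a - 1.0) * slc
                + w  # log-scale Jacobian
            )

        alpha = float(np.exp(_slice_update(logf_la, np.array([np.log(alpha)]), rng)[0]))

        def logf_lb(w):
            b = np.exp(w)
            return (
                -b / theta_beta
                + n * (gammaln(alpha + b) - gammaln(b))
                + (b - 1.0) * sl1c
                + w
            )

        beta = float(np.exp(_slice_update(logf_lb, np.array([np.log(beta)]), rng)[0]))

        def logf_lg(w):
            g = np.exp(w)
            return -g / theta_gamma + sx * w - g * sc + w

        gamma = float(np.exp(_slice_update(logf_lg, np.array([np.log(gamma)]), rng)[0]))

        if sweep >= n_burnin and (sweep - n_burnin) % thin == 0:
            draws[kept] = (alpha, beta, gamma)
            kept += 1
    return PosteriorSamples(
        draws=draws[:kept],
        latent_c=_sigmoid(z),
        n_burnin=n_burnin,
        n_kept=kept,
        seed=seed if isinstance(seed, int) else None,
    )


def point_estimate(post: PosteriorSamples, statistic: str = "median") -> PBParams:
    """Posterior point estimate (per-parameter median by default, mean optional)."""
    if post.n_kept < 1:
        raise ValueError("no posterior draws")
    if statistic == "median":
        a, b, g = np.median(post.draws, axis=0)
    elif statistic == "mean":
        a, b, g = np.mean(post.draws, axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return PBParams(float(a), float(b), float(g))


# ---------------------------------------------------------------------------
# Model / Results surface


class PoissonBetaModel:
    """Poisson-Beta bursting model for one gene's count vector.

    Examples
    --------
    >>> res = PoissonBetaModel([0, 3, 17, 0, 9]).fit(method="moments")
    >>> res.params.alpha  # doctest: +SKIP
    """

    def __init__(self, endog) -> None:
        self.endog = _as_counts(endog)

    @classmethod
    def from_dataframe(cls, frame, gene: str, cells=None) -> "PoissonBetaModel":
        row = frame.loc[gene]
        if cells is not None:
            row = row[cells]
        return cls(row.to_numpy())

    def fit(
        self,
        method: str = "moments",
        seed: int | None = None,
        **kwargs,
    ) -> "PoissonBetaResults":
        if method in ("moments", "mom"):
            params = estimate_mom(self.endog)
            return PoissonBetaResults(self, params, method="moments")
        if method in ("bayes", "bayesian"):
            post = estimate_bayes(self.endog, seed=seed, **kwargs)
            return PoissonBetaResults(self, point_estimate(post), method="bayes", posterior=post)
        raise ValueError(f"unknown method {method!r}")


@dataclass
class PoissonBetaResults:
    model: PoissonBetaModel
    params: PBParams
    method: str
    posterior: PosteriorSamples | None = field(default=None)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Posterior credible intervals (Bayesian fits only), rows (alpha, beta, gamma)."""
        if self.posterior is None:
            raise ValueError("confidence intervals require a Bayesian fit")
        lo = (1.0 - level) / 2.0
        return np.quantile(self.posterior.draws, [lo, 1.0 - lo], axis=0).T

    @property
    def derived(self):
        return derived_quantities(self.params)

    def summary(self) -> str:
        p = self.params
        d = self.derived
        m = pb_moments(p)
        lines = [
            "Poisson-Beta bursting model fit",
            f"  method: {self.method}   n_cells: {len(self.model.endog)}",
            f"  alpha = {p.alpha:.5g}   beta = {p.beta:.5g}   gamma = {p.gamma:.5g}",
        ]
        if self.posterior is not None:
            ci = self.conf_int()
            for name, row in zip(("alpha", "beta", "gamma"), ci):
                lines.append(f"    {name} 95% CI: [{row[0]:.4g}, {row[1]:.4g}]")
        lines += [
            f"  duty cycle = {d.duty_cycle:.4g}   burst size = {d.burst_size:.4g}",
            f"  burst frequency = {d.burst_frequency:.4g} (units of lambda)",
            f"  mean = {m.mean:.4g}   variance = {m.variance:.4g}   CV = {d.cv:.4g}",
        ]
        return "\n".join(lines)
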