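"""Two-state (telegraph) transcriptional bursting model and its Poisson-Beta
stationary distribution.

The model: a promoter switches from inactive to active at rate ``alpha`` and
back at rate ``beta``; while active, transcripts are produced at rate
``gamma``; every transcript degrades at rate ``lambda``.  At stationarity the
transcript count follows a Poisson-Beta mixture,

    n ~ Poisson(gamma * x / lambda),   x ~ Beta(alpha / lambda, beta / lambda),

so only the ratios of the kinetic rates to the degradation rate are
identifiable from a snapshot of counts.  Fits therefore report rates at
``lambda_rate = 1`` (in units of the degradation rate); a measured
degradation rate can be attached afterwards with ``PBParams.rescaled_to`` to
put time-dependent quantities (burst frequency in real time, the
autocorrelation time) into physical units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "PBParams",
    "PBMoments",
    "DerivedQuantities",
    "sample_pb",
    "pb_pmf_mc",
    "pb_pmf_analytic",
    "pb_moments",
    "derived_quantities",
    "spectral_density",
    "autocorrelation",
    "autocorrelation_time",
    "gillespie_trajectory",
    "empirical_autocorrelation_time",
]


@dataclass(frozen=True)
class PBParams:
    """Bursting-model parameters, all strictly positive.

    ``alpha``, ``beta``, ``gamma`` and ``lambda_rate`` are absolute rates
    sharing one time unit; the stationary count distribution depends only on
    the ratios alpha/lambda, beta/lambda, gamma/lambda.  With the default
    ``lambda_rate = 1`` the three rates are read in units of the degradation
    rate, which is how fits from snapshot data are reported.
    """

    alpha: float
    beta: float
    gamma: float
    lambda_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "lambda_rate"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def rescaled_to(self, lambda_rate: float) -> "PBParams":
        """Re-express the same system at a different absolute degradation rate.

        Fits from snapshot data identify the rates only up to the time unit
        (they are reported at ``lambda_rate = 1``); attaching a measured
        degradation rate is a pure rescaling of all four rates, which leaves
        every dimensionless quantity unchanged and scales times by 1/r.
        """
        r = lambda_rate / self.lambda_rate
        return PBParams(self.alpha * r, self.beta * r, self.gamma * r, lambda_rate)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class PBMoments:
    """Mean, variance and the first three factorial moments e_i = E[X(X-1)...(X-i+1)]."""

    mean: float
    variance: float
    e1: float
    e2: float
    e3: float


@dataclass(frozen=True)
class DerivedQuantities:
    """Biologically interpretable re-parameterisation of (alpha, beta, gamma).

    duty_cycle      alpha/(alpha+beta), fraction of time the promoter is active
    burst_size      gamma/beta, mean transcripts per active period
    burst_frequency rate of burst initiations at stationarity (units of lambda)
    mean_expression gamma*alpha/(alpha+beta)
    cv              std/mean of the stationary count distribution
    tau_c           autocorrelation time in absolute time units (None when the
                    degradation rate is not meaningful/supplied)
    """

    duty_cycle: float
    burst_size: float
    burst_frequency: float
    mean_expression: float
    cv: float
    tau_c: float | None = field(default=None)


def sample_pb(
    params: PBParams,
    n_cells: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n_cells`` stationary transcript counts.

    Each draw is ``x ~ Poisson(c * gamma)`` with promoter activity
    ``c ~ Beta(alpha, beta)``.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lam = params.lambda_rate
    c = rng.beta(params.alpha / lam, params.beta / lam, size=n_cells)
    return rng.poisson(c * params.gamma / lam).astype(np.int64)


def _beta_draws(params: PBParams, n_draws: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.beta(params.alpha / params.lambda_rate,
                    params.beta / params.lambda_rate, size=n_draws)


def pb_pmf_mc(
    params: PBParams,
    n,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    c_draws: np.ndarray | None = None,
) -> np.ndarray | float:
    """Monte-Carlo Poisson-Beta pmf.

    Rao-Blackwellised estimate ``(1/N) * sum_k Poisson(n | gamma*c_k)`` with
    ``c_k ~ Beta(alpha, beta)``.  A single shared set of Beta draws evaluates
    the pmf at every ``n`` (pass ``c_draws`` to reuse draws across calls, e.g.
    for a deterministic likelihood within one test), so the estimates at
    different ``n`` sum to one up to truncation.
    """
    if c_draws is None:
        c_draws = _beta_draws(params, n_draws, seed)
    n_arr = np.atleast_1d(np.asarray(n))
    rate = params.gamma / params.lambda_rate
    pm = stats.poisson.pmf(n_arr[:, None], rate * c_draws[None, :]).mean(axis=1)
    return float(pm[0]) if np.isscalar(n) else pm


_HYP1F1_OVERFLOW = 1e280


def _pmf_analytic_one(n: int, a: float, b: float, g: float) -> float:
    # log of  g^n e^-g  B(a+n, b) / (B(a, b) n!)
    logc = (
        n * math.log(g)
        - g
        + special.gammaln(a + n)
        + special.gammaln(a + b)
        - special.gammaln(a)
        - special.gammaln(a + b + n)
        - special.gammaln(n + 1)
    )
    h = special.hyp1f1(b, a + b + n, g)
    if np.isfinite(h) and 0 < h < _HYP1F1_OVERFLOW:
        return float(math.exp(logc + math.log(h)))
    # scipy's 1F1 loses accuracy / overflows for a large third argument; fall
    # back to arbitrary precision.
    import mpmath

    with mpmath.workdps(40):
        h = mpmath.hyp1f1(b, a + b + n, g)
        if h <= 0:
            raise FloatingPointError(
                f"Poisson-Beta pmf evaluation failed at n={n}, params=({a},{b},{g})"
            )
        return float(mpmath.e ** (logc + mpmath.log(h)))


def pb_pmf_analytic(params: PBParams, n) -> np.ndarray | float:
    """Exact stationary pmf of the bursting model.

    ``P(n) = g^n e^-g Γ(a+n)Γ(a+b) / (n! Γ(a+b+n) Γ(a)) · ₁F₁(b; a+b+n; g)``
    evaluated in log space, with an arbitrary-precision fallback when the
    confluent hypergeometric overflows double precision.
    """
    lam = params.lambda_rate
    a, b, g = params.alpha / lam, params.beta / lam, params.gamma / lam
    n_arr = np.atleast_1d(np.asarray(n))
    if np.any(n_arr < 0) or np.any(n_arr != np.floor(n_arr)):
        raise ValueError("n must be a nonnegative integer")
    out = np.array([_pmf_analytic_one(int(k), a, b, g) for k in n_arr])
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if np.isscalar(n) else out


def pb_moments(params: PBParams) -> PBMoments:
    """Analytic factorial moments of the mixture.

    ``e_i = gamma^i * prod_{j<i} (alpha+j)/(alpha+beta+j)``; the mean is e1 and
    the variance ``e2 + e1 - e1^2`` (always >= mean: a Poisson mixture is
    over-dispersed).
    """
    lam = params.lambda_rate
    a, b, g = params.alpha / lam, params.beta / lam, params.gamma / lam
    e = []
    prod = 1.0
    for i in range(3):
        prod *= (a + i) / (a + b + i)
        e.append(g ** (i + 1) * prod)
    e1, e2, e3 = e
    return PBMoments(mean=e1, variance=e2 + e1 - e1 * e1, e1=e1, e2=e2, e3=e3)


def derived_quantities(
    params: PBParams,
    *,
    burst_frequency_convention: str = "stationary",
    with_tau_c: bool = True,
) -> DerivedQuantities:
    """Map (alpha, beta, gamma) to duty cycle, burst size/frequency, mean, CV, tau_c.

    ``burst_frequency_convention``: "stationary" gives alpha*beta/(alpha+beta),
    the rate of burst initiations at stationarity; "alpha" gives the bursty-limit
    approximation f = alpha (valid when beta >> alpha).  The burst frequency
    and tau_c are absolute rates/times; everything else is dimensionless.
    """
    a, b, g = params.alpha, params.beta, params.gamma
    if burst_frequency_convention == "stationary":
        freq = a * b / (a + b)
    elif burst_frequency_convention == "alpha":
        freq = a
    else:
        raise ValueError(f"unknown burst frequency convention {burst_frequency_convention!r}")
    m = pb_moments(params)
    tau = autocorrelation_time(params) if with_tau_c else None
    return DerivedQuantities(
        duty_cycle=a / (a + b),
        burst_size=g / b,
        burst_frequency=freq,
        mean_expression=g * a / ((a + b) * params.lambda_rate),
        cv=math.sqrt(m.variance) / m.mean,
        tau_c=tau,
    )


_SINGULAR_RTOL = 1e-6


def _sr_terms(params: PBParams):
    """Common pieces of the spectral density / autocovariance.

    Both are two-Lorentzian / two-exponential forms in the degradation rate
    lambda and the switching rate k = alpha + beta, with a burst contribution
    B = d*beta*gamma^2 / (k^2 - lambda^2) where d = alpha/k is the duty
    cycle.  (The weight d*beta*gamma^2 = d(1-d)*k*gamma^2 follows from the
    regression theorem applied to the promoter covariance d(1-d)e^{-k|t|};
    it also makes R(0) equal the stationary Poisson-Beta variance, as it
    must.)  The closed form has a removable singularity at k == lambda,
    which is guarded.
    """
    a, b, g, lam = params.alpha, params.beta, params.gamma, params.lambda_rate
    k = a + b
    d = a / k
    if abs(k - lam) < _SINGULAR_RTOL * lam:
        raise ValueError(
            "spectral density is written with a removable singularity at "
            f"alpha+beta == lambda (got alpha+beta={k}, lambda={lam}); perturb "
            "the parameters or evaluate the limit explicitly"
        )
    burst = d * b * g * g / (k * k - lam * lam)
    return g, lam, k, d, burst


def spectral_density(params: PBParams, omega: float) -> float:
    """Power spectral density S(omega) of the transcript count at stationarity."""
    g, lam, k, d, burst = _sr_terms(params)
    return 2.0 / (lam * lam + omega * omega) * (d * g + burst) - 2.0 / (
        k * k + omega * omega
    ) * burst


def autocorrelation(params: PBParams, t: float) -> float:
    """Stationary autocovariance R(t) (inverse Fourier transform of S); even in t."""
    g, lam, k, d, burst = _sr_terms(params)
    at = abs(t)
    return math.exp(-lam * at) * (d * g + burst) / lam - math.exp(-k * at) * burst / k


def autocorrelation_time(params: PBParams) -> float:
    """Characteristic fluctuation timescale tau_c = S(0) / (2 R(0))."""
    r0 = autocorrelation(params, 0.0)
    if r0 <= 0:
        raise ValueError("autocorrelation at lag 0 must be positive")
    return spectral_density(params, 0.0) / (2.0 * r0)


def gillespie_trajectory(
    params: PBParams,
    t_max: float,
    seed: int | np.random.Generator | None = None,
    *,
    t_burnin: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact stochastic simulation of the two-state model.

    Events: promoter activation (rate alpha*lambda when off), inactivation
    (beta*lambda when on), transcription (gamma*lambda when on), degradation
    (n*lambda).  Returns event times (starting at 0 after ``t_burnin``) and the
    transcript count on [t_i, t_{i+1}).  Used as an independent simulation
    oracle for the analytic autocorrelation.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lam = params.lambda_rate
    a, b, g = params.alpha, params.beta, params.gamma
    d = a / (a + b)
    on = rng.random() < d
    n = int(rng.poisson(g * d / lam))

    def step(t: float) -> float:
        nonlocal on, n
        r_switch = a if not on else b
        r_prod = g if on else 0.0
        total = r_switch + r_prod + n * lam
        t += rng.exponential(1.0 / total)
        u = rng.random() * total
        if u < r_switch:
            on = not on
        elif u < r_switch + r_prod:
            n += 1
        else:
            n -= 1
        return t

    t = -t_burnin
    rec_t = [t]
    rec_n = [n]
    while t < t_max:
        t = step(t)
        rec_t.append(t)
        rec_n.append(n)
    rec_t_arr = np.asarray(rec_t)
    rec_n_arr = np.asarray(rec_n, dtype=np.int64)
    # clip the record to [0, t_max]; state at time 0 is the state set by the
    # last event before 0
    i0 = int(np.searchsorted(rec_t_arr, 0.0, side="right")) - 1
    times = np.concatenate(([0.0], rec_t_arr[i0 + 1 :]))
    counts = rec_n_arr[i0:]
    keep = times <= t_max
    return times[keep], counts[keep]


def empirical_autocorrelation_time(
    times: np.ndarray,
    counts: np.ndarray,
    dt: float = 0.05,
    max_lag: float = 8.0,
) -> float:
    """Autocorrelation time of a piecewise-constant trajectory.

    Samples the trajectory on a uniform grid of spacing ``dt``, estimates the
    autocovariance by FFT up to ``max_lag``, and returns the trapezoidal
    integral of R(t)/R(0) over [0, max_lag] — the empirical counterpart of
    S(0)/(2 R(0)).
    """
    grid = np.arange(times[0], times[-1], dt)
    idx = np.searchsorted(times, grid, side="right") - 1
    v = counts[idx].astype(float)
    v -= v.mean()
    n = len(v)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(v, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: int(max_lag / dt)]
    acov /= np.arange(n, n - len(acov), -1)  # unbiased normalisation
    if acov[0] <= 0:
        raise ValueError("degenerate trajectory (zero variance)")
    r = acov / acov[0]
    return float(np.trapezoid(r, dx=dt))
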