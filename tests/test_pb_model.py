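import numpy as np
import pytest
from scipy import integrate, stats

from d3e.pb_model import (
    PBParams,
    autocorrelation,
    autocorrelation_time,
    derived_quantities,
    empirical_autocorrelation_time,
    gillespie_trajectory,
    pb_moments,
    pb_pmf_analytic,
    pb_pmf_mc,
    sample_pb,
    spectral_density,
)

GRID = [
    PBParams(0.1, 0.5, 20),
    PBParams(1.0, 10.0, 100.0),
    PBParams(0.01, 1.0, 5.0),
    PBParams(2.0, 2.0, 50.0),
]


class TestParams:
    @pytest.mark.parametrize("bad", [dict(alpha=0), dict(beta=-1), dict(gamma=np.nan)])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(alpha=1.0, beta=1.0, gamma=10.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            PBParams(**kw)


class TestSampling:
    def test_poisson_limit_mean(self, rng):
        x = sample_pb(PBParams(1e6, 1.0, 5.0), 100_000, rng)
        assert abs(x.mean() - 5.0) < 0.05

    def test_mixture_mean(self, rng):
        x = sample_pb(PBParams(1.0, 1.0, 10.0), 100_000, rng)
        assert abs(x.mean() - 5.0) < 0.1

    def test_seed_reproducibility_and_bad_n(self):
        np.testing.assert_array_equal(
            sample_pb(GRID[0], 20, seed=5), sample_pb(GRID[0], 20, seed=5)
        )
        with pytest.raises(ValueError):
            sample_pb(GRID[0], 0, seed=1)


class TestPmf:
    @pytest.mark.parametrize("params", GRID, ids=str)
    def test_analytic_pmf_matches_quadrature(self, params):
        ns = np.arange(0, 60)
        exact = pb_pmf_analytic(params, ns)
        quad = [
            integrate.quad(
                lambda x: stats.poisson.pmf(n, params.gamma * x)
                * stats.beta.pdf(x, params.alpha, params.beta),
                0, 1, limit=200,
            )[0]
            for n in ns
        ]
        np.testing.assert_allclose(exact, quad, atol=1e-8)

    def test_analytic_pmf_normalises(self):
        params = PBParams(1.0, 10.0, 100.0)
        total = np.sum(pb_pmf_analytic(params, np.arange(0, 400)))
        assert abs(total - 1.0) < 1e-6

    def test_poisson_limit_at_zero(self):
        assert abs(pb_pmf_analytic(PBParams(1e6, 1.0, 5.0), 0) - np.exp(-5)) < 1e-4
        assert abs(pb_pmf_mc(PBParams(1e6, 1.0, 5.0), 0, 2000, seed=0) - np.exp(-5)) < 1e-3

    def test_mc_pmf_normalises_with_shared_draws(self, rng):
        params = PBParams(0.1, 0.5, 20.0)
        pm = pb_pmf_mc(params, np.arange(0, 200), 1000, rng)
        assert abs(pm.sum() - 1.0) < 1e-6  # shared draws: exact up to truncation

    def test_mc_pmf_within_3se_of_analytic(self):
        params = PBParams(0.1, 0.5, 20.0)
        ns = np.arange(0, 51)
        n_draws = 2000
        rng = np.random.default_rng(7)
        c = rng.beta(params.alpha, params.beta, n_draws)
        mc = pb_pmf_mc(params, ns, c_draws=c)
        per_draw = stats.poisson.pmf(ns[:, None], params.gamma * c[None, :])
        se = per_draw.std(axis=1, ddof=1) / np.sqrt(n_draws)
        exact = pb_pmf_analytic(params, ns)
        assert np.all(np.abs(mc - exact) <= 3 * se + 1e-12)

    def test_large_gamma_falls_back_to_high_precision(self):
        # scipy's hyp1f1 overflows around here; the pmf must still normalise
        params = PBParams(0.5, 0.5, 900.0)
        pm = pb_pmf_analytic(params, np.arange(0, 1400, 7))
        assert np.all((pm >= 0) & (pm <= 1))


class TestMoments:
    def test_exact_factorial_moments(self):
        m = pb_moments(PBParams(1.0, 1.0, 10.0))
        assert m.e1 == pytest.approx(5.0)
        assert m.e2 == pytest.approx(100.0 / 3.0)
        assert m.e3 == pytest.approx(250.0)
        assert m.mean == m.e1
        assert m.variance == pytest.approx(m.e2 + m.e1 - m.e1**2)

    @pytest.mark.parametrize("params", GRID, ids=str)
    def test_overdispersion_and_sample_agreement(self, params, rng):
        m = pb_moments(params)
        assert m.variance >= m.mean
        x = sample_pb(params, 200_000, rng)
        assert abs(x.mean() - m.mean) < 5 * np.sqrt(m.variance / 200_000) + 1e-9

    def test_moments_match_analytic_pmf(self):
        params = PBParams(0.1, 0.5, 20.0)
        ns = np.arange(0, 400)
        pm = pb_pmf_analytic(params, ns)
        m = pb_moments(params)
        assert np.sum(ns * pm) == pytest.approx(m.mean, rel=1e-8)
        assert np.sum(ns * (ns - 1) * pm) == pytest.approx(m.e2, rel=1e-8)


class TestDerivedQuantities:
    def test_hand_computed_example(self):
        d = derived_quantities(PBParams(1.0, 10.0, 100.0))
        assert d.burst_size == pytest.approx(10.0)
        assert d.duty_cycle == pytest.approx(1.0 / 11.0)
        assert d.mean_expression == pytest.approx(100.0 / 11.0)

    def test_symmetry_and_identities(self):
        d = derived_quantities(PBParams(0.3, 0.3, 7.0))
        assert d.duty_cycle == pytest.approx(0.5)
        for params in GRID:
            d = derived_quantities(params)
            assert d.duty_cycle * params.gamma == pytest.approx(d.mean_expression)

    def test_joint_scaling_homogeneity(self):
        base = PBParams(0.2, 0.6, 30.0)
        scaled = PBParams(0.6, 1.8, 90.0)
        d0, d1 = derived_quantities(base), derived_quantities(scaled)
        assert d1.duty_cycle == pytest.approx(d0.duty_cycle)
        assert d1.burst_size == pytest.approx(d0.burst_size)
        assert d1.burst_frequency == pytest.approx(3 * d0.burst_frequency)

    def test_alpha_convention(self):
        d = derived_quantities(PBParams(0.05, 5.0, 100.0),
                               burst_frequency_convention="alpha")
        assert d.burst_frequency == pytest.approx(0.05)


class TestAutocorrelation:
    PAR = PBParams(1.0, 10.0, 100.0, 1.0)

    def test_spectral_density_even_and_decaying(self):
        s1 = spectral_density(self.PAR, 2.3)
        assert s1 == pytest.approx(spectral_density(self.PAR, -2.3))
        assert spectral_density(self.PAR, 1e4) < 1e-4 * spectral_density(self.PAR, 0.0)

    def test_wiener_khinchin_consistency(self):
        q, _ = integrate.quad(lambda t: autocorrelation(self.PAR, t), -60, 60, limit=400)
        assert spectral_density(self.PAR, 0.0) == pytest.approx(q, rel=1e-6)

    def test_r0_equals_stationary_variance(self):
        m = pb_moments(self.PAR)
        assert autocorrelation(self.PAR, 0.0) == pytest.approx(m.variance, rel=1e-10)

    def test_r_even_and_decaying(self):
        assert autocorrelation(self.PAR, 1.5) == pytest.approx(autocorrelation(self.PAR, -1.5))
        assert autocorrelation(self.PAR, 80.0) < 1e-10

    def test_singular_parameters_raise(self):
        with pytest.raises(ValueError, match="singular"):
            spectral_density(PBParams(0.4, 0.6, 10.0, 1.0), 0.0)

    def test_tau_c_always_on_limit(self):
        # promoter always active: pure birth-death, tau_c -> 1/lambda
        tau = autocorrelation_time(PBParams(5e4, 1.0, 5.0, 2.0))
        assert tau == pytest.approx(1.0 / 2.0, rel=1e-3)

    def test_tau_c_time_rescaling(self):
        base = PBParams(1.0, 10.0, 100.0, 1.0)
        fast = PBParams(3.0, 30.0, 300.0, 3.0)
        assert autocorrelation_time(fast) == pytest.approx(
            autocorrelation_time(base) / 3.0, rel=1e-10
        )

    def test_gillespie_agreement(self):
        tau = autocorrelation_time(self.PAR)
        times, counts = gillespie_trajectory(self.PAR, 8000.0, seed=3, t_burnin=20.0)
        tau_emp = empirical_autocorrelation_time(times, counts)
        assert abs(tau_emp - tau) / tau < 0.15
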