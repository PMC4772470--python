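import numpy as np
import pytest
from scipy import stats

from d3e.estimation import (
    InfeasibleMomentsError,
    MomentDegeneracyError,
    PoissonBetaModel,
    estimate_bayes,
    estimate_mom,
    factorial_moments,
    mom_from_ratios,
    moment_ratios,
    plausible_fit,
    point_estimate,
    PosteriorSamples,
)
from d3e.pb_model import PBParams, pb_moments, sample_pb


class TestFactorialMoments:
    def test_small_hand_example(self):
        assert factorial_moments([2, 2]) == (2.0, 2.0, 0.0)

    def test_all_zero_sample_degenerate(self):
        assert factorial_moments(np.zeros(5)) == (0.0, 0.0, 0.0)
        with pytest.raises(MomentDegeneracyError):
            moment_ratios(np.zeros(5))

    def test_poisson_factorial_moments(self, rng):
        x = rng.poisson(5.0, 100_000)
        e1, e2, e3 = factorial_moments(x)
        assert e1 == pytest.approx(5.0, rel=0.02)
        assert e2 == pytest.approx(25.0, rel=0.05)
        assert e3 == pytest.approx(125.0, rel=0.1)


class TestMomentsMatching:
    @pytest.mark.parametrize(
        "truth,ratios",
        [
            ((1.0, 1.0, 10.0), (5.0, 20.0 / 3.0, 7.5)),
            ((2.0, 2.0, 20.0), (10.0, 12.0, 40.0 / 3.0)),
        ],
    )
    def test_exact_recovery_from_analytic_ratios(self, truth, ratios):
        est = mom_from_ratios(*ratios)
        assert est.as_tuple() == pytest.approx(truth, rel=1e-12)

    def test_analytic_ratios_consistent_with_model_moments(self):
        m = pb_moments(PBParams(1.0, 1.0, 10.0))
        assert (m.e1, m.e2 / m.e1, m.e3 / m.e2) == pytest.approx((5.0, 20.0 / 3.0, 7.5))

    def test_exactness_across_grid(self):
        # inversion of analytic factorial moments is exact to float precision
        for a in np.geomspace(0.01, 1.0, 3):
            for b in np.geomspace(0.1, 10.0, 3):
                for g in np.geomspace(1.0, 100.0, 3):
                    m = pb_moments(PBParams(a, b, g))
                    try:
                        est = mom_from_ratios(m.e1, m.e2 / m.e1, m.e3 / m.e2)
                    except MomentDegeneracyError:
                        continue
                    assert est.as_tuple() == pytest.approx((a, b, g), rel=1e-10)

    def test_poisson_sample_degenerates(self):
        with pytest.raises(MomentDegeneracyError):
            mom_from_ratios(5.0, 5.0, 5.0)

    def test_infeasible_estimates_rejected_not_clipped(self):
        # ratios arranged so the inversion goes negative
        with pytest.raises((InfeasibleMomentsError, MomentDegeneracyError)):
            mom_from_ratios(5.0, 4.0, 3.0)

    def test_plausibility_gate(self):
        fit = PBParams(0.02, 4.0, 20.0)
        assert plausible_fit(fit, np.array([0, 0, 3, 12]))
        assert not plausible_fit(fit, np.array([0, 0, 3, 80]))


class TestGibbsSampler:
    def test_chain_reproducibility(self):
        x = np.array([0, 0, 3, 17, 0, 40, 2, 0, 9, 1] * 3)
        a = estimate_bayes(x, 300, 100, seed=11)
        b = estimate_bayes(x, 300, 100, seed=11)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_support_constraints(self):
        x = np.array([0, 0, 3, 17, 0, 40, 2, 0, 9, 1] * 3)
        post = estimate_bayes(x, 400, 100, seed=3)
        assert np.all(post.draws > 0)
        assert np.all((post.latent_c > 0) & (post.latent_c < 1))
        assert post.n_kept == 300

    def test_all_zero_input_handled(self):
        post = estimate_bayes(np.zeros(20), 200, 50, seed=1)
        assert np.all(np.isfinite(post.draws))

    def test_parameter_recovery(self, rng):
        # scaled-down recovery check; the full 50-replicate study runs in the
        # acceptance suite
        ok = 0
        for _ in range(5):
            x = sample_pb(PBParams(1.0, 10.0, 100.0), 250, rng)
            pe = point_estimate(estimate_bayes(x, 2000, 700, rng))
            ok += all(
                0.5 <= est / true <= 2.0
                for est, true in zip(pe.as_tuple(), (1.0, 10.0, 100.0))
            )
        assert ok >= 3

    def test_simulation_based_calibration(self):
        # draw parameters from the prior, simulate data, run the sampler, and
        # rank the truth within thinned posterior draws: ranks must be uniform
        scales = dict(theta_alpha=2.0, theta_beta=2.0, theta_gamma=30.0)
        n_rep, m_draws = 96, 7
        rng = np.random.default_rng(314)
        ranks = {k: [] for k in ("alpha", "beta", "gamma")}
        for _ in range(n_rep):
            truth = PBParams(
                rng.gamma(1.0, scales["theta_alpha"]),
                rng.gamma(1.0, scales["theta_beta"]),
                rng.gamma(1.0, scales["theta_gamma"]),
            )
            x = sample_pb(truth, 15, rng)
            post = estimate_bayes(x, 330, 100, rng, thin=32, **scales)
            draws = post.draws[:m_draws]
            for j, name in enumerate(("alpha", "beta", "gamma")):
                ranks[name].append(int(np.sum(draws[:, j] < getattr(truth, name))))
        for name, r in ranks.items():
            counts = np.bincount(r, minlength=m_draws + 1)
            p = stats.chisquare(counts).pvalue
            assert p > 0.01, f"{name} SBC ranks not uniform: {counts}"

    def test_point_estimate_conventions(self):
        draws = np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0], [2.0, 3.0, 4.0]])
        post = PosteriorSamples(draws, np.array([0.5]), 0, 3)
        assert point_estimate(post).as_tuple() == (2.0, 3.0, 4.0)
        assert point_estimate(post, "mean").as_tuple() == (2.0, 3.0, 4.0)
        single = PosteriorSamples(draws[:1], np.array([0.5]), 0, 1)
        assert point_estimate(single).as_tuple() == (1.0, 2.0, 3.0)

    def test_cross_estimator_consistency(self, rng):
        x = sample_pb(PBParams(0.5, 0.5, 50.0), 500, rng)
        mom = estimate_mom(x)
        bayes = point_estimate(estimate_bayes(x, 1500, 500, rng))
        for est, ref in zip(bayes.as_tuple(), mom.as_tuple()):
            assert abs(est - ref) / ref < 0.35


class TestModelSurface:
    def test_moments_fit_roundtrip(self, rng):
        x = sample_pb(PBParams(0.5, 0.5, 50.0), 400, rng)
        res = PoissonBetaModel(x).fit(method="moments")
        assert res.method == "moments"
        assert res.params.gamma > 0
        assert "duty cycle" in res.summary()

    def test_bayes_fit_has_posterior_and_ci(self, rng):
        x = sample_pb(PBParams(1.0, 2.0, 30.0), 60, rng)
        res = PoissonBetaModel(x).fit(method="bayes", seed=4, n_iter=400, n_burnin=100)
        ci = res.conf_int()
        assert ci.shape == (3, 2)
        assert np.all(ci[:, 0] <= ci[:, 1])
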