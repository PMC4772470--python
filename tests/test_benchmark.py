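import numpy as np
import pytest

from d3e.benchmark import (
    DropoutConfig,
    PARAM_RANGES,
    apply_dropout,
    draw_triplet,
    dropout_recovery_experiment,
    mean_fixed_variance_experiment,
    null_control_experiment,
    roc_labels,
    sensitivity_matrix,
    sensitivity_score,
)
from d3e.pb_model import PBParams, pb_moments


class TestSensitivityGrid:
    def test_grid_spans_range_endpoints(self):
        m = sensitivity_matrix({"alpha": 0.05, "beta": 0.3}, "gamma", 30, "ks", seed=0)
        lo, hi = PARAM_RANGES["gamma"]
        assert m.grid[0] == pytest.approx(lo) and m.grid[-1] == pytest.approx(hi)
        assert m.p.shape == (10, 10)
        assert np.all((m.p >= 0) & (m.p <= 1))

    def test_diagonal_mostly_null(self):
        rng = np.random.default_rng(5)
        diags = []
        for seed in range(5):
            m = sensitivity_matrix({"alpha": 0.1, "beta": 0.1}, "gamma", 50, "ks", rng)
            diags.extend(np.diag(m.p))
        assert np.mean(np.asarray(diags) > 0.05) >= 0.85

    def test_extreme_gamma_pair_detected(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            m = sensitivity_matrix({"alpha": 0.1, "beta": 0.1}, "gamma", 50, "ks", rng)
            hits += m.p[0, -1] < 0.05  # gamma = 1 vs gamma = 100
        assert hits >= 19

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_matrix({"alpha": 0.1, "beta": 0.1}, "delta", 10, "ks", 0)


class TestSensitivityScore:
    def test_ideal_pattern_scores_one(self):
        p = np.full((10, 10), 0.01)
        np.fill_diagonal(p, 0.5)
        assert sensitivity_score(p) == pytest.approx(1.0)

    def test_all_low_scores_point_nine(self):
        assert sensitivity_score(np.full((10, 10), 0.01)) == pytest.approx(0.9)

    def test_all_high_exceeds_one(self):
        # the printed heuristic is not normalised; an all-high grid scores 1.9
        assert sensitivity_score(np.full((10, 10), 0.5)) == pytest.approx(1.9)

    def test_wrong_shape(self):
        with pytest.raises(ValueError):
            sensitivity_score(np.ones((5, 5)))


class TestNullControl:
    def test_fraction_in_unit_interval_and_a_zero(self):
        f = null_control_experiment(n_pairs=40, seed=2)
        assert 0.0 <= f <= 1.0
        assert null_control_experiment(n_pairs=20, seed=2, a=0.0) == 1.0

    def test_matches_reported_calibration(self):
        # scaled-down version of the 1,000-pair control experiment (~97 %)
        f = null_control_experiment(n_pairs=250, seed=5)
        assert 0.90 <= f <= 1.00


class TestVarianceExperiment:
    def test_scale_one_is_null(self):
        r = mean_fixed_variance_experiment(scale=1.0, n_reps=60, seed=3)
        assert r.median_p > 0.2
        assert r.frac_below_05 <= 0.15

    def test_mean_preserved_analytically(self, rng):
        for _ in range(20):
            base = draw_triplet(rng)
            scaled = PBParams(2 * base.alpha, 2 * base.beta, base.gamma)
            assert pb_moments(scaled).mean == pytest.approx(pb_moments(base).mean)

    def test_detection_improves_with_scale(self):
        r2 = mean_fixed_variance_experiment(scale=2.0, n_reps=60, seed=4)
        r8 = mean_fixed_variance_experiment(scale=8.0, n_reps=60, seed=4)
        assert r8.median_p < r2.median_p


class TestDropout:
    def test_limits(self, rng):
        x = rng.poisson(5.0, 200)
        np.testing.assert_array_equal(apply_dropout(x, 5.0, 1e12, rng), x)
        np.testing.assert_array_equal(apply_dropout(x, 0.0, 10.0, rng), x)

    def test_dropout_rate_matches_formula(self, rng):
        x = np.ones(20000, dtype=int)
        mu, b = 10.0, 100.0  # mu^2 = b -> p = 1 - 1/e
        out = apply_dropout(x, mu, b, rng)
        assert np.mean(out == 0) == pytest.approx(1 - np.exp(-1), abs=0.01)

    def test_oracle_estimator_recovers_exactly(self):
        cfg = DropoutConfig(b=None, n_cells=10, n_triplets=8)
        rep = dropout_recovery_experiment(cfg, seed=0, estimator="oracle")
        for v in rep.gmsre.values():
            assert v < 1e-20
        for c in rep.correlations.values():
            assert c == pytest.approx(1.0)

    def test_mom_report_structure_and_noise_monotonicity(self):
        clean = dropout_recovery_experiment(
            DropoutConfig(b=None, n_cells=50, n_triplets=60), seed=1, estimator="mom"
        )
        noisy = dropout_recovery_experiment(
            DropoutConfig(b=10.0, n_cells=50, n_triplets=60), seed=1, estimator="mom"
        )
        assert set(clean.gmsre) == {"alpha", "beta", "gamma"}
        for c in clean.correlations.values():
            assert -1.0 <= c <= 1.0
        assert noisy.gmsre["gamma"] >= clean.gmsre["gamma"]


class TestRocLabels:
    def test_threshold_logic(self):
        fc = np.array([1.0, 0.25, 1.6, 2.0, 0.6])
        np.testing.assert_array_equal(
            roc_labels(fc, 1.5), [False, True, True, True, True]
        )
        np.testing.assert_array_equal(
            roc_labels(fc, 4.0), [False, True, False, False, False]
        )
        np.testing.assert_array_equal(
            roc_labels(fc, 2.0), [False, True, False, True, False]
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            roc_labels([0.0, 1.0], 2.0)
        with pytest.raises(ValueError):
            roc_labels([1.0], 0.5)
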