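import numpy as np
import pytest

from ealpipe import (
    CandidateSet,
    FitResult,
    ModelSpec,
    NoiseSpec,
    ParameterSpace,
    benchmark_ensemble,
    benchmark_scores,
    build_candidate_set,
    ealpipe_scores,
    select_next,
)
from ealpipe.acquisition import benchmark_pins
from ealpipe.identifiability import ParamCI
from ealpipe.noise import predicted_noise_variance


def _lookup_model(values_by_theta_key):
    """Single-output model whose trajectory is a preset table keyed by theta[0]."""
    def forward(theta, times):
        return np.asarray(values_by_theta_key[float(theta[0])],
                          dtype=float)[None, :len(times)]
    return ModelSpec(id="toy", output_names=("y",),
                     initial_conditions=(0.0,), forward=forward)


def _two_member_set(mle_key, other_key, weights):
    mle = FitResult(np.array([mle_key]), 0.0, True, 1)
    other = FitResult(np.array([other_key]), 0.0, True, 1)
    return CandidateSet(mle=mle, boundary={("p", "upper"): other},
                        weights=np.asarray(weights, dtype=float))


class TestEalpipeScores:
    def test_hand_worked_two_model_value(self):
        # one output, m=2, w=(1/2,1/2), f at x: MLE 1.0, other 1.4; with
        # sigma=0.2 (f/sigma=5) the predicted variance is ~0.04, so the
        # scaled weighted disagreement is 0.5*0.4^2/0.04 = 2.0
        model = _lookup_model({0.0: [1.0], 1.0: [1.4]})
        cs = _two_member_set(0.0, 1.0, [0.5, 0.5])
        sc = ealpipe_scores(cs, model, np.array([1.0]), NoiseSpec(sigma=(0.2,)))
        assert sc.scores[0] == pytest.approx(2.0, rel=1e-4)

    def test_coincident_candidates_score_zero(self):
        model = _lookup_model({0.0: [1.0, 2.0], 1.0: [1.0, 2.0]})
        cs = _two_member_set(0.0, 1.0, [0.7, 0.3])
        sc = ealpipe_scores(cs, model, np.array([1.0, 2.0]),
                            NoiseSpec(sigma=(0.2,)))
        np.testing.assert_array_equal(sc.scores, 0.0)

    def test_noise_scaling_law(self):
        # with truncation negligible, multiplying sigma by 10 shrinks every
        # score ~100-fold
        model = _lookup_model({0.0: [10.0, 12.0], 1.0: [10.5, 12.8]})
        cs = _two_member_set(0.0, 1.0, [0.6, 0.4])
        grid = np.array([1.0, 2.0])
        s1 = ealpipe_scores(cs, model, grid, NoiseSpec(sigma=(0.01,))).scores
        s2 = ealpipe_scores(cs, model, grid, NoiseSpec(sigma=(0.1,))).scores
        np.testing.assert_allclose(s1 / s2, 100.0, rtol=1e-10)

    def test_uniform_two_member_closed_form(self):
        # w = (1/2, 1/2): score is half the squared, noise-scaled gap
        model = _lookup_model({0.0: [2.0, 3.0], 1.0: [2.5, 3.1]})
        cs = _two_member_set(0.0, 1.0, [0.5, 0.5])
        grid = np.array([1.0, 2.0])
        noise = NoiseSpec(sigma=(0.3,))
        sc = ealpipe_scores(cs, model, grid, noise)
        gap2 = np.array([(2.5 - 2.0) ** 2, (3.1 - 3.0) ** 2])
        var = predicted_noise_variance(np.array([2.0, 3.0]), 0.3)
        np.testing.assert_allclose(sc.scores, 0.5 * gap2 / var, rtol=1e-12)

    def test_real_candidate_set_scores_nonnegative(self, exp1, exp1_noisy20):
        cs = build_candidate_set(exp1_noisy20, exp1.model, exp1.space,
                                 exp1.noise, n_starts=6,
                                 rng=np.random.default_rng(0))
        sc = ealpipe_scores(cs, exp1.model, exp1.grid_array, exp1.noise)
        assert sc.scores.shape == exp1.grid_array.shape
        assert np.all(sc.scores >= 0)


class TestBenchmarkScores:
    def test_identical_trajectories_score_zero(self):
        trajs = np.tile(np.array([[1.0, 2.0, 3.0]]), (4, 1, 1))
        sc = benchmark_scores(trajs)
        np.testing.assert_allclose(sc.scores, 0.0, atol=1e-20)

    def test_single_output_is_population_variance(self):
        rng = np.random.default_rng(1)
        trajs = rng.random((5, 1, 7))
        sc = benchmark_scores(trajs)
        # brute-force two-pass population variance per grid point
        for t in range(7):
            vals = trajs[:, 0, t]
            ref = np.sum((vals - vals.mean()) ** 2) / len(vals)
            assert sc.scores[t] == pytest.approx(ref, rel=1e-12)

    def test_two_output_hand_covariance_determinant(self):
        # 3 models, 2 outputs at a single grid point
        f1 = np.array([1.0, 2.0, 3.0])
        f2 = np.array([0.5, 0.4, 0.9])
        trajs = np.stack([f1, f2], axis=1)[:, :, None]  # (3, 2, 1)
        v1 = np.sum((f1 - f1.mean()) ** 2) / 3
        v2 = np.sum((f2 - f2.mean()) ** 2) / 3
        cv = np.sum((f1 - f1.mean()) * (f2 - f2.mean())) / 3
        sc = benchmark_scores(trajs)
        assert sc.scores[0] == pytest.approx(v1 * v2 - cv**2, rel=1e-6)

    def test_determinant_homogeneity(self):
        rng = np.random.default_rng(2)
        trajs = rng.random((6, 2, 5)) + 1.0
        a = benchmark_scores(trajs).scores
        b = benchmark_scores(3.0 * trajs).scores
        np.testing.assert_allclose(b, 3.0**4 * a, rtol=1e-6)

    def test_scaled_divides_by_noise_variance(self):
        rng = np.random.default_rng(3)
        trajs = rng.random((4, 1, 6))
        sig2 = np.full((1, 6), 0.25)
        a = benchmark_scores(trajs).scores
        b = benchmark_scores(trajs, sigma_hat2=sig2, scaled=True).scores
        np.testing.assert_allclose(b, a / 0.25, rtol=1e-12)
        with pytest.raises(ValueError):
            benchmark_scores(trajs, scaled=True)

    def test_minimum_ensemble_size(self):
        with pytest.raises(ValueError):
            benchmark_scores(np.zeros((1, 1, 3)))


class TestBenchmarkEnsemble:
    def test_pin_layout_without_identifiability(self, exp1):
        pins = benchmark_pins(exp1.space)
        assert set(pins) == {"beta1", "beta2"}
        for nm, values in pins.items():
            lo, up = exp1.space.bounds(nm)
            assert len(values) == 10
            assert lo < values[0] and values[-1] < up
            np.testing.assert_allclose(np.diff(values), values[1] - values[0])

    def test_ci_filtering_keeps_inside_values(self, exp1):
        pins_all = benchmark_pins(exp1.space)["beta1"]
        ci = ParamCI(lower=pins_all[2] - 1e-9, upper=pins_all[4] + 1e-9,
                     epsilon=1e-3, n_probes_lower=5, n_probes_upper=5)
        pins = benchmark_pins(exp1.space, identifiable={"beta1": True},
                              cis={"beta1": ci})
        assert len(pins["beta1"]) == 3
        assert len(pins["beta2"]) == 10  # 13 models in total

    def test_narrow_ci_contributes_midpoint(self, exp1):
        ci = ParamCI(lower=1.001, upper=1.002, epsilon=1e-3,
                     n_probes_lower=5, n_probes_upper=5)
        pins = benchmark_pins(exp1.space, identifiable={"beta1": True},
                              cis={"beta1": ci})
        np.testing.assert_allclose(pins["beta1"], [1.0015])

    def test_fits_on_data(self, exp1, exp1_noisy20):
        ensemble, cache = benchmark_ensemble(
            exp1_noisy20, exp1.model, exp1.space, exp1.noise,
            n_starts=2, rng=np.random.default_rng(0))
        assert len(ensemble) == 20
        assert len(cache) == 20
        assert all(np.isfinite(f.nll) for f in ensemble)


class TestSelectNext:
    def test_argmax_and_tie_breaking(self):
        grid = np.array([1.0, 2.0, 3.0])
        assert select_next(np.array([0.1, 5.0, 0.2]), grid) == 2.0
        assert select_next(np.zeros(3), grid) == 1.0  # earliest on ties
        assert select_next(np.array([1.0, 1.0, 0.5]), grid) == 1.0

    def test_random_selection_reproducible(self):
        grid = np.arange(1.0, 11.0)
        a = [select_next(None, grid, rng=np.random.default_rng(5), random=True)
             for _ in range(1)]
        b = [select_next(None, grid, rng=np.random.default_rng(5), random=True)
             for _ in range(1)]
        assert a == b
        draws = {select_next(None, grid, rng=np.random.default_rng(i),
                             random=True) for i in range(50)}
        assert len(draws) > 3  # actually varies across seeds

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_next(np.array([]), np.array([]))
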