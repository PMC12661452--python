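import itertools

import numpy as np
import pytest

from ealpipe import ModelSpec, experiment_preset
from ealpipe.evaluation import (
    ci_width_at_budget,
    diff_metric,
    identifiability_probability,
    iterations_to_identifiability,
    mean_iterations_to_identifiability,
    paired_rank_test,
    summarize_method,
    write_report,
)
from ealpipe.identifiability import IdentifiabilityReport, ParamCI
from ealpipe.loop import ReplicationTrace, run_experiment


def _trace(reliable, n_obs=20, report=None, theta=None):
    return ReplicationTrace(
        method="ealpipe", rep=0, seed=0, iterations=[],
        reliable_identifiability_iteration=reliable,
        termination="budget_exhausted",
        final_report=report, final_mle_theta=theta,
        times=np.zeros(n_obs), observations=np.zeros((n_obs, 1)),
    )


def _report(space, id_flags, cis):
    return IdentifiabilityReport(
        threshold=0.0,
        pl={nm: (5.0, 5.0) for nm in space.free_names},
        identifiable=id_flags,
        ci=cis,
        epsilon={nm: 1e-3 for nm in space.free_names},
    )


class TestSpeedMetrics:
    def test_mean_with_failure_assignment(self):
        assert mean_iterations_to_identifiability(
            [_trace(5), _trace(5)], 50) == 5.0
        assert mean_iterations_to_identifiability(
            [_trace(10), _trace(None)], 50) == 30.0
        with pytest.raises(ValueError):
            mean_iterations_to_identifiability([], 50)

    def test_never_exceeds_cap(self):
        traces = [_trace(None), _trace(49), _trace(3)]
        m = mean_iterations_to_identifiability(traces, 50)
        assert m <= 50
        assert iterations_to_identifiability(_trace(None), 50) == 50

    def test_probability_curve_shapes(self):
        assert identifiability_probability([_trace(None)], 5).tolist() == [0] * 5
        np.testing.assert_array_equal(
            identifiability_probability([_trace(3), _trace(3)], 5),
            [0, 0, 1, 1, 1])
        mixed = identifiability_probability(
            [_trace(2), _trace(4), _trace(None)], 6)
        assert np.all(np.diff(mixed) >= 0)  # cumulative
        assert mixed[-1] == pytest.approx(2 / 3)


class TestCIWidthAtBudget:
    def test_failure_gets_full_box_width(self, exp1):
        rep = _report(exp1.space, {"beta1": False, "beta2": False},
                      {"beta1": None, "beta2": None})
        w = ci_width_at_budget(_trace(None, report=rep), exp1.space)
        assert w == {"beta1": 3.0, "beta2": 3.0}

    def test_identifiable_uses_interval(self, exp1):
        ci = ParamCI(1.9, 2.1, 1e-3, 5, 5)
        rep = _report(exp1.space, {"beta1": True, "beta2": False},
                      {"beta1": ci, "beta2": None})
        w = ci_width_at_budget(_trace(None, report=rep), exp1.space)
        assert w["beta1"] == pytest.approx(0.2)
        assert w["beta2"] == 3.0

    def test_missing_report_rejected(self, exp1):
        with pytest.raises(ValueError):
            ci_width_at_budget(_trace(None, report=None), exp1.space)


class TestDiffMetric:
    def test_exact_fit_is_zero(self, exp1):
        d = diff_metric(exp1.space.truth_vector, exp1.space.truth_vector,
                        exp1.model, exp1.grid)
        np.testing.assert_array_equal(d, [0.0])

    def test_constant_offset(self):
        base = ModelSpec(id="c0", output_names=("y",),
                         initial_conditions=(0.0,),
                         forward=lambda th, t: np.full((1, len(t)), th[0]))
        d = diff_metric(np.array([1.5]), np.array([1.0]), base,
                        np.linspace(0, 1, 11))
        assert d[0] == pytest.approx(0.5)

    def test_matches_direct_sum_oracle(self, exp1):
        theta = np.array([2.1, 4.0])
        d = diff_metric(theta, exp1.space.truth_vector, exp1.model, exp1.grid)
        g = exp1.grid_array
        acc = 0.0
        for t in g:
            pred = float(exp1.model.forward(theta, np.array([t]))[0, 0])
            true = float(exp1.model.forward(exp1.space.truth_vector,
                                            np.array([t]))[0, 0])
            acc += abs(pred - true)
        assert d[0] == pytest.approx(acc / len(g), rel=1e-12)


def exact_signed_rank_p(diffs):
    """Exhaustive enumeration oracle for the two-sided signed-rank test."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # handle ties by midranks
    uniq = {}
    for v in np.abs(d):
        uniq.setdefault(v, []).append(v)
    order = np.argsort(np.abs(d), kind="stable")
    sorted_abs = np.abs(d)[order]
    midranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        midranks[i:j] = 0.5 * (i + 1 + j)
        i = j
    ranks = np.empty(n)
    ranks[order] = midranks
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2.0
    stat_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / total


class TestPairedRankTest:
    def test_identical_samples(self):
        assert paired_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_strict_dominance_ten_pairs(self):
        a = np.arange(10.0)
        b = a + np.linspace(1, 2, 10)
        assert paired_rank_test(a, b) == pytest.approx(2 / 2**10, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        a = rng.normal(size=n)
        b = a + rng.normal(scale=0.8, size=n)
        assert paired_rank_test(a, b) == pytest.approx(
            exact_signed_rank_p(a - b), rel=1e-9)

    def test_textbook_small_sample(self):
        # hand-workable n=6 example with distinct ranks
        a = [10.0, 12.0, 9.0, 14.0, 8.0, 11.0]
        b = [9.0, 13.0, 5.0, 10.0, 6.0, 7.0]
        assert paired_rank_test(a, b) == pytest.approx(
            exact_signed_rank_p(np.array(a) - np.array(b)), rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_rank_test([1.0], [1.0, 2.0])


class TestReporting:
    def test_summary_and_report_round_trip(self, tmp_path):
        import pandas as pd

        cfg = experiment_preset(1, max_points=4, method="random",
                                mode="fixed_budget", budget=4)
        traces = run_experiment(cfg, reps=[0, 1])
        summary = summarize_method(cfg, budget_traces=traces)
        assert summary.n_reps == 2
        assert set(summary.ci_width_mean) == {"beta1", "beta2"}
        paths = write_report({"random": summary}, tmp_path, prefix="exp1")
        df = pd.read_csv(paths["ci_width"])
        got = dict(zip(df["parameter"], df["mean_width"]))
        for nm, v in summary.ci_width_mean.items():
            assert got[nm] == pytest.approx(v)

    def test_empty_summaries_write_headers(self, tmp_path):
        import pandas as pd

        paths = write_report({}, tmp_path, prefix="none")
        for p in paths.values():
            df = pd.read_csv(p)
            assert len(df) == 0 and len(df.columns) >= 3
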