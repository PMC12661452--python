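"""Performance metrics, paired significance tests and report tables.

Three study metrics are computed from replication traces:

1. Speed: the iteration (dataset size) at which a run first becomes reliably
   identifiable, failures scored at the iteration cap; reported both as a
   mean and as a cumulative per-iteration identifiability probability.
2. Precision: per-parameter profile-likelihood CI widths at a fixed
   observation budget, with the full search-box width assigned when the
   parameter is not identifiable at the budget.
3. Accuracy: the mean absolute deviation between the trajectory of the
   budget MLE and the true trajectory over the candidate grid, per output.

Method pairs sharing replication seeds are compared with the two-sided
Wilcoxon signed-rank test (exact for small n, normal approximation with
continuity correction otherwise; zero differences dropped).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .loop import ExperimentConfig, ReplicationTrace
from .models import ModelSpec, ParameterSpace

__all__ = [
    "iterations_to_identifiability",
    "mean_iterations_to_identifiability",
    "identifiability_probability",
    "ci_width_at_budget",
    "diff_metric",
    "paired_rank_test",
    "sampling_histogram",
    "MethodSummary",
    "summarize_method",
    "write_report",
]


def iterations_to_identifiability(trace: ReplicationTrace, max_points: int) -> int:
    """Reliable-identifiability iteration, or ``max_points`` on failure."""
    k = trace.reliable_identifiability_iteration
    return int(k) if k is not None else int(max_points)


def mean_iterations_to_identifiability(
    traces: Sequence[ReplicationTrace], max_points: int
) -> float:
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    return float(np.mean([iterations_to_identifiability(t, max_points)
                          for t in traces]))


def identifiability_probability(
    traces: Sequence[ReplicationTrace], max_iterations: int | None = None
) -> np.ndarray:
    """Fraction of replications reliably identifiable by iteration k.

    Entry ``k-1`` is the fraction of traces whose reliable-identifiability
    iteration is at most ``k``; cumulative, hence nondecreasing in ``k``.
    """
    if max_iterations is None:
        max_iterations = max(t.n_obs for t in traces)
    ks = np.arange(1, max_iterations + 1)
    hits = np.zeros(max_iterations)
    for t in traces:
        r = t.reliable_identifiability_iteration
        if r is not None:
            hits += ks >= r
    return hits / len(traces)


def ci_width_at_budget(
    trace: ReplicationTrace, space: ParameterSpace
) -> dict[str, float]:
    """Per-parameter CI width at the end of a fixed-budget run.

    Uses the bisection interval when the parameter was identifiable at the
    final assessment, else the full width of its search range.
    """
    if trace.final_report is None:
        raise ValueError("trace has no final identifiability report")
    return {nm: trace.final_report.width_or_box(nm, space)
            for nm in space.free_names}


def diff_metric(
    theta_hat: np.ndarray, truth: np.ndarray, model: ModelSpec,
    grid: Sequence[float],
) -> np.ndarray:
    """Mean absolute deviation per output between fitted and true trajectories."""
    g = np.asarray(grid, dtype=float)
    pred = model.forward(np.asarray(theta_hat, float), g)
    true = model.forward(np.asarray(truth, float), g)
    return np.mean(np.abs(pred - true), axis=1)


def paired_rank_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired replications."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)


def sampling_histogram(
    traces: Sequence[ReplicationTrace], grid: Sequence[float]
) -> pd.DataFrame:
    """Counts of selected measurement times over a replication set.

    Plumbing for sampling-location heatmaps: one row per grid time with the
    number of times any replication measured there (the seed observation
    included).
    """
    g = np.round(np.asarray(grid, dtype=float), 10)
    counts = np.zeros(g.size, dtype=int)
    for t in traces:
        idx = np.searchsorted(g, np.round(t.times, 10))
        idx = np.clip(idx, 0, g.size - 1)
        np.add.at(counts, idx, 1)
    return pd.DataFrame({"time": g, "count": counts})


@dataclasses.dataclass
class MethodSummary:
    """Across-replication summary of one strategy on one experiment."""

    method: str
    n_reps: int
    mean_iterations: float | None
    se_iterations: float | None
    id_probability: np.ndarray | None
    ci_width_mean: dict[str, float] | None
    ci_width_se: dict[str, float] | None
    diff_mean: dict[str, float] | None
    diff_se: dict[str, float] | None


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return float(np.mean(x)), se


def summarize_method(
    cfg: ExperimentConfig,
    stop_traces: Sequence[ReplicationTrace] | None = None,
    budget_traces: Sequence[ReplicationTrace] | None = None,
) -> MethodSummary:
    """Summarise speed from stop-on-identifiability traces and precision /
    accuracy from fixed-budget traces (either may be omitted)."""
    method = cfg.method
    mean_it = se_it = None
    id_prob = None
    if stop_traces:
        its = np.array([iterations_to_identifiability(t, cfg.max_points)
                        for t in stop_traces])
        mean_it, se_it = _mean_se(its)
        id_prob = identifiability_probability(stop_traces, cfg.max_points)
    ci_mean = ci_se = diff_mean = diff_se = None
    if budget_traces:
        space, model = cfg.space, cfg.model
        widths = {nm: [] for nm in space.free_names}
        for t in budget_traces:
            w = ci_width_at_budget(t, space)
            for nm in space.free_names:
                widths[nm].append(w[nm])
        ci_mean, ci_se = {}, {}
        for nm, vals in widths.items():
            ci_mean[nm], ci_se[nm] = _mean_se(np.array(vals))
        diffs = {nm: [] for nm in model.output_names}
        for t in budget_traces:
            d = diff_metric(t.final_mle_theta, space.truth_vector, model, cfg.grid)
            for j, nm in enumerate(model.output_names):
                diffs[nm].append(d[j])
        diff_mean, diff_se = {}, {}
        for nm, vals in diffs.items():
            diff_mean[nm], diff_se[nm] = _mean_se(np.array(vals))
    n = len(stop_traces or budget_traces or ())
    return MethodSummary(
        method=method, n_reps=n,
        mean_iterations=mean_it, se_iterations=se_it, id_probability=id_prob,
        ci_width_mean=ci_mean, ci_width_se=ci_se,
        diff_mean=diff_mean, diff_se=diff_se,
    )


def write_report(
    summaries: Mapping[str, MethodSummary], out_dir: str | Path,
    prefix: str = "experiment",
) -> dict[str, Path]:
    """Write delimited-text summary tables (means and standard errors).

    Produces ``{prefix}_iterations.csv`` (speed), ``{prefix}_ci_width.csv``
    (precision), ``{prefix}_diff.csv`` (accuracy) and
    ``{prefix}_id_prob.csv`` (cumulative identifiability-probability
    curves); empty summaries yield header-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = [{"method": m, "n_reps": s.n_reps,
             "mean_iterations": s.mean_iterations,
             "se_iterations": s.se_iterations}
            for m, s in summaries.items() if s.mean_iterations is not None]
    paths["iterations"] = out / f"{prefix}_iterations.csv"
    pd.DataFrame(rows, columns=["method", "n_reps", "mean_iterations",
                                "se_iterations"]).to_csv(
        paths["iterations"], index=False)

    ci_rows, diff_rows = [], []
    for m, s in summaries.items():
        if s.ci_width_mean:
            for nm in s.ci_width_mean:
                ci_rows.append({"method": m, "parameter": nm,
                                "mean_width": s.ci_width_mean[nm],
                                "se_width": s.ci_width_se[nm]})
        if s.diff_mean:
            for nm in s.diff_mean:
                diff_rows.append({"method": m, "output": nm,
                                  "mean_diff": s.diff_mean[nm],
                                  "se_diff": s.diff_se[nm]})
    paths["ci_width"] = out / f"{prefix}_ci_width.csv"
    pd.DataFrame(ci_rows, columns=["method", "parameter", "mean_width",
                                   "se_width"]).to_csv(
        paths["ci_width"], index=False)
    paths["diff"] = out / f"{prefix}_diff.csv"
    pd.DataFrame(diff_rows, columns=["method", "output", "mean_diff",
                                     "se_diff"]).to_csv(
        paths["diff"], index=False)

    prob_rows = []
    for m, s in summaries.items():
        if s.id_probability is not None:
            for k, p in enumerate(s.id_probability, start=1):
                prob_rows.append({"method": m, "iteration": k,
                                  "probability": float(p)})
    paths["id_prob"] = out / f"{prefix}_id_prob.csv"
    pd.DataFrame(prob_rows, columns=["method", "iteration",
                                     "probability"]).to_csv(
        paths["id_prob"], index=False)
    return paths
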