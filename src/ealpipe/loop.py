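"""Sequential active-learning loop: estimate, assess, acquire, collect.

A replication starts from a single observation at a user-chosen first time
and then alternates between an estimation phase (MLE + boundary models) and
an exploration phase (score the candidate grid with the configured strategy
and measure at the best time).  Identifiability is assessed from the second
data point onwards; a run is *reliably* identifiable at the second of two
consecutive iterations whose verdicts are all positive, at which point
confidence intervals are computed and (in ``stop_on_id`` mode) the run ends.
``fixed_budget`` mode instead always runs to an exact observation count so
that CI-width and point-estimate comparisons across strategies use equal
data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .acquisition import (
    benchmark_ensemble,
    benchmark_scores,
    ealpipe_scores,
    mle_noise_variance,
    select_next,
)
from .estimation import (
    CandidateSet,
    Dataset,
    build_candidate_set,
    fit_mle,
)
from .identifiability import (
    IdentifiabilityReport,
    ParamCI,
    bisection_ci,
    check_identifiability,
    default_epsilon,
    likelihood_threshold,
)
from .models import IntegrationError, ModelSpec, ParameterSpace, get_model
from .noise import NoiseSpec, sample_observation

__all__ = [
    "ExperimentConfig",
    "IterationRecord",
    "ReplicationTrace",
    "collect_observation",
    "experiment_preset",
    "run_replication",
    "run_experiment",
    "write_traces",
    "read_traces",
]

METHODS = ("ealpipe", "benchmark", "scaled_benchmark", "random")
MODES = ("stop_on_id", "fixed_budget")


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one simulation study."""

    model_id: str
    space: ParameterSpace
    noise: NoiseSpec
    grid: tuple[float, ...]  # candidate measurement times (hours)
    first_observation_time: float
    max_points: int = 50
    confidence: float = 0.95
    method: str = "ealpipe"
    n_starts: int = 10
    n_starts_profile: int = 3
    epsilon_rel: float = 1e-3
    seed: int = 0
    n_reps: int = 1
    mode: str = "stop_on_id"
    budget: int = 20  # observation count in fixed_budget mode

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.max_points < 1 or self.budget < 1:
            raise ValueError("max_points and budget must be >= 1")
        g = np.asarray(self.grid, dtype=float)
        if not np.any(np.isclose(g, self.first_observation_time)):
            raise ValueError("first_observation_time must lie on the grid")

    @property
    def model(self) -> ModelSpec:
        return get_model(self.model_id)

    @property
    def grid_array(self) -> np.ndarray:
        return np.asarray(self.grid, dtype=float)

    @property
    def target_points(self) -> int:
        return self.budget if self.mode == "fixed_budget" else self.max_points

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step))
    return tuple(np.round(start + step * np.arange(n + 1), 10))


def experiment_preset(number: int, **overrides) -> ExperimentConfig:
    """The three synthetic studies.

    1. Sum of two exponentials, truth (2, 4) hr^-1, non-overlapping bounds
       [0,3] and [3,6], sigma = 0.005, grid 1:0.1:10 h, first obs at t=3.
    2. Monod model observing BG only; KS fixed at 30 g/L; truth
       (muMax, KD, YieldC) = (1, 0.1, 0.5); sigma_BG = 2; grid 1:0.5:60 h,
       first obs at t=10.
    3. Monod model observing BG and SC; truth (0.5, 30, 0.05, 0.6);
       sigma_BG = 0.5, sigma_SC = 1.6; same grid and first time.
    """
    if number == 1:
        cfg = ExperimentConfig(
            model_id="sum_of_exponentials",
            space=ParameterSpace(
                names=("beta1", "beta2"),
                lower=(0.0, 3.0), upper=(3.0, 6.0), truth=(2.0, 4.0),
            ),
            noise=NoiseSpec(sigma=(0.005,)),
            grid=_grid(1.0, 10.0, 0.1),
            first_observation_time=3.0,
            n_starts=8,
        )
    elif number == 2:
        cfg = ExperimentConfig(
            model_id="microbial_growth_1out",
            space=ParameterSpace(
                names=("muMax", "KS", "KD", "YieldC"),
                lower=(0.1, 0.1, 0.0001, 0.01),
                upper=(50.0, 50.0, 1.0, 10.0),
                truth=(1.0, 30.0, 0.1, 0.5),
                fixed={"KS": 30.0},
            ),
            noise=NoiseSpec(sigma=(2.0,)),
            grid=_grid(1.0, 60.0, 0.5),
            first_observation_time=10.0,
            n_starts=6,
        )
    elif number == 3:
        cfg = ExperimentConfig(
            model_id="microbial_growth_2out",
            space=ParameterSpace(
                names=("muMax", "KS", "KD", "YieldC"),
                lower=(0.1, 0.1, 0.0001, 0.01),
                upper=(50.0, 50.0, 1.0, 10.0),
                truth=(0.5, 30.0, 0.05, 0.6),
            ),
            noise=NoiseSpec(sigma=(0.5, 1.6)),
            grid=_grid(1.0, 60.0, 0.5),
            first_observation_time=10.0,
            n_starts=6,
        )
    else:
        raise ValueError("experiment number must be 1, 2 or 3")
    return cfg.replace(**overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Trace containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IterationRecord:
    n_obs: int
    mle_theta: np.ndarray
    mle_nll: float
    threshold: float
    identifiable: dict[str, bool]
    all_identifiable: bool
    chosen_time: float | None  # next measurement chosen at this iteration

    def to_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "mle_theta": [float(v) for v in self.mle_theta],
            "mle_nll": float(self.mle_nll),
            "threshold": float(self.threshold),
            "identifiable": dict(self.identifiable),
            "all_identifiable": bool(self.all_identifiable),
            "chosen_time": self.chosen_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IterationRecord":
        return cls(
            n_obs=d["n_obs"], mle_theta=np.asarray(d["mle_theta"], float),
            mle_nll=d["mle_nll"], threshold=d["threshold"],
            identifiable=dict(d["identifiable"]),
            all_identifiable=d["all_identifiable"],
            chosen_time=d["chosen_time"],
        )


@dataclasses.dataclass
class ReplicationTrace:
    """Per-iteration log of one replication plus its final assessment."""

    method: str
    rep: int
    seed: int
    iterations: list[IterationRecord]
    reliable_identifiability_iteration: int | None
    termination: str
    final_report: IdentifiabilityReport | None
    final_mle_theta: np.ndarray | None
    times: np.ndarray
    observations: np.ndarray  # (n, M)

    @property
    def n_obs(self) -> int:
        return int(self.times.shape[0])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rep": self.rep,
            "seed": self.seed,
            "iterations": [it.to_dict() for it in self.iterations],
            "reliable_identifiability_iteration":
                self.reliable_identifiability_iteration,
            "termination": self.termination,
            "final_report":
                None if self.final_report is None else self.final_report.to_dict(),
            "final_mle_theta":
                None if self.final_mle_theta is None
                else [float(v) for v in self.final_mle_theta],
            "times": [float(t) for t in self.times],
            "observations": self.observations.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReplicationTrace":
        return cls(
            method=d["method"], rep=d["rep"], seed=d["seed"],
            iterations=[IterationRecord.from_dict(it) for it in d["iterations"]],
            reliable_identifiability_iteration=
                d["reliable_identifiability_iteration"],
            termination=d["termination"],
            final_report=None if d["final_report"] is None
                else IdentifiabilityReport.from_dict(d["final_report"]),
            final_mle_theta=None if d["final_mle_theta"] is None
                else np.asarray(d["final_mle_theta"], float),
            times=np.asarray(d["times"], float),
            observations=np.asarray(d["observations"], float),
        )


def write_traces(traces: Iterable[ReplicationTrace], path: str | Path) -> None:
    """Write one JSON object per replication (JSON lines)."""
    with open(path, "w") as fh:
        for tr in traces:
            fh.write(json.dumps(tr.to_dict()) + "\n")


def read_traces(path: str | Path) -> list[ReplicationTrace]:
    with open(path) as fh:
        return [ReplicationTrace.from_dict(json.loads(line))
                for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------

def collect_observation(
    model: ModelSpec, truth: np.ndarray, time: float, noise: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One noisy draw of every observed output at the chosen time."""
    f = model.forward(truth, np.array([float(time)]))[:, 0]
    return sample_observation(f, noise.sigma_vector, rng)


def _final_report(
    dataset: Dataset, cfg: ExperimentConfig, cs: CandidateSet,
    threshold: float, flags: dict[str, bool], eps: dict[str, float],
    opt_rng: np.random.Generator,
) -> IdentifiabilityReport:
    cis: dict[str, ParamCI | None] = {}
    for nm in cfg.space.free_names:
        if flags.get(nm):
            cis[nm] = bisection_ci(
                dataset, cfg.model, cfg.space, cfg.noise, nm,
                cs.mle.theta, threshold, eps[nm],
                n_starts=cfg.n_starts_profile, rng=opt_rng,
            )
        else:
            cis[nm] = None
    return IdentifiabilityReport(
        threshold=threshold,
        pl={nm: cs.pl_bounds(nm) for nm in cfg.space.free_names},
        identifiable=dict(flags),
        ci=cis,
        epsilon=dict(eps),
    )


def run_replication(cfg: ExperimentConfig, rep: int = 0) -> ReplicationTrace:
    """Run one seeded replication of the configured strategy.

    Noise draws, optimiser starts and random selection use independent
    sub-streams derived from ``(seed, rep)``, so strategies compared under
    the same seed see identical noise wherever their datasets coincide.
    """
    ss = np.random.SeedSequence([cfg.seed, rep])
    noise_rng, opt_rng, select_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    model, space, noise = cfg.model, cfg.space, cfg.noise
    grid = cfg.grid_array
    truth = space.truth_vector
    eps = default_epsilon(space, cfg.epsilon_rel)

    dataset = Dataset.empty(model.n_outputs)
    dataset.append(cfg.first_observation_time,
                   collect_observation(model, truth, cfg.first_observation_time,
                                       noise, noise_rng))

    records: list[IterationRecord] = []
    prev_all = False
    prev_cs: CandidateSet | None = None
    reliable: int | None = None
    recent_cis: dict[str, ParamCI] = {}
    ens_warm: dict[tuple[str, float], np.ndarray] = {}

    while True:
        n = dataset.n
        cs = build_candidate_set(
            dataset, model, space, noise,
            n_starts=cfg.n_starts, n_starts_profile=cfg.n_starts_profile,
            rng=opt_rng, previous=prev_cs,
        )
        threshold = likelihood_threshold(cs.mle.nll, cfg.confidence)
        if n >= 2:
            flags = check_identifiability(cs, threshold)
        else:
            flags = {nm: False for nm in space.free_names}
        all_id = n >= 2 and all(flags.values())
        reliable_now = all_id and prev_all
        if reliable is None and reliable_now:
            reliable = n

        record = IterationRecord(
            n_obs=n, mle_theta=cs.mle.theta, mle_nll=cs.mle.nll,
            threshold=threshold, identifiable=dict(flags),
            all_identifiable=all_id, chosen_time=None,
        )
        records.append(record)

        stop_reason = None
        if cfg.mode == "stop_on_id" and reliable_now:
            stop_reason = "reliable_identifiability"
        elif n >= cfg.target_points:
            stop_reason = "budget_exhausted"
        if stop_reason is not None:
            report = _final_report(dataset, cfg, cs, threshold, flags, eps, opt_rng)
            if cfg.mode == "fixed_budget":
                final_mle = fit_mle(dataset, model, space, noise,
                                    n_starts=cfg.n_starts, rng=opt_rng,
                                    warm=[cs.mle.theta]).theta
            else:
                final_mle = cs.mle.theta
            return ReplicationTrace(
                method=cfg.method, rep=rep, seed=cfg.seed,
                iterations=records,
                reliable_identifiability_iteration=reliable,
                termination=stop_reason,
                final_report=report,
                final_mle_theta=final_mle,
                times=dataset.times.copy(),
                observations=dataset.y.copy(),
            )

        # -- exploration phase -------------------------------------------
        if cfg.method == "random":
            chosen = select_next(None, grid, rng=select_rng, random=True)
        elif cfg.method == "ealpipe":
            chosen = select_next(ealpipe_scores(cs, model, grid, noise), grid)
        else:  # benchmark / scaled_benchmark
            for nm in space.free_names:  # keep most recent CI per parameter
                if flags.get(nm):
                    recent_cis[nm] = bisection_ci(
                        dataset, model, space, noise, nm, cs.mle.theta,
                        threshold, eps[nm], n_starts=cfg.n_starts_profile,
                        rng=opt_rng,
                    )
            ensemble, ens_warm = benchmark_ensemble(
                dataset, model, space, noise,
                identifiable=flags, cis=recent_cis,
                n_starts=cfg.n_starts_profile, rng=opt_rng,
                warm=ens_warm, mle_theta=cs.mle.theta,
            )
            trajs = []
            for f in ensemble:
                try:
                    trajs.append(model.forward(f.theta, grid))
                except IntegrationError:
                    continue
            trajs = np.stack(trajs)
            sigma_hat2 = None
            if cfg.method == "scaled_benchmark":
                sigma_hat2 = mle_noise_variance(model.forward(cs.mle.theta, grid),
                                                noise)
            chosen = select_next(
                benchmark_scores(trajs, sigma_hat2,
                                 scaled=cfg.method == "scaled_benchmark"),
                grid,
            )

        record.chosen_time = chosen
        dataset.append(chosen, collect_observation(model, truth, chosen,
                                                   noise, noise_rng))
        prev_all = all_id
        prev_cs = cs


def run_experiment(
    cfg: ExperimentConfig, reps: Sequence[int] | None = None,
    progress: bool = False,
) -> list[ReplicationTrace]:
    """Run ``cfg.n_reps`` replications (or the given replication indices)."""
    indices = list(reps) if reps is not None else list(range(cfg.n_reps))
    traces = []
    for r in indices:
        traces.append(run_replication(cfg, r))
        if progress:
            tr = traces[-1]
            print(f"[{cfg.method} rep {r}] n_obs={tr.n_obs} "
                  f"reliable={tr.reliable_identifiability_iteration} "
                  f"({tr.termination})", flush=True)
    return traces
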