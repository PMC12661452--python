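"""Next-measurement selection strategies.

Four strategies are implemented:

* **ealpipe** — likelihood-weighted squared disagreement between the
  candidate trajectories and the MLE trajectory, scaled per output by the
  predicted truncated-normal observation variance along the MLE trajectory
  and summed over outputs.
* **benchmark** — generalized variance across an ensemble of profile models
  (10 evenly spaced pin values per free parameter, constrained-fit each):
  the sample variance of the predicted output for single-output models, the
  determinant of the across-ensemble output covariance for multi-output ones.
* **scaled_benchmark** — the benchmark score divided by the predicted noise
  variance (single output) or the product of per-output noise variances
  (relative variance).
* **random** — uniform draw from the candidate grid, ignoring scores.

All scores are non-negative and vanish wherever the ensemble trajectories
coincide.  The selected time is the score argmax with ties broken by the
earliest grid time; already-sampled times remain selectable (replicates are
informative under noise).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np

from .estimation import CandidateSet, Dataset, FitResult, fit_with_fixed
from .identifiability import ParamCI
from .models import IntegrationError, ModelSpec, ParameterSpace
from .noise import NoiseSpec, predicted_noise_variance

__all__ = [
    "AcquisitionScore",
    "candidate_trajectories",
    "ealpipe_scores",
    "benchmark_pins",
    "benchmark_ensemble",
    "benchmark_scores",
    "select_next",
]

_DET_JITTER = 1e-12


@dataclasses.dataclass(frozen=True)
class AcquisitionScore:
    """Per-grid-point acquisition scores and the noise variances used."""

    scores: np.ndarray  # (T,)
    sigma_hat2: np.ndarray | None  # (M, T) predicted noise variance at the MLE


def _trajectory(model: ModelSpec, theta: np.ndarray, grid: np.ndarray,
                fallback: np.ndarray | None) -> np.ndarray:
    try:
        return model.forward(theta, grid)
    except IntegrationError:
        if fallback is None:
            raise
        warnings.warn("candidate trajectory failed to integrate; "
                      "treating it as coincident with the MLE", stacklevel=2)
        return fallback


def candidate_trajectories(
    candidate_set: CandidateSet, model: ModelSpec, grid: np.ndarray
) -> np.ndarray:
    """Stack the (m, M, T) trajectories of all candidate models.

    The MLE trajectory comes first.  A member whose integration fails is
    replaced by the MLE trajectory (its weight is already ~0), which zeroes
    its disagreement contribution.
    """
    grid = np.asarray(grid, dtype=float)
    mle_traj = model.forward(candidate_set.mle.theta, grid)
    trajs = [mle_traj]
    for fit in candidate_set.boundary.values():
        trajs.append(_trajectory(model, fit.theta, grid, mle_traj))
    return np.stack(trajs)


def mle_noise_variance(
    mle_traj: np.ndarray, noise: NoiseSpec
) -> np.ndarray:
    """Predicted observation variance along the MLE trajectory, (M, T)."""
    return predicted_noise_variance(mle_traj, noise.sigma_vector[:, None])


def ealpipe_scores(
    candidate_set: CandidateSet, model: ModelSpec, grid: np.ndarray,
    noise: NoiseSpec,
) -> AcquisitionScore:
    """Scaled weighted disagreement of the candidate set at each grid time.

    ``score(x) = sum_j (1/sigma_hat_j^2(x)) *
    sum_i w_i (f_j(x|theta_i) - f_j(x|theta_MLE))^2``
    with the noise variance predicted from the MLE trajectory.
    """
    grid = np.asarray(grid, dtype=float)
    trajs = candidate_trajectories(candidate_set, model, grid)  # (m, M, T)
    mle_traj = trajs[0]
    sigma_hat2 = mle_noise_variance(mle_traj, noise)
    dev2 = (trajs - mle_traj[None]) ** 2  # (m, M, T)
    weighted = np.einsum("i,imt->mt", candidate_set.weights, dev2)
    scores = np.sum(weighted / sigma_hat2, axis=0)
    return AcquisitionScore(scores=scores, sigma_hat2=sigma_hat2)


# ---------------------------------------------------------------------------
# Benchmark ensemble of profile models
# ---------------------------------------------------------------------------

def benchmark_pins(
    space: ParameterSpace,
    identifiable: Mapping[str, bool] | None = None,
    cis: Mapping[str, ParamCI] | None = None,
    n_values: int = 10,
) -> dict[str, np.ndarray]:
    """Pin values per free parameter for the benchmark ensemble.

    10 evenly spaced *interior* values across the search range (the bound
    endpoints are excluded: a parameter pinned exactly at a bound can yield
    a degenerate model — e.g. a zero decay rate — whose trajectory dominates
    the ensemble variance at uninformative times and locks the benchmark
    onto pure-noise measurements).  For a parameter currently deemed
    identifiable, only values inside its most recent profile-likelihood CI
    are retained; if none fall inside, the CI midpoint is used so the
    parameter still contributes one model.
    """
    pins: dict[str, np.ndarray] = {}
    for nm in space.free_names:
        lo, up = space.bounds(nm)
        values = np.linspace(lo, up, n_values + 2)[1:-1]
        ci = (cis or {}).get(nm)
        if identifiable and identifiable.get(nm) and ci is not None:
            inside = values[(values >= ci.lower) & (values <= ci.upper)]
            values = inside if inside.size else np.array([0.5 * (ci.lower + ci.upper)])
        pins[nm] = values
    return pins


def benchmark_ensemble(
    dataset: Dataset,
    model: ModelSpec,
    space: ParameterSpace,
    noise: NoiseSpec,
    identifiable: Mapping[str, bool] | None = None,
    cis: Mapping[str, ParamCI] | None = None,
    n_starts: int = 3,
    rng: np.random.Generator | None = None,
    warm: Mapping[tuple[str, float], np.ndarray] | None = None,
    mle_theta: np.ndarray | None = None,
) -> tuple[list[FitResult], dict[tuple[str, float], np.ndarray]]:
    """Fit the (at most 10*N) profile models of the benchmark strategies.

    Each pin value yields one constrained fit, warm-started from the current
    MLE and the previous iteration's fit at the same pin when available.
    Fits that fail to produce a finite likelihood are dropped with a warning.
    Returns the ensemble and a warm-start cache for the next iteration.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    warm = dict(warm or {})
    ensemble: list[FitResult] = []
    cache: dict[tuple[str, float], np.ndarray] = {}
    for nm, values in benchmark_pins(space, identifiable, cis).items():
        for value in values:
            key = (nm, round(float(value), 12))
            starts: list[np.ndarray] = []
            if mle_theta is not None:
                starts.append(np.asarray(mle_theta, dtype=float))
            if key in warm:
                starts.append(warm[key])
            fit = fit_with_fixed(dataset, model, space, noise, nm, float(value),
                                 n_starts=n_starts, rng=rng, warm=starts)
            if np.isfinite(fit.nll):
                ensemble.append(fit)
                cache[key] = fit.theta
            else:
                warnings.warn(
                    f"benchmark profile fit failed for {nm}={value:g}; dropped",
                    stacklevel=2,
                )
    return ensemble, cache


def benchmark_scores(
    trajectories: np.ndarray,
    sigma_hat2: np.ndarray | None = None,
    scaled: bool = False,
) -> AcquisitionScore:
    """(Scaled) generalized variance of the ensemble predictions per time.

    ``trajectories`` is (m, M, T).  Variances and covariances use the
    population convention (denominator m): the ensemble is an exhaustive
    model set, not a sample.  With ``scaled=True`` the score is divided by
    the predicted noise variance (M = 1) or the product of per-output noise
    variances (M > 1); ``sigma_hat2`` of shape (M, T) is then required.
    """
    trajs = np.asarray(trajectories, dtype=float)
    if trajs.ndim != 3 or trajs.shape[0] < 2:
        raise ValueError("need an (m, M, T) stack with m >= 2")
    m, n_out, n_t = trajs.shape
    centered = trajs - trajs.mean(axis=0, keepdims=True)
    if n_out == 1:
        scores = np.mean(centered[:, 0, :] ** 2, axis=0)
    else:
        # (T, M, M) population covariance per grid point
        cov = np.einsum("imt,ijt->tmj", centered, centered) / m
        trace = np.einsum("tmm->t", cov)
        cov = cov + (_DET_JITTER * trace)[:, None, None] * np.eye(n_out)
        scores = np.linalg.det(cov)
    scores = np.maximum(scores, 0.0)
    if scaled:
        if sigma_hat2 is None:
            raise ValueError("sigma_hat2 required for the scaled benchmark")
        scores = scores / np.prod(sigma_hat2, axis=0)
    return AcquisitionScore(scores=scores,
                            sigma_hat2=sigma_hat2 if scaled else None)


def select_next(
    scores: np.ndarray | AcquisitionScore | None,
    grid: Sequence[float],
    rng: np.random.Generator | None = None,
    random: bool = False,
) -> float:
    """Argmax selection with earliest-time tie-breaking; uniform if random."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("candidate grid is empty")
    if random:
        if rng is None:
            raise ValueError("random selection needs an rng")
        return float(grid[rng.integers(grid.size)])
    s = scores.scores if isinstance(scores, AcquisitionScore) else np.asarray(scores)
    if s.shape != grid.shape:
        raise ValueError("scores and grid must be aligned")
    return float(grid[int(np.argmax(s))])
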