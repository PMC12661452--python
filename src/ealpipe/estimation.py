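"""Maximum-likelihood estimation and the profile-boundary candidate set.

Fitting is box-constrained L-BFGS-B with multi-start (Latin-hypercube draws
plus optional warm starts), run in unit-box coordinates so finite-difference
steps are comparable across parameters of very different magnitudes.

The candidate set used by the acquisition step consists of the MLE model plus
``2N`` boundary models, one per free parameter pinned at each search bound;
boundary fits are exactly the profile-likelihood values at the bounds.
Candidate weights are likelihoods normalized in the log domain.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .models import IntegrationError, ModelSpec, ParameterSpace
from .noise import NoiseSpec, log_density

__all__ = [
    "Dataset",
    "FitResult",
    "CandidateSet",
    "negative_log_likelihood",
    "fit_mle",
    "fit_with_fixed",
    "build_candidate_set",
    "read_observations",
    "write_observations",
]

_OPT_OPTIONS = {"maxiter": 200, "ftol": 1e-9, "eps": 1e-6}


class Dataset:
    """Accumulating set of (time, observation-vector) records.

    Records are kept sorted by time; repeated times are permitted (replicate
    measurements).  Observations are non-negative M-vectors.
    """

    def __init__(self, times: Sequence[float] = (), y: Sequence[Sequence[float]] = (),
                 n_outputs: int | None = None):
        t = np.asarray(times, dtype=float)
        yy = np.asarray(y, dtype=float)
        if yy.size == 0:
            if n_outputs is None:
                raise ValueError("n_outputs required for an empty dataset")
            yy = np.empty((0, n_outputs))
        if yy.ndim == 1:
            yy = yy[:, None]
        if yy.shape[0] != t.shape[0]:
            raise ValueError("times and y must have matching length")
        if np.any(yy < 0):
            raise ValueError("observations must be non-negative")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.y = yy[order]

    @classmethod
    def empty(cls, n_outputs: int) -> "Dataset":
        return cls(n_outputs=n_outputs)

    @property
    def n(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_outputs(self) -> int:
        return int(self.y.shape[1])

    def append(self, time: float, obs: Sequence[float]) -> None:
        obs = np.atleast_1d(np.asarray(obs, dtype=float))
        if obs.shape != (self.n_outputs,):
            raise ValueError("observation has wrong number of outputs")
        if np.any(obs < 0):
            raise ValueError("observations must be non-negative")
        i = int(np.searchsorted(self.times, time, side="right"))
        self.times = np.insert(self.times, i, float(time))
        self.y = np.insert(self.y, i, obs, axis=0)

    def copy(self) -> "Dataset":
        return Dataset(self.times.copy(), self.y.copy(), n_outputs=self.n_outputs)

    def to_frame(self, output_names: Sequence[str]) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times})
        for j, nm in enumerate(output_names):
            df[nm] = self.y[:, j]
        return df


def read_observations(path: str | Path | io.IOBase,
                      output_names: Sequence[str] | None = None) -> Dataset:
    """Read a delimited observation table with a ``time`` column."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("observation table needs a 'time' column")
    cols = list(output_names) if output_names else [c for c in df.columns if c != "time"]
    return Dataset(df["time"].to_numpy(), df[cols].to_numpy())


def write_observations(dataset: Dataset, path: str | Path | io.IOBase,
                       output_names: Sequence[str]) -> None:
    dataset.to_frame(output_names).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def negative_log_likelihood(
    dataset: Dataset, theta: np.ndarray, model: ModelSpec, noise: NoiseSpec
) -> float:
    """Negative log-likelihood of ``theta`` under the truncated-normal model.

    Independent across records and outputs, so it is additive over datasets;
    an empty dataset scores 0.  Integration failures and non-finite densities
    score ``+inf`` (an infinitely bad fit).
    """
    if dataset.n == 0:
        return 0.0
    try:
        f = model.forward(theta, dataset.times)
    except IntegrationError:
        return np.inf
    sigma = noise.sigma_vector[:, None]
    ll = float(np.sum(log_density(dataset.y.T, f, sigma)))
    return -ll if np.isfinite(ll) else np.inf


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Outcome of one (possibly constrained) maximum-likelihood fit."""

    theta: np.ndarray  # full vector, fixed/pinned entries included
    nll: float
    converged: bool
    n_starts_used: int


def _run_multistart(objective, d, starts_unit, lo, up, idx, template):
    best_fun = np.inf
    best_x = np.asarray(starts_unit[0], dtype=float)
    converged = False
    for x0 in starts_unit:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * d, options=_OPT_OPTIONS,
        )
        fun = float(res.fun) if np.isfinite(res.fun) else np.inf
        if fun < best_fun:
            best_fun, best_x = fun, res.x
            converged = bool(res.success)
    theta = template.copy()
    theta[idx] = lo + best_x * (up - lo)
    return theta, best_fun, converged and np.isfinite(best_fun)


def _fit(
    dataset: Dataset,
    model: ModelSpec,
    space: ParameterSpace,
    noise: NoiseSpec,
    pinned: Mapping[str, float],
    n_starts: int,
    rng: np.random.Generator,
    warm: Sequence[np.ndarray] = (),
) -> FitResult:
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    free = [nm for nm in space.free_names if nm not in pinned]
    template = space.template()
    for nm, val in pinned.items():
        lo_b, up_b = space.bounds(nm)
        if not (lo_b <= val <= up_b):
            raise ValueError(f"pinned value for {nm!r} outside its bounds")
        template[space.index(nm)] = val
    idx = np.array([space.index(nm) for nm in free], dtype=int)
    if idx.size == 0:
        nll = negative_log_likelihood(dataset, template, model, noise)
        return FitResult(template, float(nll), np.isfinite(nll), 0)
    lo = np.array([space.bounds(nm)[0] for nm in free])
    up = np.array([space.bounds(nm)[1] for nm in free])
    span = up - lo

    def objective(x_unit: np.ndarray) -> float:
        theta = template.copy()
        theta[idx] = lo + x_unit * span
        return negative_log_likelihood(dataset, theta, model, noise)

    starts = [np.clip((np.asarray(w, float)[idx] - lo) / span, 0.0, 1.0) for w in warm]
    n_lhs = n_starts - len(starts)
    if n_lhs > 0:
        sampler = qmc.LatinHypercube(d=idx.size, seed=rng)
        starts.extend(sampler.random(n_lhs))
    theta, nll, converged = _run_multistart(objective, idx.size, starts, lo, up, idx, template)
    return FitResult(theta, nll, converged, len(starts))


def fit_mle(
    dataset: Dataset,
    model: ModelSpec,
    space: ParameterSpace,
    noise: NoiseSpec,
    n_starts: int = 10,
    rng: np.random.Generator | None = None,
    warm: Sequence[np.ndarray] = (),
) -> FitResult:
    """Best-of-starts box-constrained MLE over the free parameters."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return _fit(dataset, model, space, noise, {}, n_starts, rng, warm)


def fit_with_fixed(
    dataset: Dataset,
    model: ModelSpec,
    space: ParameterSpace,
    noise: NoiseSpec,
    param: str,
    value: float,
    n_starts: int = 10,
    rng: np.random.Generator | None = None,
    warm: Sequence[np.ndarray] = (),
) -> FitResult:
    """Profile fit: pin ``param`` at ``value`` and re-optimise the rest."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return _fit(dataset, model, space, noise, {param: value}, n_starts, rng, warm)


# ---------------------------------------------------------------------------
# Candidate set
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CandidateSet:
    """MLE model plus the 2N profile-boundary models with simplex weights.

    ``boundary`` maps ``(param, side)`` with ``side in {"lower", "upper"}``
    to the corresponding constrained fit; ``weights`` is aligned with
    ``members`` (MLE first, then bounds in free-parameter order).
    """

    mle: FitResult
    boundary: Mapping[tuple[str, str], FitResult]
    weights: np.ndarray

    @property
    def m(self) -> int:
        return 1 + len(self.boundary)

    @property
    def members(self) -> list[FitResult]:
        return [self.mle, *self.boundary.values()]

    def pl_bounds(self, param: str) -> tuple[float, float]:
        """Profile negative log-likelihood at the lower/upper bound."""
        return (self.boundary[(param, "lower")].nll,
                self.boundary[(param, "upper")].nll)


def _normalized_weights(nlls: np.ndarray) -> np.ndarray:
    # exp(-nll) normalized in the log domain; +inf members get weight 0.
    finite = np.isfinite(nlls)
    if not finite.any():
        return np.full(nlls.shape, 1.0 / nlls.size)
    z = np.where(finite, -(nlls - nlls[finite].min()), -np.inf)
    w = np.exp(z)
    return w / w.sum()


def build_candidate_set(
    dataset: Dataset,
    model: ModelSpec,
    space: ParameterSpace,
    noise: NoiseSpec,
    n_starts: int = 10,
    n_starts_profile: int = 3,
    rng: np.random.Generator | None = None,
    previous: CandidateSet | None = None,
) -> CandidateSet:
    """Fit the MLE and the 2N boundary models and weight them by likelihood.

    The MLE warm-starts from the previous iteration's MLE, boundary fits from
    the MLE and the previous fit at the same bound (profile continuity).
    """
    if dataset.n == 0:
        raise ValueError("candidate set requires a nonempty dataset")
    rng = rng if rng is not None else np.random.default_rng(0)
    warm_mle = [previous.mle.theta] if previous is not None else []
    mle = fit_mle(dataset, model, space, noise, n_starts, rng, warm=warm_mle)
    boundary: dict[tuple[str, str], FitResult] = {}
    for nm in space.free_names:
        lo, up = space.bounds(nm)
        for side, value in (("lower", lo), ("upper", up)):
            warm = [mle.theta]
            if previous is not None:
                warm.append(previous.boundary[(nm, side)].theta)
            boundary[(nm, side)] = fit_with_fixed(
                dataset, model, space, noise, nm, value,
                n_starts_profile, rng, warm=warm,
            )
    nlls = np.array([mle.nll, *(f.nll for f in boundary.values())])
    return CandidateSet(mle=mle, boundary=boundary, weights=_normalized_weights(nlls))
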