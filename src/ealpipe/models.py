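"""Deterministic forward models and the parameter-space container.

Two model families are provided:

* ``sum_of_exponentials`` — the analytic two-component decay
  ``y(t) = exp(-beta1 t) + exp(-beta2 t)``, a classic example of a model whose
  parameters are only practically identifiable once enough well-placed time
  points are observed.
* ``microbial_growth_{1out,2out}`` — a Monod-kinetics bioreactor with states
  bacterial growth BG (g/L) and substrate concentration SC (g/L)::

      d(BG)/dt = muMax * SC/(KS + SC) * BG - KD * BG
      d(SC)/dt = -(1/YieldC) * muMax * SC/(KS + SC) * BG

  with BG(0) = 1 g/L and SC(0) = 30 g/L.  The one-output variant observes BG
  only; the two-output variant observes both states.

Forward maps are deterministic functions ``(theta, times) -> (M, T)`` of the
full parameter vector and a nondecreasing time grid (hours).  User models can
be added through :func:`register_model`.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping

import numba
import numpy as np

__all__ = [
    "IntegrationError",
    "ParameterSpace",
    "ModelSpec",
    "sum_of_exponentials",
    "microbial_growth",
    "register_model",
    "get_model",
    "list_models",
]


class IntegrationError(RuntimeError):
    """Numerical integration of a forward model failed.

    Raised on step-size collapse or when the step budget is exhausted.
    Callers treat the corresponding parameter vector as an infinitely bad fit.
    """


@dataclasses.dataclass(frozen=True)
class ParameterSpace:
    """Box-bounded parameter space with fixed parameters and a ground truth.

    Parameters
    ----------
    names
        Ordered parameter identifiers.
    lower, upper
        Per-parameter search bounds, aligned with ``names`` (model units).
    truth
        Full ground-truth vector used by the simulator, aligned with
        ``names``.  Free entries must lie strictly inside the box.
    fixed
        Mapping of parameter name to its pinned value.  Fixed parameters are
        excluded from estimation and from identifiability analysis.
    """

    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    truth: tuple[float, ...]
    fixed: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.names)
        if not (len(self.lower) == len(self.upper) == len(self.truth) == k):
            raise ValueError("names, lower, upper and truth must be aligned")
        for nm in self.fixed:
            if nm not in self.names:
                raise ValueError(f"fixed parameter {nm!r} not in names")
        for i, nm in enumerate(self.names):
            if nm in self.fixed:
                continue
            if not self.lower[i] < self.upper[i]:
                raise ValueError(f"empty bound interval for {nm!r}")
            if not (self.lower[i] < self.truth[i] < self.upper[i]):
                raise ValueError(f"truth for {nm!r} not strictly inside the box")

    # -- derived views ----------------------------------------------------
    @property
    def N(self) -> int:
        """Number of free parameters."""
        return len(self.names) - len(self.fixed)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(nm for nm in self.names if nm not in self.fixed)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def bounds(self, name: str) -> tuple[float, float]:
        i = self.index(name)
        return float(self.lower[i]), float(self.upper[i])

    def box_width(self, name: str) -> float:
        lo, up = self.bounds(name)
        return up - lo

    @property
    def truth_vector(self) -> np.ndarray:
        v = np.array(self.truth, dtype=float)
        for nm, val in self.fixed.items():
            v[self.index(nm)] = val
        return v

    def template(self) -> np.ndarray:
        """Full vector with fixed entries filled in and free entries at truth.

        Free entries are placeholders only; estimation overwrites them.
        """
        return self.truth_vector


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A deterministic forward model.

    ``forward(theta, times)`` maps a full parameter vector and a
    nondecreasing time grid to an ``(M, T)`` matrix of noise-free outputs.
    """

    id: str
    output_names: tuple[str, ...]
    initial_conditions: tuple[float, ...]
    forward: Callable[[np.ndarray, np.ndarray], np.ndarray]

    @property
    def n_outputs(self) -> int:
        return len(self.output_names)


# ---------------------------------------------------------------------------
# Sum of two exponentials
# ---------------------------------------------------------------------------

def sum_of_exponentials(theta: np.ndarray, times: np.ndarray) -> np.ndarray:
    """``y(t) = exp(-beta1 t) + exp(-beta2 t)`` as a ``(1, T)`` trajectory."""
    t = np.asarray(times, dtype=float)
    th = np.asarray(theta, dtype=float)
    with np.errstate(over="ignore"):
        y = np.exp(-th[0] * t) + np.exp(-th[1] * t)
    return y[None, :]


# ---------------------------------------------------------------------------
# Monod microbial growth model
# ---------------------------------------------------------------------------

_RTOL_DEFAULT = 1e-8
_ATOL_DEFAULT = 1e-10
_MAX_STEPS = 1_000_000


@numba.njit(cache=True)
def _monod_rhs(bg: float, sc: float, mu: float, ks: float, kd: float, yc: float):
    # Clip tiny negative substrate excursions inside the Monod term only;
    # they are integrator noise, not model behaviour.
    scp = sc if sc > 0.0 else 0.0
    g = mu * scp / (ks + scp) * bg
    return g - kd * bg, -g / yc


@numba.njit(cache=True)
def _monod_rk45(theta, times, rtol, atol, max_steps):  # pragma: no cover - jitted
    """Adaptive Dormand-Prince 5(4) integration hitting each output time.

    Returns a (2, T) array of (BG, SC); all-NaN on failure.
    """
    mu, ks, kd, yc = theta[0], theta[1], theta[2], theta[3]
    nt = times.shape[0]
    out = np.empty((2, nt))
    t = 0.0
    bg, sc = 1.0, 30.0
    h = 1e-3
    k1b, k1s = _monod_rhs(bg, sc, mu, ks, kd, yc)
    steps = 0
    for i in range(nt):
        tend = times[i]
        while t < tend:
            if steps > max_steps:
                out[:] = np.nan
                return out
            steps += 1
            if h > tend - t:
                h = tend - t
            k2b, k2s = _monod_rhs(bg + h * 0.2 * k1b, sc + h * 0.2 * k1s, mu, ks, kd, yc)
            k3b, k3s = _monod_rhs(
                bg + h * (3.0 / 40.0 * k1b + 9.0 / 40.0 * k2b),
                sc + h * (3.0 / 40.0 * k1s + 9.0 / 40.0 * k2s), mu, ks, kd, yc)
            k4b, k4s = _monod_rhs(
                bg + h * (44.0 / 45.0 * k1b - 56.0 / 15.0 * k2b + 32.0 / 9.0 * k3b),
                sc + h * (44.0 / 45.0 * k1s - 56.0 / 15.0 * k2s + 32.0 / 9.0 * k3s),
                mu, ks, kd, yc)
            k5b, k5s = _monod_rhs(
                bg + h * (19372.0 / 6561.0 * k1b - 25360.0 / 2187.0 * k2b
                          + 64448.0 / 6561.0 * k3b - 212.0 / 729.0 * k4b),
                sc + h * (19372.0 / 6561.0 * k1s - 25360.0 / 2187.0 * k2s
                          + 64448.0 / 6561.0 * k3s - 212.0 / 729.0 * k4s),
                mu, ks, kd, yc)
            k6b, k6s = _monod_rhs(
                bg + h * (9017.0 / 3168.0 * k1b - 355.0 / 33.0 * k2b
                          + 46732.0 / 5247.0 * k3b + 49.0 / 176.0 * k4b
                          - 5103.0 / 18656.0 * k5b),
                sc + h * (9017.0 / 3168.0 * k1s - 355.0 / 33.0 * k2s
                          + 46732.0 / 5247.0 * k3s + 49.0 / 176.0 * k4s
                          - 5103.0 / 18656.0 * k5s),
                mu, ks, kd, yc)
            nb = bg + h * (35.0 / 384.0 * k1b + 500.0 / 1113.0 * k3b
                           + 125.0 / 192.0 * k4b - 2187.0 / 6784.0 * k5b
                           + 11.0 / 84.0 * k6b)
            ns = sc + h * (35.0 / 384.0 * k1s + 500.0 / 1113.0 * k3s
                           + 125.0 / 192.0 * k4s - 2187.0 / 6784.0 * k5s
                           + 11.0 / 84.0 * k6s)
            k7b, k7s = _monod_rhs(nb, ns, mu, ks, kd, yc)
            eb = h * ((35.0 / 384.0 - 5179.0 / 57600.0) * k1b
                      + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3b
                      + (125.0 / 192.0 - 393.0 / 640.0) * k4b
                      + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5b
                      + (11.0 / 84.0 - 187.0 / 2100.0) * k6b
                      - 1.0 / 40.0 * k7b)
            es = h * ((35.0 / 384.0 - 5179.0 / 57600.0) * k1s
                      + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3s
                      + (125.0 / 192.0 - 393.0 / 640.0) * k4s
                      + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5s
                      + (11.0 / 84.0 - 187.0 / 2100.0) * k6s
                      - 1.0 / 40.0 * k7s)
            sb = atol + rtol * max(abs(bg), abs(nb))
            ss = atol + rtol * max(abs(sc), abs(ns))
            err = math.sqrt(0.5 * ((eb / sb) ** 2 + (es / ss) ** 2))
            if err <= 1.0:
                t += h
                bg, sc = nb, ns
                k1b, k1s = k7b, k7s
                fac = 5.0 if err == 0.0 else min(5.0, 0.9 * err ** -0.2)
            else:
                fac = max(0.2, 0.9 * err ** -0.2)
            h = h * fac
            if h < 1e-13:
                out[:] = np.nan
                return out
        out[0, i] = bg
        out[1, i] = sc
    return out


def microbial_growth(
    theta: np.ndarray,
    times: np.ndarray,
    *,
    outputs: str = "both",
    rtol: float = _RTOL_DEFAULT,
    atol: float = _ATOL_DEFAULT,
) -> np.ndarray:
    """Integrate the Monod bioreactor model.

    Parameters
    ----------
    theta
        Full parameter vector ``(muMax, KS, KD, YieldC)``.
    times
        Nondecreasing sample times in hours (t >= 0).
    outputs
        ``"both"`` for the (BG, SC) trajectory, ``"bg"`` for BG only.

    Raises
    ------
    IntegrationError
        If the adaptive integrator collapses its step size or exhausts its
        step budget inside the requested interval.
    """
    t = np.ascontiguousarray(times, dtype=float)
    if t.size and (t[0] < 0 or np.any(np.diff(t) < 0)):
        raise ValueError("times must be nonnegative and nondecreasing")
    th = np.ascontiguousarray(theta, dtype=float)
    traj = _monod_rk45(th, t, rtol, atol, _MAX_STEPS)
    if not np.all(np.isfinite(traj)):
        raise IntegrationError(f"ODE integration failed for theta={th.tolist()}")
    if outputs == "bg":
        return traj[:1]
    return traj


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, ModelSpec] = {}


def register_model(spec: ModelSpec, *, overwrite: bool = False) -> None:
    """Register a user model under its string id for config-driven lookup."""
    if spec.id in _REGISTRY and not overwrite:
        raise ValueError(f"model id {spec.id!r} already registered")
    _REGISTRY[spec.id] = spec


def get_model(model_id: str) -> ModelSpec:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id!r}; known: {sorted(_REGISTRY)}"
        ) from None


def list_models() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


register_model(ModelSpec(
    id="sum_of_exponentials",
    output_names=("y",),
    initial_conditions=(1.0, 1.0),
    forward=sum_of_exponentials,
))
register_model(ModelSpec(
    id="microbial_growth_1out",
    output_names=("BG",),
    initial_conditions=(1.0, 30.0),
    forward=lambda theta, times: microbial_growth(theta, times, outputs="bg"),
))
register_model(ModelSpec(
    id="microbial_growth_2out",
    output_names=("BG", "SC"),
    initial_conditions=(1.0, 30.0),
    forward=lambda theta, times: microbial_growth(theta, times, outputs="both"),
))
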