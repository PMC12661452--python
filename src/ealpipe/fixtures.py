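"""Deterministic toy-data generators used throughout the test suite.

Everything here is regenerable from stated parameters and seeds; no files
are read or downloaded.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .estimation import Dataset
from .models import ModelSpec

__all__ = [
    "make_noisefree_dataset",
    "make_noisy_dataset",
    "make_quadratic_profile_surrogate",
]


def make_noisefree_dataset(
    model: ModelSpec, truth: np.ndarray, times: Sequence[float]
) -> Dataset:
    """Observations equal to the true trajectory (the sigma -> 0 pathway)."""
    t = np.asarray(times, dtype=float)
    f = model.forward(np.asarray(truth, float), t)  # (M, T)
    return Dataset(t, f.T)


def make_noisy_dataset(
    model: ModelSpec, truth: np.ndarray, times: Sequence[float],
    sigma: Sequence[float], seed: int,
) -> Dataset:
    """Truncated-normal noisy observations from the true model, seeded."""
    from .noise import sample_observation

    t = np.asarray(times, dtype=float)
    f = model.forward(np.asarray(truth, float), t)  # (M, T)
    rng = np.random.default_rng(seed)
    y = sample_observation(f, np.asarray(sigma, float)[:, None], rng)
    return Dataset(t, y.T)


def make_quadratic_profile_surrogate(
    center: float, curvature: float, box: tuple[float, float]
) -> tuple[Callable[[float], float], tuple[float, float]]:
    """Analytic profile ``nll(v) = curvature * (v - center)^2`` on a box.

    Its threshold crossings at offset ``c`` above the minimum are the closed
    form ``center +/- sqrt(c / curvature)`` — the oracle for the bisection
    search.  Returns ``(profile, box)``.
    """
    if curvature <= 0:
        raise ValueError("curvature must be positive")
    lo, up = box
    if not lo < center < up:
        raise ValueError("center must lie inside the box")

    def profile(v: float) -> float:
        return curvature * (v - center) ** 2

    return profile, (float(lo), float(up))
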