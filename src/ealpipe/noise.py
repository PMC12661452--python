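"""Lower-truncated normal observation noise.

Observations are modelled as ``y = f + e`` where ``f >= 0`` is the noise-free
model output and the additive error ``e ~ N(0, sigma^2)`` is truncated below
at ``-f`` so that ``y >= 0`` almost surely.  Equivalently, ``y`` follows a
normal distribution with location ``f`` and scale ``sigma`` truncated to
``[0, inf)``:

    p(y) = phi((y - f)/sigma) / (sigma * Phi(f/sigma)),   y >= 0.

Because the truncation point moves with the mean, the observation variance
shrinks below ``sigma^2`` as ``f`` approaches zero; acquisition scores use
this predicted variance for signal-to-noise scaling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import special

__all__ = [
    "NoiseSpec",
    "sample_observation",
    "log_density",
    "predicted_noise_variance",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Per-output noise standard deviations (output units).

    The truncation rule — additive error truncated below so that observations
    stay non-negative — is part of the model and not configurable.
    """

    sigma: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sigma) == 0 or any(s <= 0 for s in self.sigma):
            raise ValueError("sigma must be positive for every output")

    @property
    def sigma_vector(self) -> np.ndarray:
        return np.array(self.sigma, dtype=float)


def _norm_logpdf(z: np.ndarray) -> np.ndarray:
    return -0.5 * z * z - _LOG_SQRT_2PI


def sample_observation(
    f: np.ndarray, sigma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``y = f + e`` with ``e ~ N(0, sigma^2)`` conditioned on ``e >= -f``.

    Sampling is by inverse-CDF so that a given generator state yields a
    reproducible draw.  ``f`` must be non-negative.
    """
    f = np.asarray(f, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), f.shape)
    if np.any(f < 0):
        raise ValueError("noise-free output f must be non-negative")
    a = special.ndtr(-f / sigma)  # probability mass below the truncation point
    u = rng.random(f.shape)
    y = f + sigma * special.ndtri(a + u * (1.0 - a))
    return np.maximum(y, 0.0)


def log_density(y: np.ndarray, f: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log-density of the truncated observation model, ``-inf`` for ``y < 0``.

    Stable for large ``f/sigma`` through ``scipy.special.log_ndtr``.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    out = (
        _norm_logpdf((y - f) / sigma)
        - np.log(sigma)
        - special.log_ndtr(f / sigma)
    )
    return np.where(y >= 0, out, -np.inf)


def predicted_noise_variance(f: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Variance of an observation with noise-free mean ``f``.

    Closed form for a normal truncated below at ``alpha = -f/sigma`` standard
    units: ``sigma^2 * (1 + alpha*lambda - lambda^2)`` with hazard
    ``lambda = phi(alpha) / (1 - Phi(alpha))``.  Monotone nondecreasing in
    ``f`` and bounded above by ``sigma^2``; equals ``sigma^2 * (1 - 2/pi)``
    (the half-normal variance) at ``f = 0``.
    """
    f = np.asarray(f, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    alpha = -f / sigma
    # 1 - Phi(alpha) = Phi(-alpha) >= 1/2 here, so the ratio is stable.
    lam = np.exp(_norm_logpdf(alpha) - special.log_ndtr(-alpha))
    return sigma**2 * (1.0 + alpha * lam - lam**2)
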