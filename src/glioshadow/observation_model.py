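"""Synthetic MR observations of tumor cell density.

An observation is an idealised contrast-enhancement image: per voxel, the
total tumor cell density as a fraction of carrying capacity plus additive
uniform noise, clamped to [0, 1]:

    h(x) = max{0, min[1, u(x, t)/T_max + η(x)]},   η ~ U[−b, +b] i.i.d.

with noise bound b = 0.1 by default.  Ensemble members predict their own
observation using their *own* carrying capacity T_max^k.  Predicted
observations are noise-free by default, as is standard for square-root
ensemble filters where observation noise enters only through the error
covariance R; a ``literal`` mode adds a fresh η draw to each member's
prediction for fidelity experiments.

The filter's observation-error model is a Gaussian diagonal R whose
per-voxel variance equals that of the uniform noise, Var(U[−b, b]) = b²/3
(1/300 at the default bound) — a documented Gaussian approximation to the
actually-uniform truth noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tumor_models import TumorState


@dataclass
class Observation:
    """Per-voxel enhancement fractions in [0, 1] at one time."""

    values: np.ndarray
    mask: np.ndarray
    t: float = 0.0
    noise_bound: float = 0.1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a shape")
        inside = self.values[self.mask]
        if inside.size and (inside.min() < 0 or inside.max() > 1):
            raise ValueError("observed values must lie in [0, 1]")


@dataclass(frozen=True)
class ObsErrorModel:
    """Diagonal observation-error covariance (same variance per voxel)."""

    variance: float
    noise_bound: float

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("variance must be positive")


def build_R(mask: np.ndarray | None = None, noise_bound: float = 0.1) -> ObsErrorModel:
    """Observation-error model for uniform noise on [−b, +b].

    The per-voxel variance is (2b)²/12 = b²/3, independent of how many
    voxels are observed.
    """
    if noise_bound <= 0:
        raise ValueError("noise_bound must be positive")
    return ObsErrorModel(variance=noise_bound**2 / 3.0, noise_bound=noise_bound)


def synth_observe(
    total_density: np.ndarray,
    T_max: float,
    rng: np.random.Generator,
    noise_bound: float = 0.1,
    mask: np.ndarray | None = None,
    t: float = 0.0,
) -> Observation:
    """Generate a noisy synthetic MR image from a truth density field.

    Every voxel in ``mask`` (default: all voxels) is observed.  The result
    is deterministic for a fixed generator state.
    """
    total_density = np.asarray(total_density, dtype=float)
    if T_max <= 0:
        raise ValueError("T_max must be positive")
    if (total_density < 0).any():
        raise ValueError("total_density must be non-negative")
    if mask is None:
        mask = np.ones(total_density.shape, dtype=bool)
    eta = rng.uniform(-noise_bound, noise_bound, size=total_density.shape)
    values = np.clip(total_density / T_max + eta, 0.0, 1.0)
    values[~mask] = 0.0
    return Observation(values=values, mask=mask, t=t, noise_bound=noise_bound)


def predicted_observation(
    member_state: TumorState,
    member_T_max: float,
    mode: str = "noise_free",
    rng: np.random.Generator | None = None,
    noise_bound: float = 0.1,
) -> np.ndarray:
    """Predicted enhancement image for one ensemble member.

    Total density (g, or g+m) divided by the member's own carrying
    capacity, clamped to [0, 1].  In ``perturbed`` mode an independent
    uniform η is added before clamping.
    """
    if member_T_max <= 0:
        raise ValueError("member_T_max must be positive")
    frac = member_state.total() / member_T_max
    if mode == "perturbed":
        if rng is None:
            raise ValueError("perturbed mode needs an rng")
        frac = frac + rng.uniform(-noise_bound, noise_bound, size=frac.shape)
    elif mode != "noise_free":
        raise ValueError(f"unknown mode {mode!r}")
    return np.clip(frac, 0.0, 1.0)
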