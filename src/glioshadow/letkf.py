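"""The Local Ensemble Transform Kalman Filter (LETKF).

Each grid point is updated independently using only the observations in a
small square region centred on it.  The analysis is computed in the
k-dimensional ensemble subspace: with background perturbations X_b and
predicted-observation perturbations Y_b, the local update is

    C     = Y_bᵀ R⁻¹
    P̃_a   = [(k−1) I / ρ + C Y_b]⁻¹
    W̃_a   = [(k−1) P̃_a]^{1/2}          (symmetric square root)
    w̄_a   = P̃_a C (y_o − ȳ_b)
    W_a   = W̃_a + w̄_a 1ᵀ
    x_a^i = x̄_b + (X_b W_a)_i

w̄_a minimises the ensemble-space cost function
J*(w) = (k−1)wᵀw/ρ + (y_o − ȳ_b − Y_b w)ᵀ R⁻¹ (y_o − ȳ_b − Y_b w).
The multiplicative factor ρ rescales the background covariance; note that
with the formula above, ρ < 1 *contracts* the analysis
perturbations by √ρ in observation-free regions.  The symmetric square
root makes the analysis depend continuously on P̃_a, which keeps
neighbouring local analyses consistent.

A textbook linear Kalman filter (:func:`kf_reference`) is included purely
as an equivalence oracle for tests: with a single global region, ρ = 1,
and a linear model, the LETKF analysis mean and covariance must match it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage

from .errors import ConditioningError, FilterError
from .observation_model import Observation, ObsErrorModel

_EIG_FLOOR = 1e-12


@dataclass(frozen=True)
class LETKFConfig:
    """Filter configuration.

    ``local_halfwidth`` of 3 gives the 7×7-voxel (7 mm × 7 mm at 1-mm
    spacing) local regions; ``rho_inflation`` enters as (k−1)I/ρ in the
    ensemble-space precision.
    """

    k: int = 50
    local_halfwidth: int = 3
    rho_inflation: float = 0.1
    min_local_obs: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("ensemble size k must be at least 2")
        if self.local_halfwidth < 0:
            raise ValueError("local_halfwidth must be non-negative")
        if self.rho_inflation <= 0:
            raise ValueError("rho_inflation must be positive")


@dataclass
class LocalProblem:
    """One local analysis problem.

    ``Xb`` is m×k (state perturbations), ``Yb`` is ℓ×k (predicted-
    observation perturbations); both have zero row-sums by construction.
    ``r_diag`` is the diagonal of R (fast path); a full ``R`` matrix may
    be given instead for correlated observation errors.
    """

    Xb: np.ndarray
    xb_mean: np.ndarray
    Yb: np.ndarray
    yb_mean: np.ndarray
    yo: np.ndarray
    r_diag: np.ndarray | None = None
    R: np.ndarray | None = None

    @classmethod
    def from_ensemble(cls, X: np.ndarray, Y: np.ndarray, yo: np.ndarray, r_diag):
        """Build a problem from raw member columns (m×k and ℓ×k)."""
        xb_mean = X.mean(axis=1)
        yb_mean = Y.mean(axis=1)
        return cls(
            Xb=X - xb_mean[:, None],
            xb_mean=xb_mean,
            Yb=Y - yb_mean[:, None],
            yb_mean=yb_mean,
            yo=np.asarray(yo, dtype=float),
            r_diag=np.broadcast_to(np.asarray(r_diag, dtype=float), yo.shape).copy(),
        )


@dataclass
class WeightSolution:
    """Ensemble-space weights of one local analysis."""

    Wa_sym: np.ndarray
    wa_mean: np.ndarray
    Wa: np.ndarray


def local_indices(
    domain_shape: tuple[int, int], center: tuple[int, int], halfwidth: int
) -> tuple[slice, slice]:
    """Index window of the square local region, truncated at the domain
    boundary.  Returned as a pair of slices; the centre is always inside."""
    r, c = center
    nr, nc = domain_shape
    if not (0 <= r < nr and 0 <= c < nc):
        raise ValueError(f"center {center} outside domain {domain_shape}")
    return (
        slice(max(r - halfwidth, 0), min(r + halfwidth + 1, nr)),
        slice(max(c - halfwidth, 0), min(c + halfwidth + 1, nc)),
    )


def solve_weights(problem: LocalProblem, rho_inflation: float = 1.0) -> WeightSolution:
    """Solve one local analysis for its ensemble-space weights.

    With no local observations (ℓ = 0) the analysis preserves the
    background mean and scales the perturbations by √ρ.
    """
    k = problem.Xb.shape[1]
    ell = problem.yo.shape[0]
    if ell == 0:
        Wa_sym = np.sqrt(rho_inflation) * np.eye(k)
        wa = np.zeros(k)
        return WeightSolution(Wa_sym, wa, Wa_sym + wa[:, None])

    Yb = problem.Yb
    if not (np.isfinite(Yb).all() and np.isfinite(problem.yo).all()):
        raise ConditioningError("non-finite values in local problem")
    # C = Yb^T R^{-1}; diagonal fast path, else solve R C^T = Yb
    if problem.r_diag is not None:
        C = (Yb / problem.r_diag[:, None]).T
    elif problem.R is not None:
        C = linalg.solve(problem.R, Yb, assume_a="pos").T
    else:
        raise ValueError("LocalProblem needs r_diag or R")

    A = ((k - 1) / rho_inflation) * np.eye(k) + C @ Yb
    evals, vecs = linalg.eigh(A)
    if evals[-1] <= 0 or evals[0] <= _EIG_FLOOR * evals[-1]:
        raise ConditioningError(
            f"ensemble-space precision matrix is singular (eigenvalues {evals[0]:.3e}"
            f"..{evals[-1]:.3e})"
        )
    inv_evals = 1.0 / evals
    Pa = (vecs * inv_evals) @ vecs.T                       # P̃_a
    Wa_sym = (vecs * np.sqrt((k - 1) * inv_evals)) @ vecs.T
    wa = Pa @ (C @ (problem.yo - problem.yb_mean))
    return WeightSolution(Wa_sym, wa, Wa_sym + wa[:, None])


def apply_weights(problem: LocalProblem, solution: WeightSolution) -> np.ndarray:
    """Analysis ensemble columns at the centre voxel: x̄_b + X_b W_a."""
    return problem.xb_mean[:, None] + problem.Xb @ solution.Wa


def letkf_global(
    ensemble_fields: np.ndarray,
    predicted: np.ndarray,
    observation: Observation,
    obs_error: ObsErrorModel,
    config: LETKFConfig,
    brain_mask: np.ndarray,
    var_bounds: tuple = ((0.0, None),),
    voxel_order: np.ndarray | None = None,
) -> np.ndarray:
    """Global analysis: one local solve per brain-mask voxel.

    Parameters
    ----------
    ensemble_fields : ndarray, shape (k, n_vars, rows, cols)
        Background member states (e.g. n_vars = 1 for the one-field model,
        3 for (g, m, w)).
    predicted : ndarray, shape (k, rows, cols)
        Noise-free predicted observation per member (each member uses its
        own carrying capacity).
    observation, obs_error
        The image being assimilated and its diagonal error model.
    var_bounds
        Per-variable (lo, hi) clamps applied to the analysis (densities
        are non-negative; the ECM field is clipped to [0, 1]).
    voxel_order
        Optional (n, 2) array of brain voxels to process, in any order —
        the analysis is independent of processing order because every
        local solve reads only the background.

    Returns the analysis ensemble with the same shape as
    ``ensemble_fields``; non-brain voxels are untouched.
    """
    ensemble_fields = np.asarray(ensemble_fields, dtype=float)
    k, n_vars = ensemble_fields.shape[:2]
    if k != config.k:
        raise ValueError(f"ensemble has {k} members but config.k = {config.k}")
    if len(var_bounds) != n_vars:
        raise ValueError("var_bounds must give one (lo, hi) pair per variable")
    shape = ensemble_fields.shape[2:]
    obs_ok = observation.mask & brain_mask
    rho = config.rho_inflation
    sqrt_rho = np.sqrt(rho)

    analysis = ensemble_fields.copy()
    if voxel_order is None:
        voxel_order = np.argwhere(brain_mask)
    process = np.zeros(shape, dtype=bool)
    process[voxel_order[:, 0], voxel_order[:, 1]] = True

    # Voxels whose local window holds no observation with any ensemble
    # spread reduce exactly to the filter's no-information limit
    # (mean preserved, perturbations scaled by sqrt(rho)); handle them
    # vectorised and loop only where the local solve has signal.
    spread = np.abs(predicted - predicted.mean(axis=0)).max(axis=0)
    spread[~obs_ok] = 0.0
    window = 2 * config.local_halfwidth + 1
    local_signal = ndimage.maximum_filter(spread, size=window, mode="constant") > 1e-14
    if config.min_local_obs > 0:
        n_local = ndimage.uniform_filter(
            obs_ok.astype(float), size=window, mode="constant"
        ) * window**2
        local_signal &= n_local >= config.min_local_obs - 0.5
    trivial = process & ~local_signal
    if trivial.any():
        mean = ensemble_fields.mean(axis=0, keepdims=True)
        analysis[:, :, trivial] = (
            mean[:, :, trivial]
            + sqrt_rho * (ensemble_fields[:, :, trivial] - mean[:, :, trivial])
        )
        for v, (lo, hi) in enumerate(var_bounds):
            analysis[:, v, trivial] = np.clip(analysis[:, v, trivial], lo, hi)

    for r, c in voxel_order:
        if not local_signal[r, c]:
            continue
        rs, cs = local_indices(shape, (r, c), config.local_halfwidth)
        sel = obs_ok[rs, cs].ravel()
        Xb_cols = ensemble_fields[:, :, r, c].T            # n_vars × k
        xb_mean = Xb_cols.mean(axis=1)
        Xp = Xb_cols - xb_mean[:, None]
        Y_cols = predicted[:, rs, cs].reshape(k, -1)[:, sel].T   # ℓ × k
        ell = Y_cols.shape[0]
        if ell < max(config.min_local_obs, 1) or np.abs(
            Y_cols - Y_cols.mean(axis=1, keepdims=True)
        ).max() < 1e-14:
            # no observations (or no ensemble signal) after selection
            xa = xb_mean[:, None] + sqrt_rho * Xp
        else:
            yb_mean = Y_cols.mean(axis=1)
            problem = LocalProblem(
                Xb=Xp,
                xb_mean=xb_mean,
                Yb=Y_cols - yb_mean[:, None],
                yb_mean=yb_mean,
                yo=observation.values[rs, cs].ravel()[sel],
                r_diag=np.full(ell, obs_error.variance),
            )
            try:
                xa = apply_weights(problem, solve_weights(problem, rho))
            except ConditioningError as exc:
                raise FilterError((r, c), f"voxel ({r}, {c}): {exc}") from exc
        for v, (lo, hi) in enumerate(var_bounds):
            analysis[:, v, r, c] = np.clip(xa[v], lo, hi)
    return analysis


# ---------------------------------------------------------------------------
# linear Kalman filter reference (test oracle)

@dataclass
class KFState:
    """Linear-Gaussian system for the exact Kalman recursion."""

    u_mean: np.ndarray
    P: np.ndarray
    M: np.ndarray
    H: np.ndarray
    C_model: np.ndarray
    R: np.ndarray


def kf_reference(kf: KFState, observations) -> list[tuple[np.ndarray, np.ndarray]]:
    """Exact linear Kalman filter recursion.

    For each observation vector y:  forecast  ū_b = M ū_a,
    P_b = M P_a Mᵀ + C;  update  P_a = (I + P_b Hᵀ R⁻¹ H)⁻¹ P_b,
    ū_a = ū_b + P_a Hᵀ R⁻¹ (y − H ū_b).  Returns the sequence of
    (analysis mean, analysis covariance).
    """
    ua, Pa = np.asarray(kf.u_mean, float).copy(), np.asarray(kf.P, float).copy()
    M, H, C, R = (np.asarray(a, float) for a in (kf.M, kf.H, kf.C_model, kf.R))
    HtRinv = H.T @ linalg.inv(R)
    out = []
    for y in observations:
        ub = M @ ua
        Pb = M @ Pa @ M.T + C
        S = np.eye(len(ub)) + Pb @ HtRinv @ H
        try:
            Pa = linalg.solve(S, Pb)
        except linalg.LinAlgError as exc:
            raise ConditioningError(f"singular update matrix: {exc}") from exc
        Pa = 0.5 * (Pa + Pa.T)
        ua = ub + Pa @ HtRinv @ (np.asarray(y, float) - H @ ub)
        out.append((ua.copy(), Pa.copy()))
    return out
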