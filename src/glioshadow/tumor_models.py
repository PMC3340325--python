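"""Reaction–diffusion glioblastoma growth models on a labeled tissue grid.

Two models are provided.  The *logistic Swanson* model tracks a single
cell-density field g(x, t) (cells·mm⁻² in 2-D):

    ∂g/∂t = ∇·(D(x)∇g) + α g (1 − g/T_max)

The *two-phenotype* model splits the population into proliferating (g) and
migrating (m) cells and couples them to the extracellular matrix density
w ∈ [0, 1]:

    ∂g/∂t = ∇·(D_G∇g) + α g (1 − (g+m)/T_max) − ∇·(χ g ∇w)
    ∂m/∂t = ∇·(D_M∇m) + ∇·(χ g ∇w)
    ∂w/∂t = −ρ_ecm w (g+m)/(θ_W + g+m) + α_W w (1 − w)

The haptotaxis term moves the same flux of cells out of the proliferating
class and into the migrating class, so it cancels identically in g + m.

Spatial derivatives use a conservative 5-point flux-form stencil with
arithmetic-mean interface coefficients and no-flux conditions across the
brain-mask boundary; time stepping is Heun's second-order
predictor–corrector with a fixed step (0.1 day by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .errors import DomainError, NumericalBlowupError
from .tissue_geometry import TissueGrid, expand_parameters

logger = logging.getLogger(__name__)

DEFAULT_DT_DAYS = 0.1


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class SwansonParams:
    """Logistic Swanson model parameters (nominal values in 2-D).

    ``D`` maps tissue class to diffusion rate in mm²·day⁻¹.
    """

    alpha: float = 0.2                     # day^-1
    T_max: float = 10_000.0                # cells mm^-2
    D: Mapping[str, float] = field(
        default_factory=lambda: {"white": 0.0065, "gray": 0.0013, "csf": 0.001}
    )

    def __post_init__(self):
        if self.alpha <= 0 or self.T_max <= 0:
            raise ValueError("alpha and T_max must be positive")
        if any(v < 0 for v in self.D.values()):
            raise ValueError("diffusion rates must be non-negative")


@dataclass(frozen=True)
class TwoPhenotypeParams:
    """Two-phenotype model parameters (nominal values in 2-D)."""

    alpha: float = 0.025                   # day^-1
    T_max: float = 10_000.0                # cells mm^-2
    alpha_W: float = 0.01                  # day^-1, ECM recovery
    rho_ecm: float = 0.02                  # day^-1, ECM remodeling
    theta_W: float = 100.0                 # cells mm^-2, half-max density
    D_G: Mapping[str, float] = field(
        default_factory=lambda: {"white": 0.002, "gray": 0.0004, "csf": 0.001}
    )
    D_M: Mapping[str, float] = field(
        default_factory=lambda: {"white": 0.10, "gray": 0.02, "csf": 0.001}
    )
    chi: Mapping[str, float] = field(
        default_factory=lambda: {"white": 0.25, "gray": 0.05, "csf": 0.0}
    )

    def __post_init__(self):
        if min(self.alpha, self.T_max, self.theta_W) <= 0:
            raise ValueError("alpha, T_max, theta_W must be positive")
        if min(self.alpha_W, self.rho_ecm) < 0:
            raise ValueError("rates must be non-negative")
        for table in (self.D_G, self.D_M, self.chi):
            if any(v < 0 for v in table.values()):
                raise ValueError("per-class coefficients must be non-negative")


# ---------------------------------------------------------------------------
# state containers

@dataclass
class TumorState:
    """Per-voxel cell-density fields at one simulation time.

    ``g`` (and ``m``) are cells·mm⁻²; ``w`` is the dimensionless ECM
    density in [0, 1].  ``m`` and ``w`` are None for the one-field model.
    """

    g: np.ndarray
    m: np.ndarray | None = None
    w: np.ndarray | None = None
    t: float = 0.0

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        if (self.m is None) != (self.w is None):
            raise ValueError("m and w must both be present or both absent")
        if self.m is not None:
            self.m = np.asarray(self.m, dtype=float)
            self.w = np.asarray(self.w, dtype=float)
            if self.m.shape != self.g.shape or self.w.shape != self.g.shape:
                raise ValueError("g, m, w must share a shape")

    @property
    def is_two_phenotype(self) -> bool:
        return self.m is not None

    def total(self) -> np.ndarray:
        """Total tumor cell density (g, or g + m)."""
        return self.g if self.m is None else self.g + self.m

    def copy(self) -> "TumorState":
        return TumorState(
            self.g.copy(),
            None if self.m is None else self.m.copy(),
            None if self.w is None else self.w.copy(),
            self.t,
        )


@dataclass
class Tendency:
    """Time derivative of a :class:`TumorState` (per day)."""

    dg: np.ndarray
    dm: np.ndarray | None = None
    dw: np.ndarray | None = None


def total_population(state: TumorState, spacing_mm: float) -> float:
    """Total cell count: density integrated over the domain."""
    return float(state.total().sum() * spacing_mm**2)


def area_above(state: TumorState, threshold: float, spacing_mm: float) -> float:
    """Area (mm²) where total density exceeds ``threshold``."""
    return float((state.total() > threshold).sum() * spacing_mm**2)


# ---------------------------------------------------------------------------
# spatial operators

def _check_shapes(*arrays):
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise DomainError(f"shape mismatch: {sorted(shapes)}")


def diffusive_flux_divergence(
    field_: np.ndarray, D: np.ndarray, mask: np.ndarray, spacing_mm: float = 1.0
) -> np.ndarray:
    """Conservative flux-form discretisation of ∇·(D(x)∇f).

    Interface diffusivity is the arithmetic mean of the two adjacent voxel
    values; fluxes across faces between a masked and an unmasked voxel are
    zero (no-flux boundary at the brain-mask edge).  The output sums to
    zero over the mask to roundoff.
    """
    field_ = np.asarray(field_, dtype=float)
    D = np.asarray(D, dtype=float)
    _check_shapes(field_, D, mask)
    h = spacing_mm
    out = np.zeros_like(field_)
    for axis in (0, 1):
        lo = tuple(slice(0, -1) if a == axis else slice(None) for a in (0, 1))
        hi = tuple(slice(1, None) if a == axis else slice(None) for a in (0, 1))
        open_face = mask[lo] & mask[hi]
        d_face = 0.5 * (D[lo] + D[hi])
        flux = np.where(open_face, d_face * (field_[hi] - field_[lo]) / h, 0.0)
        out[lo] += flux / h
        out[hi] -= flux / h
    out[~mask] = 0.0
    return out


def haptotaxis_divergence(
    g: np.ndarray,
    w: np.ndarray,
    chi: np.ndarray,
    mask: np.ndarray,
    spacing_mm: float = 1.0,
) -> np.ndarray:
    """Flux-form discretisation of ∇·(χ(x) g ∇w).

    The face flux is χ_face · g_upwind · Δw/h, with g taken from the
    upwind voxel relative to the haptotactic velocity χ∇w (cells drift up
    the ECM gradient).  Conservative in the same sense as the diffusion
    operator.
    """
    g = np.asarray(g, dtype=float)
    w = np.asarray(w, dtype=float)
    chi = np.asarray(chi, dtype=float)
    _check_shapes(g, w, chi, mask)
    h = spacing_mm
    out = np.zeros_like(g)
    for axis in (0, 1):
        lo = tuple(slice(0, -1) if a == axis else slice(None) for a in (0, 1))
        hi = tuple(slice(1, None) if a == axis else slice(None) for a in (0, 1))
        open_face = mask[lo] & mask[hi]
        v = 0.5 * (chi[lo] + chi[hi]) * (w[hi] - w[lo]) / h
        g_up = np.where(v > 0, g[lo], g[hi])
        flux = np.where(open_face, v * g_up, 0.0)
        out[lo] += flux / h
        out[hi] -= flux / h
    out[~mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# right-hand sides

def _swanson_fields(grid: TissueGrid, params: SwansonParams) -> dict:
    return {"D": expand_parameters(grid, params.D)}


def _two_phenotype_fields(grid: TissueGrid, params: TwoPhenotypeParams) -> dict:
    return {
        "D_G": expand_parameters(grid, params.D_G),
        "D_M": expand_parameters(grid, params.D_M),
        "chi": expand_parameters(grid, params.chi),
    }


def swanson_rhs(
    state: TumorState,
    params: SwansonParams,
    grid: TissueGrid,
    fields: dict | None = None,
) -> Tendency:
    """Right-hand side of the logistic Swanson model."""
    if state.is_two_phenotype:
        raise ValueError("Swanson model expects a one-field state")
    if fields is None:
        fields = _swanson_fields(grid, params)
    mask = grid.brain_mask
    dg = diffusive_flux_divergence(state.g, fields["D"], mask, grid.spacing_mm)
    dg += np.where(mask, params.alpha * state.g * (1.0 - state.g / params.T_max), 0.0)
    return Tendency(dg)


def two_phenotype_rhs(
    state: TumorState,
    params: TwoPhenotypeParams,
    grid: TissueGrid,
    fields: dict | None = None,
) -> Tendency:
    """Right-hand side of the two-phenotype model.

    The haptotaxis flux divergence enters the g-equation with a minus sign
    and the m-equation with a plus sign, so it cancels in ∂(g+m)/∂t.
    """
    if not state.is_two_phenotype:
        raise ValueError("two-phenotype model expects a (g, m, w) state")
    if fields is None:
        fields = _two_phenotype_fields(grid, params)
    mask = grid.brain_mask
    h = grid.spacing_mm
    hapto = haptotaxis_divergence(state.g, state.w, fields["chi"], mask, h)
    total = state.g + state.m
    logistic = np.where(
        mask, params.alpha * state.g * (1.0 - total / params.T_max), 0.0
    )
    dg = diffusive_flux_divergence(state.g, fields["D_G"], mask, h) + logistic - hapto
    dm = diffusive_flux_divergence(state.m, fields["D_M"], mask, h) + hapto
    dw = np.where(
        mask,
        -params.rho_ecm * state.w * total / (params.theta_W + total)
        + params.alpha_W * state.w * (1.0 - state.w),
        0.0,
    )
    return Tendency(dg, dm, dw)


def rhs_for(params, grid: TissueGrid) -> Callable[[TumorState], Tendency]:
    """Bind a model RHS to a grid with coefficient fields expanded once."""
    if isinstance(params, SwansonParams):
        fields = _swanson_fields(grid, params)
        return lambda s: swanson_rhs(s, params, grid, fields)
    if isinstance(params, TwoPhenotypeParams):
        fields = _two_phenotype_fields(grid, params)
        return lambda s: two_phenotype_rhs(s, params, grid, fields)
    raise TypeError(f"unknown parameter type {type(params)!r}")


# ---------------------------------------------------------------------------
# time integration

def _axpy(state: TumorState, tend: Tendency, c: float, t: float) -> TumorState:
    """state + c * tendency, without clamping."""
    g = state.g + c * tend.dg
    m = w = None
    if state.m is not None:
        m = state.m + c * tend.dm
        w = state.w + c * tend.dw
    return TumorState(g, m, w, t)


def _combine(state: TumorState, t1: Tendency, t2: Tendency, c: float, t: float):
    g = state.g + c * (t1.dg + t2.dg)
    m = w = None
    if state.m is not None:
        m = state.m + c * (t1.dm + t2.dm)
        w = state.w + c * (t1.dw + t2.dw)
    return TumorState(g, m, w, t)


def heun_step(
    state: TumorState,
    rhs: Callable[[TumorState], Tendency],
    dt: float,
    stats: dict | None = None,
) -> TumorState:
    """One Heun (RK2 predictor–corrector) step.

    After the corrector, negative densities are clamped to zero and the
    ECM field to [0, 1]; small undershoots are expected near sharp fronts
    and the clamp count can be collected through ``stats``.  Non-finite
    values raise :class:`NumericalBlowupError` naming the offending time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k1 = rhs(state)
    pred = _axpy(state, k1, dt, state.t + dt)
    k2 = rhs(pred)
    new = _combine(state, k1, k2, 0.5 * dt, state.t + dt)

    clamped = int((new.g < 0).sum())
    np.maximum(new.g, 0.0, out=new.g)
    if new.m is not None:
        clamped += int((new.m < 0).sum())
        np.maximum(new.m, 0.0, out=new.m)
        clamped += int(((new.w < 0) | (new.w > 1)).sum())
        np.clip(new.w, 0.0, 1.0, out=new.w)
    if stats is not None:
        stats["clamped"] = stats.get("clamped", 0) + clamped
        stats["steps"] = stats.get("steps", 0) + 1

    if not np.isfinite(new.g).all() or (
        new.m is not None and not (np.isfinite(new.m).all() and np.isfinite(new.w).all())
    ):
        raise NumericalBlowupError(new.t)
    return new


def integrate(
    state: TumorState,
    params,
    grid: TissueGrid,
    days: float,
    dt: float = DEFAULT_DT_DAYS,
    snapshot_every: float | None = None,
) -> TumorState | list[TumorState]:
    """Integrate a state forward by ``days``.

    Repeated Heun steps at fixed ``dt`` (a final partial step covers any
    remainder).  With ``snapshot_every`` set, returns the list of state
    copies at that cadence (including the initial and final state);
    otherwise returns the final state.
    """
    if days < 0:
        raise ValueError("days must be non-negative")
    rhs = rhs_for(params, grid)
    stats: dict = {}
    snaps = [state.copy()] if snapshot_every else None
    current = state.copy()
    if days > 0:
        n_full = int(math.floor(days / dt + 1e-9))
        remainder = days - n_full * dt
        next_snap = snapshot_every
        elapsed = 0.0
        for _ in range(n_full):
            current = heun_step(current, rhs, dt, stats)
            elapsed += dt
            if snaps is not None and next_snap is not None and elapsed >= next_snap - 1e-9:
                snaps.append(current.copy())
                next_snap += snapshot_every
        if remainder > 1e-12:
            current = heun_step(current, rhs, remainder, stats)
            elapsed += remainder
        if snaps is not None and (not snaps or snaps[-1].t < current.t - 1e-9):
            snaps.append(current.copy())
    if stats.get("clamped"):
        logger.debug(
            "integrate: clamped %d voxel values over %d steps",
            stats["clamped"], stats["steps"],
        )
    return snaps if snaps is not None else current


def integrate_swanson_ensemble(
    states: list[TumorState],
    params: list[SwansonParams],
    grid: TissueGrid,
    days: float,
    dt: float = DEFAULT_DT_DAYS,
) -> list[TumorState]:
    """Integrate many one-field Swanson members in lockstep.

    Numerically identical (to roundoff) to calling :func:`integrate` per
    member, but steps the whole ensemble as one (k, rows, cols) array with
    per-member face conductances precomputed — the hot path of ensemble
    forecasting.
    """
    if days < 0:
        raise ValueError("days must be non-negative")
    if len(states) != len(params):
        raise ValueError("one parameter set per member required")
    if days == 0:
        return [s.copy() for s in states]
    k = len(states)
    mask = grid.brain_mask
    h2 = grid.spacing_mm**2
    G = np.stack([np.asarray(s.g, dtype=float) for s in states])

    # per-member, per-axis face conductance (already divided by h^2)
    D = np.stack([expand_parameters(grid, p.D) for p in params])
    conds = []
    slices = []
    for axis in (0, 1):
        lo = (slice(None),) + tuple(
            slice(0, -1) if a == axis else slice(None) for a in (0, 1)
        )
        hi = (slice(None),) + tuple(
            slice(1, None) if a == axis else slice(None) for a in (0, 1)
        )
        open_face = mask[lo[1:]] & mask[hi[1:]]
        conds.append(0.5 * (D[lo] + D[hi]) * open_face / h2)
        slices.append((lo, hi))
    alpha_arr = np.ascontiguousarray(
        np.array([p.alpha for p in params])[:, None, None] * mask
    )
    inv_K_arr = np.array([1.0 / p.T_max for p in params])

    n_full = int(math.floor(days / dt + 1e-9))
    remainder = days - n_full * dt
    steps = np.array([dt] * n_full + ([remainder] if remainder > 1e-12 else []))
    t = states[0].t
    stepper = _compiled_swanson_stepper()
    # run in blocks so blowups are caught close to where they occur
    block = 50
    for start in range(0, steps.size, block):
        chunk = steps[start : start + block]
        stepper(G, conds[0], conds[1], alpha_arr, inv_K_arr, chunk)
        t += chunk.sum()
        if not np.isfinite(G).all():
            raise NumericalBlowupError(t)
    return [TumorState(G[i].copy(), t=t) for i in range(k)]


def _compiled_swanson_stepper():
    """Build (once) the jitted Heun stepper for Swanson ensembles.

    Identical arithmetic to :func:`swanson_rhs` + :func:`heun_step`,
    restructured as fused per-voxel loops; falls back to a pure-numpy
    version when numba is unavailable.
    """
    global _SWANSON_STEPPER
    if _SWANSON_STEPPER is not None:
        return _SWANSON_STEPPER

    def stepper(G, cond_r, cond_c, alpha, inv_K, dts):
        k, R, C = G.shape
        k1 = np.empty_like(G)
        k2 = np.empty_like(G)
        Gp = np.empty_like(G)
        for s in range(dts.size):
            dt = dts[s]
            _swanson_rhs_raw(G, cond_r, cond_c, alpha, inv_K, k1)
            for i in range(k):
                for r in range(R):
                    for c in range(C):
                        Gp[i, r, c] = G[i, r, c] + dt * k1[i, r, c]
            _swanson_rhs_raw(Gp, cond_r, cond_c, alpha, inv_K, k2)
            for i in range(k):
                for r in range(R):
                    for c in range(C):
                        v = G[i, r, c] + 0.5 * dt * (k1[i, r, c] + k2[i, r, c])
                        G[i, r, c] = v if v > 0.0 else 0.0

    def rhs_raw(G, cond_r, cond_c, alpha, inv_K, out):
        k, R, C = G.shape
        for i in range(k):
            for r in range(R):
                for c in range(C):
                    g = G[i, r, c]
                    out[i, r, c] = alpha[i, r, c] * g * (1.0 - g * inv_K[i])
            for r in range(R - 1):
                for c in range(C):
                    f = cond_r[i, r, c] * (G[i, r + 1, c] - G[i, r, c])
                    out[i, r, c] += f
                    out[i, r + 1, c] -= f
            for r in range(R):
                for c in range(C - 1):
                    f = cond_c[i, r, c] * (G[i, r, c + 1] - G[i, r, c])
                    out[i, r, c] += f
                    out[i, r, c + 1] -= f

    try:
        import numba

        _swanson_rhs_raw = numba.njit(cache=True)(rhs_raw)
        _SWANSON_STEPPER = numba.njit(cache=True)(stepper)
    except ImportError:  # pragma: no cover - numba is a hard dependency
        _swanson_rhs_raw = rhs_raw
        _SWANSON_STEPPER = stepper
    return _SWANSON_STEPPER


_SWANSON_STEPPER = None


def seed_tumor(
    grid: TissueGrid,
    voxel: tuple[int, int],
    g0: float,
    m0: float,
    params,
    days: float,
    dt: float = DEFAULT_DT_DAYS,
) -> TumorState:
    """Grow a tumor from a single-voxel seed.

    ``g0``/``m0`` are cell *counts* placed in one voxel (density is
    count / spacing²).  For the two-phenotype model the ECM is initialised
    to 1 on the brain mask.  Returns the state after ``days`` of growth.
    """
    r, c = voxel
    if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]) or not grid.brain_mask[r, c]:
        raise DomainError(f"seed voxel {voxel} is outside the brain mask")
    h2 = grid.spacing_mm**2
    g = np.zeros(grid.shape)
    g[r, c] = g0 / h2
    if isinstance(params, TwoPhenotypeParams):
        m = np.zeros(grid.shape)
        m[r, c] = m0 / h2
        w = np.where(grid.brain_mask, 1.0, 0.0)
        state = TumorState(g, m, w, 0.0)
    else:
        if m0:
            g[r, c] += m0 / h2
        state = TumorState(g, t=0.0)
    grown = integrate(state, params, grid, days, dt)
    logger.info(
        "seed_tumor: %.0f days -> population %.3g cells, area>%.3g: %.0f mm^2",
        days,
        total_population(grown, grid.spacing_mm),
        3.0 / 128.0 * getattr(params, "T_max", 1.0),
        area_above(grown, 3.0 / 128.0 * getattr(params, "T_max", 1.0), grid.spacing_mm),
    )
    return grown


def smooth_seed_state(
    grid: TissueGrid,
    center_frac: tuple[float, float] = (0.62, 0.40),
    g_amp: float = 2000.0,
    g_sigma_mm: float = 3.0,
    m_amp: float = 100.0,
    m_sigma_mm: float = 5.0,
) -> TumorState:
    """A smooth Gaussian initial (g, m, w) state for convergence studies.

    Defined in physical (mm) coordinates from a fractional domain
    position, so the same tumor can be laid down on grids of any
    resolution; densities are zeroed outside the brain mask and the ECM
    starts at 1 on the mask.
    """
    rows, cols = grid.shape
    h = grid.spacing_mm
    yy = (np.arange(rows)[:, None] + 0.5) * h
    xx = (np.arange(cols)[None, :] + 0.5) * h
    cy, cx = center_frac[0] * rows * h, center_frac[1] * cols * h
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    mask = grid.brain_mask
    g = np.where(mask, g_amp * np.exp(-d2 / (2 * g_sigma_mm**2)), 0.0)
    m = np.where(mask, m_amp * np.exp(-d2 / (2 * m_sigma_mm**2)), 0.0)
    w = np.where(mask, 1.0, 0.0)
    return TumorState(g, m, w, 0.0)


def logistic_transition_time(alpha: float, f0: float = 0.01, f1: float = 0.99) -> float:
    """Time for the logistic ODE g' = αg(1 − g/T_max) to grow from
    f0·T_max to f1·T_max:  (1/α)·ln[f1(1−f0) / (f0(1−f1))]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not (0 < f0 <= f1 < 1):
        raise ValueError("need 0 < f0 <= f1 < 1")
    return math.log(f1 * (1 - f0) / (f0 * (1 - f1))) / alpha
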