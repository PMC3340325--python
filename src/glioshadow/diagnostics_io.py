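"""Diagnostics and shared I/O: density binning, error maps, half-max
contour "spaghetti" and spread, RMSE summaries, rendering, field rasters.

Density rendering follows the 128-bin convention: a voxel's bin is
floor(128·u/T_max) clipped to [0, 127], and voxels below bin 3 (density
under 3/128·T_max) show the tissue underlay instead of the colour ramp.
The contour-spread metric operationalises the visual "margin" between
member contours: cast angular rays from the density-weighted tumor
centroid and average, over rays, the spread (max − min) of the member
contour radii along each ray.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import measure

from .errors import DomainError
from .raster import read_raster, write_raster
from .tissue_geometry import TissueGrid
from .tumor_models import TumorState

N_BINS = 128
DISPLAY_FLOOR_BIN = 3


def density_bins(
    field: np.ndarray,
    T_max: float,
    n_bins: int = N_BINS,
    display_floor_bin: int = DISPLAY_FLOOR_BIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Map densities to colour bins; return (bin index, visible mask)."""
    field = np.asarray(field, dtype=float)
    if (field < 0).any():
        raise ValueError("density field must be non-negative")
    bins = np.clip(np.floor(n_bins * field / T_max).astype(int), 0, n_bins - 1)
    return bins, bins >= display_floor_bin


def error_map(analysis_mean: np.ndarray, truth_total: np.ndarray) -> np.ndarray:
    """Pointwise absolute difference |analysis − truth|."""
    a = np.asarray(analysis_mean, dtype=float)
    b = np.asarray(truth_total, dtype=float)
    if a.shape != b.shape:
        raise DomainError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b)


def rmse(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Root-mean-square difference over a voxel mask."""
    a, b, mask = np.asarray(a, float), np.asarray(b, float), np.asarray(mask, bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise DomainError("rmse: shapes must match")
    if not mask.any():
        raise DomainError("rmse: empty mask")
    d = a[mask] - b[mask]
    return float(np.sqrt(np.mean(d * d)))


def half_max_contour(
    member_state: TumorState, member_T_max: float, spacing_mm: float = 1.0
) -> list[np.ndarray]:
    """Marching-squares contours where total density = T_max/2.

    Returns a list of (N, 2) polylines in (row, col) mm coordinates; empty
    when the density never crosses the level.
    """
    total = member_state.total()
    level = 0.5 * member_T_max
    if total.max() < level or total.min() > level:
        return []
    return [c * spacing_mm for c in measure.find_contours(total, level)]


def density_weighted_centroid(field: np.ndarray, spacing_mm: float = 1.0):
    """Centroid of a density field in (row, col) mm coordinates."""
    field = np.asarray(field, dtype=float)
    mass = field.sum()
    if mass <= 0:
        raise DomainError("cannot take centroid of an empty field")
    rr, cc = np.mgrid[0 : field.shape[0], 0 : field.shape[1]]
    return (
        float((rr * field).sum() / mass) * spacing_mm,
        float((cc * field).sum() / mass) * spacing_mm,
    )


def contour_spread(
    contour_set: dict[int, list[np.ndarray]],
    centroid_mm: tuple[float, float],
    n_rays: int = 72,
) -> float:
    """Mean over angular rays of the (max − min) member contour radius.

    For each member, the contour radius along a ray is the largest radius
    of its contour vertices whose polar angle falls in the ray's angular
    bin; rays where any member has no vertex are skipped.  Zero iff all
    member contours coincide; translation invariant by construction.
    """
    members = [m for m, cs in contour_set.items() if cs]
    if not members:
        raise DomainError("contour set is empty")
    edges = np.linspace(-np.pi, np.pi, n_rays + 1)
    radii = np.full((len(members), n_rays), -np.inf)
    cy, cx = centroid_mm
    for i, m in enumerate(members):
        pts = np.vstack(contour_set[m])
        dy, dx = pts[:, 0] - cy, pts[:, 1] - cx
        r = np.hypot(dy, dx)
        which = np.clip(np.digitize(np.arctan2(dy, dx), edges) - 1, 0, n_rays - 1)
        np.maximum.at(radii[i], which, r)
    valid = np.isfinite(radii).all(axis=0)
    if not valid.any():
        raise DomainError("no ray is crossed by every member contour")
    spread = radii[:, valid].max(axis=0) - radii[:, valid].min(axis=0)
    return float(spread.mean())


# ---------------------------------------------------------------------------
# summaries

def cycle_summary(records, brain_mask: np.ndarray, free_run_mean=None) -> pd.DataFrame:
    """RMSE table (fractions of carrying capacity) per assimilation cycle."""
    rows = []
    for rec in records:
        rows.append(
            {
                "t_days": rec.t,
                "rmse_background": rmse(rec.background_mean, rec.truth_total, brain_mask),
                "rmse_analysis": rmse(rec.analysis_mean, rec.truth_total, brain_mask),
            }
        )
    df = pd.DataFrame(rows)
    if free_run_mean is not None:
        df["rmse_freerun_final"] = np.nan
        df.loc[df.index[-1], "rmse_freerun_final"] = rmse(
            free_run_mean, records[-1].truth_total, brain_mask
        )
    return df


# ---------------------------------------------------------------------------
# rendering

#: underlay grey levels by tissue class (glial drawn as white matter)
_UNDERLAY = {
    "background": 0,
    "other_nonbrain": 0,
    "gray": 90,
    "white": 255,
    "glial": 255,
    "csf": 190,
}


def _ramp(n_bins: int) -> np.ndarray:
    """Blue-to-red colour ramp as an (n_bins, 3) uint8 array."""
    t = np.linspace(0.0, 1.0, n_bins)
    r = np.clip(1.5 - np.abs(4 * t - 3), 0, 1)
    g = np.clip(1.5 - np.abs(4 * t - 2), 0, 1)
    b = np.clip(1.5 - np.abs(4 * t - 1), 0, 1)
    return (np.stack([r, g, b], axis=1) * 255).astype(np.uint8)


def render(
    grid: TissueGrid,
    field: np.ndarray | None = None,
    T_max: float = 10_000.0,
    path=None,
    n_bins: int = N_BINS,
) -> np.ndarray:
    """Render a density field over the tissue underlay.

    Returns the RGB array; writes a PNG when ``path`` is given.  Output
    bytes are deterministic for fixed inputs.
    """
    rgb = np.zeros(grid.shape + (3,), dtype=np.uint8)
    for name, level in _UNDERLAY.items():
        rgb[grid.class_mask(name)] = level
    if field is not None:
        bins, visible = density_bins(field, T_max, n_bins)
        rgb[visible] = _ramp(n_bins)[bins[visible]]
    if path is not None:
        Image.fromarray(rgb).save(Path(path), format="PNG")
    return rgb


# ---------------------------------------------------------------------------
# field raster I/O

def write_field(path, field: np.ndarray, t_days: float, variable: str,
                units: str = "", **extra) -> None:
    """Write a float field raster with its JSON sidecar."""
    header = {"t_days": t_days, "variable": variable, "units": units, **extra}
    write_raster(path, np.asarray(field, dtype=float), header)


def read_field(path) -> tuple[np.ndarray, dict]:
    """Read a float field raster; returns (array, header)."""
    return read_raster(path, dtype=float)
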