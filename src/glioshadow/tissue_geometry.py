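"""Labeled 2-D brain domains and per-voxel parameter fields.

The simulation domain is a raster of integer tissue-class labels at 1-mm
(default) spacing, following the discrete-anatomy convention of the
BrainWeb atlas: each voxel is background, cerebrospinal fluid (CSF), gray
matter, white matter, or glial matter (non-brain classes such as skull,
fat and skin are treated as background).  Model coefficients that vary by
tissue type (diffusion rates, haptotaxis coefficients) are expanded to
piecewise-constant per-voxel fields; glial voxels receive white-matter
values, as is conventional for glioma simulations.

A built-in phantom generator produces a brain-shaped synthetic slice
(background border, gray-matter shell, white-matter core, CSF pockets,
sparse glial flecks) for experiments that do not load an external atlas
slice.  Its geometry is defined in resolution-independent fractional
coordinates, so one seed yields consistent anatomy at any grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

import numpy as np

from .errors import DomainError, LabeledInputError
from .raster import read_raster, write_raster

#: tissue classes that make up the brain mask
BRAIN_CLASSES = ("csf", "gray", "white", "glial")
#: every class name the package understands
KNOWN_CLASSES = BRAIN_CLASSES + ("background", "other_nonbrain")

#: label convention used by the phantom generator and the writers
DEFAULT_CLASS_MAP: dict[int, str] = {
    0: "background",
    1: "csf",
    2: "gray",
    3: "white",
    4: "glial",
}


@dataclass
class TissueGrid:
    """Integer tissue-class raster with physical spacing.

    Parameters
    ----------
    labels : ndarray of int, shape (rows, cols)
        Tissue-class id per voxel.
    spacing_mm : float
        Voxel edge length in millimetres (voxels are square).
    class_map : mapping of int to str
        Label id -> class name; names outside :data:`KNOWN_CLASSES` are
        rejected.  Non-brain anatomy (skull, fat, ...) should map to
        ``"other_nonbrain"`` and is treated exactly like background.
    """

    labels: np.ndarray
    spacing_mm: float = 1.0
    class_map: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DomainError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise LabeledInputError("labels must be integers")
        if self.spacing_mm <= 0:
            raise DomainError("spacing_mm must be positive")
        self.class_map = {int(k): str(v) for k, v in dict(self.class_map).items()}
        unknown_names = set(self.class_map.values()) - set(KNOWN_CLASSES)
        if unknown_names:
            raise LabeledInputError(f"unknown class names: {sorted(unknown_names)}")
        present = set(np.unique(self.labels).tolist())
        unmapped = present - set(self.class_map)
        if unmapped:
            raise LabeledInputError(
                f"labels {sorted(unmapped)} have no entry in class_map"
            )
        if not self.brain_mask.any():
            raise DomainError("brain mask is empty (no csf/gray/white/glial voxels)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_mask(self, name: str) -> np.ndarray:
        """Boolean mask of voxels belonging to one tissue class."""
        ids = [k for k, v in self.class_map.items() if v == name]
        mask = np.zeros(self.labels.shape, dtype=bool)
        for k in ids:
            mask |= self.labels == k
        return mask

    @cached_property
    def brain_mask(self) -> np.ndarray:
        mask = np.zeros(self.labels.shape, dtype=bool)
        for name in BRAIN_CLASSES:
            mask |= self.class_mask(name)
        mask.setflags(write=False)
        return mask

    def glial_mask(self) -> np.ndarray:
        """Glial voxels, flagged so they can be treated as white matter."""
        return self.class_mask("glial")


def brain_mask(grid: TissueGrid) -> np.ndarray:
    """True exactly on csf/gray/white/glial voxels."""
    return grid.brain_mask


def expand_parameters(
    grid: TissueGrid, per_class: Mapping[str, float], fill: float = 0.0
) -> np.ndarray:
    """Expand a per-tissue-class table to a piecewise-constant voxel field.

    Glial voxels receive the white-matter value.  Voxels outside the brain
    mask get ``fill`` (default 0).

    Raises
    ------
    LabeledInputError
        If a brain class present in the grid has no table entry.
    """
    values = np.full(grid.shape, float(fill))
    for name in ("csf", "gray", "white"):
        mask = grid.class_mask(name)
        if name == "white":
            mask = mask | grid.glial_mask()
        if not mask.any():
            continue
        if name not in per_class:
            raise LabeledInputError(f"no parameter value for tissue class {name!r}")
        values[mask] = float(per_class[name])
    if grid.glial_mask().any() and "white" not in per_class:
        raise LabeledInputError("glial voxels present but no white-matter value")
    return values


def generate_phantom(
    rows: int, cols: int, seed: int, spacing_mm: float = 1.0
) -> TissueGrid:
    """Generate a brain-shaped synthetic tissue slice.

    The phantom emulates a 2-D coronal slice: an elliptical brain with a
    contiguous white-matter core, a gray-matter shell, ventricle-like CSF
    pockets plus small CSF sulci in the shell, sparse glial arcs at the
    gray/white interface, and a non-brain background border.  White matter
    occupies more area than gray matter by construction.  Geometry is a
    deterministic function of ``seed`` in fractional coordinates, so the
    same seed produces consistent anatomy at any resolution.
    """
    if rows < 32 or cols < 32:
        raise DomainError("phantom domain must be at least 32x32 voxels")
    rng = np.random.default_rng(seed)
    # voxel-centre fractional coordinates
    y = (np.arange(rows) + 0.5)[:, None] / rows
    x = (np.arange(cols) + 0.5)[None, :] / cols

    ay = 0.42 * (1.0 + 0.04 * rng.uniform(-1, 1))
    ax = 0.40 * (1.0 + 0.04 * rng.uniform(-1, 1))
    r2 = ((y - 0.5) / ay) ** 2 + ((x - 0.5) / ax) ** 2

    labels = np.zeros((rows, cols), dtype=np.int16)
    labels[r2 < 1.0] = 2          # gray shell
    labels[r2 < 0.72] = 3         # white core

    # lateral-ventricle-like CSF pockets
    for sx in (-1.0, 1.0):
        cy = 0.46 + 0.01 * rng.uniform(-1, 1)
        cx = 0.5 + sx * (0.10 + 0.01 * rng.uniform(-1, 1))
        vy = 0.100 * (1.0 + 0.1 * rng.uniform(-1, 1))
        vx = 0.045 * (1.0 + 0.1 * rng.uniform(-1, 1))
        vent = ((y - cy) / vy) ** 2 + ((x - cx) / vx) ** 2 < 1.0
        labels[vent & (labels == 3)] = 1

    # small CSF sulci in the gray shell
    for theta in rng.uniform(0, 2 * np.pi, size=6):
        cy = 0.5 + 0.93 * ay * np.sin(theta)
        cx = 0.5 + 0.93 * ax * np.cos(theta)
        pocket = (y - cy) ** 2 + (x - cx) ** 2 < 0.03**2
        labels[pocket & (labels == 2)] = 1

    # glial arcs in a band at the gray/white interface
    band = (r2 >= 0.64) & (r2 < 0.72)
    angle = np.arctan2((y - 0.5) / ay, (x - 0.5) / ax)
    for theta in rng.uniform(-np.pi, np.pi, size=5):
        d = np.abs(np.angle(np.exp(1j * (angle - theta))))
        labels[band & (d < np.deg2rad(20.0)) & (labels == 3)] = 4

    grid = TissueGrid(labels, spacing_mm=spacing_mm, class_map=dict(DEFAULT_CLASS_MAP))
    for name in BRAIN_CLASSES:
        if not grid.class_mask(name).any():
            raise DomainError(f"phantom domain too small: no {name} voxels generated")
    if grid.class_mask("white").sum() <= grid.class_mask("gray").sum():
        raise DomainError("phantom violated white > gray area requirement")
    return grid


def default_seed_voxel(grid: TissueGrid) -> tuple[int, int]:
    """A white-matter voxel in the lower half of the slice, clear of the
    ventricles — the default site for initiating a tumor."""
    white = grid.class_mask("white") & ~grid.glial_mask()
    if not white.any():
        raise DomainError("grid has no white-matter voxels")
    rows, cols = grid.shape
    target = np.array([0.62 * (rows - 1), 0.40 * (cols - 1)])
    rr, cc = np.nonzero(white)
    i = np.argmin((rr - target[0]) ** 2 + (cc - target[1]) ** 2)
    return int(rr[i]), int(cc[i])


def write_labeled_raster(grid: TissueGrid, path) -> None:
    """Write a tissue grid as a text raster plus JSON sidecar."""
    header = {
        "rows": grid.shape[0],
        "cols": grid.shape[1],
        "spacing_mm": grid.spacing_mm,
        "class_map": {str(k): v for k, v in grid.class_map.items()},
    }
    write_raster(path, grid.labels, header, fmt="%d")


def load_labeled_raster(path, class_map: Mapping[int, str] | None = None) -> TissueGrid:
    """Load a labeled tissue raster (text or raw8 binary + sidecar).

    ``class_map`` overrides the sidecar's mapping when given; a label with
    no mapping raises :class:`LabeledInputError`.
    """
    labels, header = read_raster(path, dtype=np.int64)
    if class_map is None:
        try:
            class_map = {int(k): v for k, v in header["class_map"].items()}
        except KeyError as exc:
            raise LabeledInputError(
                f"{path}: no class_map given and none in sidecar"
            ) from exc
    spacing = float(header.get("spacing_mm", 1.0))
    return TissueGrid(labels.astype(np.int16), spacing_mm=spacing, class_map=class_map)


def crop_to_brain(grid: TissueGrid, margin: int = 1) -> TissueGrid:
    """Crop a grid to the bounding box of its brain mask plus a margin."""
    rr, cc = np.nonzero(grid.brain_mask)
    r0, r1 = max(rr.min() - margin, 0), min(rr.max() + margin + 1, grid.shape[0])
    c0, c1 = max(cc.min() - margin, 0), min(cc.max() + margin + 1, grid.shape[1])
    return TissueGrid(
        grid.labels[r0:r1, c0:c1].copy(),
        spacing_mm=grid.spacing_mm,
        class_map=dict(grid.class_map),
    )
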