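"""Plain-text raster I/O with a one-line JSON header sidecar.

A raster is a rectangular matrix stored as whitespace-separated numbers,
one row per line.  Metadata (shape, spacing, class maps, timestamps, ...)
lives in ``<path>.json`` next to the matrix.  An 8-bit raw binary variant
(``format: "raw8"`` in the sidecar) is accepted on read, which covers
discrete-anatomy exports in the BrainWeb style.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import RasterFormatError


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.name + ".json")


def write_raster(path, array: np.ndarray, header: dict, fmt: str = "%.10g") -> None:
    """Write a 2-D array as text plus its JSON sidecar."""
    path = Path(path)
    array = np.asarray(array)
    if array.ndim != 2:
        raise RasterFormatError(f"expected a 2-D raster, got shape {array.shape}")
    header = dict(header)
    header.setdefault("rows", int(array.shape[0]))
    header.setdefault("cols", int(array.shape[1]))
    np.savetxt(path, array, fmt=fmt)
    sidecar_path(path).write_text(json.dumps(header) + "\n")


def read_raster(path, dtype=float) -> tuple[np.ndarray, dict]:
    """Read a raster written by :func:`write_raster` (text or raw8).

    Returns ``(array, header)``; header is ``{}`` when no sidecar exists.
    """
    path = Path(path)
    header: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        try:
            header = json.loads(sp.read_text())
        except json.JSONDecodeError as exc:
            raise RasterFormatError(f"bad JSON sidecar {sp}: {exc}") from exc
    if header.get("format") == "raw8":
        try:
            rows, cols = int(header["rows"]), int(header["cols"])
        except KeyError as exc:
            raise RasterFormatError("raw8 raster requires rows/cols in sidecar") from exc
        data = np.fromfile(path, dtype=np.uint8)
        if data.size != rows * cols:
            raise RasterFormatError(
                f"raw8 raster {path} has {data.size} bytes, expected {rows * cols}"
            )
        return data.reshape(rows, cols).astype(dtype), header
    rows = [line.split() for line in path.read_text().splitlines() if line.strip()]
    if not rows:
        raise RasterFormatError(f"empty raster file {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise RasterFormatError(f"non-rectangular raster {path}")
    try:
        array = np.array(rows, dtype=dtype)
    except ValueError as exc:
        raise RasterFormatError(f"non-numeric raster {path}: {exc}") from exc
    if "rows" in header and (int(header["rows"]), int(header["cols"])) != array.shape:
        raise RasterFormatError(
            f"raster {path} shape {array.shape} disagrees with sidecar"
        )
    return array, header
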