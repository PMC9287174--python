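"""Cellular brightness ratios and chromophore-maturation time courses.

The cellular brightness assay co-expresses a green-emitting protein and
mCherry from one bicistronic transcript, so each cell produces the two
fluorophores at an equimolar ratio.  Per cell, green fluorescence divided by
red fluorescence cancels expression level; the population summary divided by
the same quantity for a reference protein (EGFP) gives the relative cellular
brightness.  Maturation is followed after transfection as total fluorescence
per unit transfected-cell area, normalized to its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CellMeasurement",
    "MaturationSeries",
    "brightness_ratio",
    "brightness_ratio_field",
    "measure_cells",
    "estimate_background",
    "maturation_timecourse",
]


@dataclass(frozen=True)
class CellMeasurement:
    """Background-subtracted mean green/red intensity of one cell."""

    cell_id: int
    green: float
    red: float

    def __post_init__(self) -> None:
        if self.green < 0 or self.red < 0:
            raise ValueError(f"cell {self.cell_id}: intensities must be >= 0")


@dataclass
class MaturationSeries:
    """Fluorescence per transfected-cell area over time since transfection.

    ``fi_per_area`` may contain NaN where a frame had an empty mask; the
    normalized series is the same values divided by the (NaN-ignoring) maximum.
    """

    times: np.ndarray
    fi_per_area: np.ndarray
    normalized: np.ndarray


def brightness_ratio(cells: Sequence[CellMeasurement], reference_ratio: float) -> float:
    """Relative cellular brightness from per-cell green/red ratios.

    The median ratio across cells is used (robust to cell-to-cell expression
    variation) and divided by ``reference_ratio``, the same median measured for
    the reference protein.
    """
    if reference_ratio <= 0:
        raise ValueError("reference_ratio must be positive")
    ratios = [c.green / c.red for c in cells if c.red > 0]
    if not ratios:
        raise ValueError("no cell has red > 0; assay is uninterpretable")
    return float(np.median(ratios)) / reference_ratio


def brightness_ratio_field(cells: Sequence[CellMeasurement], reference_ratio: float) -> float:
    """Field-level variant: total green over total red, then normalized.

    Secondary summary; weights bright cells more heavily than the per-cell
    median and is provided for comparison only.
    """
    if reference_ratio <= 0:
        raise ValueError("reference_ratio must be positive")
    total_red = sum(c.red for c in cells)
    if total_red <= 0:
        raise ValueError("no red signal in the field")
    total_green = sum(c.green for c in cells)
    return (total_green / total_red) / reference_ratio


def estimate_background(image: np.ndarray, labels: np.ndarray) -> float:
    """Scalar background: the mode of pixels outside every labelled cell."""
    bg = np.asarray(image)[np.asarray(labels) == 0]
    if bg.size == 0:
        return 0.0
    if np.issubdtype(bg.dtype, np.integer):
        counts = np.bincount(bg.ravel().astype(np.int64))
        return float(np.argmax(counts))
    if bg.min() == bg.max():
        return float(bg.flat[0])
    hist, edges = np.histogram(bg, bins=256)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def measure_cells(
    green: np.ndarray,
    red: np.ndarray,
    labels: np.ndarray,
    background_green: float | None = None,
    background_red: float | None = None,
) -> list[CellMeasurement]:
    """Per-cell background-subtracted mean intensities from a label image.

    ``labels`` is an integer image, 0 = background.  Backgrounds default to
    the mode of the non-cell pixels of each channel.  Negative means after
    subtraction are clipped to 0.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    labels = np.asarray(labels)
    if green.shape != red.shape or green.shape != labels.shape:
        raise ValueError("green, red and labels must have identical shapes")
    if background_green is None:
        background_green = estimate_background(green, labels)
    if background_red is None:
        background_red = estimate_background(red, labels)
    out: list[CellMeasurement] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        g = max(float(green[sel].mean()) - background_green, 0.0)
        r = max(float(red[sel].mean()) - background_red, 0.0)
        out.append(CellMeasurement(cell_id=int(lab), green=g, red=r))
    return out


def maturation_timecourse(
    frames: np.ndarray,
    masks: np.ndarray,
    background: float = 0.0,
    times: np.ndarray | None = None,
) -> MaturationSeries:
    """Total fluorescence per transfected-cell area, frame by frame.

    Per frame, FI = sum over the mask of (intensity - background), divided by
    the mask area in pixels.  A frame with an empty mask yields NaN (missing),
    never zero.  The normalized series divides by the maximum over frames.
    """
    frames = np.asarray(frames, dtype=float)
    masks = np.asarray(masks)
    if background < 0:
        raise ValueError("background must be >= 0")
    if frames.shape != masks.shape:
        raise ValueError("masks must align with frames")
    n = frames.shape[0]
    if times is None:
        times = np.arange(n, dtype=float)
    times = np.asarray(times, dtype=float)
    fi = np.full(n, np.nan)
    for t in range(n):
        m = masks[t] > 0
        area = int(m.sum())
        if area == 0:
            continue
        fi[t] = float((frames[t][m] - background).sum()) / area
    peak = np.nanmax(fi) if np.any(np.isfinite(fi)) else np.nan
    normalized = fi / peak if peak and np.isfinite(peak) and peak != 0 else fi.copy()
    return MaturationSeries(times=times, fi_per_area=fi, normalized=normalized)
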