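"""ER-network rearrangement mapping from time-lapse movies.

Each frame is binarized with a per-frame Otsu threshold (so the segmentation
adapts to photobleaching), the field is divided into square sub-blocks
(default 16 x 16 px, small relative to a tubule network but large relative to
a tubule width), and for every consecutive frame pair the fraction of pixels
per block that switched between foreground and background is computed.  The
(T-1) fraction maps are rendered as 8-bit heat maps normalized over the whole
movie so frames remain comparable along time, and can be aggregated into
per-cell temporal motion profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MovieStack",
    "BinaryStack",
    "MovementMap",
    "otsu_threshold",
    "binarize_frame",
    "binarize_stack",
    "subblock_movement",
    "movement_heatmaps",
    "movement_map",
    "cell_movement_profile",
]

DEFAULT_BLOCK = 16


@dataclass
class MovieStack:
    """T x H x W intensity movie with acquisition metadata.

    ``frame_interval`` is in seconds; ``pixel_size`` (nm) is optional.
    """

    frames: np.ndarray
    frame_interval: float = 1.0
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[1] == 0 or self.frames.shape[2] == 0:
            raise ValueError("frames must have positive height and width")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval


@dataclass
class BinaryStack:
    """Per-frame Otsu binarization of a movie.

    ``thresholds`` holds the gray level used per frame (NaN for frames flagged
    degenerate, which are carried as all-background).
    """

    frames: np.ndarray
    thresholds: np.ndarray
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.frames.shape[0], dtype=bool)


@dataclass
class MovementMap:
    """Sub-block change fractions per frame pair plus their 8-bit rendering."""

    fractions: np.ndarray  # (T-1, Bh, Bw) in [0, 1]
    heatmaps: np.ndarray  # (T-1, Bh, Bw) uint8
    block_size: int = DEFAULT_BLOCK


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu threshold on a histogram of counts over gray levels 0..L-1.

    Returns the level t maximizing the between-class variance of the split
    {levels < t} vs {levels >= t}; pixels at or above t are foreground.  Ties
    are broken toward the lower level.  A histogram with fewer than two
    nonzero bins is degenerate.
    """
    h = np.asarray(histogram)
    if h.ndim != 1 or h.size < 2:
        raise ValueError("histogram must be 1-D with at least two bins")
    if np.count_nonzero(h) < 2:
        raise ValueError("degenerate histogram: fewer than two occupied gray levels")
    # between-class variance at cut t is (S0*W - W0*S)^2 / (W0*(W-W0)) up to a
    # constant, with W0/S0 the cumulative count/level-weighted sums below t.
    # Counts are integral, so the comparison can be done exactly in integer
    # arithmetic, making the tie rule (lower level wins) deterministic.
    hf = h.astype(float)
    if np.all(hf == np.round(hf)):
        counts = [int(c) for c in np.round(hf).astype(np.int64)]
        W = sum(counts)
        S = sum(l * c for l, c in enumerate(counts))
        best_t, best_num, best_den = 1, -1, 1
        W0 = S0 = 0
        for t in range(1, len(counts)):
            W0 += counts[t - 1]
            S0 += (t - 1) * counts[t - 1]
            den = W0 * (W - W0)
            if den == 0:
                continue
            num = (S0 * W - W0 * S) ** 2
            if num * best_den > best_num * den:
                best_t, best_num, best_den = t, num, den
        return best_t
    levels = np.arange(h.size, dtype=float)
    total = hf.sum()
    total_mean = float((levels * hf).sum()) / total
    w0 = np.cumsum(hf)[:-1] / total
    mu0_sum = np.cumsum(levels * hf)[:-1] / total
    valid = (w0 > 0) & (w0 < 1)
    var_between = np.zeros_like(w0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between[valid] = (total_mean * w0 - mu0_sum)[valid] ** 2 / (
            w0 * (1.0 - w0)
        )[valid]
    return int(np.argmax(var_between)) + 1


def _frame_histogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pixel values plus the gray level of each bin."""
    if np.issubdtype(values.dtype, np.integer):
        counts = np.bincount(values.ravel().astype(np.int64))
        return counts, np.arange(counts.size, dtype=float)
    counts, edges = np.histogram(values, bins=256)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def binarize_frame(
    frame: np.ndarray, roi: np.ndarray, smooth_sigma: float = 0.0
) -> tuple[np.ndarray, float, bool]:
    """Otsu-binarize one frame inside a ROI; returns (mask, threshold, degenerate).

    ``smooth_sigma`` > 0 applies a Gaussian pre-filter (in pixels) before
    thresholding; with shot-noise-limited input a sigma below the tubule
    radius suppresses pixel flips at the foreground boundary without moving it.
    """
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        frame = gaussian_filter(np.asarray(frame, dtype=float), smooth_sigma)
    vals = frame[roi]
    vmin, vmax = vals.min(), vals.max()
    if vmin == vmax:
        return np.zeros(frame.shape, dtype=bool), float("nan"), True
    counts, levels = _frame_histogram(vals)
    t_idx = otsu_threshold(counts)
    thresh = float(levels[t_idx])
    return (frame >= thresh) & roi, thresh, False


def binarize_stack(
    movie: MovieStack, roi: np.ndarray | None = None, smooth_sigma: float = 0.0
) -> BinaryStack:
    """Per-frame adaptive Otsu binarization of a movie.

    The threshold is computed on ROI pixels only, each frame independently, so
    a globally dimming (photobleaching) movie keeps a stable foreground.
    Pixels outside the ROI are always background.  A frame with a single gray
    level inside the ROI is flagged degenerate and carried as all-background.
    """
    frames = movie.frames
    if roi is None:
        roi = np.ones(frames.shape[1:], dtype=bool)
    roi = np.asarray(roi) > 0
    if roi.shape != frames.shape[1:]:
        raise ValueError("ROI shape must match the frame shape")
    if not roi.any():
        raise ValueError("ROI is empty")
    masks = np.empty(frames.shape, dtype=bool)
    thresholds = np.empty(frames.shape[0])
    degenerate = np.zeros(frames.shape[0], dtype=bool)
    for t in range(frames.shape[0]):
        masks[t], thresholds[t], degenerate[t] = binarize_frame(frames[t], roi, smooth_sigma)
        if degenerate[t]:
            warnings.warn(f"frame {t}: single-valued within ROI, carried as background",
                          stacklevel=2)
    return BinaryStack(frames=masks, thresholds=thresholds, degenerate=degenerate)


def _block_view(a: np.ndarray, block: int) -> np.ndarray:
    """Crop to whole blocks and reshape to (Bh, block, Bw, block)."""
    bh, bw = a.shape[0] // block, a.shape[1] // block
    return a[: bh * block, : bw * block].reshape(bh, block, bw, block)


def subblock_movement(prev: np.ndarray, curr: np.ndarray, block: int = DEFAULT_BLOCK) -> np.ndarray:
    """Per-block fraction of pixels that flipped between two binary frames.

    The denominator is the full block area (block^2); partial edge blocks are
    dropped.  Symmetric in its two arguments.
    """
    prev = np.asarray(prev)
    curr = np.asarray(curr)
    if prev.shape != curr.shape:
        raise ValueError("frames must have the same shape")
    if block < 1:
        raise ValueError("block size must be >= 1")
    if prev.shape[0] < block or prev.shape[1] < block:
        raise ValueError("frame smaller than one block")
    diff = _block_view(prev != curr, block)
    return diff.sum(axis=(1, 3)) / float(block * block)


def movement_heatmaps(fractions: np.ndarray, per_frame: bool = False) -> np.ndarray:
    """Render change fractions as 0-255 integers.

    By default the normalization is global over the whole (T-1, Bh, Bw) series
    so heat maps are comparable along time; ``per_frame=True`` normalizes each
    frame pair by its own maximum instead.  All-zero input maps to all zeros.
    """
    f = np.asarray(fractions, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if per_frame:
        peak = f.max(axis=tuple(range(1, f.ndim)), keepdims=True)
    else:
        peak = f.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(peak > 0, 255.0 * f / peak, 0.0)
    return np.floor(scaled + 0.5).astype(np.uint8)


def movement_map(
    binary: BinaryStack,
    block: int = DEFAULT_BLOCK,
    per_frame_normalization: bool = False,
) -> MovementMap:
    """Full movement quantification of a binarized movie."""
    frames = binary.frames
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames")
    fractions = np.stack(
        [subblock_movement(frames[t], frames[t + 1], block) for t in range(frames.shape[0] - 1)]
    )
    heat = movement_heatmaps(fractions, per_frame=per_frame_normalization)
    return MovementMap(fractions=fractions, heatmaps=heat, block_size=block)


def cell_movement_profile(mmap: MovementMap, cell_mask: np.ndarray) -> np.ndarray:
    """Temporal motion profile of one cell: mean block fraction per frame pair.

    The pixel-level cell mask is resampled to the block grid; a block counts
    as belonging to the cell when at least 50% of its area is covered.
    """
    block = mmap.block_size
    mask = np.asarray(cell_mask) > 0
    coverage = _block_view(mask, block).mean(axis=(1, 3))
    if coverage.shape != mmap.fractions.shape[1:]:
        raise ValueError("cell mask does not match the movie geometry")
    sel = coverage >= 0.5
    if not sel.any():
        raise ValueError("cell mask covers no block at >= 50%")
    return mmap.fractions[:, sel].mean(axis=1)
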