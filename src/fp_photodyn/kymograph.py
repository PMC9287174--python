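"""Kymograph analysis of rapid tubule oscillations and image FFT spectra.

A tubule segment with stable endpoints is described by an axis (two
endpoints); the fluorescence profile along the perpendicular bisector of that
axis, sampled every frame, forms a kymograph.  The transverse position of the
intensity peak tracked over time is Fourier-analysed in fixed-length windows
(default 128 samples), which at 134.47 frames/s gives a frequency resolution
of 134.47/128 ~= 1.05 Hz.  Radially averaged image FFT spectra quantify how
much high-spatial-frequency content (resolution) a movie retains over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks
from skimage.morphology import remove_small_objects

from .er_dynamics import MovieStack

__all__ = [
    "AxisSpec",
    "Kymograph",
    "PeakTrack",
    "OscillationSpectrum",
    "RadialSpectrum",
    "remove_small_components",
    "masked_crop",
    "perpendicular_profile",
    "build_kymograph",
    "peak_position_track",
    "windowed_fft",
    "image_fft_spectrum",
]


@dataclass(frozen=True)
class AxisSpec:
    """User-drawn axis along a tubule, in pixel (x, y) coordinates.

    The analysis samples the intensity along the perpendicular bisector of the
    segment p1-p2, from -profile_halflength to +profile_halflength in steps of
    sample_spacing (pixels; sub-pixel positions allowed).
    """

    p1: tuple[float, float]
    p2: tuple[float, float]
    profile_halflength: float = 16.0
    sample_spacing: float = 0.5

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise ValueError("axis endpoints must differ")
        if self.profile_halflength <= 0 or self.sample_spacing <= 0:
            raise ValueError("profile_halflength and sample_spacing must be positive")

    @property
    def positions(self) -> np.ndarray:
        """Signed sample offsets from the axis, symmetric about 0."""
        n = int(round(self.profile_halflength / self.sample_spacing))
        return np.arange(-n, n + 1) * self.sample_spacing

    def sample_points(self) -> np.ndarray:
        """(P, 2) array of (x, y) sample coordinates along the bisector."""
        p1 = np.asarray(self.p1, dtype=float)
        p2 = np.asarray(self.p2, dtype=float)
        mid = 0.5 * (p1 + p2)
        d = (p2 - p1) / np.linalg.norm(p2 - p1)
        normal = np.array([-d[1], d[0]])
        return mid[None, :] + self.positions[:, None] * normal[None, :]


@dataclass
class Kymograph:
    """Time x position intensity matrix along a perpendicular bisector."""

    matrix: np.ndarray  # (T, P)
    positions: np.ndarray  # (P,) signed pixels from the axis
    frame_rate: float  # frames per second


@dataclass
class PeakTrack:
    """Per-frame position of the kymograph intensity maximum.

    ``positions`` is NaN for all-zero rows.  ``single_peak`` is True where
    exactly one local maximum exceeds half the row maximum, the criterion for
    an unambiguous transverse tubule position.
    """

    positions: np.ndarray
    single_peak: np.ndarray


@dataclass
class OscillationSpectrum:
    """One-sided FFT magnitude spectra of the peak-position track.

    ``amplitudes`` has one row per accepted window; ``freqs`` spacing is
    exactly frame_rate/window.
    """

    freqs: np.ndarray
    amplitudes: np.ndarray  # (n_windows, len(freqs))
    window: int

    @property
    def mean_amplitude(self) -> np.ndarray:
        return self.amplitudes.mean(axis=0)

    def dominant_frequency(self) -> float:
        """Frequency of the largest non-DC bin of the window-averaged spectrum."""
        mean = self.mean_amplitude
        return float(self.freqs[1 + int(np.argmax(mean[1:]))])


@dataclass
class RadialSpectrum:
    """Radially averaged log-magnitude image spectrum."""

    freqs: np.ndarray  # cycles/pixel
    log_magnitude: np.ndarray
    freqs_per_um: np.ndarray | None = None


def remove_small_components(binary: np.ndarray, min_area: int, connectivity: int = 2) -> np.ndarray:
    """Drop connected components smaller than ``min_area`` pixels.

    Components of area >= min_area are kept (a 20-pixel blob survives a
    min_area of 20).  8-connectivity by default (``connectivity=2``).
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = np.asarray(binary).astype(bool)
    if min_area == 1:
        return mask.copy()
    return remove_small_objects(mask, max_size=min_area - 1, connectivity=connectivity)


def masked_crop(raw: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Keep raw intensities where the mask is set, zero elsewhere.

    Bit depth is preserved so 16-bit detail survives the masking step.
    """
    raw = np.asarray(raw)
    mask = np.asarray(mask)
    if raw.shape != mask.shape:
        raise ValueError("raw frame and mask must have the same shape")
    return np.where(mask.astype(bool), raw, np.zeros((), dtype=raw.dtype)).astype(raw.dtype)


def perpendicular_profile(frame: np.ndarray, axis: AxisSpec) -> np.ndarray:
    """Bilinear intensity profile along the perpendicular bisector of the axis."""
    frame = np.asarray(frame, dtype=float)
    pts = axis.sample_points()  # (P, 2) as (x, y)
    xs, ys = pts[:, 0], pts[:, 1]
    h, w = frame.shape
    if np.any(xs < 0) or np.any(xs > w - 1) or np.any(ys < 0) or np.any(ys > h - 1):
        warnings.warn("profile samples fall outside the image; clipped to bounds",
                      stacklevel=2)
        xs = np.clip(xs, 0, w - 1)
        ys = np.clip(ys, 0, h - 1)
    return map_coordinates(frame, [ys, xs], order=1, mode="nearest")


def build_kymograph(
    movie: MovieStack,
    axis: AxisSpec,
    preprocess=None,
    frame_rate: float | None = None,
) -> Kymograph:
    """Stack per-frame bisector profiles into a kymograph.

    ``preprocess`` is an optional callable applied to each raw frame before
    sampling (e.g. mask -> small-object removal -> 16-bit crop).
    """
    if frame_rate is None:
        frame_rate = movie.frame_rate
    rows = np.empty((movie.n_frames, axis.positions.size))
    for t in range(movie.n_frames):
        f = movie.frames[t]
        if preprocess is not None:
            f = preprocess(f)
        rows[t] = perpendicular_profile(f, axis)
    return Kymograph(matrix=rows, positions=axis.positions.copy(), frame_rate=frame_rate)


def peak_position_track(k: Kymograph) -> PeakTrack:
    """Track the position of maximum intensity in each kymograph row.

    Ties are broken toward position 0; a tie set symmetric about 0 reports
    position 0.  The single-peak flag is True when exactly one local maximum
    exceeds 50% of the row maximum; maxima additionally need a prominence of
    10% of the row maximum so shot-noise wiggles riding a single ridge do not
    count as separate peaks.  All-zero rows yield NaN (missing).
    """
    T = k.matrix.shape[0]
    pos = np.full(T, np.nan)
    single = np.zeros(T, dtype=bool)
    for t in range(T):
        row = k.matrix[t]
        m = row.max()
        if m <= 0:
            continue
        tied = k.positions[row == m]
        closest = tied[np.abs(tied) == np.abs(tied).min()]
        pos[t] = float(closest.mean())  # symmetric pair about 0 -> 0
        padded = np.concatenate(([-np.inf], row, [-np.inf]))
        peaks, _ = find_peaks(padded, height=0.5 * m, prominence=0.1 * m)
        single[t] = peaks.size == 1
    return PeakTrack(positions=pos, single_peak=single)


def windowed_fft(
    track: np.ndarray,
    frame_rate: float,
    window: int = 128,
) -> OscillationSpectrum:
    """FFT of the peak-position track in consecutive fixed-length windows.

    Each non-overlapping block of ``window`` samples is mean-subtracted and
    transformed with a rectangular window (no taper), so the frequency axis
    has spacing exactly frame_rate/window.  Windows containing missing values
    are skipped, never interpolated.
    """
    track = np.asarray(track, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    if track.size < window:
        raise ValueError(f"track has {track.size} samples, need >= {window}")
    if window & (window - 1):
        warnings.warn(f"window {window} is not a power of two", stacklevel=2)
    freqs = np.arange(window // 2 + 1) * (frame_rate / window)
    spectra = []
    for start in range(0, track.size - window + 1, window):
        block = track[start : start + window]
        if np.any(~np.isfinite(block)):
            continue
        spectra.append(np.abs(np.fft.rfft(block - block.mean())))
    if not spectra:
        raise ValueError("no window free of missing values")
    return OscillationSpectrum(freqs=freqs, amplitudes=np.array(spectra), window=window)


def image_fft_spectrum(image: np.ndarray, pixel_size_nm: float | None = None) -> RadialSpectrum:
    """Radially averaged log10 FFT magnitude of a single image.

    Frequencies are in cycles/pixel (Nyquist at 0.5); when the pixel size is
    known the axis is also returned in cycles/um.  Used to compare how much
    fine structure the first and last frames of a movie retain.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    mag = np.abs(np.fft.fft2(img))
    fy = np.fft.fftfreq(img.shape[0])
    fx = np.fft.fftfreq(img.shape[1])
    rho = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    n_bins = min(img.shape) // 2
    step = 0.5 / n_bins
    idx = np.minimum((rho / step).astype(int), n_bins - 1)
    logmag = np.log10(mag + 1e-12)
    sums = np.bincount(idx.ravel(), weights=logmag.ravel(), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    radial = sums / counts
    freqs = (np.arange(n_bins) + 0.5) * step
    per_um = freqs * 1000.0 / pixel_size_nm if pixel_size_nm else None
    return RadialSpectrum(freqs=freqs, log_magnitude=radial, freqs_per_um=per_um)
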