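"""Photobleaching kinetics on the standardized photon-emission-rate scale.

Photostability of fluorescent proteins is compared on a brightness-adjusted
scale: the measured intensity decay is rescaled so that the curve starts at an
emission rate of 1,000 photons/s/molecule, and the time axis is stretched by
the ratio of the true initial per-molecule emission rate to 1,000.  The true
rate follows from the absorption cross-section at the illumination wavelength,
the fluorescence quantum yield and the excitation photon flux.  The bleaching
half-time t1/2 is then the time for the normalized rate to fall from 1,000 to
500 photons/s/molecule, which makes proteins with very different molecular
brightness directly comparable.

This module also computes molecular brightness (eps(lambda_ab) x QY), the
alkali-denaturation extinction-coefficient estimate, and the power-law fit of
bleaching half-time against irradiance, log10(t_half) = -alpha*log10(I) + c.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SpectralParams",
    "BleachTrace",
    "NormalizedCurve",
    "HalfTimeResult",
    "PowerLawFit",
    "absorption_cross_section",
    "initial_emission_rate",
    "normalize_trace",
    "smooth_curve",
    "half_time",
    "molecular_brightness",
    "extinction_from_alkali",
    "fit_irradiance_powerlaw",
]

#: Avogadro constant, mol^-1 (CODATA 2018, exact).
N_AVOGADRO = 6.02214076e23
#: Planck constant, J s (exact).
PLANCK_H = 6.62607015e-34
#: Speed of light in vacuum, m/s (exact).
SPEED_OF_LIGHT = 2.99792458e8
#: Molar extinction of the alkali-denatured GFP-type chromophore at 447 nm.
ALKALI_EPS_447 = 44_000.0
#: Rates above this (on the 1,000-normalized scale) flag a photoactivation rise.
PHOTOACTIVATION_LEVEL = 1050.0


@dataclass(frozen=True)
class SpectralParams:
    """Photophysical constants of one fluorophore.

    Parameters
    ----------
    name : str
        Fluorophore identifier (e.g. ``"StayGold"``).
    eps_peak : float
        Extinction coefficient at the absorbance maximum, M^-1 cm^-1.
    eps_ex : float
        Extinction coefficient at the excitation wavelength, M^-1 cm^-1.
    qy : float
        Fluorescence quantum yield in [0, 1].
    lambda_ab : float
        Absorbance maximum, nm.
    lambda_em : float
        Emission maximum, nm.
    """

    name: str
    eps_peak: float
    eps_ex: float
    qy: float
    lambda_ab: float
    lambda_em: float

    def __post_init__(self) -> None:
        if not (self.eps_peak >= self.eps_ex >= 0):
            raise ValueError(
                f"{self.name}: require eps_peak >= eps_ex >= 0, "
                f"got {self.eps_peak}, {self.eps_ex}"
            )
        if not (0 <= self.qy <= 1):
            raise ValueError(f"{self.name}: quantum yield {self.qy} outside [0, 1]")
        if not (self.lambda_em >= self.lambda_ab > 0):
            raise ValueError(
                f"{self.name}: require lambda_em >= lambda_ab > 0, "
                f"got {self.lambda_ab}, {self.lambda_em}"
            )


@dataclass
class BleachTrace:
    """Raw photobleaching intensity trace under continuous illumination.

    ``times`` (s, strictly increasing, starting at 0) and ``intensities``
    (detector units, >= 0) must have equal length >= 2.  ``irradiance`` is the
    excitation power density in W cm^-2 and ``lambda_ex`` the excitation center
    wavelength in nm.  Sampling need not be uniform; gaps (e.g. dark-recovery
    shutter closures) are represented simply by larger time steps.
    """

    times: np.ndarray
    intensities: np.ndarray
    irradiance: float
    lambda_ex: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.size < 2:
            raise ValueError("times and intensities must have equal length >= 2")
        if self.times[0] != 0:
            raise ValueError("trace must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if not self.irradiance > 0:
            raise ValueError("irradiance must be positive")


@dataclass
class NormalizedCurve:
    """Bleaching curve on the standard 1,000 photons/s/molecule scale."""

    norm_times: np.ndarray
    rates: np.ndarray
    scale_factor: float


@dataclass
class HalfTimeResult:
    """Bleaching half-time: first crossing from 1,000 down through 500.

    ``censored`` is True when the curve never drops to 500 within the record
    (the half-time is then a lower bound, ``t_half`` is None).
    ``photoactivation`` flags curves whose normalized rate exceeds 1,050 at any
    point, i.e. an initial photoactivation rise.
    """

    t_half: float | None
    censored: bool
    photoactivation: bool = False


@dataclass
class PowerLawFit:
    """Least-squares fit of log10(t_half) = -alpha*log10(irradiance) + c."""

    alpha: float
    c: float
    r_squared: float
    alpha_se: float = field(default=float("nan"))
    c_se: float = field(default=float("nan"))


def absorption_cross_section(eps_ex: float) -> float:
    """Absorption cross-section sigma (cm^2/molecule) from a molar extinction.

    sigma = 1000 * ln(10) * eps / N_A  ~= 3.8236e-21 * eps, with eps in
    M^-1 cm^-1.  The factor 1000 converts litres to cm^3.
    """
    if eps_ex < 0:
        raise ValueError(f"extinction coefficient must be >= 0, got {eps_ex}")
    return 1000.0 * math.log(10.0) * eps_ex / N_AVOGADRO


def initial_emission_rate(sp: SpectralParams, irradiance: float, lambda_ex: float) -> float:
    """Initial fluorescence emission rate, photons/s/molecule.

    rate = QY * sigma(eps_ex) * phi, where the excitation photon flux is
    phi = irradiance * lambda / (h c) in photons s^-1 cm^-2 (irradiance in
    W cm^-2, lambda converted to metres).
    """
    if irradiance <= 0:
        raise ValueError("irradiance must be positive")
    if lambda_ex <= 0:
        raise ValueError("excitation wavelength must be positive")
    if sp.qy == 0:
        warnings.warn(
            f"{sp.name}: quantum yield is 0; emission rate is 0 and the "
            "standard-scale normalization is undefined downstream",
            stacklevel=2,
        )
        return 0.0
    sigma = absorption_cross_section(sp.eps_ex)
    photon_energy = PLANCK_H * SPEED_OF_LIGHT / (lambda_ex * 1e-9)  # J
    photon_flux = irradiance / photon_energy  # photons s^-1 cm^-2
    return sp.qy * sigma * photon_flux


def normalize_trace(trace: BleachTrace, sp: SpectralParams) -> NormalizedCurve:
    """Rescale a raw trace onto the standard emission-rate scale.

    Intensities are scaled so the first sample is exactly 1,000
    photons/s/molecule; the time axis is multiplied by
    ``initial_emission_rate / 1000`` so that equal normalized times correspond
    to equal numbers of photons emitted per molecule.
    """
    if trace.intensities[0] <= 0:
        raise ValueError("cannot normalize a trace whose initial intensity is <= 0")
    rate0 = initial_emission_rate(sp, trace.irradiance, trace.lambda_ex)
    if rate0 <= 0:
        raise ValueError(f"{sp.name}: initial emission rate is not positive")
    rates = trace.intensities * (1000.0 / trace.intensities[0])
    rates[0] = 1000.0  # exact by construction
    scale = rate0 / 1000.0
    return NormalizedCurve(norm_times=trace.times * scale, rates=rates, scale_factor=scale)


def smooth_curve(curve: NormalizedCurve, window: int) -> NormalizedCurve:
    """Centered moving average of the rates; the t=0 anchor stays at 1,000.

    First-crossing half-times are biased early on noisy traces, because any
    downward noise excursion before the true crossing triggers detection;
    averaging over an odd ``window`` of samples (a small fraction of the
    half-time) removes the bias without shifting the crossing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window == 1:
        return NormalizedCurve(curve.norm_times.copy(), curve.rates.copy(), curve.scale_factor)
    kernel = np.ones(window) / window
    rates = np.convolve(curve.rates, kernel, mode="same")
    rates[0] = curve.rates[0]
    return NormalizedCurve(curve.norm_times.copy(), rates, curve.scale_factor)


def half_time(curve: NormalizedCurve) -> HalfTimeResult:
    """First time the normalized rate falls through 500 photons/s/molecule.

    The crossing is located by linear interpolation between the bracketing
    samples.  A curve that never reaches 500 is censored, not an error.
    """
    rates = np.asarray(curve.rates, dtype=float)
    times = np.asarray(curve.norm_times, dtype=float)
    photoact = bool(np.max(rates) > PHOTOACTIVATION_LEVEL)
    below = np.nonzero(rates <= 500.0)[0]
    below = below[below > 0]
    if below.size == 0:
        return HalfTimeResult(t_half=None, censored=True, photoactivation=photoact)
    i = int(below[0])
    r_prev, r_next = rates[i - 1], rates[i]
    if r_next == 500.0:
        t = times[i]
    else:
        t = times[i - 1] + (times[i] - times[i - 1]) * (r_prev - 500.0) / (r_prev - r_next)
    return HalfTimeResult(t_half=float(t), censored=False, photoactivation=photoact)


def molecular_brightness(eps_peak_kilo: float, qy: float) -> int:
    """Molecular brightness: eps(lambda_ab) in 10^3 M^-1 cm^-1 times QY.

    Rounded to the nearest integer, halves away from zero, matching the
    convention of published brightness tables.
    """
    if eps_peak_kilo < 0 or qy < 0:
        raise ValueError("extinction and quantum yield must be >= 0")
    x = eps_peak_kilo * qy
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def extinction_from_alkali(abs_native_peak: float, abs_denat_447: float) -> float:
    """Extinction coefficient by the alkali-denaturation ratio method.

    After alkali denaturation the GFP-type chromophore absorbs maximally at
    447 nm with eps = 44,000 M^-1 cm^-1; at equal concentration the native
    peak extinction is 44,000 * A_native / A_denat(447).
    """
    if abs_denat_447 <= 0:
        raise ValueError("denatured-state absorbance at 447 nm must be positive")
    if abs_native_peak < 0:
        raise ValueError("native absorbance must be >= 0")
    return ALKALI_EPS_447 * abs_native_peak / abs_denat_447


def fit_irradiance_powerlaw(pairs) -> PowerLawFit:
    """OLS fit of log10(t_half) on log10(irradiance).

    ``pairs`` is a sequence of (irradiance W cm^-2, t_half s) tuples, all
    strictly positive, at least two of them.  Returns the slope magnitude
    alpha, intercept c, r^2 and the standard errors of alpha and c.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (irradiance, t_half) pairs")
    if np.any(arr <= 0):
        raise ValueError("irradiance and t_half values must all be positive")
    x = np.log10(arr[:, 0])
    y = np.log10(arr[:, 1])
    res = stats.linregress(x, y)
    return PowerLawFit(
        alpha=-res.slope,
        c=res.intercept,
        r_squared=res.rvalue**2,
        alpha_se=res.stderr,
        c_se=res.intercept_stderr,
    )
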