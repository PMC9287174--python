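"""Readers and writers for the TIFF/CSV/JSON formats the pipeline uses.

Movies travel as single- or multi-page grayscale TIFF stacks; acquisition
metadata (frame interval, pixel size, irradiance) travels in a sidecar JSON
next to the TIFF, because TIFF tags are unreliable across writers.  Traces
and spectral tables are plain CSV with mandatory headers.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .er_dynamics import MovieStack
from .photophysics import BleachTrace, SpectralParams

__all__ = [
    "UnsupportedFormatError",
    "read_movie",
    "write_movie",
    "read_label_mask",
    "read_bleach_trace",
    "write_bleach_trace",
    "read_spectra",
    "load_reference_spectra",
    "write_json",
]


class UnsupportedFormatError(ValueError):
    """Raised for image files the pipeline cannot interpret."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_movie(path, frame_interval: float | None = None) -> MovieStack:
    """Read a single- or multi-page grayscale TIFF as a T x H x W stack.

    A single page becomes a T=1 stack.  RGB or floating-point TIFFs are
    rejected.  The frame interval comes from the ``<name>.tif.json`` sidecar
    when present, from the argument otherwise (default 1 s).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise UnsupportedFormatError(
                f"{path.name}: {page.samplesperpixel} samples/pixel "
                "(RGB/multichannel TIFFs are not supported)"
            )
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise UnsupportedFormatError(
            f"{path.name}: expected grayscale pages, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise UnsupportedFormatError(
            f"{path.name}: dtype {arr.dtype} not supported; use 8/16-bit grayscale"
        )
    pixel_size = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame_interval = meta.get("frame_interval", frame_interval)
        pixel_size = meta.get("pixel_size")
    return MovieStack(
        frames=arr,
        frame_interval=frame_interval if frame_interval else 1.0,
        pixel_size=pixel_size,
    )


def write_movie(path, movie: MovieStack) -> None:
    """Write a movie as multi-page TIFF plus a metadata sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.frames), photometric="minisblack")
    meta = {"frame_interval": movie.frame_interval}
    if movie.pixel_size is not None:
        meta["pixel_size"] = movie.pixel_size
    _sidecar_path(path).write_text(json.dumps(meta))


def read_label_mask(path) -> np.ndarray:
    """Read an integer label image (0 = background) from TIFF."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.integer):
        raise UnsupportedFormatError(f"{Path(path).name}: expected a 2-D integer label image")
    return arr


def read_bleach_trace(path, irradiance: float, lambda_ex: float) -> BleachTrace:
    """Read a trace CSV with mandatory header columns time_s,intensity."""
    df = pd.read_csv(path)
    missing = {"time_s", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing required columns {sorted(missing)}")
    return BleachTrace(
        times=df["time_s"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        irradiance=irradiance,
        lambda_ex=lambda_ex,
    )


def write_bleach_trace(path, trace: BleachTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "intensity": trace.intensities}).to_csv(
        path, index=False
    )


def _spectra_from_frame(df: pd.DataFrame) -> dict[str, SpectralParams]:
    required = {"name", "eps_peak", "eps_ex", "qy", "lambda_ab", "lambda_em"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spectral table missing columns {sorted(missing)}")
    return {
        str(row["name"]): SpectralParams(
            name=str(row["name"]),
            eps_peak=float(row["eps_peak"]),
            eps_ex=float(row["eps_ex"]),
            qy=float(row["qy"]),
            lambda_ab=float(row["lambda_ab"]),
            lambda_em=float(row["lambda_em"]),
        )
        for _, row in df.iterrows()
    }


def read_spectra(path) -> dict[str, SpectralParams]:
    """Read a spectral-parameter CSV keyed by fluorophore name."""
    return _spectra_from_frame(pd.read_csv(path))


def load_reference_spectra() -> dict[str, SpectralParams]:
    """Published photophysics of the five green-emitting reference proteins."""
    ref = resources.files("fp_photodyn") / "data" / "green_fp_spectra.csv"
    with ref.open() as fh:
        return _spectra_from_frame(pd.read_csv(fh))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return None if np.isnan(obj) else float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(path, payload: dict) -> None:
    """Write a JSON result file with numpy-safe full-precision encoding."""
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")
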