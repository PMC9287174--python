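"""Reproducible stage runner: config in, results + config + log out.

Each stage reads its inputs, runs one analysis from the library, and writes
results into an output directory along with the resolved configuration and
the seed used, so any run can be repeated exactly.  Numeric outputs are
written at full precision to CSV/JSON; heat-map images are presentation-only
renderings and are never re-read for computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__, cell_assays, er_dynamics, io as fpio, kymograph, synthetic

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("fp_photodyn")


@dataclass
class RunConfig:
    """Parameters of one pipeline run; recorded verbatim in the output dir."""

    command: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "params": {k: _jsonable(v) for k, v in self.params.items()},
            "seed": self.seed,
            "version": self.version,
        }


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def _require_inputs(params: dict, keys: list[str]) -> None:
    """Validate every input path before any output is written."""
    for key in keys:
        p = params.get(key)
        if p is None:
            raise FileNotFoundError(f"missing required input parameter '{key}'")
        if not Path(p).exists():
            raise FileNotFoundError(f"input {key}={p} does not exist")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute one named stage and write its result bundle.

    Returns a dict of the principal numeric results.  Raises on any stage
    error before partial outputs are committed (inputs are validated first).
    """
    stage = _STAGES.get(config.command)
    if stage is None:
        raise ValueError(f"unknown command {config.command!r}; choose from {sorted(_STAGES)}")
    outdir = Path(outdir)
    p = dict(config.params)
    stage_inputs = _STAGE_INPUTS.get(config.command, [])
    _require_inputs(p, stage_inputs)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    result = stage(p, config.seed, outdir)
    fpio.write_json(outdir / "config.json", config.to_dict())
    fpio.write_json(outdir / "result.json", result)
    return result


def _stage_bleach(p: dict, seed: int, outdir: Path) -> dict:
    from . import photophysics as ph

    spectra = fpio.read_spectra(p["spectra"]) if "spectra" in p else fpio.load_reference_spectra()
    name = p["name"]
    if name not in spectra:
        raise KeyError(f"fluorophore {name!r} not in the spectral table")
    trace = fpio.read_bleach_trace(p["trace"], p["irradiance"], p["wavelength"])
    curve = ph.normalize_trace(trace, spectra[name])
    res = ph.half_time(curve)
    pd.DataFrame({"norm_time_s": curve.norm_times, "rate_photons_s": curve.rates}).to_csv(
        outdir / "normalized_curve.csv", index=False
    )
    return {
        "name": name,
        "scale_factor": curve.scale_factor,
        "t_half_s": res.t_half,
        "censored": res.censored,
        "photoactivation": res.photoactivation,
    }


def _stage_brightness(p: dict, seed: int, outdir: Path) -> dict:
    green = tifffile.imread(p["green"])
    red = tifffile.imread(p["red"])
    labels = fpio.read_label_mask(p["labels"])
    cells = cell_assays.measure_cells(green, red, labels)
    ref = float(p.get("reference_ratio", 1.0))
    rows = [
        {"cell_id": c.cell_id, "green": c.green, "red": c.red,
         "ratio": c.green / c.red if c.red > 0 else np.nan}
        for c in cells
    ]
    pd.DataFrame(rows).to_csv(outdir / "cells.csv", index=False)
    return {
        "n_cells": len(cells),
        "relative_brightness": cell_assays.brightness_ratio(cells, ref),
        "relative_brightness_field": cell_assays.brightness_ratio_field(cells, ref),
    }


def _stage_maturation(p: dict, seed: int, outdir: Path) -> dict:
    movie = fpio.read_movie(p["movie"])
    masks = tifffile.imread(p["masks"])
    series = cell_assays.maturation_timecourse(
        movie.frames, masks, background=float(p.get("background", 0.0))
    )
    pd.DataFrame(
        {"time": series.times, "fi_per_area": series.fi_per_area, "normalized": series.normalized}
    ).to_csv(outdir / "maturation.csv", index=False)
    finite = np.isfinite(series.normalized)
    return {"n_timepoints": int(finite.sum()),
            "peak_time": float(series.times[np.nanargmax(series.fi_per_area)])}


def _stage_ermap(p: dict, seed: int, outdir: Path) -> dict:
    movie = fpio.read_movie(p["movie"])
    roi = fpio.read_label_mask(p["roi"]) > 0 if "roi" in p and p["roi"] else None
    binary = er_dynamics.binarize_stack(movie, roi)
    for t, thr in enumerate(binary.thresholds):
        log.info("frame %d: Otsu threshold %s", t, thr)
    block = int(p.get("block", 16))
    mmap = er_dynamics.movement_map(
        binary, block=block, per_frame_normalization=bool(p.get("per_frame", False))
    )
    t_idx, bi, bj = np.indices(mmap.fractions.shape).reshape(3, -1)
    pd.DataFrame(
        {"t": t_idx, "bi": bi, "bj": bj, "fraction": mmap.fractions.ravel()}
    ).to_csv(outdir / "fractions.csv", index=False)
    tifffile.imwrite(outdir / "heatmaps.tif", mmap.heatmaps)
    iio.imwrite(outdir / "heatmap_mean.png",
                er_dynamics.movement_heatmaps(mmap.fractions.mean(axis=0)[None])[0])
    return {
        "n_frame_pairs": int(mmap.fractions.shape[0]),
        "block": block,
        "mean_fraction": float(mmap.fractions.mean()),
        "max_fraction": float(mmap.fractions.max()),
    }


def _parse_axis(p: dict) -> kymograph.AxisSpec:
    x1, y1, x2, y2 = (float(v) for v in str(p["axis"]).split(","))
    return kymograph.AxisSpec(
        p1=(x1, y1),
        p2=(x2, y2),
        profile_halflength=float(p.get("halflength", 16.0)),
        sample_spacing=float(p.get("spacing", 0.5)),
    )


def _stage_kymo(p: dict, seed: int, outdir: Path) -> dict:
    movie = fpio.read_movie(p["movie"])
    axis = _parse_axis(p)
    min_area = int(p.get("min_area", 20))

    def preprocess(frame):
        mask, _, degenerate = er_dynamics.binarize_frame(
            frame, np.ones(frame.shape, dtype=bool)
        )
        if degenerate:
            return frame
        mask = kymograph.remove_small_components(mask, min_area)
        return kymograph.masked_crop(frame, mask)

    kymo = kymograph.build_kymograph(movie, axis, preprocess=preprocess)
    track = kymograph.peak_position_track(kymo)
    window = int(p.get("window", 128))
    spectrum = kymograph.windowed_fft(track.positions, kymo.frame_rate, window=window)
    tifffile.imwrite(outdir / "kymograph.tif", kymo.matrix.astype(np.float32))
    pd.DataFrame(
        {"frame": np.arange(track.positions.size), "position_px": track.positions,
         "single_peak": track.single_peak}
    ).to_csv(outdir / "peak_track.csv", index=False)
    spec_df = pd.DataFrame({"freq_hz": spectrum.freqs, "amplitude": spectrum.mean_amplitude})
    spec_df.to_csv(outdir / "spectrum.csv", index=False)
    return {
        "frame_rate": kymo.frame_rate,
        "frequency_unit_hz": float(spectrum.freqs[1]),
        "dominant_frequency_hz": spectrum.dominant_frequency(),
        "n_windows": int(spectrum.amplitudes.shape[0]),
    }


def _stage_fftspec(p: dict, seed: int, outdir: Path) -> dict:
    movie = fpio.read_movie(p["movie"])
    out = {}
    for label, idx in (("first", 0), ("last", movie.n_frames - 1)):
        spec = kymograph.image_fft_spectrum(movie.frames[idx], pixel_size_nm=movie.pixel_size)
        pd.DataFrame({"freq_cyc_per_px": spec.freqs, "log10_magnitude": spec.log_magnitude}).to_csv(
            outdir / f"fftspec_{label}.csv", index=False
        )
        out[f"{label}_highfreq_logmag"] = float(spec.log_magnitude[-len(spec.freqs) // 4 :].mean())
    return out


def _stage_simulate(p: dict, seed: int, outdir: Path) -> dict:
    what = p.get("what", "bleach")
    if what == "bleach":
        trace, truth = synthetic.simulate_bleach_trace(
            k=float(p.get("k", 1e-3)),
            model=p.get("model", "mono"),
            noise_cv=float(p.get("noise_cv", 0.0)),
            n_points=int(p.get("n_points", 600)),
            dt=float(p.get("dt", 6.0)),
            seed=seed,
        )
        fpio.write_bleach_trace(outdir / "trace.csv", trace)
    elif what == "ermovie":
        movie, truth = synthetic.simulate_er_movie(
            osc_freq=float(p.get("osc_freq", 7.0)),
            n_frames=int(p.get("n_frames", 256)),
            seed=seed,
        )
        fpio.write_movie(outdir / "movie.tif", movie)
    elif what == "cells":
        cells, truth = synthetic.simulate_expression_field(
            n_cells=int(p.get("n_cells", 200)),
            true_relative_brightness=float(p.get("brightness", 2.06)),
            seed=seed,
        )
        pd.DataFrame([{"cell_id": c.cell_id, "green": c.green, "red": c.red} for c in cells]).to_csv(
            outdir / "cells.csv", index=False
        )
    else:
        raise ValueError(f"unknown simulation target {what!r}")
    fpio.write_json(outdir / "truth.json", {"seed": truth.seed, "params": truth.params,
                                            "description": truth.description})
    return {"what": what, "seed": seed}


_STAGES = {
    "bleach": _stage_bleach,
    "brightness": _stage_brightness,
    "maturation": _stage_maturation,
    "ermap": _stage_ermap,
    "kymo": _stage_kymo,
    "fftspec": _stage_fftspec,
    "simulate": _stage_simulate,
}

_STAGE_INPUTS = {
    "bleach": ["trace"],
    "brightness": ["green", "red", "labels"],
    "maturation": ["movie", "masks"],
    "ermap": ["movie"],
    "kymo": ["movie"],
    "fftspec": ["movie"],
}
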