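"""Frame and curve I/O plus the end-to-end evaluation pipeline.

Frames are exchanged as single-page TIFF (written 16-bit little-endian by
default, any integer/float dtype read back unscaled) or as headerless raw
binary with explicit geometry.  Pixel pitch is *metadata required at read
time* — it is never inferred from a file — because every frequency axis
depends on it.

Curves travel as two-column CSV with unit-bearing headers
(``frequency_lp_per_mm`` plus ``mtf``/``nnps_mm2``/``dqe``) that round-trip
losslessly at nine significant digits.

:func:`run_pipeline` ties the stages together: slanted-edge MTF from an edge
image, NNPS from a flat-field series, their combination into the DQE at a
stated beam quality and air kerma, and optional phantom CNR/COV — writing
the curves as CSV and a versioned JSON summary that records every decision
parameter (oversample, ROI side, detrend order, window) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .curves import DQECurve, FrequencyCurve, MTFCurve, NNPSCurve
from .exceptions import ConfigError, FormatError, PipelineStageError
from .frames import ImageFrame, ROIRect
from .metrics import compute_cnr, compute_cov, roi_stats
from .mtf import measure_mtf
from .nnps import measure_nnps
from .dqe import compute_dqe
from .protocols import get_beam_quality

__all__ = [
    "read_frame",
    "write_frame",
    "read_curve",
    "write_curve",
    "run_pipeline",
]

log = logging.getLogger("dqekit")

SUMMARY_SCHEMA_VERSION = 1

_METRIC_COLUMNS = {"mtf": "mtf", "nnps": "nnps_mm2", "dqe": "dqe"}


# ----------------------------------------------------------------------------
# frames

def read_frame(path: str | Path, pixel_pitch: float, format: str = "tiff",
               width: int | None = None, height: int | None = None,
               dtype: str = "uint16", endianness: str = "little") -> ImageFrame:
    """Read a frame from TIFF or headerless raw binary.

    Pixel values are taken as linear detector signal with no rescaling.
    Raw files require the full geometry (width, height, dtype, endianness);
    a byte-count mismatch raises :class:`FormatError` naming both counts.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tiff":
        data = tifffile.imread(path)
        if data.ndim != 2:
            raise FormatError(f"expected a single-page 2-D TIFF, got shape "
                              f"{data.shape}")
        return ImageFrame(pixels=np.asarray(data), pixel_pitch=pixel_pitch)
    if format == "raw":
        if width is None or height is None:
            raise ConfigError("raw format requires explicit width and height")
        dt = np.dtype(dtype).newbyteorder("<" if endianness == "little" else ">")
        expected = width * height * dt.itemsize
        actual = path.stat().st_size
        if actual != expected:
            raise FormatError(
                f"raw file {path} holds {actual} bytes but geometry "
                f"{width}x{height}x{dt.itemsize} requires {expected}")
        data = np.fromfile(path, dtype=dt).reshape(height, width)
        return ImageFrame(pixels=data, pixel_pitch=pixel_pitch)
    raise ConfigError(f"unknown frame format {format!r}")


def write_frame(frame: ImageFrame, path: str | Path,
                dtype: str | None = "uint16") -> None:
    """Write a frame as a single-page little-endian TIFF.

    ``dtype="uint16"`` (default) rounds and clips to the 16-bit range;
    ``dtype=None`` keeps the array's values as 32-bit float, which preserves
    them exactly.
    """
    pixels = frame.pixels
    if dtype == "uint16":
        pixels = np.clip(np.round(pixels), 0, 65535).astype("<u2")
    elif dtype is None:
        pixels = pixels.astype("<f4")
    else:
        pixels = pixels.astype(np.dtype(dtype).newbyteorder("<"))
    tifffile.imwrite(Path(path), pixels)


# ----------------------------------------------------------------------------
# curves

def write_curve(curve: FrequencyCurve, path: str | Path) -> None:
    """Write a curve as CSV with unit-bearing headers (9 significant digits)."""
    if isinstance(curve, MTFCurve):
        metric = "mtf"
    elif isinstance(curve, NNPSCurve):
        metric = "nnps"
    elif isinstance(curve, DQECurve):
        metric = "dqe"
    else:
        raise ConfigError(f"cannot infer metric for {type(curve).__name__}")
    frame = pd.DataFrame({
        "frequency_lp_per_mm": curve.frequencies,
        _METRIC_COLUMNS[metric]: curve.values,
    })
    if metric == "nnps":
        frame["n_rois"] = curve.n_rois
    frame.to_csv(Path(path), index=False, float_format="%.9g")


def read_curve(path: str | Path) -> FrequencyCurve:
    """Read a curve CSV back into the matching curve type."""
    frame = pd.read_csv(Path(path))
    if "frequency_lp_per_mm" not in frame.columns:
        raise FormatError(f"{path}: missing frequency_lp_per_mm column")
    f = frame["frequency_lp_per_mm"].to_numpy()
    if "mtf" in frame.columns:
        return MTFCurve(frequencies=f, values=frame["mtf"].to_numpy(),
                        nyquist=float(f[-1]))
    if "nnps_mm2" in frame.columns:
        n_rois = int(frame["n_rois"].iloc[0]) if "n_rois" in frame.columns else 0
        return NNPSCurve(frequencies=f, values=frame["nnps_mm2"].to_numpy(),
                         n_rois=n_rois)
    if "dqe" in frame.columns:
        return DQECurve(frequencies=f, values=frame["dqe"].to_numpy(),
                        kerma=0.0, beam="")
    raise FormatError(f"{path}: no recognized metric column")


# ----------------------------------------------------------------------------
# pipeline

def _roi_from_config(value) -> ROIRect:
    x, y, w, h = (int(v) for v in value)
    return ROIRect(x, y, w, h)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False
    return _Ctx()


def run_pipeline(config: dict | str | Path,
                 out_dir: str | Path | None = None) -> dict:
    """Run the full evaluation chain MTF -> NNPS -> DQE (+ optional CNR/COV).

    ``config`` is a mapping (or path to a YAML file) with keys:

    - ``pixel_pitch_mm`` (required)
    - ``beam`` and ``kerma_uGy`` (required for the DQE stage)
    - ``edge_image``: path to the tilted-edge frame
    - ``flat_frames``: list of flat-field frame paths
    - ``mtf``: options (``roi`` [x,y,w,h], ``oversample``, ``window``)
    - ``nnps``: options (``roi_side``, ``detrend_order``, ``mode``,
      ``region``, ``reference``)
    - ``phantom``: optional ``image``, ``roi_a``, ``roi_b`` for CNR/COV

    Writes ``mtf.csv``, ``nnps.csv``, ``dqe.csv`` and ``summary.json`` to
    ``out_dir`` (if given) and returns the summary dict.  Any stage failure
    propagates as :class:`PipelineStageError` naming the stage.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    log.info("pipeline config hash %s", cfg_hash)

    pitch = float(config.get("pixel_pitch_mm", 0) or 0)
    if pitch <= 0:
        raise PipelineStageError("config", ConfigError(
            "pixel_pitch_mm is required and must be > 0"))

    mtf_opts = dict(config.get("mtf") or {})
    nnps_opts = dict(config.get("nnps") or {})
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "config_sha256": cfg_hash,
        "parameters": {
            "pixel_pitch_mm": pitch,
            "mtf_oversample": int(mtf_opts.get("oversample", 10)),
            "mtf_window": mtf_opts.get("window", "hann"),
            "nnps_roi_side": int(nnps_opts.get("roi_side", 256)),
            "nnps_detrend_order": int(nnps_opts.get("detrend_order", 2)),
            "nnps_mode": nnps_opts.get("mode", "axial"),
            "nnps_reference": nnps_opts.get("reference", "surface"),
        },
    }

    with _stage("mtf"):
        if "edge_image" not in config:
            raise ConfigError("config lacks 'edge_image'")
        edge = read_frame(config["edge_image"], pitch)
        roi = _roi_from_config(mtf_opts["roi"]) if "roi" in mtf_opts else None
        mtf = measure_mtf(edge, roi=roi,
                          oversample=summary["parameters"]["mtf_oversample"],
                          window=summary["parameters"]["mtf_window"])
        log.info("MTF: %d bins to Nyquist %.3f lp/mm", len(mtf), mtf.nyquist)

    with _stage("nnps"):
        paths = config.get("flat_frames") or []
        if not paths:
            raise ConfigError("config lacks 'flat_frames'")
        flats = [read_frame(p, pitch) for p in paths]
        nnps = measure_nnps(
            flats,
            roi_side=summary["parameters"]["nnps_roi_side"],
            detrend_order=summary["parameters"]["nnps_detrend_order"],
            mode=summary["parameters"]["nnps_mode"],
            region=int(nnps_opts.get("region", 1024)),
            reference=summary["parameters"]["nnps_reference"],
        )
        log.info("NNPS: %d bins from %d ROIs", len(nnps), nnps.n_rois)

    with _stage("dqe"):
        if "beam" not in config or "kerma_uGy" not in config:
            raise ConfigError("config lacks 'beam' / 'kerma_uGy'")
        bq = get_beam_quality(config["beam"],
                              str(config.get("protocol_version", "2015")))
        kerma = float(config["kerma_uGy"])
        dqe = compute_dqe(mtf, nnps, bq, kerma)

    summary["curves"] = {
        "mtf": {"n": len(mtf), "nyquist_lp_per_mm": mtf.nyquist,
                "at_half_nyquist": float(mtf.interp(mtf.nyquist / 2))},
        "nnps": {"n": len(nnps), "n_rois": nnps.n_rois,
                 "lowest_frequency_mm2": float(nnps.values[0])},
        "dqe": {"n": len(dqe), "beam": bq.name, "kerma_uGy": kerma,
                "low_frequency": float(dqe.values[0])},
    }

    if config.get("phantom"):
        with _stage("phantom_metrics"):
            ph = config["phantom"]
            image = read_frame(ph["image"], pitch)
            roi_a = _roi_from_config(ph["roi_a"])
            roi_b = _roi_from_config(ph["roi_b"])
            a, b = roi_stats(image, roi_a), roi_stats(image, roi_b)
            summary["phantom"] = {
                "roi_a": {"mean": a.mean, "sd": a.sd, "n": a.n},
                "roi_b": {"mean": b.mean, "sd": b.sd, "n": b.n},
                "cnr": compute_cnr(image, roi_a, roi_b),
                "cov_a": compute_cov(image, roi_a),
            }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_curve(mtf, out / "mtf.csv")
        write_curve(nnps, out / "nnps.csv")
        write_curve(dqe, out / "dqe.csv")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
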