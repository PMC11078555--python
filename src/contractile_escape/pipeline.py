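"""End-to-end orchestration: stacks in, displacement/spreading curves and
Table-style rate summaries out; creep-trace directories in, cohort
contractility summaries out.

Every run writes a manifest (settings echo, seeds, package versions, settings
hash) and is bit-reproducible: config plus seeds determine all CSV/JSON
outputs byte-identically.  Each stage can be re-run from the previous stage's
CSV outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import angular_profile, escape_displacement_correlation
from .io import read_image_sequence, read_traces
from .piv import (
    PIVSettings,
    SquareRoi,
    accumulate,
    displacement_curve,
    displacement_rate,
    estimate_sequence,
    explant_roi,
    write_fields_csv,
    write_series_csv,
)
from .spreading import (
    equivalent_radius,
    rasterize_polygon_masks,
    segment_sequence,
    spreading_curve,
    spreading_rate,
    write_spreading_csv,
)
from .stretcher import StretchProtocol, cohort_summary, fit_trace

log = logging.getLogger("contractile_escape")

__all__ = ["PipelineConfig", "PipelineError", "run_imaging_pipeline", "run_stretcher_pipeline"]


class PipelineError(RuntimeError):
    """Structured stage failure: names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    collagen_stack: str | None = None
    cell_stack: str | None = None
    masks_csv: str | None = None  # hand-drawn boundary polygons (explants)
    traces: str | None = None
    mode: str = "spheroid"  # or "explant"
    R0: float | str = "auto"  # um, or "auto" from first-frame segmentation
    piv_window: int = 32
    piv_overlap: float = 0.5
    protocol: dict = field(default_factory=dict)
    correlate: bool = False
    n_bins: int = 36
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def settings_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _manifest(config: PipelineConfig, stage: str, t0: float) -> dict:
    return {
        "stage": stage,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "settings": asdict(config),
        "settings_hash": config.settings_hash(),
        "seed": config.seed,
        "elapsed_s": round(time.monotonic() - t0, 3),
    }


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def run_imaging_pipeline(config: PipelineConfig) -> dict:
    """PIV -> accumulate -> |u|/R0 curve and rate; segmentation -> R_eq curve
    and area rate; optional angular escape-displacement correlation.

    Returns the summary dict; all stage outputs land in ``config.out_dir``.
    """
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    settings = PIVSettings(window=config.piv_window, overlap=config.piv_overlap)

    if config.collagen_stack and not Path(config.collagen_stack).exists():
        raise PipelineError("piv", f"collagen stack not found: {config.collagen_stack}")

    cell_masks = None
    cell_seq = None
    if config.cell_stack:
        if not Path(config.cell_stack).exists():
            raise PipelineError("spreading", f"cell stack not found: {config.cell_stack}")
        cell_seq = read_image_sequence(config.cell_stack)
        log.info("spreading: loaded %d frames from %s", len(cell_seq), config.cell_stack)
        if config.masks_csv:
            polys = pd.read_csv(config.masks_csv)
            cell_masks = rasterize_polygon_masks(
                polys, cell_seq.shape, cell_seq.times, cell_seq.pixel_size
            )
        else:
            cell_masks = segment_sequence(cell_seq)

    # resolve R0 and the ROI centre
    if config.R0 == "auto":
        if cell_masks is None:
            raise PipelineError("config", "R0='auto' needs a cell stack to segment")
        R0 = float(equivalent_radius(cell_masks.areas[0]))
        ys, xs = np.nonzero(cell_masks.masks[0])
        center = (float(xs.mean()) * cell_masks.pixel_size, float(ys.mean()) * cell_masks.pixel_size)
    else:
        R0 = float(config.R0)
        center = None
    summary["R0_um"] = R0

    if config.collagen_stack:
        seq = read_image_sequence(config.collagen_stack)
        log.info("piv: %d frames, window=%d", len(seq), settings.window)
        incremental = estimate_sequence(seq, settings)
        cumulative = accumulate(incremental)
        if config.mode == "explant":
            if center is None:
                h, w = seq.shape
                center = ((w - 1) / 2 * seq.pixel_size, (h - 1) / 2 * seq.pixel_size)
            roi = explant_roi(center, R0)
        else:
            roi = None
        series = displacement_curve(cumulative, R0=R0, times=seq.times[1:], roi=roi)
        write_fields_csv(cumulative, seq.times[1:], out / "cumulative_fields.csv")
        write_series_csv(series, out / "displacement_series.csv")
        summary["displacement_rate_um_per_h"] = displacement_rate(series)
        summary["final_normalized_displacement"] = float(series.normalized[-1])

    if cell_masks is not None:
        spread = spreading_curve(cell_masks)
        write_spreading_csv(spread, out / "spreading_series.csv")
        summary["spreading_rate_per_h"] = spreading_rate(cell_masks)
        summary["final_normalized_req"] = float(spread.normalized[-1])

    if config.correlate:
        if not (config.collagen_stack and cell_masks is not None):
            raise PipelineError("correlation", "needs both a collagen and a cell stack")
        prof = angular_profile(
            cumulative[-1],
            cell_masks.masks[0],
            cell_masks.masks[-1],
            center=center
            or (
                (seq.shape[1] - 1) / 2 * seq.pixel_size,
                (seq.shape[0] - 1) / 2 * seq.pixel_size,
            ),
            n_bins=config.n_bins,
            pixel_size=cell_masks.pixel_size,
            R0=R0,
        )
        pd.DataFrame(
            {
                "angle_rad": prof.bin_centers,
                "disp_mag_um": prof.disp_mag,
                "expansion_um": prof.boundary_expansion,
            }
        ).to_csv(out / "angular_profile.csv", index=False, float_format="%.6g")
        summary["escape_displacement_r"] = escape_displacement_correlation(prof)

    _write_json(summary, out / "summary.json")
    _write_json(_manifest(config, "imaging", t0), out / "manifest.json")
    return summary


def run_stretcher_pipeline(config: PipelineConfig) -> dict:
    """Fit the active SLS model to every trace and summarize the cohort."""
    t0 = time.monotonic()
    if not config.traces or not Path(config.traces).exists():
        raise PipelineError("stretcher", f"traces not found: {config.traces}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = StretchProtocol(**config.protocol)
    traces = read_traces(config.traces)
    if not traces:
        raise PipelineError("stretcher", f"no parsable traces in {config.traces}")
    log.info("stretcher: fitting %d traces", len(traces))

    fits = [
        fit_trace(tr, protocol, seed=config.seed + i) for i, tr in enumerate(traces)
    ]
    pd.DataFrame(
        [
            {
                "cell_id": f.cell_id,
                "k_series_pa": f.params.k_series,
                "k_parallel_pa": f.params.k_parallel,
                "eta_pa_s": f.params.eta,
                "sigma_int_pa": f.params.sigma_int,
                "t_on_s": f.params.t_on,
                "residual_rms": f.residual_rms,
                "converged": int(f.converged),
                "class": f.contractility_class,
            }
            for f in fits
        ]
    ).to_csv(out / "fits.csv", index=False, float_format="%.6g")
    summary = cohort_summary(fits)
    _write_json(summary, out / "cohort_summary.json")
    _write_json(_manifest(config, "stretcher", t0), out / "manifest.json")
    return summary
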