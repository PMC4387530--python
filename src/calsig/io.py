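"""File formats, configuration and the end-to-end pipeline.

The pipeline composes: (optional) synthesis -> channel combination ->
segmentation -> per-ROI ratiometric trace extraction -> denoising ->
signature metrics -> classification -> (wound protocol) spatial statistics.
Every written artifact gets a JSON provenance sidecar with the config hash,
seed and package version, so outputs are regenerable from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import defaults as dflt
from . import segment as seg
from . import signatures as sig
from . import spatial as spa
from . import synth
from .classify import ClassifyParams, classify_transient, tabulate

log = logging.getLogger("calsig")

_CONFIG_FIELDS = {
    "red_path", "green_path", "synthetic", "protocol", "pixel_size_um",
    "frame_interval_s", "stimulus_time_s", "duration_s", "n_cells",
    "field_size_px", "wound_strip_width_px", "rng_seed", "out_dir",
    "segmentation", "metrics", "classify", "interleaved",
}


@dataclasses.dataclass
class PipelineConfig:
    protocol: str = "ATP"                  # "ATP" or "wound"
    synthetic: bool = True
    red_path: str | None = None
    green_path: str | None = None
    interleaved: bool = False              # one two-channel stack per file
    pixel_size_um: float = dflt.DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = dflt.DEFAULT_FRAME_INTERVAL_S
    stimulus_time_s: float = dflt.DEFAULT_PRESTIM_S
    duration_s: float | None = None
    n_cells: int = 64
    field_size_px: tuple[int, int] = (256, 256)
    wound_strip_width_px: int = 40
    rng_seed: int = 0
    out_dir: str = "calsig_out"
    segmentation: seg.SegmentationParams = dataclasses.field(
        default_factory=seg.SegmentationParams)
    metrics: sig.MetricParams = dataclasses.field(
        default_factory=sig.MetricParams)
    classify: ClassifyParams = dataclasses.field(
        default_factory=ClassifyParams)

    def validate(self) -> None:
        if self.protocol not in ("ATP", "wound"):
            raise ValueError("protocol must be 'ATP' or 'wound'")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("units must be positive")
        if not self.synthetic and not (self.red_path and self.green_path):
            raise ValueError("non-synthetic runs need red_path and green_path")
        self.segmentation.validate()

    def content_hash(self) -> str:
        blob = json.dumps(_to_jsonable(dataclasses.asdict(self)),
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, cls in (("segmentation", seg.SegmentationParams),
                     ("metrics", sig.MetricParams),
                     ("classify", ClassifyParams)):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = cls(**raw[key])
    if "field_size_px" in raw:
        raw["field_size_px"] = tuple(raw["field_size_px"])
    return PipelineConfig(**raw)


def read_sequence(red_path: str | Path, green_path: str | Path,
                  frame_interval_s: float, pixel_size_um: float,
                  stimulus_time_s: float) -> synth.ImageSequence:
    """Load two single-channel multi-page TIFF stacks as an ImageSequence."""
    red = tifffile.imread(red_path).astype(np.float32)
    green = tifffile.imread(green_path).astype(np.float32)
    if red.ndim == 2:
        red = red[None]
    if green.ndim == 2:
        green = green[None]
    if red.shape[0] != green.shape[0]:
        raise ValueError(f"frame-count mismatch: red has {red.shape[0]} "
                         f"frames, green has {green.shape[0]}")
    return synth.ImageSequence(red=red, green=green,
                               frame_interval_s=frame_interval_s,
                               pixel_size_um=pixel_size_um,
                               stimulus_time_s=stimulus_time_s)


def write_sequence(seq: synth.ImageSequence, red_path: str | Path,
                   green_path: str | Path) -> None:
    tifffile.imwrite(red_path, seq.red)
    tifffile.imwrite(green_path, seq.green)


def _provenance(config: PipelineConfig) -> dict:
    from . import __version__
    return {"config_hash": config.content_hash(), "seed": config.rng_seed,
            "version": __version__}


def _write_with_sidecar(df: pd.DataFrame, path: Path,
                        config: PipelineConfig) -> None:
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".prov.json").write_text(
        json.dumps(_provenance(config), indent=2))


@dataclasses.dataclass
class PipelineResult:
    sequence: synth.ImageSequence
    layout: synth.CellLayout | None
    roimap: seg.ROIMap
    traces: list[sig.Trace]
    metrics_table: pd.DataFrame
    class_table: object            # ClassTable
    spatial_summary: pd.DataFrame | None
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis described by ``config`` and write all outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    layout = None
    if config.synthetic:
        duration = config.duration_s or (
            config.stimulus_time_s
            + (dflt.ATP_DURATION_S if config.protocol == "ATP"
               else dflt.WOUND_DURATION_S))
        if config.protocol == "ATP":
            layout = synth.make_monolayer_layout(
                n_cells=config.n_cells, field_size_px=config.field_size_px,
                pixel_size_um=config.pixel_size_um, rng_seed=config.rng_seed)
        else:
            area_mm2 = (config.field_size_px[0] * config.pixel_size_um * 1e-3
                        * config.field_size_px[1] * config.pixel_size_um * 1e-3)
            layout = synth.make_wound_layout(
                field_size_px=config.field_size_px,
                pixel_size_um=config.pixel_size_um,
                density_per_mm2=config.n_cells / area_mm2,
                wound_strip_width_px=config.wound_strip_width_px,
                rng_seed=config.rng_seed)
        seq, layout = synth.render_sequence(
            layout, config.frame_interval_s, duration,
            rng_seed=config.rng_seed + 1,
            stimulus_time_s=config.stimulus_time_s)
        log.info("synthesized %d cells, %d frames [%.1fs]",
                 len(layout.cells), seq.n_frames, time.time() - t0)
    else:
        seq = read_sequence(config.red_path, config.green_path,
                            config.frame_interval_s, config.pixel_size_um,
                            config.stimulus_time_s)

    combined = seg.combine_channels(seq.red[[0, -1]], seq.green[[0, -1]])
    prepared = seg.preprocess(combined, config.segmentation)
    roimap = seg.extract_rois(prepared, config.segmentation)
    log.info("segmentation: %d ROIs [%.1fs]", len(roimap), time.time() - t0)
    tifffile.imwrite(out / "labels.tif", roimap.labels.astype(np.uint16))
    roi_df = pd.DataFrame([{"roi_id": r.id, "seed_x": r.seed_px[0],
                            "seed_y": r.seed_px[1],
                            "centroid_x": r.centroid_px[0],
                            "centroid_y": r.centroid_px[1],
                            "area_px": r.pixel_count} for r in roimap.rois])
    _write_with_sidecar(roi_df, out / "rois.csv", config)

    traces, metrics = [], []
    mp = config.metrics
    for r in roimap.rois:
        tr = sig.extract_trace(seq, roimap, r.id)
        tr = sig.denoise(tr, mp.slope_threshold, mp.denoise_window_s)
        traces.append(tr)
        metrics.append(sig.compute_metrics(tr, seq.stimulus_time_s, mp))
    long = pd.concat([pd.DataFrame({"roi_id": r.id, "t_s": tr.times_s,
                                    "ratio": tr.values})
                      for r, tr in zip(roimap.rois, traces)],
                     ignore_index=True) if traces else pd.DataFrame()
    _write_with_sidecar(long, out / "traces.csv", config)
    mdf = sig.metrics_table(metrics, roimap.ids)
    _write_with_sidecar(mdf, out / "metrics.csv", config)

    classes = [classify_transient(m, tr, config.protocol,
                                  seq.stimulus_time_s, config.classify)
               for m, tr in zip(metrics, traces)]
    mdf2 = mdf.copy()
    mdf2["secondary"] = [c.secondary for c in classes]
    mdf2["primary"] = [c.primary for c in classes]
    _write_with_sidecar(mdf2, out / "classes.csv", config)
    class_table = tabulate([(1, c) for c in classes]) if classes else None
    if class_table is not None:
        _write_with_sidecar(class_table.primary_summary.reset_index(),
                            out / "class_table.csv", config)

    spatial_summary = None
    if config.protocol == "wound":
        if layout is None or layout.wound is None:
            log.warning("wound protocol without wound geometry; "
                        "spatial stage skipped")
        else:
            records = [spa.SpatialRecord(
                r.id, spa.distance_to_wound(r.centroid_px, layout.wound,
                                            config.pixel_size_um), m)
                for r, m in zip(roimap.rois, metrics)]
            prox, dist = spa.split_proximal_distal(records)
            if prox and dist:
                rows = []
                for feat in ("peak_height", "peak_time_min", "fwhm_min",
                             "plateau_height"):
                    a = np.array([getattr(r.metrics, feat) for r in prox])
                    b = np.array([getattr(r.metrics, feat) for r in dist])
                    u, p = spa.mann_whitney_u(a, b)
                    rows.append({"feature": feat, "proximal_mean": a.mean(),
                                 "proximal_sd": a.std(ddof=1),
                                 "distal_mean": b.mean(),
                                 "distal_sd": b.std(ddof=1), "U": u, "p": p})
                spatial_summary = pd.DataFrame(rows)
                _write_with_sidecar(spatial_summary,
                                    out / "proximal_distal.csv", config)
                sweep = spa.threshold_sweep(
                    records, ["peak_height", "fwhm_min", "plateau_height"])
                sweep_df = pd.concat([
                    pd.DataFrame({"feature": s.feature,
                                  "x_um": s.thresholds_um,
                                  "n_below": s.n_below, "n_above": s.n_above,
                                  "p": s.p_values})
                    for s in sweep.values()], ignore_index=True)
                _write_with_sidecar(sweep_df, out / "sweep.csv", config)
    log.info("pipeline done [%.1fs]", time.time() - t0)
    return PipelineResult(seq, layout, roimap, traces, mdf2, class_table,
                          spatial_summary, out)
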