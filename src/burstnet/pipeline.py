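"""End-to-end orchestration: movie -> traces -> split -> bursts -> catalog ->
graph complexity + metrics, with CSV/JSON outputs and a run manifest.

:func:`analyze_movie` is the single entry point used by the command line,
the test-suite and the acceptance script.  All tunable parameters live in
:class:`PipelineConfig`; the defaults are the values the analysis was
designed around (11 x 11 ROIs at 9-px spacing, 1 s smoothing, 10th-percentile
dF/F baseline, 1.96 x noise-SD burst threshold, +/- 1 s catalog window, 4%
support filter, I.C.V. rhythmicity cut 0.2, 20 frames/s).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import bursts as _bursts
from . import complexity as _complexity
from . import metrics as _metrics
from . import signals as _signals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis chain in one place."""

    roi_size: int = 11
    spacing: int = 9
    smooth_s: float = 1.0
    dff_percentile: float = 10.0
    k_sigma: float = 1.96
    window_s: float = 1.0
    min_support: float = 0.04
    min_separation_s: float = 0.5
    icv_threshold: float = 0.2
    n_boot: int = 1000
    fps: float = 20.0
    seed: int = 0
    mode: str = "network"       # "network" or "cellular"
    resize_to: int | None = None  # e.g. 128 to mimic standard preprocessing

    def detection_params(self) -> _bursts.DetectionParams:
        return _bursts.DetectionParams(k_sigma=self.k_sigma,
                                       min_separation_s=self.min_separation_s)


@dataclass
class AnalysisResult:
    """Everything one movie's analysis produced."""

    config: PipelineConfig
    traces_dff: _signals.TraceMatrix
    split: _signals.SignalNoiseSplit
    events_by_roi: dict[int, list[_bursts.BurstEvent]]
    catalog_unfiltered: _bursts.BurstCatalog
    catalog: _bursts.BurstCatalog
    complexity: _complexity.ComplexityResult
    roi_metrics: pd.DataFrame
    network: dict
    counts: dict
    warnings: list[str] = field(default_factory=list)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def analyze_movie(movie: _signals.MovieStack,
                  config: PipelineConfig | None = None) -> AnalysisResult:
    """Run the full analysis chain on an in-memory movie."""
    cfg = config or PipelineConfig()
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("burstnet")
    pkg_logger.addHandler(collector)
    try:
        grid = _signals.tile_rois(movie.height, movie.width, cfg.roi_size, cfg.spacing)
        raw = _signals.extract_traces(movie, grid)
        smoothed = _signals.smooth_traces(raw, cfg.smooth_s)
        traces_dff = _signals.dff(smoothed, cfg.dff_percentile)
        split = _signals.pca_split(traces_dff)

        events = _bursts.detect_bursts_matrix(split.signal, split.noise,
                                              params=cfg.detection_params(),
                                              fps=movie.fps)
        catalog_raw = _bursts.catalog_bursts(events, window_s=cfg.window_s)
        catalog = _bursts.filter_catalog(catalog_raw, min_support=cfg.min_support)

        graph = _complexity.build_graph(catalog.sequences)
        comp = _complexity.complexity_score(graph)

        duration = movie.duration_s
        roi_rows = []
        for roi in range(grid.n_rois):
            train = _bursts.roi_train(events[roi], duration)
            rhy = _metrics.rhythmicity(train, cfg.icv_threshold)
            amp_mean, amp_cv = _metrics.amplitude_stats(train)
            roi_rows.append({"roi_id": roi, "n_bursts": train.n_bursts,
                             "frequency_bpm": rhy.frequency_bpm, "icv": rhy.icv,
                             "rhythmic": rhy.rhythmic, "amp_mean": amp_mean,
                             "amp_cv": amp_cv})
        roi_metrics = pd.DataFrame(roi_rows)

        net_train = _bursts.network_train(catalog, duration)
        net_rhy = _metrics.rhythmicity(net_train, cfg.icv_threshold)
        net_amp_mean, net_amp_cv = _metrics.amplitude_stats(net_train)
        sync = _metrics.pairwise_synchrony(traces_dff)
        network = {
            "n_bursts": net_train.n_bursts,
            "frequency_bpm": net_rhy.frequency_bpm,
            "icv": net_rhy.icv,
            "rhythmic": net_rhy.rhythmic,
            "amp_mean": net_amp_mean,
            "amp_cv": net_amp_cv,
            "mean_pairwise_correlation": sync.mean_correlation,
            "complexity": comp.score,
            "complexity_out_ratio": comp.out_ratio,
            "complexity_in_ratio": comp.in_ratio,
        }
        counts = {
            "n_frames": movie.n_frames,
            "n_rois": grid.n_rois,
            "n_signal_components": split.n_signal_components,
            "n_events": int(sum(len(v) for v in events.values())),
            "n_catalog_entries_unfiltered": catalog_raw.n_entries,
            "n_catalog_entries": catalog.n_entries,
            "n_nodes": comp.n_nodes,
            "n_edges": comp.n_edges,
        }
    finally:
        pkg_logger.removeHandler(collector)
    return AnalysisResult(config=cfg, traces_dff=traces_dff, split=split,
                          events_by_roi=events, catalog_unfiltered=catalog_raw,
                          catalog=catalog, complexity=comp, roi_metrics=roi_metrics,
                          network=network, counts=counts,
                          warnings=collector.messages)


def analyze_path(movie_path, config: PipelineConfig | None = None) -> AnalysisResult:
    """Load a TIFF stack and analyze it (resized when the config asks for it)."""
    cfg = config or PipelineConfig()
    movie = _signals.load_stack(movie_path, target_size=cfg.resize_to, fps=cfg.fps)
    return analyze_movie(movie, cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(v):
    if isinstance(v, float) and math.isnan(v):
        return None
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def write_results(result: AnalysisResult, out_dir, extra_inputs: dict | None = None) -> dict:
    """Persist an analysis as CSV/JSON files plus a manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    times = result.traces_dff.times
    tm = pd.DataFrame(result.traces_dff.values, columns=[f"{t:.3f}" for t in times])
    tm.insert(0, "roi_id", np.arange(result.traces_dff.n_rois))
    tm.to_csv(out / "traces_dff.csv", index=False)

    ev_rows = [{"roi_id": ev.roi_id, "base_frame": ev.base_frame,
                "peak_frame": ev.peak_frame, "base_value": ev.base_value,
                "peak_value": ev.peak_value, "amplitude": ev.amplitude,
                "position_s": ev.position_s}
               for evs in result.events_by_roi.values() for ev in evs]
    pd.DataFrame(ev_rows, columns=["roi_id", "base_frame", "peak_frame", "base_value",
                                   "peak_value", "amplitude", "position_s"]
                 ).to_csv(out / "events.csv", index=False)

    n_rois = result.counts["n_rois"]
    cat_rows = [{"catalog_id": e.catalog_id, "time_s": e.time_s,
                 "support_count": e.support_count,
                 "support_fraction": e.support_fraction(n_rois)}
                for e in result.catalog.entries]
    pd.DataFrame(cat_rows, columns=["catalog_id", "time_s", "support_count",
                                    "support_fraction"]).to_csv(out / "catalog.csv", index=False)

    seq_rows = [{"roi_id": roi, "sequence": " ".join(map(str, seq))}
                for roi, seq in sorted(result.catalog.sequences.items())]
    pd.DataFrame(seq_rows, columns=["roi_id", "sequence"]).to_csv(
        out / "sequences.csv", index=False)

    result.roi_metrics.to_csv(out / "roi_metrics.csv", index=False)

    comp = result.complexity
    pd.DataFrame([{"n_nodes": comp.n_nodes, "n_edges": comp.n_edges,
                   "out_ratio": comp.out_ratio, "in_ratio": comp.in_ratio,
                   "score": comp.score, "definition_variant": comp.variant}]
                 ).to_csv(out / "complexity.csv", index=False)

    with open(out / "network_metrics.json", "w") as fh:
        json.dump({k: _jsonable(v) for k, v in result.network.items()}, fh, indent=2)

    outputs = ["traces_dff.csv", "events.csv", "catalog.csv", "sequences.csv",
               "roi_metrics.csv", "complexity.csv", "network_metrics.json"]
    manifest = {
        "software": {"name": "burstnet", "version": __version__},
        "config": dataclasses.asdict(result.config),
        "inputs": extra_inputs or {},
        "counts": result.counts,
        "warnings": result.warnings,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
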