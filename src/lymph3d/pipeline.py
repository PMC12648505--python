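"""End-to-end pipeline driver: denoise -> segment -> graph -> valves -> metrics."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig, config_hash
from .metrics import compute_metrics
from .preprocess import denoise_gaussian, denoise_nlm3d, resample_isotropic
from .segmentation import auto_thresholds, filter_components, hysteresis_segment
from .skeleton import apply_border_rules, classify_edges, skeleton_to_graph, skeletonize
from .types import MetricsReport, NetworkGraph, SegmentationMask, Valve, Volume3D
from .valves import (
    assign_layers,
    attenuate_background,
    classify_valve_positions,
    detect_valve_blobs,
)

log = logging.getLogger("lymph3d")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    mask: SegmentationMask
    graph: NetworkGraph
    valves: list[Valve]
    metrics: MetricsReport
    thresholds: tuple[float, float]
    config: PipelineConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _stage(name: str, start: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s duration=%.2fs %s", name, time.perf_counter() - start, extras)


def run_pipeline(
    cfg: PipelineConfig,
    volume: Volume3D,
    channel2: Volume3D | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage in order on a single volume.

    With ``outdir`` set, writes the mask (TIFF), graph (CSV + GraphML), valve
    table (CSV) and metrics (JSON), each carrying the config hash.
    """
    chash = config_hash(cfg)
    meta = {"config_hash": chash}

    t = time.perf_counter()
    if cfg.flip_z:
        volume = volume.with_data(volume.data[::-1].copy())
    volume = resample_isotropic(volume, cfg.iso_spacing_um)
    _stage("resample", t, shape=volume.shape)

    t = time.perf_counter()
    if cfg.denoise_method == "nlm":
        den = denoise_nlm3d(
            volume,
            cfg.nlm_patch_radius_vox,
            cfg.nlm_search_radius_vox,
            h_factor=cfg.nlm_h_factor,
        )
    elif cfg.denoise_method == "gaussian":
        den = denoise_gaussian(volume, cfg.gaussian_denoise_sigma_vox)
    else:
        den = volume
    _stage("denoise", t, method=cfg.denoise_method)

    t = time.perf_counter()
    t_low, t_high = cfg.t_low, cfg.t_high
    if t_high is None:
        auto_low, t_high = auto_thresholds(den, cfg.otsu_low_fraction)
        if t_low is None:
            t_low = auto_low
    elif t_low is None:
        t_low = cfg.otsu_low_fraction * t_high
    mask = hysteresis_segment(den, t_low, t_high, cfg.connectivity)
    mask = filter_components(mask, cfg.min_component_volume_um3, cfg.connectivity)
    _stage(
        "segment",
        t,
        t_low=round(float(t_low), 3),
        t_high=round(float(t_high), 3),
        foreground=int(mask.data.sum()),
    )

    t = time.perf_counter()
    skel = skeletonize(mask)
    graph = skeleton_to_graph(skel, cfg.min_edge_length_um)
    graph = classify_edges(graph)
    graph = apply_border_rules(
        graph, mask.shape, cfg.border_capillary_max_um, cfg.border_precollector_min_um
    )
    graph = assign_layers(graph, cfg.layer_z_bands_um)
    _stage("graph", t, nodes=graph.n_nodes, edges=graph.n_edges)

    t = time.perf_counter()
    enhanced = attenuate_background(den, mask, cfg.opening_radius_um)
    valves = detect_valve_blobs(
        enhanced,
        mask,
        cfg.preblur_sigma_vox,
        cfg.adaptive_sensitivity,
        cfg.window_vox(den.spacing_um) if cfg.adaptive_window_vox is None else cfg.adaptive_window_vox,
        (cfg.valve_volume_min_um3, cfg.valve_volume_max_um3),
        cfg.connectivity,
        cfg.valve_mask_erosion_vox,
        cfg.adaptive_margin,
    )
    valves = classify_valve_positions(valves, graph, cfg.junction_radius_um)
    valves = assign_layers(valves, cfg.layer_z_bands_um)
    _stage("valves", t, detected=len(valves))

    t = time.perf_counter()
    sample_volume = float(np.prod(volume.extent_um))
    metrics = compute_metrics(mask, graph, valves, sample_volume, channel2)
    _stage("metrics", t)

    if outdir is not None:
        from .io import write_graph, write_mask, write_metrics, write_valves

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mask(mask, outdir / "mask.tif")
        write_graph(graph, outdir / "graph", meta)
        write_valves(valves, outdir / "valves.csv", meta)
        write_metrics(metrics, outdir / "metrics.json", meta)

    return PipelineResult(mask, graph, valves, metrics, (float(t_low), float(t_high)), cfg)
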