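"""The two end-to-end pipelines: live kinetics and fixed morphometry.

``run_live_pipeline`` chains preprocessing -> detection -> linking ->
pre-formed exclusion -> segmentation/drift correction -> boundary-distance
classification -> membrane-initiated filtering -> first-formation time,
lifetime fit and compartment counts. ``run_fixed_pipeline`` chains reference
thresholding -> colocalisation -> morphometry (shape factor, FWHM sizing) ->
spherical fractions and per-timepoint size statistics.

Both log counts in and out of every filter so the filtering cascade is
auditable, and both write deterministic CSV/JSON outputs plus a provenance
manifest when an output directory is given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import detect, geometry, kinetics, morphology, track
from .config import PipelineConfig
from .io import ImageStack4D, load_stack, write_manifest, write_table

__all__ = ["LiveResult", "FixedResult", "run_live_pipeline",
           "run_fixed_pipeline", "fit_report"]

logger = logging.getLogger("myddotrack")


@dataclass
class LiveResult:
    """Outputs of the live-kinetics pipeline."""

    points: pd.DataFrame
    summary: pd.DataFrame            # all non-pre-formed tracks
    membrane_summary: pd.DataFrame   # membrane-initiated subset
    counts: pd.DataFrame
    first_formation_s: Optional[float]
    fit: Optional[kinetics.LifetimeFit]
    cell: geometry.CellGeometry
    stage_log: dict = field(default_factory=dict)


@dataclass
class FixedResult:
    """Outputs of the fixed-morphometry pipeline."""

    morphometry: pd.DataFrame
    summary: pd.DataFrame
    tests: pd.DataFrame
    spherical_fractions: pd.DataFrame
    stage_log: dict = field(default_factory=dict)


def fit_report(fit: Optional[kinetics.LifetimeFit]) -> dict:
    """JSON-serialisable summary of a lifetime fit."""
    if fit is None:
        return {"fitted": False}
    return {
        "fitted": True,
        "k1_per_s": fit.k1,
        "k2_per_s": fit.k2,
        "tau_mean_s": fit.tau_mean,
        "method": fit.method,
        "n": int(fit.n),
        "log_likelihood": fit.log_likelihood,
        "converged": fit.converged,
        "near_degenerate": fit.near_degenerate,
        "ci": fit.ci,
    }


def _preprocess(stack: ImageStack4D, config: PipelineConfig) -> np.ndarray:
    """Background subtraction, 3D blur and brightest-point projection."""
    frames = []
    for t in range(stack.n_frames):
        vol = stack.data[t].astype(np.float32)
        if config.background_mode == "slice":
            vol = detect.subtract_background(vol, config.ball_radius)
            vol = detect.blur_3d(vol, config.blur_sigma)
            frames.append(detect.project_brightest(vol))
        else:
            vol = detect.blur_3d(vol, config.blur_sigma)
            proj = detect.project_brightest(vol)
            frames.append(detect.subtract_background(proj, config.ball_radius))
    return np.stack(frames)


def run_live_pipeline(stack: ImageStack4D | str | Path,
                      config: Optional[PipelineConfig] = None,
                      outdir: Optional[str | Path] = None) -> LiveResult:
    """Run the full live-cell kinetics pipeline on a calibrated 4D stack."""
    config = config or PipelineConfig()
    if not isinstance(stack, ImageStack4D):
        stack = load_stack(stack, pixel_size_xy=config.pixel_size_xy,
                           z_spacing=config.z_spacing,
                           frame_interval=config.frame_interval)
    px = stack.pixel_size_xy
    dt = stack.frame_interval
    log: dict = {}

    raw_proj = detect.project_brightest(stack.data)
    cell = geometry.segment_cell(raw_proj, px)

    proc = _preprocess(stack, config)
    detections = detect.detect_stack(proc, prominence=config.prominence,
                                     subpixel=config.subpixel)
    log["detections"] = int(len(detections))
    logger.info("detected %d puncta across %d frames", len(detections),
                stack.n_frames)

    points = track.link_trajectories(detections,
                                     search_range=config.search_range,
                                     memory=config.memory,
                                     min_length=config.min_track_length)
    summary_all = track.summarise_tracks(points, dt, n_frames=stack.n_frames)
    log["tracks_min_length"] = int(len(summary_all))

    summary, points = track.filter_preformed(summary_all, points)
    log["tracks_preformed_removed"] = log["tracks_min_length"] - len(summary)
    logger.info("%d tracks after min-length filter, %d pre-formed removed",
                log["tracks_min_length"], log["tracks_preformed_removed"])

    points = points.copy()
    points["t_s"] = points["frame"] * dt
    points["x_um"] = points["x_px"] * px
    points["y_um"] = points["y_px"] * px
    points = geometry.correct_drift(points, cell)
    points = geometry.annotate_distances(points, cell,
                                         threshold=config.membrane_threshold)

    first_s = track.first_formation_time(summary, dt)
    if first_s is None:
        logger.warning("no formation observed")

    mem_points, mem_summary = geometry.filter_membrane_initiated(points, summary)
    log["tracks_membrane_initiated"] = int(len(mem_summary))
    logger.info("%d of %d tracks membrane-initiated", len(mem_summary),
                len(summary))

    counts = geometry.counts_over_time(mem_points, stack.n_frames, dt,
                                       n_cells=config.n_cells)

    fit = None
    lifetimes = mem_summary["lifetime_s"].to_numpy()
    if lifetimes.size >= config.min_fit_n:
        fit = kinetics.fit_two_step(
            lifetimes, method=config.fit_method,
            bin_width=config.histogram_bin_width,
            interval_censored=config.interval_censored,
            frame_interval=dt, n_bootstrap=config.n_bootstrap,
            seed=config.seed)
    else:
        logger.warning("only %d membrane-initiated tracks; skipping fit "
                       "(min_fit_n=%d)", lifetimes.size, config.min_fit_n)
    log["censored_tracks"] = int(mem_summary["censored"].sum()) \
        if len(mem_summary) else 0

    result = LiveResult(points=points, summary=summary,
                        membrane_summary=mem_summary, counts=counts,
                        first_formation_s=first_s, fit=fit, cell=cell,
                        stage_log=log)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(points[[c for c in [
            "track_id", "frame", "t_s", "x_px", "y_px", "x_um", "y_um",
            "x_rel_um", "y_rel_um", "intensity", "distance_um", "compartment"]
            if c in points.columns]], outdir / "trajectories.csv")
        write_table(summary, outdir / "tracks.csv")
        write_table(mem_summary, outdir / "tracks_membrane.csv")
        write_table(counts, outdir / "counts.csv")
        report = {
            "first_formation_s": first_s,
            "no_formation_observed": first_s is None,
            "lifetime_fit": fit_report(fit),
            "stage_log": log,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        write_manifest(outdir / "manifest.json", config, config.seed)
    return result


def run_fixed_pipeline(sr_image: np.ndarray, reference_image: np.ndarray,
                       pixel_size_nm: float,
                       config: Optional[PipelineConfig] = None,
                       condition: str = "condition",
                       timepoint: str = "t0",
                       sr_threshold: Optional[float] = None,
                       outdir: Optional[str | Path] = None) -> FixedResult:
    """Run the fixed-cell morphometry pipeline on one condition/timepoint.

    ``sr_image`` is the reconstructed super-resolved intensity image (it is
    thresholded — Otsu by default — into binary cluster masks and also used
    for the 1D FWHM profiles); ``reference_image`` is the matched widefield
    reference channel used for colocalisation filtering.
    """
    config = config or PipelineConfig()
    sr = np.asarray(sr_image, dtype=float)
    ref = np.asarray(reference_image, dtype=float)
    if sr.shape != ref.shape:
        raise ValueError("super-resolved and reference images must share a "
                         "coordinate frame (same shape)")
    log: dict = {}

    from skimage.filters import threshold_otsu
    if np.ptp(sr) == 0:
        clusters = morphology.measure_clusters(np.zeros_like(sr, dtype=bool),
                                               pixel_size_nm)
    else:
        thr = threshold_otsu(sr) if sr_threshold is None else sr_threshold
        clusters = morphology.measure_clusters(
            sr > thr, pixel_size_nm, min_pixels=config.min_cluster_px,
            intensity_image=sr)
    log["clusters_detected"] = int(len(clusters))

    rois = morphology.threshold_reference_rois(ref,
                                               expand_px=config.roi_expand_px)
    log["reference_rois"] = len(rois)
    clusters = morphology.colocalise_clusters(clusters, rois)
    coloc = clusters[clusters["colocalised"]].reset_index(drop=True)
    log["clusters_colocalised"] = int(len(coloc))
    logger.info("%d/%d clusters colocalised with %d reference ROIs",
                len(coloc), len(clusters), len(rois))

    coloc = coloc.copy()
    coloc["condition"] = condition
    coloc["timepoint"] = timepoint

    if len(coloc):
        summary, tests = morphology.size_by_timepoint(coloc)
        frac = morphology.spherical_fraction(
            coloc["shape_factor"], tolerance=config.spherical_tolerance)
        fracs = pd.DataFrame([{
            "condition": condition, "timepoint": timepoint,
            "n": len(coloc), "spherical_fraction": frac,
            "tolerance": config.spherical_tolerance}])
    else:
        logger.warning("empty cluster set after colocalisation filtering")
        summary = pd.DataFrame(columns=["condition", "timepoint", "n",
                                        "mean", "median", "std"])
        tests = pd.DataFrame()
        fracs = pd.DataFrame(columns=["condition", "timepoint", "n",
                                      "spherical_fraction", "tolerance"])

    result = FixedResult(morphometry=coloc, summary=summary, tests=tests,
                         spherical_fractions=fracs, stage_log=log)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(coloc, outdir / "morphometry.csv")
        write_table(summary, outdir / "size_summary.csv")
        write_table(tests, outdir / "size_tests.csv")
        write_table(fracs, outdir / "spherical_fractions.csv")
        write_manifest(outdir / "manifest.json", config, config.seed,
                       extra={"stage_log": log})
    return result
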