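"""End-to-end pipeline: segment a movie, link, RMSD-filter, fit motility.

Mirrors the processing workflow of an interactive tracker: per-frame
settings interpolated between user-tuned first/last frames, optional
overlay images for visual QC, RMSD filtering of non-motile objects, manual
exclusion lists honored, then velocity-autocovariance and MSD fits with
bootstrap-corrected errors. Deterministic for a fixed config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .io import (
    apply_exclusions,
    read_exclusions,
    read_frame_sequence,
    write_tracks,
)
from .motility import MotilityModel, MotilityResults
from .segmentation import Detection, interpolate_params, segment_frame
from .tracking import Track, filter_tracks_by_rmsd, link_detections

__all__ = ["PipelineResult", "run_pipeline", "segment_movie"]

log = logging.getLogger("bftrack")


@dataclass
class PipelineResult:
    """Bundle of everything one pipeline run produced."""

    detections: list[list[Detection]]
    tracks: list[Track]
    kept: list[Track]
    discarded: list[Track]
    acov_results: MotilityResults | None
    msd_results: MotilityResults | None
    report: dict = field(default_factory=dict)


def segment_movie(stack: np.ndarray, config: PipelineConfig) -> list[list[Detection]]:
    """Segment every frame with interpolated settings; returns per-frame lists."""
    n = len(stack)
    out = []
    for fi in range(n):
        sp = (
            interpolate_params(config.seg_first, config.seg_last, fi, n)
            if n >= 2
            else config.seg_first
        )
        dets = segment_frame(stack[fi], config.filter, sp, frame_index=fi)
        log.info("frame %d: %d detections (threshold %.3g)", fi, len(dets), sp.peak_threshold)
        out.append(dets)
    return out


def _write_overlays(stack: np.ndarray, detections, outdir: Path) -> None:
    """Visual-QC overlays: frame + footprint contour + centroid/peak crosses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proc = outdir / "processed"
    proc.mkdir(parents=True, exist_ok=True)
    for fi, dets in enumerate(detections):
        fig, ax = plt.subplots(figsize=(8, 6))
        ax.imshow(stack[fi], cmap="gray")
        for det in dets:
            xs = [p[0] for p in det.footprint]
            ys = [p[1] for p in det.footprint]
            ax.plot(xs, ys, ".", color="tab:blue", ms=1, alpha=0.3)
            ax.plot(*det.centroid, "+", color="tab:cyan", ms=10)
            ax.plot(*det.peak_position, "x", color="tab:red", ms=8)
        ax.set_title(f"frame {fi}: {len(dets)} objects")
        ax.set_axis_off()
        fig.savefig(proc / f"frame_{fi:04d}.png", dpi=100, bbox_inches="tight")
        plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run processing -> RMSD filtering -> post-processing -> statistics.

    Stages abort with stage-tagged errors; outputs written so far are left
    in `config.output_dir`. The JSON report embeds the full config for
    provenance.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}

    try:
        stack, meta = read_frame_sequence(config.input)
    except Exception as exc:
        raise RuntimeError(f"[input] failed to read {config.input!r}: {exc}") from exc
    report["stages"]["input"] = {"n_frames": int(len(stack)), "shape": list(stack.shape[1:])}

    try:
        detections = segment_movie(stack, config)
    except Exception as exc:
        raise RuntimeError(f"[segmentation] {exc}") from exc
    report["stages"]["segmentation"] = {
        "per_frame_counts": [len(d) for d in detections]
    }
    if config.write_overlays:
        _write_overlays(stack, detections, outdir)

    try:
        tracks = link_detections(detections, config.link)
    except Exception as exc:
        raise RuntimeError(f"[tracking] {exc}") from exc
    kept, discarded = filter_tracks_by_rmsd(tracks, config.rmsd_threshold)
    report["stages"]["tracking"] = {
        "n_tracks": len(tracks),
        "n_kept": len(kept),
        "n_discarded_rmsd": len(discarded),
    }
    write_tracks(tracks, outdir / "tracks_all.csv", config.dt, config.pixel_size)
    write_tracks(kept, outdir / "tracks_kept.csv", config.dt, config.pixel_size)

    if config.exclusions:
        kept = apply_exclusions(kept, read_exclusions(config.exclusions))
        report["stages"]["post_processing"] = {"n_after_exclusions": len(kept)}

    acov_res = msd_res = None
    analyzable = [t for t in kept if len(t) >= 3]
    if len(analyzable) >= 1:
        try:
            model = MotilityModel(analyzable, dt=config.dt, pixel_size=config.pixel_size)
            seed = config.seed if len(analyzable) >= 3 else None
            acov_res = model.fit(
                method="acov", fit_range=config.acov_fit_range,
                n_boot=config.n_boot, seed=seed,
            )
            msd_res = model.fit(method="furth", n_boot=config.n_boot, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"[motility] {exc}") from exc
        report["stages"]["motility"] = _motility_report(acov_res, msd_res)
        _write_lag_tables(acov_res, msd_res, outdir)

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=_json_default))
    log.info("report written to %s", report_path)
    return PipelineResult(
        detections=detections,
        tracks=tracks,
        kept=kept,
        discarded=discarded,
        acov_results=acov_res,
        msd_results=msd_res,
        report=report,
    )


def _motility_report(acov_res: MotilityResults, msd_res: MotilityResults) -> dict:
    def block(res: MotilityResults) -> dict:
        return {
            "P": res.fit.P,
            "phi0": res.fit.phi0,
            "sigma_pos": None if np.isnan(res.fit.sigma_pos) else res.fit.sigma_pos,
            "raw_err": res.fit.raw_errors,
            "corr_err": res.fit.corrected_errors,
            "n_tracks": len(res.model.tracks),
            "settings": {k: v for k, v in res.fit.settings.items()},
            "flags": res.fit.flags,
        }

    return {"acov": block(acov_res), "furth": block(msd_res)}


def _write_lag_tables(acov_res, msd_res, outdir: Path) -> None:
    import pandas as pd

    for name, res in (("acov", acov_res), ("msd", msd_res)):
        est = res.estimate
        pd.DataFrame(
            {"lag_min": est.lags, "value": est.values,
             "stderr": est.stderrs, "n_pairs": est.n_pairs}
        ).to_csv(outdir / f"{name}_lags.csv", index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
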