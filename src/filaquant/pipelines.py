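"""End-to-end workflows: fibre batches, tube batches, track batches,
condition comparison.  Each writes a self-describing output directory:

    config.json            exact configuration used (tau resolved)
    report.json            per-image metrics and pooled summaries
    <stem>_lmax.tif etc.   per-image maps and renders
    pooled_distribution.csv, cdf.png

Re-running a pipeline from the stored ``config.json`` on the same inputs
reproduces all numeric outputs byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import filament, io, kernels, motility, stats, tubes
from .config import RunConfig
from .grids import ImageGrid

logger = logging.getLogger(__name__)


def _resolve_tau(config: RunConfig, bank) -> float:
    if config.tau != "calibrate":
        return float(config.tau)
    return filament.calibrate_tau(bank.lengths_um, bank)


def _as_image(item, config: RunConfig, modality: str) -> tuple[str, ImageGrid]:
    if isinstance(item, ImageGrid):
        return "image", item
    path = Path(item)
    grid = io.read_image(path, pixel_size_um=config.pixel_size_um,
                         modality=modality)
    return path.stem, grid


def _load_images(items, config: RunConfig, modality: str):
    named, skipped = [], 0
    for i, item in enumerate(items):
        try:
            name, grid = _as_image(item, config, modality)
        except (OSError, ValueError, RuntimeError) as exc:
            logger.warning("skipping unreadable input %r: %s", item, exc)
            skipped += 1
            continue
        named.append((f"{i:03d}_{name}", grid))
    if not named:
        raise ValueError("no readable input image")
    return named, skipped


def run_fibres(images, config: RunConfig, outdir) -> dict:
    """Fibre workflow: correlation-length map, HSV render and length
    distribution per image, pooled distribution and the below-threshold
    fraction (25 um convention) across the batch."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    named, skipped = _load_images(images, config, "fluorescence")

    bank = kernels.build_kernel_bank(
        config.lengths_um,
        config.orientations_deg(),
        width_px=config.kernel_width_px,
        pixel_size_um=config.pixel_size_um,
        blur_px=config.kernel_blur_px,
    )
    tau = _resolve_tau(config, bank)
    stored = config.with_updates(tau=tau)
    stored.to_json(outdir / "config.json")

    length_range = (float(bank.lengths_um[0]), float(bank.lengths_um[-1]))
    per_image = []
    pooled = None
    for name, grid in named:
        stack = filament.correlate(grid, bank)
        lmap = filament.length_map(
            stack, grid, tau,
            intensity_percentiles=config.intensity_percentiles,
            mask_mode=config.mask_mode,
        )
        io.write_length_map(lmap, outdir / name)
        render = filament.render_hsv(lmap, length_range)
        io.write_hsv_png(
            render, outdir / f"{name}_hsv.png",
            extra_legend={"tau": tau, "lengths_um": stored.lengths_um},
        )
        entry = {"image": name}
        try:
            dist = stats.length_distribution(lmap, weighting=config.weighting)
        except ValueError:
            logger.warning("%s: empty length map, excluded from pooling", name)
            entry["fraction_below"] = None
            per_image.append(entry)
            continue
        io.write_distribution_csv(dist, outdir / f"{name}_distribution.csv")
        entry["fraction_below"] = stats.fraction_below(dist, config.threshold_um)
        entry["total_weight"] = dist.total_weight
        per_image.append(entry)
        pooled = dist if pooled is None else pooled.pooled_with(dist)

    if pooled is None:
        raise ValueError("no filamentous signal in any input image")
    io.write_distribution_csv(pooled, outdir / "pooled_distribution.csv")
    io.plot_cdf({"pooled": pooled}, outdir / "cdf.png",
                threshold_um=config.threshold_um)
    report = {
        "workflow": "fibres",
        "n_images": len(named),
        "n_skipped": skipped,
        "tau": tau,
        "threshold_um": config.threshold_um,
        "per_image": per_image,
        "pooled_fraction_below": stats.fraction_below(
            pooled, config.threshold_um
        ),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_tubes(images, config: RunConfig, outdir) -> dict:
    """Tube workflow: local contrast map then cord-scale correlation
    length; reports the above-threshold fraction (300 um convention)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    named, skipped = _load_images(images, config, "phase_contrast")

    cparams = tubes.ContrastMapParams(
        window_px=config.contrast_window_px,
        norm_percentile=config.contrast_percentile,
    )
    bank = kernels.build_kernel_bank(
        config.lengths_um,
        config.orientations_deg(),
        width_px=config.kernel_width_px,
        pixel_size_um=config.pixel_size_um,
        blur_px=config.kernel_blur_px,
    )
    tau = _resolve_tau(config, bank)
    stored = config.with_updates(tau=tau)
    stored.to_json(outdir / "config.json")

    length_range = (float(bank.lengths_um[0]), float(bank.lengths_um[-1]))
    per_image = []
    pooled = None
    for name, grid in named:
        lmap, dist, contrast = tubes.analyze_tubes(
            grid,
            lengths_um=np.asarray(config.lengths_um),
            orientations_deg=config.orientations_deg(),
            tau=tau,
            width_px=config.kernel_width_px,
            blur_px=config.kernel_blur_px,
            contrast_params=cparams,
            weighting=config.weighting,
        )
        io.write_image(contrast, outdir / f"{name}_contrast.tif",
                       dtype="float32")
        io.write_length_map(lmap, outdir / name)
        io.write_hsv_png(
            filament.render_hsv(lmap, length_range),
            outdir / f"{name}_hsv.png",
            extra_legend={"tau": tau, "lengths_um": stored.lengths_um},
        )
        io.write_distribution_csv(dist, outdir / f"{name}_distribution.csv")
        per_image.append(
            {
                "image": name,
                "fraction_above": stats.fraction_above(
                    dist, config.threshold_um
                ),
                "total_weight": dist.total_weight,
            }
        )
        pooled = dist if pooled is None else pooled.pooled_with(dist)

    io.write_distribution_csv(pooled, outdir / "pooled_distribution.csv")
    io.plot_cdf({"pooled": pooled}, outdir / "cdf.png",
                threshold_um=config.threshold_um)
    report = {
        "workflow": "tubes",
        "n_images": len(named),
        "n_skipped": skipped,
        "tau": tau,
        "threshold_um": config.threshold_um,
        "per_image": per_image,
        "pooled_fraction_above": stats.fraction_above(
            pooled, config.threshold_um
        ),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_tracks(tracks, config: RunConfig, outdir) -> dict:
    """Track workflow: window filter, per-track speed and persistence,
    tracings-from-origin figure and condition summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(tracks, motility.TrackSet):
        tracks = motility.read_tracks_csv(
            tracks, frame_interval_s=config.frame_interval_s
        )
    config.to_json(outdir / "config.json")
    t0, t1 = config.track_window_h
    windowed = motility.window_filter(tracks, t0, t1)
    origin = motility.translate_to_origin(windowed)
    summary = motility.summarize(windowed)
    summary.per_track.to_csv(outdir / "per_track.csv", index=False)
    motility.write_tracks_csv(origin, outdir / "tracks_from_origin.csv")
    _plot_tracings(origin, outdir / "tracings.png")
    report = {
        "workflow": "tracks",
        "condition": tracks.condition,
        "window_h": [t0, t1],
        "n_tracks": summary.n_tracks,
        "speed_um_h": {
            "mean": summary.speed_mean,
            "sd": summary.speed_sd,
            "sem": summary.speed_sem,
        },
        "persistence_um": {
            "mean": summary.persistence_mean,
            "sd": summary.persistence_sd,
            "sem": summary.persistence_sem,
            "ensemble_fit": summary.ensemble_persistence_um,
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _plot_tracings(origin_tracks: motility.TrackSet, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    for tid in origin_tracks.track_ids:
        xy = origin_tracks.positions(tid)
        ax.plot(xy[:, 0], xy[:, 1], lw=0.6, alpha=0.7)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    ax.set_title("tracings from origin")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_compare(outdir_a, outdir_b, metric: str | None = None) -> dict:
    """Compare two analysed conditions by an unpaired t-test on their
    per-image metric values.  Refuses to compare runs whose analysis
    configuration (grids, tau, weighting, ...) differs."""
    outdir_a, outdir_b = Path(outdir_a), Path(outdir_b)
    cfg_a = RunConfig.from_json(outdir_a / "config.json")
    cfg_b = RunConfig.from_json(outdir_b / "config.json")
    if cfg_a.comparable_signature() != cfg_b.comparable_signature():
        raise ValueError(
            "conditions were analysed with different configurations; "
            "re-run with identical grids and tau before comparing"
        )
    rep_a = json.loads((outdir_a / "report.json").read_text())
    rep_b = json.loads((outdir_b / "report.json").read_text())
    if metric is None:
        metric = (
            "fraction_below"
            if rep_a["workflow"] == "fibres"
            else "fraction_above"
        )
    vals_a = [e[metric] for e in rep_a["per_image"] if e.get(metric) is not None]
    vals_b = [e[metric] for e in rep_b["per_image"] if e.get(metric) is not None]
    result = stats.compare_conditions(vals_a, vals_b)
    return {
        "metric": metric,
        "a": {"dir": str(outdir_a), "mean": result.mean_a,
              "sd": result.sd_a, "n": result.n_a},
        "b": {"dir": str(outdir_b), "mean": result.mean_b,
              "sd": result.sd_b, "n": result.n_b},
        "t": result.t_statistic,
        "p": result.p_value,
        "stars": result.stars,
    }
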