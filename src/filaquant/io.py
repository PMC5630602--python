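"""Reading and writing images, truth tables and result artifacts.

Pixel size resolution order for images: an explicit argument wins, then a
sidecar JSON (``<image>.json`` with ``{"pixel_size_um": ...}``), then TIFF
resolution tags.  Conflicts between an explicit value and file metadata
are logged, not fatal.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .filament import HSVRender, LengthMap
from .grids import ImageGrid
from .stats import LengthDistribution

logger = logging.getLogger(__name__)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _pixel_size_from_tiff(path: Path) -> float | None:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is None:
                return None
            num, den = res.value
            if num == 0:
                return None
            px_per_unit = num / den
            unit_um = {2: 25400.0, 3: 10000.0}.get(
                getattr(unit, "value", 2) if unit else 2
            )
            if unit_um is None:
                return None
            return unit_um / px_per_unit
    except Exception:  # malformed tags: fall through to other sources
        return None


def read_image(
    path,
    pixel_size_um: float | None = None,
    modality: str = "fluorescence",
) -> ImageGrid:
    """Read a grayscale TIFF/PNG micrograph with its pixel size."""
    path = Path(path)
    data = np.asarray(iio.imread(path), dtype=np.float64)
    if data.ndim == 3:  # RGB(A): average channels
        data = data[..., :3].mean(axis=-1)
    sidecar = _sidecar(path)
    meta_px = None
    if sidecar.exists():
        meta_px = json.loads(sidecar.read_text()).get("pixel_size_um")
    if meta_px is None and path.suffix.lower() in (".tif", ".tiff"):
        meta_px = _pixel_size_from_tiff(path)
    if pixel_size_um is not None:
        if meta_px is not None and abs(meta_px - pixel_size_um) > 1e-6:
            logger.warning(
                "%s: explicit pixel size %.4g um overrides metadata %.4g um",
                path.name, pixel_size_um, meta_px,
            )
        px = pixel_size_um
    elif meta_px is not None:
        px = float(meta_px)
    else:
        raise ValueError(f"{path}: pixel size not given and not in metadata")
    return ImageGrid(data, px, modality=modality)


def write_image(grid: ImageGrid, path, dtype: str = "uint16") -> None:
    """Write an image as TIFF (16-bit by default, float32 for maps) with
    the pixel size in the resolution tags and a sidecar JSON."""
    path = Path(path)
    px_cm = 10000.0 / grid.pixel_size_um  # pixels per centimetre
    if dtype == "uint16":
        arr = grid.intensity
        top = arr.max()
        scaled = arr / top * 65535 if top > 0 else arr
        data = np.clip(np.rint(scaled), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = grid.intensity.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(
        path, data, resolution=(px_cm, px_cm), resolutionunit="CENTIMETER"
    )
    _sidecar(path).write_text(
        json.dumps(
            {"pixel_size_um": grid.pixel_size_um, "modality": grid.modality},
            indent=2,
        )
    )


def write_length_map(lmap: LengthMap, prefix) -> None:
    """Write ``<prefix>_lmax.tif`` and ``<prefix>_mask.tif`` (float32)."""
    prefix = Path(prefix)
    px_cm = 10000.0 / lmap.pixel_size_um
    for name, arr in (("lmax", lmap.lmax_um), ("mask", lmap.mask)):
        tifffile.imwrite(
            prefix.parent / f"{prefix.name}_{name}.tif",
            arr.astype(np.float32),
            resolution=(px_cm, px_cm),
            resolutionunit="CENTIMETER",
        )


def write_hsv_png(render: HSVRender, path, extra_legend: dict | None = None) -> None:
    """Write the HSV rendering as 8-bit PNG plus a JSON legend."""
    path = Path(path)
    iio.imwrite(path, render.to_uint8())
    legend = {
        "length_range_um": list(render.length_range_um),
        "hue_deg": {"blue_240": render.length_range_um[0],
                    "red_0": render.length_range_um[1]},
    }
    if extra_legend:
        legend.update(extra_legend)
    _sidecar(path).write_text(json.dumps(legend, indent=2))


def write_distribution_csv(dist: LengthDistribution, path) -> None:
    support, cdf = dist.cdf_curve()
    pd.DataFrame(
        {"length_um": support, "weight": dist.weights, "cdf": cdf}
    ).to_csv(path, index=False)


def read_distribution_csv(path) -> LengthDistribution:
    df = pd.read_csv(path)
    return LengthDistribution(
        df["length_um"].to_numpy(), df["weight"].to_numpy()
    )


def write_fibre_truth_csv(truth, path) -> None:
    pd.DataFrame(
        [
            {
                "center_x_um": t.center_um[0],
                "center_y_um": t.center_um[1],
                "length_um": t.length_um,
                "orientation_deg": t.orientation_deg,
                "width_um": t.width_um,
                "amplitude": t.amplitude,
            }
            for t in truth
        ]
    ).to_csv(path, index=False)


def write_cord_truth_csv(truth, path) -> None:
    pd.DataFrame(
        [
            {
                "cord_id": t.cord_id,
                "length_um": t.length_um,
                "n_polylines": len(t.vertices_um),
            }
            for t in truth
        ]
    ).to_csv(path, index=False)


def plot_cdf(distributions: dict, path, threshold_um: float | None = None) -> None:
    """Cumulative-distribution figure (one curve per condition/image)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for name, dist in distributions.items():
        support, cdf = dist.cdf_curve()
        ax.step(support, cdf, where="post", label=str(name))
    if threshold_um is not None:
        ax.axvline(threshold_um, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("correlation length (µm)")
    ax.set_ylabel("cumulative fraction")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
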