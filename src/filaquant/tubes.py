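"""Phase-contrast branch: local contrast map and tube-network analysis.

Phase-contrast images of endothelial cord networks cannot be matched
against bright-line kernels directly — cords appear as dark bands with
bright halos on a mid-gray background.  They are therefore pre-treated
into a *local contrast map*: the per-pixel standard deviation of the
intensity over a sliding window, normalised by a high percentile of that
SD field and clipped to [0, 1].  Structures of any phase polarity become
bright ridges, which the oriented-kernel detector then quantifies with a
cord-scale length grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from . import filament, kernels, stats
from .grids import ImageGrid


@dataclass(frozen=True)
class ContrastMapParams:
    """Sliding-window contrast operator parameters.

    ``window_px`` is the (odd) side of the square window; the SD field is
    rescaled between its median (the sensor-noise floor — without this
    subtraction the normalised map is dominated by background noise) and
    its ``norm_percentile``, then clipped to [0, 1], which makes the map
    invariant to affine intensity changes of the input.
    """

    window_px: int = 15
    norm_percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ValueError("window_px must be odd and >= 3")
        if not 50.0 < self.norm_percentile <= 100.0:
            raise ValueError("norm_percentile must lie in (50, 100]")


def local_contrast_map(
    image: ImageGrid, params: ContrastMapParams = ContrastMapParams()
) -> ImageGrid:
    """Windowed-SD contrast map of a phase-contrast image."""
    if image.modality != "phase_contrast":
        raise ValueError("local_contrast_map expects a phase_contrast image")
    if params.window_px > min(image.shape):
        raise ValueError("contrast window larger than the image")
    img = image.intensity
    mean = uniform_filter(img, params.window_px, mode="reflect")
    mean_sq = uniform_filter(img * img, params.window_px, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    sd = np.sqrt(var)
    floor = np.percentile(sd, 50.0)
    scale = np.percentile(sd, params.norm_percentile) - floor
    if scale <= 0:  # structures sparser than the percentile: use the peak
        scale = sd.max() - floor
    if scale <= 0:
        contrast = np.zeros_like(sd)
    else:
        contrast = np.clip((sd - floor) / scale, 0.0, 1.0)
    return ImageGrid(
        contrast,
        image.pixel_size_um,
        modality="contrast_map",
        meta={"window_px": params.window_px,
              "norm_percentile": params.norm_percentile},
    )


DEFAULT_CORD_LENGTHS_UM = np.arange(50.0, 601.0, 50.0)


def analyze_tubes(
    image: ImageGrid,
    lengths_um=DEFAULT_CORD_LENGTHS_UM,
    orientations_deg=None,
    tau: float = 0.8,
    width_px: float = 16.0,
    blur_px: float = 2.0,
    contrast_params: ContrastMapParams = ContrastMapParams(),
    weighting: str = "uniform",
) -> tuple[filament.LengthMap, stats.LengthDistribution, ImageGrid]:
    """Full cord pipeline: contrast map -> correlation-length map ->
    length distribution.

    The length grid must extend beyond 300 um so the cord-length statistic
    (fraction of signal above 300 um) is well defined.  Returns the length
    map, its distribution and the intermediate contrast map.
    """
    lengths_um = np.asarray(lengths_um, dtype=np.float64)
    if lengths_um.max() <= stats.CORD_THRESHOLD_UM:
        raise ValueError(
            "cord length grid must extend beyond "
            f"{stats.CORD_THRESHOLD_UM:.0f} um"
        )
    if orientations_deg is None:
        orientations_deg = kernels.default_orientation_grid_deg(10.0)
    contrast = local_contrast_map(image, contrast_params)
    bank = kernels.build_kernel_bank(
        lengths_um, orientations_deg, width_px=width_px, blur_px=blur_px,
        pixel_size_um=image.pixel_size_um,
    )
    stack = filament.correlate(contrast, bank)
    lmap = filament.length_map(stack, contrast, tau)
    dist = stats.length_distribution(lmap, weighting=weighting)
    return lmap, dist, contrast
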