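"""Calibrated 2D intensity fields.

All analysis operates on :class:`ImageGrid`: a non-negative 2D intensity
array together with its physical pixel size in micrometres and a modality
tag.  Fluorescence images are analysed directly; phase-contrast images must
first be converted to a local-contrast map (see :mod:`filaquant.tubes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("fluorescence", "phase_contrast", "contrast_map")

MIN_SIDE = 16  # smallest image side we accept, in pixels


@dataclass
class ImageGrid:
    """A calibrated grayscale micrograph.

    Parameters
    ----------
    intensity:
        2D float array, finite and non-negative.
    pixel_size_um:
        Physical size of one pixel in micrometres (isotropic).
    modality:
        One of ``fluorescence``, ``phase_contrast`` or ``contrast_map``.
    """

    intensity: np.ndarray
    pixel_size_um: float
    modality: str = "fluorescence"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D array")
        if min(self.intensity.shape) < MIN_SIDE:
            raise ValueError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE} pixels, "
                f"got {self.intensity.shape}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical (height, width) of the field in micrometres."""
        h, w = self.intensity.shape
        return (h * self.pixel_size_um, w * self.pixel_size_um)
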