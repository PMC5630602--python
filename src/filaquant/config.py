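"""Run configuration: validated, JSON round-trippable, stored with outputs.

Every pipeline writes the exact configuration it ran with into its output
directory (``config.json``); re-running from that file reproduces the
outputs byte-identically, and condition comparisons refuse to mix runs
whose analysis grids or thresholds differ.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

#: fields that must match between two runs for a comparison to be valid
COMPARABLE_FIELDS = (
    "pixel_size_um",
    "lengths_um",
    "orientation_step_deg",
    "kernel_width_px",
    "kernel_blur_px",
    "tau",
    "intensity_percentiles",
    "mask_mode",
    "weighting",
    "contrast_window_px",
    "contrast_percentile",
)


@dataclass
class RunConfig:
    pixel_size_um: float = 0.5
    lengths_um: list = field(
        default_factory=lambda: [float(x) for x in range(10, 81, 10)]
    )
    orientation_step_deg: float = 5.0
    kernel_width_px: float = 3.0
    kernel_blur_px: float = 1.0
    tau: float | str = "calibrate"  # numeric, or "calibrate"
    intensity_percentiles: tuple = (50.0, 99.0)
    mask_mode: str = "indicator"
    weighting: str = "uniform"
    # phase-contrast pretreatment
    contrast_window_px: int = 15
    contrast_percentile: float = 95.0
    # track analysis
    frame_interval_s: float = 300.0
    track_window_h: tuple = (5.0, 10.0)
    # misc
    seed: int = 0
    threshold_um: float = 25.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lengths = [float(x) for x in self.lengths_um]
        if len(lengths) == 0 or any(
            b <= a for a, b in zip(lengths, lengths[1:])
        ):
            raise ValueError("lengths_um must be non-empty, strictly increasing")
        self.lengths_um = lengths
        if not 0 < self.orientation_step_deg <= 90:
            raise ValueError("orientation_step_deg must lie in (0, 90]")
        if isinstance(self.tau, str):
            if self.tau != "calibrate":
                raise ValueError("tau must be numeric or 'calibrate'")
        elif not 0 < float(self.tau) < 1:
            raise ValueError("numeric tau must lie in (0, 1)")
        if self.mask_mode not in ("indicator", "score"):
            raise ValueError("mask_mode must be 'indicator' or 'score'")
        if self.weighting not in ("uniform", "mask"):
            raise ValueError("weighting must be 'uniform' or 'mask'")
        lo, hi = self.intensity_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("bad intensity percentiles")
        self.intensity_percentiles = (float(lo), float(hi))
        self.track_window_h = tuple(float(x) for x in self.track_window_h)
        if self.track_window_h[0] >= self.track_window_h[1]:
            raise ValueError("track window start must precede end")

    def orientations_deg(self) -> np.ndarray:
        return np.arange(0.0, 180.0, self.orientation_step_deg)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["intensity_percentiles"] = list(d["intensity_percentiles"])
        d["track_window_h"] = list(d["track_window_h"])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["intensity_percentiles"] = tuple(d["intensity_percentiles"])
        d["track_window_h"] = tuple(d["track_window_h"])
        return cls(**d)

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def comparable_signature(self) -> dict:
        d = asdict(self)
        return {k: d[k] for k in COMPARABLE_FIELDS}
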