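"""Ground-truth generators for every analysis stage.

Three simulators emulate the study's raw inputs:

* fluorescence fields of thin bright fibre segments with controlled
  length/orientation statistics (matrix-fibre images),
* phase-contrast-like cord networks — chains of segments rendered as a
  dark core with a bright rim on a mid-gray background (tube-formation
  images),
* persistent random-walk trajectories with known speed and directional
  persistence (cell-migration movies, post-tracking).

Each generator takes a frozen spec including a seed and is bit-exactly
reproducible: a single ``numpy`` generator is created per call and all
samplers draw from it in the documented order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ImageGrid
from .motility import TrackSet

from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# samplers


@dataclass(frozen=True)
class Sampler:
    """Named scalar distribution: ``fixed``, ``uniform``, ``normal``,
    ``lognormal`` or ``choice`` (values + optional probs)."""

    name: str
    params: dict

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.name == "fixed":
            return np.full(size, float(p["value"]))
        if self.name == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.name == "normal":
            return rng.normal(p["mean"], p["sd"], size)
        if self.name == "lognormal":
            return rng.lognormal(p["mean"], p["sigma"], size)
        if self.name == "choice":
            return rng.choice(
                np.asarray(p["values"], dtype=np.float64),
                size=size,
                p=p.get("probs"),
            )
        raise ValueError(f"unknown sampler {self.name!r}")


def fixed(value: float) -> Sampler:
    return Sampler("fixed", {"value": value})


def choice(values, probs=None) -> Sampler:
    return Sampler("choice", {"values": list(values), "probs": probs})


def uniform(low: float, high: float) -> Sampler:
    return Sampler("uniform", {"low": low, "high": high})


# --------------------------------------------------------------------------
# fibre fields


@dataclass(frozen=True)
class FibreSegmentTruth:
    """Ground truth for one rendered fibre segment."""

    center_um: tuple[float, float]  # (x, y)
    length_um: float
    orientation_deg: float  # in [0, 180)
    width_um: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0 or self.amplitude <= 0:
            raise ValueError("length, width and amplitude must be positive")
        if not 0 <= self.orientation_deg < 180:
            raise ValueError("orientation must lie in [0, 180) degrees")


@dataclass(frozen=True)
class FibreFieldSpec:
    """Recipe for a synthetic fibre-field image."""

    shape_px: tuple[int, int] = (512, 512)  # (rows, cols)
    pixel_size_um: float = 0.5
    n_segments: int = 40
    length_sampler: Sampler = field(
        default_factory=lambda: uniform(10.0, 60.0)
    )
    orientation_sampler: Sampler = field(
        default_factory=lambda: uniform(0.0, 180.0)
    )
    width_um: float = 1.5
    amplitude: float = 400.0
    background: float = 100.0
    blur_sigma_um: float = 0.5
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape_px) < 16 or self.pixel_size_um <= 0:
            raise ValueError("invalid image geometry")
        if self.n_segments < 0:
            raise ValueError("n_segments must be >= 0")
        if self.width_um <= 0 or self.amplitude <= 0:
            raise ValueError("width and amplitude must be positive")
        if self.background < 0 or self.noise_sigma < 0 or self.blur_sigma_um < 0:
            raise ValueError("background/noise/blur must be >= 0")


def _snap(v: float) -> float:
    for t in (0.0, 1.0, -1.0):
        if abs(v - t) < 1e-12:
            return t
    return v


def _capsule_distance(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    length_px: float,
    theta_deg: float,
    reach_px: float,
):
    """Distance to a centred segment over its bounding box (± reach).

    Returns ``(r0, r1, c0, c1, d)``.  Convention matches the kernel bank:
    x along columns, theta counterclockwise on the displayed image (row
    index down).
    """
    cx, cy = center_px  # (col, row)
    c = _snap(np.cos(np.deg2rad(theta_deg)))
    s = _snap(np.sin(np.deg2rad(theta_deg)))
    half = length_px / 2.0
    hx = abs(c) * half + reach_px
    hy = abs(s) * half + reach_px
    r0 = max(int(np.floor(cy - hy)), 0)
    r1 = min(int(np.ceil(cy + hy)) + 1, shape[0])
    c0 = max(int(np.floor(cx - hx)), 0)
    c1 = min(int(np.ceil(cx + hx)) + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return r0, r1, c0, c1, np.zeros((0, 0))
    rows, cols = np.mgrid[r0:r1, c0:c1]
    x = cols - cx
    y = -(rows - cy)
    t = np.clip(x * c + y * s, -half, half)
    d = np.hypot(x - t * c, y - t * s)
    return r0, r1, c0, c1, d


def _capsule_coverage(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    length_px: float,
    theta_deg: float,
    width_px: float,
):
    """Anti-aliased coverage of a capsule, restricted to its bounding box.

    Returns ``(r0, r1, c0, c1, coverage)`` with coverage in [0, 1] per
    pixel of the box.
    """
    r0, r1, c0, c1, d = _capsule_distance(
        shape, center_px, length_px, theta_deg, width_px / 2.0 + 1.5
    )
    cov = np.clip(width_px / 2.0 + 0.5 - d, 0.0, 1.0)
    return r0, r1, c0, c1, cov


def _check_fits(length_um: float, spec_shape, pixel_size_um: float) -> None:
    diag_um = float(np.hypot(*spec_shape)) * pixel_size_um
    if length_um > diag_um:
        raise ValueError(
            f"segment of {length_um:.1f} um exceeds the image diagonal "
            f"({diag_um:.1f} um)"
        )


def generate_fibre_field(
    spec: FibreFieldSpec,
) -> tuple[ImageGrid, list[FibreSegmentTruth], np.ndarray]:
    """Render a fluorescence-like fibre field with per-pixel truth labels.

    Per segment the generator draws, in order: length, orientation, centre
    x, centre y (centres are placed so the whole capsule fits inside the
    frame).  Overlapping fibres add their intensities — crossings are
    brighter, as in real matrices — while the truth label image keeps, at
    each fibre pixel, the true length of the *longest* segment covering it.

    Returns ``(image, truth, label)`` where ``label`` is a float image with
    0 off-fibre and the covering segment's length (um) on-fibre.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    canvas = np.zeros((h, w), dtype=np.float64)
    label = np.zeros((h, w), dtype=np.float64)
    width_px = spec.width_um / spec.pixel_size_um
    truth: list[FibreSegmentTruth] = []

    for _ in range(spec.n_segments):
        length_um = float(spec.length_sampler.draw(rng, 1)[0])
        theta = float(spec.orientation_sampler.draw(rng, 1)[0]) % 180.0
        _check_fits(length_um, spec.shape_px, spec.pixel_size_um)
        length_px = length_um / spec.pixel_size_um
        c = abs(_snap(np.cos(np.deg2rad(theta))))
        s = abs(_snap(np.sin(np.deg2rad(theta))))
        hx = c * length_px / 2.0 + width_px / 2.0 + 1.0
        hy = s * length_px / 2.0 + width_px / 2.0 + 1.0
        if 2 * hx >= w - 2 or 2 * hy >= h - 2:
            raise ValueError(
                f"segment of {length_um:.1f} um at {theta:.0f} deg does not "
                "fit inside the frame"
            )
        cx = rng.uniform(hx, w - 1 - hx)
        cy = rng.uniform(hy, h - 1 - hy)
        r0, r1, c0, c1, cov = _capsule_coverage(
            (h, w), (cx, cy), length_px, theta, width_px
        )
        canvas[r0:r1, c0:c1] += spec.amplitude * cov
        core = cov >= 0.5
        patch = label[r0:r1, c0:c1]
        patch[core & (patch < length_um)] = length_um
        truth.append(
            FibreSegmentTruth(
                center_um=(cx * spec.pixel_size_um, cy * spec.pixel_size_um),
                length_um=length_um,
                orientation_deg=theta,
                width_um=spec.width_um,
                amplitude=spec.amplitude,
            )
        )

    if spec.blur_sigma_um > 0:
        canvas = gaussian_filter(canvas, spec.blur_sigma_um / spec.pixel_size_um)
    canvas += spec.background
    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, canvas.shape)
    np.clip(canvas, 0.0, None, out=canvas)
    image = ImageGrid(canvas, spec.pixel_size_um, modality="fluorescence")
    return image, truth, label


def render_probe_fibre(
    length_um: float,
    pixel_size_um: float,
    width_um: float,
    amplitude: float = 1.0,
    blur_sigma_um: float = 0.0,
    orientation_deg: float = 0.0,
    image_shape: tuple[int, int] | None = None,
    margin_px: int = 16,
) -> tuple[ImageGrid, np.ndarray]:
    """One clean, centred fibre for threshold calibration.

    ``blur_sigma_um`` should match the optical blur of the data the
    calibrated threshold will be applied to.  Returns the noise-free image
    and the boolean on-fibre pixel mask.
    """
    length_px = length_um / pixel_size_um
    width_px = width_um / pixel_size_um
    if image_shape is None:
        side = int(np.ceil(length_px)) + 2 * margin_px + 1
        side = max(side, 32)
        image_shape = (side, side)
    h, w = image_shape
    if length_px + 2 >= min(h, w):
        raise ValueError("probe fibre does not fit the requested frame")
    centre = ((w - 1) / 2.0, (h - 1) / 2.0)
    canvas = np.zeros((h, w), dtype=np.float64)
    r0, r1, c0, c1, cov = _capsule_coverage(
        (h, w), centre, length_px, orientation_deg, width_px
    )
    canvas[r0:r1, c0:c1] += amplitude * cov
    if blur_sigma_um > 0:
        canvas = gaussian_filter(canvas, blur_sigma_um / pixel_size_um)
    on_fibre = np.zeros((h, w), dtype=bool)
    on_fibre[r0:r1, c0:c1] = cov >= 0.5
    return ImageGrid(canvas, pixel_size_um, modality="fluorescence"), on_fibre


# --------------------------------------------------------------------------
# cord networks


@dataclass(frozen=True)
class CordTruth:
    """Ground truth for one cord: its polyline(s) and total path length."""

    cord_id: int
    length_um: float  # total path length, branches included
    vertices_um: tuple  # tuple of polylines, each a tuple of (x, y) um


@dataclass(frozen=True)
class CordNetworkSpec:
    """Recipe for a phase-contrast-like cord-network image."""

    shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.0
    n_cords: int = 20
    length_sampler: Sampler = field(
        default_factory=lambda: uniform(150.0, 450.0)
    )
    step_um: float = 25.0  # polyline segment length
    turn_sigma_rad: float = 0.15  # waviness of the cord path
    branch_prob: float = 0.0
    width_um: float = 12.0
    core_drop: float = 0.25  # phase-dark cord body
    rim_gain: float = 0.20  # bright halo at the cord edge
    background: float = 0.5
    blur_sigma_um: float = 2.0
    noise_sigma: float = 0.02
    min_clearance_um: float = 0.0  # >0: rejection-sample non-crossing cords
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape_px) < 16 or self.pixel_size_um <= 0:
            raise ValueError("invalid image geometry")
        if self.n_cords < 0 or self.step_um <= 0 or self.width_um <= 0:
            raise ValueError("invalid cord geometry")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.min_clearance_um < 0:
            raise ValueError("min_clearance_um must be >= 0")


def _walk_polyline(
    rng: np.random.Generator,
    start_um: np.ndarray,
    heading: float,
    target_um: float,
    spec: CordNetworkSpec,
) -> tuple[list[np.ndarray], float]:
    """Chain fixed-length segments with Gaussian heading jitter, bouncing
    off the frame edges; returns vertices and realised path length."""
    h, w = spec.shape_px
    margin = spec.width_um
    xmax = w * spec.pixel_size_um - margin
    ymax = h * spec.pixel_size_um - margin
    pts = [start_um.copy()]
    travelled = 0.0
    pos = start_um.copy()
    while travelled < target_um:
        step = min(spec.step_um, target_um - travelled)
        for _ in range(4):  # reflect until the step stays inside
            nxt = pos + step * np.array([np.cos(heading), np.sin(heading)])
            if not margin <= nxt[0] <= xmax:
                heading = np.pi - heading
                continue
            if not margin <= nxt[1] <= ymax:
                heading = -heading
                continue
            break
        else:
            break
        pts.append(nxt)
        travelled += step
        pos = nxt
        heading += rng.normal(0.0, spec.turn_sigma_rad)
    return pts, travelled


def generate_cord_network(
    spec: CordNetworkSpec,
) -> tuple[ImageGrid, list[CordTruth], np.ndarray]:
    """Render a phase-contrast-like network of cords with truth lengths.

    Per cord the generator draws, in order: target length, then (up to 50
    times when ``min_clearance_um`` demands separation) initial heading,
    start x, start y and the per-segment heading jitter, then branch
    decisions when ``branch_prob > 0`` (a Bernoulli draw per interior
    vertex, then branch length fraction and side).  Cords are rendered as
    a dark band with a bright rim on a mid-gray background.  The returned
    label image carries, on each cord-core pixel, the covering cord's
    total path length (longest cord wins where cords cross).

    With ``min_clearance_um > 0`` each cord is rejection-sampled so its
    path keeps that clearance from previously placed cords (an
    unplaceable cord is rendered overlapping, with a log notice) — used
    when per-cord truth must remain attributable pixel by pixel.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    core_total = np.zeros((h, w), dtype=np.float64)
    rim_total = np.zeros((h, w), dtype=np.float64)
    label = np.zeros((h, w), dtype=np.float64)
    truth: list[CordTruth] = []
    width_px = spec.width_um / spec.pixel_size_um
    rim_px = max(1.0, 0.4 * width_px)
    margin = spec.width_um

    def polyline_distance(polylines) -> np.ndarray:
        """Min distance (px) from each image pixel to the cord's paths."""
        d_img = np.full((h, w), np.inf)
        reach = width_px / 2.0 + rim_px + 1.5
        for pts in polylines:
            for a, b in zip(pts[:-1], pts[1:]):
                mid = (a + b) / 2.0 / spec.pixel_size_um
                seg_len_px = np.linalg.norm(b - a) / spec.pixel_size_um
                if seg_len_px == 0:
                    continue
                theta = float(
                    np.rad2deg(np.arctan2(-(b - a)[1], (b - a)[0]))
                ) % 180.0
                r0, r1, c0, c1, d = _capsule_distance(
                    (h, w), (mid[0], mid[1]), seg_len_px, theta, reach
                )
                np.minimum(d_img[r0:r1, c0:c1], d, out=d_img[r0:r1, c0:c1])
        return d_img

    xmax = w * spec.pixel_size_um - margin
    ymax = h * spec.pixel_size_um - margin
    occupancy = np.zeros((h, w), dtype=bool)  # used when clearance > 0

    def path_mask(pts, extra_um: float) -> np.ndarray:
        m = np.zeros((h, w), dtype=bool)
        for a, b in zip(pts[:-1], pts[1:]):
            mid = (a + b) / 2.0 / spec.pixel_size_um
            seg_len_px = np.linalg.norm(b - a) / spec.pixel_size_um
            if seg_len_px == 0:
                continue
            theta = float(
                np.rad2deg(np.arctan2(-(b - a)[1], (b - a)[0]))
            ) % 180.0
            r0, r1, c0, c1, cov = _capsule_coverage(
                (h, w), (mid[0], mid[1]), seg_len_px, theta,
                (spec.width_um + extra_um) / spec.pixel_size_um,
            )
            m[r0:r1, c0:c1] |= cov >= 0.5
        return m

    def draw_path(target: float):
        heading = rng.uniform(0.0, 2 * np.pi)
        # place the start so the straight-line extent fits the frame
        # (wavy cords may still bounce; the walk reflects at the edges)
        dx = target * np.cos(heading)
        dy = target * np.sin(heading)
        lo_x, hi_x = margin + max(0.0, -dx), xmax - max(0.0, dx)
        lo_y, hi_y = margin + max(0.0, -dy), ymax - max(0.0, dy)
        if lo_x >= hi_x:
            lo_x, hi_x = margin, xmax
        if lo_y >= hi_y:
            lo_y, hi_y = margin, ymax
        start = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        return _walk_polyline(rng, start, heading, target, spec)

    for cid in range(spec.n_cords):
        target = float(spec.length_sampler.draw(rng, 1)[0])
        _check_fits(min(target, spec.step_um), spec.shape_px, spec.pixel_size_um)
        if spec.min_clearance_um > 0:
            pts = travelled = None
            for _ in range(50):
                cand, trav = draw_path(target)
                if not (
                    path_mask(cand, 2 * spec.min_clearance_um) & occupancy
                ).any():
                    pts, travelled = cand, trav
                    break
            if pts is None:
                logger.info("cord %d placed overlapping after 50 tries", cid)
                pts, travelled = draw_path(target)
            occupancy |= path_mask(pts, 0.0)
        else:
            pts, travelled = draw_path(target)
        polylines = [pts]
        total = travelled
        if spec.branch_prob > 0 and len(pts) > 2:
            for vi in range(1, len(pts) - 1):
                if rng.random() < spec.branch_prob:
                    frac = rng.uniform(0.2, 0.5)
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    d = pts[vi + 1] - pts[vi]
                    base = np.arctan2(d[1], d[0])
                    bpts, blen = _walk_polyline(
                        rng, pts[vi], base + side * np.pi / 3,
                        frac * target, spec,
                    )
                    if blen > 0:
                        polylines.append(bpts)
                        total += blen
        d_cord = polyline_distance(polylines)
        core = np.clip(width_px / 2.0 + 0.5 - d_cord, 0.0, 1.0)
        outer = np.clip(width_px / 2.0 + rim_px + 0.5 - d_cord, 0.0, 1.0)
        np.maximum(core_total, core, out=core_total)
        np.maximum(rim_total, np.clip(outer - core, 0.0, 1.0), out=rim_total)
        on_core = core >= 0.5
        label[on_core & (label < total)] = total
        truth.append(
            CordTruth(
                cord_id=cid,
                length_um=total,
                vertices_um=tuple(
                    tuple((float(p[0]), float(p[1])) for p in poly)
                    for poly in polylines
                ),
            )
        )

    # phase-contrast look: dark cord body, bright halo where no body
    relief = (
        spec.rim_gain * rim_total * (core_total < 0.5)
        - spec.core_drop * core_total
    )
    canvas = spec.background + relief
    if spec.blur_sigma_um > 0:
        canvas = gaussian_filter(canvas, spec.blur_sigma_um / spec.pixel_size_um)
    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, canvas.shape)
    np.clip(canvas, 0.0, None, out=canvas)
    image = ImageGrid(canvas, spec.pixel_size_um, modality="phase_contrast")
    return image, truth, label


# --------------------------------------------------------------------------
# persistent random walks


@dataclass(frozen=True)
class PRWParams:
    """Persistent-random-walk ensemble: constant step length, independent
    Gaussian heading increments of SD ``turn_sigma_rad`` per frame."""

    n_tracks: int = 100
    n_frames: int = 61  # 5 h at 5-min frames
    frame_interval_s: float = 300.0  # study convention: 5-min frames
    mean_speed_um_h: float = 20.0
    turn_sigma_rad: float = 0.5
    position_noise_um: float = 0.0
    seed: int = 0
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_tracks < 1 or self.n_frames < 3:
            raise ValueError("need n_tracks >= 1 and n_frames >= 3")
        if self.frame_interval_s <= 0 or self.mean_speed_um_h < 0:
            raise ValueError("invalid kinetics")
        if self.turn_sigma_rad < 0 or self.position_noise_um < 0:
            raise ValueError("sigmas must be >= 0")

    @property
    def step_um(self) -> float:
        return self.mean_speed_um_h * self.frame_interval_s / 3600.0

    @property
    def theoretical_persistence_um(self) -> float:
        """Contour decay constant 2 d / sigma^2 of the tangent
        autocorrelation exp(-k sigma^2 / 2)."""
        if self.turn_sigma_rad == 0:
            return float("inf")
        return 2.0 * self.step_um / self.turn_sigma_rad**2


def generate_tracks(params: PRWParams) -> TrackSet:
    """Simulate a persistent-random-walk ensemble.

    Per track the generator draws, in order: start position (uniform in a
    1 mm square), initial heading, the heading increments, then the
    positional noise.  With ``turn_sigma_rad = 0`` every track is an exact
    straight line; the expected per-step tangent autocorrelation is
    ``exp(-turn_sigma_rad^2 / 2)``.
    """
    rng = np.random.default_rng(params.seed)
    d = params.step_um
    n_steps = params.n_frames - 1
    frames = np.arange(params.n_frames)
    t_s = frames * params.frame_interval_s
    tables = []
    for tid in range(params.n_tracks):
        start = rng.uniform(0.0, 1000.0, size=2)
        heading0 = rng.uniform(0.0, 2 * np.pi)
        increments = rng.normal(0.0, params.turn_sigma_rad, size=n_steps)
        headings = heading0 + np.concatenate([[0.0], np.cumsum(increments[:-1])])
        steps = d * np.column_stack([np.cos(headings), np.sin(headings)])
        xy = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if params.position_noise_um > 0:
            xy = xy + rng.normal(
                0.0, params.position_noise_um, size=xy.shape
            )
        tables.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": frames,
                    "t_s": t_s.astype(np.float64),
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                }
            )
        )
    table = pd.concat(tables, ignore_index=True)
    return TrackSet(
        table,
        frame_interval_s=params.frame_interval_s,
        condition=params.condition,
    )


# --------------------------------------------------------------------------
# truth-side summaries used by the test oracles


def label_fraction_below(label: np.ndarray, threshold_um: float) -> float:
    """Fraction of labelled (on-structure) pixels whose true length is
    strictly below the threshold — the pixel-weighted ground truth."""
    on = label > 0
    if not on.any():
        raise ValueError("label image has no structure pixels")
    return float(np.mean(label[on] < threshold_um))


def label_fraction_above(label: np.ndarray, threshold_um: float) -> float:
    """Strictly-above counterpart of :func:`label_fraction_below`."""
    on = label > 0
    if not on.any():
        raise ValueError("label image has no structure pixels")
    return float(np.mean(label[on] > threshold_um))
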