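"""Oriented line-kernel banks.

The filament detector matches the image against a family of line-shaped
stencils indexed by physical length ``L`` (micrometres) and orientation
``theta`` (degrees in ``[0, 180)``; 180 is redundant because a line
segment is symmetric under point reflection).  Each stencil is an
anti-aliased straight capsule of a given pixel width, optionally convolved
with an isotropic Gaussian so it matches the optically blurred line
profile of real data (matched filtering).  The stencil is restricted to a
*footprint*: the set of pixels within the capsule plus a small background
margin.  Zero-meaning and L2-normalisation are performed over the
footprint, so that matching the stencil against a footprint-normalised
image patch yields a zero-normalised cross-correlation (ZNCC) in
``[-1, 1]`` that is insensitive to unrelated structures elsewhere in the
bounding square — essential in dense fibre fields.

Because a long thin kernel tolerates only a small angular mismatch
(roughly ``atan(width / length)``), the orientation grid is refined per
length: the base step is halved (up to twice) until half a step of
misalignment displaces the kernel tip by at most half the line width.
Each per-length grid remains closed under 90-degree rotation when the
base grid is.

Coordinate convention: pixel centres, 0-based, row index increasing
downward; ``theta`` is measured counterclockwise from the +x (column)
axis as the image is displayed, so a ``theta = 90`` segment runs along
the column direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

_MEAN_TOL = 1e-9
_NORM_TOL = 1e-9

#: background margin around the capsule included in the footprint, px
FOOTPRINT_MARGIN_PX = 1.5


def _snap_trig(value: float) -> float:
    """Round cos/sin of grid angles to exact 0/±1/±0.5 when within 1e-12."""
    for target in (0.0, 1.0, -1.0, 0.5, -0.5):
        if abs(value - target) < 1e-12:
            return target
    return value


def _segment_distance_field(
    side: int, length_px: float, theta_deg: float
) -> np.ndarray:
    """Distance from each pixel centre of a side x side support to the
    centred segment of the given length and orientation."""
    c = _snap_trig(np.cos(np.deg2rad(theta_deg)))
    s = _snap_trig(np.sin(np.deg2rad(theta_deg)))
    half = length_px / 2.0
    centre = (side - 1) / 2.0
    rows, cols = np.mgrid[0:side, 0:side]
    x = cols - centre
    y = -(rows - centre)  # row index grows downward; flip to math y
    # project onto the segment axis, clamp to the endpoints (capsule)
    t = np.clip(x * c + y * s, -half, half)
    dx = x - t * c
    dy = y - t * s
    return np.hypot(dx, dy)


@dataclass
class LineStencil:
    """One oriented matched filter.

    ``weights`` is zero outside ``footprint``, has zero mean and unit L2
    norm over the footprint; ``core`` marks the pixels the kernel's line
    actually covers (used to propagate a passing score to every pixel
    under the placement).
    """

    length_um: float
    theta_deg: float
    weights: np.ndarray  # float64, side x side
    footprint: np.ndarray  # bool, side x side
    core: np.ndarray  # bool, side x side

    @property
    def side(self) -> int:
        return self.weights.shape[0]


def line_stencil(
    length_px: float,
    theta_deg: float,
    width_px: float,
    side: int,
    blur_px: float = 0.0,
    length_um: float = 0.0,
    margin_px: float = FOOTPRINT_MARGIN_PX,
    core_width_px: float | None = None,
) -> LineStencil:
    """Build one stencil: blurred anti-aliased capsule on its footprint.

    Anti-aliasing uses linear coverage: a pixel whose centre lies at
    distance ``d`` from the segment receives ``clip(w/2 + 1/2 - d, 0, 1)``
    before blurring.  ``core_width_px`` sets the width of the attribution
    core (the stripe a passing placement labels); it defaults to the
    detection width, but a narrower core keeps length attribution close
    to the structure's medial axis when wide kernels are used.
    """
    if core_width_px is None:
        core_width_px = width_px
    d = _segment_distance_field(side, length_px, theta_deg)
    capsule = np.clip(width_px / 2.0 + 0.5 - d, 0.0, 1.0)
    profile = gaussian_filter(capsule, blur_px) if blur_px > 0 else capsule
    footprint = d <= width_px / 2.0 + 0.5 + 2.0 * blur_px + margin_px
    core = np.clip(core_width_px / 2.0 + 0.5 - d, 0.0, 1.0) >= 0.5
    weights = np.where(footprint, profile, 0.0)
    n_fp = footprint.sum()
    weights[footprint] -= weights[footprint].sum() / n_fp
    norm = np.linalg.norm(weights)
    if norm == 0:
        raise ValueError("degenerate stencil (all-zero after centring)")
    weights /= norm
    return LineStencil(
        length_um=length_um,
        theta_deg=float(theta_deg),
        weights=weights,
        footprint=footprint,
        core=core,
    )


def _refined_step(
    base_step: float, length_px: float, width_px: float, max_splits: int = 2
) -> float:
    """Halve the orientation step until half-step misalignment moves the
    kernel tip by at most half the line width (or the split cap is hit)."""
    step = base_step
    for _ in range(max_splits):
        tip = (length_px / 2.0) * np.tan(np.deg2rad(step / 2.0))
        if tip <= width_px / 2.0:
            break
        step /= 2.0
    return step


@dataclass
class KernelBank:
    """Family of line stencils over a length grid with per-length
    orientation grids.

    ``stencils[i][j]`` matches ``lengths_um[i]`` at
    ``orientation_grids[i][j]``; all orientations of one length share an
    odd square support of side ``supports_px[i]``.
    """

    lengths_um: np.ndarray
    base_orientations_deg: np.ndarray
    orientation_grids: list[np.ndarray]
    width_px: float
    pixel_size_um: float
    blur_px: float
    stencils: list[list[LineStencil]]
    supports_px: np.ndarray

    @property
    def n_lengths(self) -> int:
        return len(self.lengths_um)

    @property
    def max_support_px(self) -> int:
        return int(self.supports_px.max())

    @property
    def n_stencils(self) -> int:
        return sum(len(row) for row in self.stencils)

    def lengths_px(self) -> np.ndarray:
        return self.lengths_um / self.pixel_size_um

    def validate(self) -> None:
        """Check the zero-mean / unit-norm invariants of every stencil."""
        for row in self.stencils:
            for st in row:
                if abs(st.weights.sum()) >= _MEAN_TOL * st.footprint.sum():
                    raise AssertionError("stencil mean exceeds tolerance")
                if abs(np.linalg.norm(st.weights) - 1.0) >= _NORM_TOL:
                    raise AssertionError("stencil norm deviates from 1")


def build_kernel_bank(
    lengths_um,
    orientations_deg,
    width_px: float = 3.0,
    pixel_size_um: float = 1.0,
    blur_px: float = 0.0,
    refine_orientations: bool = True,
    core_width_px: float | None = None,
) -> KernelBank:
    """Build the stencil bank for the given length/orientation grids.

    Parameters
    ----------
    lengths_um:
        Strictly increasing kernel lengths in micrometres; each must span
        at least 2 pixels at the given pixel size.
    orientations_deg:
        Strictly increasing base orientations in degrees, all in
        ``[0, 180)``.  When ``refine_orientations`` is set and the grid is
        uniform, longer kernels get proportionally finer grids (see
        module docstring).
    width_px:
        Stencil line width in pixels (>= 1).
    pixel_size_um:
        Pixel size used to convert lengths to pixels.
    blur_px:
        Isotropic Gaussian blur of the stencil profile, in pixels; set to
        the optical blur of the data for matched filtering (0 = sharp).
    """
    lengths_um = np.asarray(lengths_um, dtype=np.float64)
    orientations_deg = np.asarray(orientations_deg, dtype=np.float64)
    if lengths_um.ndim != 1 or lengths_um.size == 0:
        raise ValueError("lengths_um must be a non-empty 1D sequence")
    if np.any(np.diff(lengths_um) <= 0):
        raise ValueError("lengths_um must be strictly increasing")
    if orientations_deg.ndim != 1 or orientations_deg.size == 0:
        raise ValueError("orientations_deg must be a non-empty 1D sequence")
    if np.any(np.diff(orientations_deg) <= 0):
        raise ValueError("orientations_deg must be strictly increasing")
    if np.any(orientations_deg < 0) or np.any(orientations_deg >= 180):
        raise ValueError("orientations must lie in [0, 180) degrees")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if blur_px < 0:
        raise ValueError("blur_px must be >= 0")
    if lengths_um[0] < 2 * pixel_size_um:
        raise ValueError(
            "shortest kernel length must span at least 2 pixels "
            f"({lengths_um[0]} um < 2 x {pixel_size_um} um)"
        )

    steps = np.diff(orientations_deg)
    uniform = orientations_deg.size > 1 and np.allclose(steps, steps[0])
    base_step = float(steps[0]) if uniform else None

    stencils: list[list[LineStencil]] = []
    grids: list[np.ndarray] = []
    supports = np.empty(lengths_um.size, dtype=np.int64)
    for i, L in enumerate(lengths_um):
        length_px = round(L / pixel_size_um)
        if refine_orientations and uniform:
            step = _refined_step(base_step, length_px, width_px)
            grid = np.arange(orientations_deg[0], 180.0, step)
            grid = grid[grid < 180.0]
        else:
            grid = orientations_deg.copy()
        half_extent = (
            length_px / 2.0 + width_px / 2.0 + 1.0
            + 2.0 * blur_px + FOOTPRINT_MARGIN_PX
        )
        side = 2 * int(np.ceil(half_extent)) + 1  # odd, covers any theta
        supports[i] = side
        grids.append(grid)
        stencils.append(
            [
                line_stencil(
                    length_px, theta, width_px, side, blur_px, length_um=L,
                    core_width_px=core_width_px,
                )
                for theta in grid
            ]
        )
    bank = KernelBank(
        lengths_um=lengths_um,
        base_orientations_deg=orientations_deg,
        orientation_grids=grids,
        width_px=float(width_px),
        pixel_size_um=float(pixel_size_um),
        blur_px=float(blur_px),
        stencils=stencils,
        supports_px=supports,
    )
    bank.validate()
    return bank


def default_length_grid_um(
    image_extent_um: float, n_steps: int = 8, min_length_um: float = 5.0
) -> np.ndarray:
    """Linear length grid from ``min_length_um`` to half the image width."""
    upper = image_extent_um / 2.0
    if upper <= min_length_um:
        raise ValueError("image too small for the default length grid")
    return np.linspace(min_length_um, upper, n_steps)


def default_orientation_grid_deg(step: float = 5.0) -> np.ndarray:
    """Base orientation grid 0..180-step; step must divide 90 to keep the
    grid (and its refinements) closed under 90-degree image rotation."""
    return np.arange(0.0, 180.0, step)
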