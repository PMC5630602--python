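"""Correlation-length mapping with oriented line kernels.

For every pixel, kernel length ``L`` and orientation ``theta`` the
detector computes the zero-normalised cross-correlation (ZNCC) between
the line stencil and the image patch over the stencil's footprint (the
capsule plus a small background margin): the patch is mean-subtracted and
norm-divided over that footprint, the stencil is already normalised, so
scores lie in ``[-1, 1]`` and a flat patch scores 0 by convention.
Conceptually this is the 4D score ``Corr(x, y, L, theta)``; it is stored
reduced over orientation (best score and winning orientation per pixel
and length), from which per-length orientation slices can be recomputed
on demand.

:func:`length_map` turns the scores into the per-pixel correlation
length.  A placement (centre, L, theta) *passes* when its score reaches
the threshold ``tau``; a pixel's ``lmax`` is the largest L for which some
passing placement covers the pixel (coverage is the kernel's own line
footprint).  Two deliberate choices are folded into this definition:

* the *largest* passing length is kept, not the score argmax — a line
  kernel inside a longer straight structure scores near 1 at every
  shorter length, so no interior maximum exists;
* a passing placement labels every pixel it covers, not only its centre —
  otherwise the off-spine and tip pixels of every fibre would be
  attributed to much shorter kernels, biasing length statistics short.

A mask combining detection and image intensity accompanies the length
map and serves as the value channel of the HSV rendering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sp_fft
from scipy.signal import fftconvolve

from .grids import ImageGrid
from .kernels import KernelBank

logger = logging.getLogger(__name__)

#: patch-SD floor (relative to image RMS) below which a patch is "flat"
_FLAT_REL_TOL = 1e-5

TAU_SCAN = np.round(np.arange(0.50, 0.951, 0.05), 10)


@dataclass
class CorrelationStack:
    """Orientation-reduced ZNCC scores.

    ``scores[i]`` holds, for bank length ``lengths_um[i]``, the best score
    over that length's orientation grid at each pixel;
    ``best_theta_idx[i]`` the index of the winning orientation in
    ``bank.orientation_grids[i]``.  Pixels closer to the border than half
    the stencil support are 0 (not evaluated)."""

    scores: np.ndarray  # (n_lengths, H, W) in [-1, 1]
    best_theta_idx: np.ndarray  # (n_lengths, H, W) int16
    lengths_um: np.ndarray
    pixel_size_um: float
    bank: KernelBank = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if np.any(self.scores > 1 + 1e-6) or np.any(self.scores < -1 - 1e-6):
            raise ValueError("ZNCC scores outside [-1, 1] tolerance")


@dataclass
class LengthMap:
    """Per-pixel maximum correlation length and detection mask.

    ``lmax_um`` is 0 where no kernel length passes the threshold; ``mask``
    lies in [0, 1] and is 0 wherever ``lmax_um`` is 0.
    """

    lmax_um: np.ndarray
    mask: np.ndarray
    tau: float
    lengths_um: np.ndarray
    pixel_size_um: float
    intensity_percentiles: tuple[float, float] = (50.0, 99.0)
    meta: dict = field(default_factory=dict)


@dataclass
class HSVRender:
    """RGB rendering of a length map (float RGB in [0, 1])."""

    rgb: np.ndarray  # (H, W, 3)
    length_range_um: tuple[float, float]

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.rgb * 255), 0, 255).astype(np.uint8)


def _flat_tol(image: np.ndarray, n_footprint: float) -> float:
    rms = float(np.sqrt(np.mean(image * image)))
    return _FLAT_REL_TOL * np.sqrt(n_footprint) * rms


def _correlate_fft(image: np.ndarray, bank: KernelBank):
    h, w = image.shape
    image_sq = image * image
    n_len = bank.n_lengths
    scores = np.zeros((n_len, h, w), dtype=np.float64)
    argmax = np.zeros((n_len, h, w), dtype=np.int16)
    for i in range(n_len):
        side = int(bank.supports_px[i])
        m = side // 2
        full = (h + side - 1, w + side - 1)
        fshape = [sp_fft.next_fast_len(n, real=True) for n in full]
        f_img = sp_fft.rfftn(image, fshape)
        f_sq = sp_fft.rfftn(image_sq, fshape)

        def conv_valid(f_src, kernel):
            fk = sp_fft.rfftn(kernel[::-1, ::-1], fshape)
            out = sp_fft.irfftn(f_src * fk, fshape)[: full[0], : full[1]]
            return out[side - 1 : h, side - 1 : w]

        best = None
        best_idx = None
        for j, st in enumerate(bank.stencils[i]):
            fp = st.footprint.astype(np.float64)
            n_fp = fp.sum()
            num = conv_valid(f_img, st.weights)
            s1 = conv_valid(f_img, fp)
            s2 = conv_valid(f_sq, fp)
            var = s2 - s1 * s1 / n_fp
            np.clip(var, 0.0, None, out=var)
            den = np.sqrt(var)
            flat = den <= _flat_tol(image, n_fp)
            sc = np.where(flat, 0.0, num / np.where(flat, 1.0, den))
            np.clip(sc, -1.0, 1.0, out=sc)
            if best is None:
                best = sc
                best_idx = np.zeros_like(sc, dtype=np.int16)
            else:
                upd = sc > best
                best[upd] = sc[upd]
                best_idx[upd] = j
        scores[i, m : h - m, m : w - m] = best
        argmax[i, m : h - m, m : w - m] = best_idx
    return scores, argmax


def _correlate_direct(image: np.ndarray, bank: KernelBank):
    """Sliding-window reference path: explicit per-window sums over the
    footprint, no FFT.  Oracle for the FFT path; quadratic in support."""
    h, w = image.shape
    image_sq = image * image
    n_len = bank.n_lengths
    scores = np.zeros((n_len, h, w), dtype=np.float64)
    argmax = np.zeros((n_len, h, w), dtype=np.int16)
    for i in range(n_len):
        side = int(bank.supports_px[i])
        m = side // 2
        windows = sliding_window_view(image, (side, side))
        windows_sq = sliding_window_view(image_sq, (side, side))
        best = None
        best_idx = None
        for j, st in enumerate(bank.stencils[i]):
            fp = st.footprint.astype(np.float64)
            n_fp = fp.sum()
            num = np.einsum("ijkl,kl->ij", windows, st.weights)
            s1 = np.einsum("ijkl,kl->ij", windows, fp)
            s2 = np.einsum("ijkl,kl->ij", windows_sq, fp)
            var = np.clip(s2 - s1 * s1 / n_fp, 0.0, None)
            den = np.sqrt(var)
            flat = den <= _flat_tol(image, n_fp)
            sc = np.where(flat, 0.0, num / np.where(flat, 1.0, den))
            np.clip(sc, -1.0, 1.0, out=sc)
            if best is None:
                best = sc
                best_idx = np.zeros_like(sc, dtype=np.int16)
            else:
                upd = sc > best
                best[upd] = sc[upd]
                best_idx[upd] = j
        scores[i, m : h - m, m : w - m] = best
        argmax[i, m : h - m, m : w - m] = best_idx
    return scores, argmax


def correlate(
    image: ImageGrid, bank: KernelBank, mode: str = "fft"
) -> CorrelationStack:
    """Match every stencil of the bank against the image.

    ``mode='fft'`` and ``mode='direct'`` agree to within 1e-6 absolute;
    the direct mode is intended for small images and verification.
    """
    if abs(bank.pixel_size_um - image.pixel_size_um) > 1e-9:
        raise ValueError("bank and image pixel sizes differ")
    if bank.max_support_px > min(image.shape):
        raise ValueError(
            f"largest stencil support ({bank.max_support_px} px) exceeds "
            f"image size {image.shape}"
        )
    # pad with the median so structures near the border can still be
    # evaluated: without this, every length L has an unevaluable margin of
    # half its support and long structures near the edge read short
    pad = bank.max_support_px // 2
    fill = float(np.median(image.intensity))
    padded = np.pad(image.intensity, pad, constant_values=fill)
    if mode == "fft":
        scores, argmax = _correlate_fft(padded, bank)
    elif mode == "direct":
        scores, argmax = _correlate_direct(padded, bank)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scores = scores[:, pad:-pad, pad:-pad]
    argmax = argmax[:, pad:-pad, pad:-pad]
    return CorrelationStack(
        scores=scores,
        best_theta_idx=argmax,
        lengths_um=bank.lengths_um.copy(),
        pixel_size_um=bank.pixel_size_um,
        bank=bank,
    )


def orientation_scores(
    image: ImageGrid, bank: KernelBank, length_index: int
) -> np.ndarray:
    """Recompute the full per-orientation score slice for one bank length,
    i.e. the ``Corr(x, y, L=const, theta)`` plane of the 4D score."""
    single = KernelBank(
        lengths_um=bank.lengths_um[length_index : length_index + 1],
        base_orientations_deg=bank.base_orientations_deg,
        orientation_grids=[bank.orientation_grids[length_index]],
        width_px=bank.width_px,
        pixel_size_um=bank.pixel_size_um,
        blur_px=bank.blur_px,
        stencils=[bank.stencils[length_index]],
        supports_px=bank.supports_px[length_index : length_index + 1],
    )
    pad = single.max_support_px // 2
    img = np.pad(
        image.intensity, pad, constant_values=float(np.median(image.intensity))
    )
    h, w = img.shape
    side = int(single.supports_px[0])
    m = side // 2
    out = np.zeros((len(single.orientation_grids[0]), h, w))
    img_sq = img * img
    full = (h + side - 1, w + side - 1)
    fshape = [sp_fft.next_fast_len(n, real=True) for n in full]
    f_img = sp_fft.rfftn(img, fshape)
    f_sq = sp_fft.rfftn(img_sq, fshape)
    for j, st in enumerate(single.stencils[0]):
        fp = st.footprint.astype(np.float64)
        n_fp = fp.sum()

        def conv_valid(f_src, kernel):
            fk = sp_fft.rfftn(kernel[::-1, ::-1], fshape)
            res = sp_fft.irfftn(f_src * fk, fshape)[: full[0], : full[1]]
            return res[side - 1 : h, side - 1 : w]

        num = conv_valid(f_img, st.weights)
        s1 = conv_valid(f_img, fp)
        s2 = conv_valid(f_sq, fp)
        den = np.sqrt(np.clip(s2 - s1 * s1 / n_fp, 0.0, None))
        flat = den <= _flat_tol(img, n_fp)
        sc = np.where(flat, 0.0, num / np.where(flat, 1.0, den))
        np.clip(sc, -1.0, 1.0, out=sc)
        out[j, m : h - m, m : w - m] = sc
    return out[:, pad:-pad, pad:-pad]


def _rescale_intensity(
    intensity: np.ndarray, percentiles: tuple[float, float]
) -> np.ndarray:
    lo, hi = np.percentile(intensity, percentiles)
    if hi <= lo:
        return np.ones_like(intensity)
    return np.clip((intensity - lo) / (hi - lo), 0.0, 1.0)


def _coverage(stack: CorrelationStack, length_index: int, tau: float) -> np.ndarray:
    """Pixels covered by at least one passing placement of this length."""
    sc = stack.scores[length_index]
    idx = stack.best_theta_idx[length_index]
    passing = sc >= tau
    covered = np.zeros_like(passing)
    if not passing.any():
        return covered
    for j in np.unique(idx[passing]):
        centres = (passing & (idx == j)).astype(np.float32)
        core = stack.bank.stencils[length_index][j].core.astype(np.float32)
        covered |= fftconvolve(centres, core, mode="same") > 0.5
    return covered


def length_map(
    stack: CorrelationStack,
    image: ImageGrid,
    tau: float,
    intensity_percentiles: tuple[float, float] = (50.0, 99.0),
    mask_mode: str = "indicator",
) -> LengthMap:
    """Extract the maximum-correlation-length map and its mask.

    ``lmax(x, y)`` is the largest bank length for which some placement
    scoring at least ``tau`` covers ``(x, y)`` (0 where none does; see the
    module docstring for why coverage, not centre-only, attribution is
    used).  The mask is the product of a detection term and the image
    intensity linearly rescaled between the background and saturation
    percentiles (defaults: median and 99th).  ``mask_mode='indicator'``
    uses a 0/1 detection term; ``'score'`` uses the pixel's best ZNCC
    score over all lengths, clipped to [0, 1].
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    if stack.scores.shape[1:] != image.shape:
        raise ValueError("stack and image shapes differ")
    if mask_mode not in ("indicator", "score"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    if stack.bank is None:
        raise ValueError("stack carries no kernel bank")

    lmax = np.zeros(image.shape, dtype=np.float64)
    for i, L in enumerate(stack.lengths_um):  # ascending: larger L wins
        covered = _coverage(stack, i, tau)
        lmax[covered] = L
    detected = lmax > 0

    if mask_mode == "indicator":
        detect = detected.astype(np.float64)
    else:
        detect = np.where(detected, np.clip(stack.scores.max(axis=0), 0, 1), 0.0)
    mask = detect * _rescale_intensity(image.intensity, intensity_percentiles)
    mask = np.where(detected, mask, 0.0)

    if not detected.any():
        warnings.warn(
            "no pixel passes the correlation threshold; length map is empty",
            stacklevel=2,
        )
    return LengthMap(
        lmax_um=lmax,
        mask=mask,
        tau=float(tau),
        lengths_um=stack.lengths_um.copy(),
        pixel_size_um=stack.pixel_size_um,
        intensity_percentiles=tuple(intensity_percentiles),
        meta={"mask_mode": mask_mode},
    )


def _modal_nonzero(values: np.ndarray) -> float:
    """Most frequent nonzero value (smallest wins ties); 0 if none."""
    nz = values[values > 0]
    if nz.size == 0:
        return 0.0
    uniq, counts = np.unique(nz, return_counts=True)
    return float(uniq[np.argmax(counts)])


def calibrate_tau(
    probe_lengths_um,
    bank: KernelBank,
    width_um: float | None = None,
    blur_sigma_um: float | None = None,
    amplitude: float = 1.0,
    probe_orientation_deg: float | None = None,
    tau_grid=TAU_SCAN,
) -> float:
    """Select the score threshold by probing noise-free single fibres.

    For each probe length a clean image containing one fibre of that
    length is synthesised, with the structure width and optical blur
    expected in the data.  The probe orientation defaults to half the
    bank's base orientation step — the worst case for orientation
    quantisation — so the selected threshold transfers to structures at
    arbitrary angles.  For each candidate ``tau`` the modal nonzero
    ``lmax`` over the fibre's own pixels is compared with the true
    length; an empty map counts as an error of the full true length.  The
    ``tau`` minimising the mean absolute error across probes is returned;
    ties break toward the smallest ``tau``.
    """
    from .synthetic import render_probe_fibre  # deferred: avoid cycle

    probe_lengths_um = np.asarray(probe_lengths_um, dtype=np.float64)
    if probe_lengths_um.size == 0:
        raise ValueError("probe set must not be empty")
    if width_um is None:
        width_um = bank.width_px * bank.pixel_size_um
    if blur_sigma_um is None:
        blur_sigma_um = bank.blur_px * bank.pixel_size_um
    if probe_orientation_deg is None:
        base = bank.base_orientations_deg
        step = float(base[1] - base[0]) if base.size > 1 else 0.0
        probe_orientation_deg = step / 2.0

    errors = np.zeros(len(tau_grid), dtype=np.float64)
    for true_len in probe_lengths_um:
        img, on_fibre = render_probe_fibre(
            true_len,
            bank.pixel_size_um,
            width_um=width_um,
            amplitude=amplitude,
            blur_sigma_um=blur_sigma_um,
            orientation_deg=probe_orientation_deg,
            margin_px=bank.max_support_px // 2 + 2,
        )
        stack = correlate(img, bank)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty maps handled as error
            for k, tau in enumerate(tau_grid):
                lm = length_map(stack, img, float(tau))
                modal = _modal_nonzero(lm.lmax_um[on_fibre])
                errors[k] += abs(modal - true_len)
    errors /= probe_lengths_um.size
    best = int(np.argmin(errors))  # argmin returns first index: smallest tau
    tau = float(tau_grid[best])
    logger.info(
        "calibrated tau=%.2f (mean modal-length error %.2f um)",
        tau,
        errors[best],
    )
    return tau


def render_hsv(
    lmap: LengthMap, length_range_um: tuple[float, float]
) -> HSVRender:
    """Colour-code the length map in HSV.

    Hue encodes ``lmax`` linearly from blue (240 deg) at the range minimum
    to red (0 deg) at the maximum (clipped), saturation is 1 everywhere,
    and the value channel is the mask, so masked-out pixels are black.
    """
    from matplotlib.colors import hsv_to_rgb

    lo, hi = length_range_um
    if not lo < hi:
        raise ValueError("length_range_um must satisfy min < max")
    frac = np.clip((lmap.lmax_um - lo) / (hi - lo), 0.0, 1.0)
    hue = (240.0 * (1.0 - frac)) / 360.0
    hsv = np.stack([hue, np.ones_like(hue), lmap.mask], axis=-1)
    rgb = hsv_to_rgb(hsv)
    rgb[lmap.mask <= 0] = 0.0
    return HSVRender(rgb=rgb, length_range_um=(float(lo), float(hi)))
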