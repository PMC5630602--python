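"""Summary statistics over length maps, condition comparisons, qPCR utility.

The correlation-length map of an image is reduced to a weighted empirical
distribution over the kernel-length grid; from it come the cumulative
distribution and the threshold fractions used for reporting (fraction of
fibre signal below 25 um; fraction of cord signal above 300 um).
Conditions are compared by unpaired two-sided t-tests with the usual
star convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .filament import LengthMap

#: reporting conventions for the two assay families
FIBRE_THRESHOLD_UM = 25.0
CORD_THRESHOLD_UM = 300.0

STAR_CUTPOINTS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class LengthDistribution:
    """Weighted empirical distribution of correlation lengths.

    ``support_um`` is ascending; ``weights`` are pixel counts (uniform
    weighting) or mask sums (mask weighting).
    """

    support_um: np.ndarray
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support_um = np.asarray(self.support_um, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.support_um.shape != self.weights.shape:
            raise ValueError("support and weights must align")
        if np.any(np.diff(self.support_um) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.total_weight <= 0:
            raise ValueError("distribution has zero total weight")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def cdf(self, x: float) -> float:
        """Right-continuous CDF: weight of support <= x over total."""
        return float(self.weights[self.support_um <= x].sum() / self.total_weight)

    def cdf_curve(self) -> tuple[np.ndarray, np.ndarray]:
        return self.support_um, np.cumsum(self.weights) / self.total_weight

    def pooled_with(self, other: "LengthDistribution") -> "LengthDistribution":
        """Weight-sum of two distributions (pooling images)."""
        support = np.union1d(self.support_um, other.support_um)
        weights = np.zeros_like(support)
        for dist in (self, other):
            idx = np.searchsorted(support, dist.support_um)
            weights[idx] += dist.weights
        return LengthDistribution(support, weights, provenance={"pooled": True})


def length_distribution(
    lmap: LengthMap, weighting: str = "uniform"
) -> LengthDistribution:
    """Distribution of the nonzero correlation lengths of a map.

    ``weighting='uniform'`` counts pixels; ``'mask'`` sums the mask values,
    down-weighting dim detections.  Raises on an all-zero map.
    """
    if weighting not in ("uniform", "mask"):
        raise ValueError(f"unknown weighting {weighting!r}")
    nz = lmap.lmax_um > 0
    if not nz.any():
        raise ValueError("no filamentous signal: the length map is all zero")
    support = []
    weights = []
    for L in lmap.lengths_um:
        sel = lmap.lmax_um == L
        if not sel.any():
            continue
        support.append(L)
        weights.append(
            float(sel.sum()) if weighting == "uniform" else float(lmap.mask[sel].sum())
        )
    return LengthDistribution(
        np.asarray(support),
        np.asarray(weights),
        provenance={
            "tau": lmap.tau,
            "weighting": weighting,
            "lengths_um": [float(x) for x in lmap.lengths_um],
        },
    )


def fraction_below(dist: LengthDistribution, threshold_um: float) -> float:
    """Weight fraction of lengths strictly below the threshold."""
    return float(
        dist.weights[dist.support_um < threshold_um].sum() / dist.total_weight
    )


def fraction_above(dist: LengthDistribution, threshold_um: float) -> float:
    """Weight fraction of lengths strictly above the threshold."""
    return float(
        dist.weights[dist.support_um > threshold_um].sum() / dist.total_weight
    )


# --------------------------------------------------------------------------
# condition comparison


@dataclass(frozen=True)
class ComparisonResult:
    """Unpaired two-sided t-test between two samples of per-image or
    per-cell values, with the star significance convention."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    stars: str
    equal_var: bool = True


def stars_for_p(p: float) -> str:
    for cut, mark in STAR_CUTPOINTS:
        if p < cut:
            return mark
    return "ns"


def compare_conditions(
    sample_a, sample_b, equal_var: bool = True
) -> ComparisonResult:
    """Two-sided unpaired t-test (Student by default, Welch optional)."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    # identical samples: scipy returns NaN (zero pooled variance); by
    # convention report no difference
    if np.isnan(t):
        t, p = 0.0, 1.0
    return ComparisonResult(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        t_statistic=float(t),
        p_value=float(p),
        stars=stars_for_p(float(p)),
        equal_var=equal_var,
    )


# --------------------------------------------------------------------------
# qPCR relative quantification


@dataclass(frozen=True)
class QPCRMeasurement:
    """Ct values of a target and a reference gene in a condition and in
    its control."""

    ct_target: float
    ct_reference: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        vals = (
            self.ct_target,
            self.ct_reference,
            self.ct_target_control,
            self.ct_reference_control,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("Ct values must be finite")


def ddct_fold_change(m: QPCRMeasurement) -> dict:
    """Relative quantification by the ddCt method.

    dCt = Ct_target - Ct_reference per condition; ddCt is the condition
    dCt minus the control dCt; the fold change over control is
    ``RQ = 2 ** -ddCt`` (1 when condition equals control).
    """
    dct = m.ct_target - m.ct_reference
    dct_control = m.ct_target_control - m.ct_reference_control
    ddct = dct - dct_control
    return {
        "delta_ct": float(dct),
        "delta_ct_control": float(dct_control),
        "delta_delta_ct": float(ddct),
        "fold_change": float(2.0 ** (-ddct)),
    }
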