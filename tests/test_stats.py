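"""Length distributions, threshold fractions, t-tests, ddCt."""

import numpy as np
import pytest

from filaquant.filament import LengthMap
from filaquant.stats import (
    LengthDistribution,
    QPCRMeasurement,
    compare_conditions,
    ddct_fold_change,
    fraction_above,
    fraction_below,
    length_distribution,
    stars_for_p,
)


def _map_from_counts(counts: dict, mask_value=1.0) -> LengthMap:
    """Small synthetic length map with the given {length: n_pixels}."""
    values = []
    for length, n in counts.items():
        values.extend([length] * n)
    side = int(np.ceil(np.sqrt(len(values))))
    arr = np.zeros(side * side)
    arr[: len(values)] = values
    lmax = arr.reshape(side, side)
    mask = (lmax > 0) * mask_value
    return LengthMap(
        lmax_um=lmax, mask=mask, tau=0.8,
        lengths_um=np.array(sorted(set(counts))), pixel_size_um=1.0,
    )


def test_distribution_counts_pixels_and_cdf():
    lmap = _map_from_counts({10.0: 30, 50.0: 70})
    dist = length_distribution(lmap)
    assert dist.cdf(10.0) == pytest.approx(0.30)
    assert dist.cdf(50.0) == pytest.approx(1.0)
    assert dist.total_weight == 100


def test_mask_weighting_with_unit_mask_equals_uniform():
    lmap = _map_from_counts({10.0: 12, 30.0: 8})
    a = length_distribution(lmap, weighting="uniform")
    b = length_distribution(lmap, weighting="mask")
    np.testing.assert_allclose(a.weights, b.weights)


def test_all_zero_map_raises():
    lmap = LengthMap(lmax_um=np.zeros((8, 8)), mask=np.zeros((8, 8)),
                     tau=0.8, lengths_um=np.array([10.0]), pixel_size_um=1.0)
    with pytest.raises(ValueError, match="no filamentous signal"):
        length_distribution(lmap)


def test_cdf_non_decreasing_terminal_one():
    dist = LengthDistribution(np.array([10.0, 20.0, 40.0]),
                              np.array([5.0, 0.0, 3.0]))
    support, cdf = dist.cdf_curve()
    assert np.all(np.diff(cdf) >= 0)
    assert cdf[-1] == pytest.approx(1.0)
    assert dist.cdf(np.inf) == pytest.approx(1.0)


def test_threshold_fractions_partition():
    dist = LengthDistribution(np.array([10.0, 25.0, 40.0]),
                              np.array([2.0, 3.0, 5.0]))
    below = fraction_below(dist, 25.0)
    above = fraction_above(dist, 25.0)
    at = 3.0 / 10.0
    assert below == pytest.approx(0.2)
    assert above == pytest.approx(0.5)
    assert below + above + at == pytest.approx(1.0)
    # extremes
    assert fraction_below(dist, 5.0) == 0.0
    assert fraction_above(dist, 100.0) == 0.0
    assert fraction_below(dist, 100.0) == 1.0


def test_fraction_monotone_in_threshold():
    dist = LengthDistribution(np.array([10.0, 20.0, 30.0]),
                              np.array([1.0, 2.0, 3.0]))
    thresholds = [5.0, 15.0, 25.0, 35.0]
    belows = [fraction_below(dist, t) for t in thresholds]
    aboves = [fraction_above(dist, t) for t in thresholds]
    assert belows == sorted(belows)
    assert aboves == sorted(aboves, reverse=True)


def test_pooling_adds_weights():
    a = LengthDistribution(np.array([10.0, 20.0]), np.array([3.0, 1.0]))
    b = LengthDistribution(np.array([20.0, 40.0]), np.array([2.0, 4.0]))
    pooled = a.pooled_with(b)
    np.testing.assert_allclose(pooled.support_um, [10.0, 20.0, 40.0])
    np.testing.assert_allclose(pooled.weights, [3.0, 3.0, 4.0])


def test_invalid_distributions_rejected():
    with pytest.raises(ValueError):
        LengthDistribution(np.array([10.0, 5.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        LengthDistribution(np.array([10.0]), np.array([-1.0]))
    with pytest.raises(ValueError):
        LengthDistribution(np.array([10.0]), np.array([0.0]))


# --------------------------------------------------------------------------
# condition comparison


def test_identical_samples_not_significant():
    res = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t_statistic == 0.0
    assert res.p_value == pytest.approx(1.0)
    assert res.stars == "ns"


def test_large_shift_reaches_three_stars():
    res = compare_conditions([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
    assert res.p_value < 1e-3
    assert res.stars == "***"


def test_t_statistic_matches_textbook_formula():
    """Pooled-variance two-sample t on two printed triples, against the
    hand formula t = (ma - mb) / (sp * sqrt(1/na + 1/nb))."""
    a = np.array([4.0, 5.0, 6.0])
    b = np.array([1.0, 3.0, 2.0])
    res = compare_conditions(a, b)
    sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
    expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert res.t_statistic == pytest.approx(expected, abs=1e-9)


def test_star_convention_cutpoints():
    assert stars_for_p(0.2) == "ns"
    assert stars_for_p(0.05) == "ns"  # strict inequality at the cutpoint
    assert stars_for_p(0.04) == "*"
    assert stars_for_p(0.004) == "**"
    assert stars_for_p(0.0004) == "***"


def test_small_samples_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        compare_conditions([1.0], [1.0, 2.0])


def test_welch_flag_reported():
    res = compare_conditions([1.0, 2.0, 3.0], [2.0, 4.0, 9.0],
                             equal_var=False)
    assert res.equal_var is False
    assert 0 <= res.p_value <= 1


# --------------------------------------------------------------------------
# qPCR fold change


def test_control_equals_condition_gives_unit_fold_change():
    m = QPCRMeasurement(20.0, 15.0, 20.0, 15.0)
    out = ddct_fold_change(m)
    assert out["delta_delta_ct"] == 0.0
    assert out["fold_change"] == pytest.approx(1.0)


def test_one_cycle_earlier_doubles_expression():
    # ddCt = -1 <=> RQ = 2
    m = QPCRMeasurement(19.0, 15.0, 20.0, 15.0)
    assert ddct_fold_change(m)["fold_change"] == pytest.approx(2.0)


def test_worked_example_rq_four():
    """Target/reference Ct (20, 15) vs control (22, 15):
    dCt = 5, control dCt = 7, ddCt = -2, RQ = 4."""
    m = QPCRMeasurement(20.0, 15.0, 22.0, 15.0)
    out = ddct_fold_change(m)
    assert out["delta_ct"] == 5.0
    assert out["delta_ct_control"] == 7.0
    assert out["fold_change"] == pytest.approx(4.0)


def test_non_finite_ct_rejected():
    with pytest.raises(ValueError, match="finite"):
        QPCRMeasurement(np.nan, 15.0, 20.0, 15.0)


# --------------------------------------------------------------------------
# property-based invariants


from hypothesis import given, settings
from hypothesis import strategies as hst


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    weights=hst.lists(
        hst.floats(0.01, 1e4, allow_nan=False), min_size=1, max_size=8
    ),
    threshold=hst.floats(0.0, 120.0),
)
def test_fraction_partition_and_cdf_properties(weights, threshold):
    """For any weighted distribution: below + at + above = 1, the CDF is
    non-decreasing and ends at 1."""
    support = 10.0 * np.arange(1, len(weights) + 1)
    dist = LengthDistribution(support, np.array(weights))
    below = fraction_below(dist, threshold)
    above = fraction_above(dist, threshold)
    at = dist.weights[dist.support_um == threshold].sum() / dist.total_weight
    assert below + above + at == pytest.approx(1.0)
    _, cdf = dist.cdf_curve()
    assert np.all(np.diff(cdf) >= -1e-12)
    assert cdf[-1] == pytest.approx(1.0)
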