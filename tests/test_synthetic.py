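"""Ground-truth generators: determinism, truth conservation, kinetics."""

import numpy as np
import pytest

from filaquant import synthetic as syn
from filaquant.motility import directional_autocorrelation


# --------------------------------------------------------------------------
# fibre fields


def test_identical_seed_reproduces_field_bit_exactly():
    spec = syn.FibreFieldSpec(shape_px=(128, 128), n_segments=10, seed=3)
    a_img, a_truth, a_label = syn.generate_fibre_field(spec)
    b_img, b_truth, b_label = syn.generate_fibre_field(spec)
    np.testing.assert_array_equal(a_img.intensity, b_img.intensity)
    np.testing.assert_array_equal(a_label, b_label)
    assert a_truth == b_truth


def test_zero_segments_gives_background_and_empty_truth():
    spec = syn.FibreFieldSpec(shape_px=(64, 64), n_segments=0,
                              noise_sigma=5.0, seed=0)
    img, truth, label = syn.generate_fibre_field(spec)
    assert truth == []
    assert not label.any()
    assert img.intensity.mean() == pytest.approx(spec.background, rel=0.05)


def test_single_horizontal_segment_labels_a_stripe():
    """50 um fibre at 0.5 um/px: the label stripe is 100 px long and
    carries the value 50."""
    spec = syn.FibreFieldSpec(
        shape_px=(128, 256), pixel_size_um=0.5, n_segments=1,
        length_sampler=syn.fixed(50.0), orientation_sampler=syn.fixed(0.0),
        blur_sigma_um=0.0, noise_sigma=0.0, seed=1,
    )
    img, truth, label = syn.generate_fibre_field(spec)
    assert len(truth) == 1
    assert set(np.unique(label)) == {0.0, 50.0}
    rows, cols = np.nonzero(label)
    # capsule rendering: the rounded end caps add half a width per end
    width_px = spec.width_um / spec.pixel_size_um
    assert cols.max() - cols.min() + 1 == pytest.approx(100 + width_px, abs=2)
    # noise-free: the intensity maximum sits on the fibre
    peak = np.unravel_index(np.argmax(img.intensity), img.shape)
    assert label[peak] == 50.0


def test_truth_entries_match_rendered_segments(fibre_mixture):
    spec, image, truth, label = fibre_mixture
    assert len(truth) == spec.n_segments
    for t in truth:
        assert t.length_um in (15.0, 60.0)
        assert 0 <= t.orientation_deg < 180
    assert set(np.unique(label)) <= {0.0, 15.0, 60.0}
    assert (label > 0).sum() > 0


def test_oversized_segment_rejected():
    spec = syn.FibreFieldSpec(
        shape_px=(64, 64), pixel_size_um=0.5, n_segments=1,
        length_sampler=syn.fixed(500.0), seed=0,
    )
    with pytest.raises(ValueError, match="exceeds|fit"):
        syn.generate_fibre_field(spec)


def test_label_fraction_counting(fibre_mixture):
    _, _, _, label = fibre_mixture
    below = syn.label_fraction_below(label, 25.0)
    above = syn.label_fraction_above(label, 25.0)
    assert below + above == pytest.approx(1.0)  # no mass exactly at 25
    on = label > 0
    assert below == pytest.approx(np.mean(label[on] == 15.0))


# --------------------------------------------------------------------------
# cord networks


def test_single_straight_cord_truth():
    spec = syn.CordNetworkSpec(n_cords=1, length_sampler=syn.fixed(400.0),
                               turn_sigma_rad=0.0, seed=3)
    img, truth, label = syn.generate_cord_network(spec)
    assert len(truth) == 1
    assert truth[0].length_um == pytest.approx(400.0)
    assert img.modality == "phase_contrast"
    # polyline segment lengths sum to the total
    v = np.array(truth[0].vertices_um[0])
    seg_sum = np.linalg.norm(np.diff(v, axis=0), axis=1).sum()
    assert seg_sum == pytest.approx(400.0)


def test_unbranched_cords_are_single_polylines(cord_mixture):
    spec, _, truth, label = cord_mixture
    assert len(truth) == spec.n_cords
    for t in truth:
        assert len(t.vertices_um) == 1
        assert t.length_um in (150.0, 450.0)
    assert set(np.unique(label)) <= {0.0, 150.0, 450.0}


def test_branching_adds_length_and_polylines():
    spec = syn.CordNetworkSpec(n_cords=5, length_sampler=syn.fixed(300.0),
                               branch_prob=0.8, seed=11)
    _, truth, _ = syn.generate_cord_network(spec)
    assert any(len(t.vertices_um) > 1 for t in truth)
    for t in truth:
        total = 0.0
        for poly in t.vertices_um:
            v = np.array(poly)
            total += np.linalg.norm(np.diff(v, axis=0), axis=1).sum()
        assert t.length_um == pytest.approx(total)


def test_cord_network_deterministic():
    spec = syn.CordNetworkSpec(n_cords=5, seed=21)
    a = syn.generate_cord_network(spec)
    b = syn.generate_cord_network(spec)
    np.testing.assert_array_equal(a[0].intensity, b[0].intensity)
    assert a[1] == b[1]


def test_clearance_keeps_cords_separated():
    spec = syn.CordNetworkSpec(shape_px=(512, 512), n_cords=6,
                               length_sampler=syn.fixed(200.0),
                               turn_sigma_rad=0.0, min_clearance_um=30.0,
                               seed=2)
    _, truth, label = syn.generate_cord_network(spec)
    # every cord contributed its own labelled pixels
    assert set(np.unique(label)) == {0.0, 200.0}
    assert (label > 0).sum() >= 6 * 50  # each cord leaves a visible core


# --------------------------------------------------------------------------
# persistent random walks


def test_zero_turning_gives_exact_straight_lines():
    p = syn.PRWParams(n_tracks=4, n_frames=25, mean_speed_um_h=20.0,
                      turn_sigma_rad=0.0, seed=9)
    ts = syn.generate_tracks(p)
    for tid in ts.track_ids:
        xy = ts.positions(tid)
        steps = np.diff(xy, axis=0)
        # all steps identical: straight line at constant speed
        np.testing.assert_allclose(
            steps, np.broadcast_to(steps[0], steps.shape), atol=1e-9
        )
        path = np.linalg.norm(steps, axis=1).sum()
        duration_h = (p.n_frames - 1) * p.frame_interval_s / 3600.0
        assert path == pytest.approx(p.mean_speed_um_h * duration_h)


def test_isotropic_turning_decorrelates_directions():
    p = syn.PRWParams(n_tracks=200, n_frames=40, turn_sigma_rad=np.pi,
                      seed=10)
    ts = syn.generate_tracks(p)
    acs = []
    for tid in ts.track_ids:
        _, ac = directional_autocorrelation(ts.positions(tid), max_lag=1)
        acs.append(ac[0])
    assert abs(np.mean(acs)) < 0.05


def test_tangent_autocorrelation_matches_gaussian_theory():
    """Independent Gaussian turns of SD sigma give autocorrelation
    exp(-k sigma^2 / 2) at step lag k."""
    sigma = 0.5
    p = syn.PRWParams(n_tracks=500, n_frames=61, turn_sigma_rad=sigma,
                      seed=12)
    ts = syn.generate_tracks(p)
    per_lag = {k: [] for k in range(1, 6)}
    for tid in ts.track_ids:
        _, ac = directional_autocorrelation(ts.positions(tid), max_lag=5)
        for k in range(5):
            per_lag[k + 1].append(ac[k])
    for k, vals in per_lag.items():
        theory = np.exp(-k * sigma**2 / 2.0)
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - theory) < 3 * sem


def test_track_table_layout_and_determinism():
    p = syn.PRWParams(n_tracks=3, n_frames=5, seed=4)
    a = syn.generate_tracks(p)
    b = syn.generate_tracks(p)
    assert list(a.table.columns) == ["track_id", "frame", "t_s", "x_um", "y_um"]
    assert a.table.equals(b.table)
    assert a.frame_interval_s == 300.0  # 5-min frames


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_tracks": 0},
        {"n_frames": 2},
        {"frame_interval_s": 0.0},
        {"turn_sigma_rad": -0.1},
    ],
)
def test_invalid_prw_params_rejected(kwargs):
    with pytest.raises(ValueError):
        syn.PRWParams(**kwargs)
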