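"""Trajectory analysis: windows, speed, autocorrelation, persistence."""

import numpy as np
import pandas as pd
import pytest

from filaquant import synthetic as syn
from filaquant.motility import (
    TrackSet,
    directional_autocorrelation,
    ensemble_autocorrelation,
    persistence_length,
    persistence_length_from_curve,
    summarize,
    track_speed,
    translate_to_origin,
    window_filter,
)


def _track(xy, frame_interval_s=300.0, track_id=0, t0_s=0.0):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": np.arange(n),
            "t_s": t0_s + np.arange(n) * frame_interval_s,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
        }
    )


@pytest.fixture(scope="module")
def prw_500():
    params = syn.PRWParams(n_tracks=500, n_frames=61, mean_speed_um_h=20.0,
                           turn_sigma_rad=0.5, seed=42)
    return params, syn.generate_tracks(params)


# --------------------------------------------------------------------------
# windowing and origin translation


def test_window_covering_everything_is_identity(prw_500):
    _, tracks = prw_500
    out = window_filter(tracks, 0.0, 10.0)
    assert out.table.equals(tracks.table)


def test_five_to_ten_hour_window_keeps_61_frames():
    """0-16 h at 5-min frames: [5, 10] h retains 61 positions."""
    n = 16 * 12 + 1
    xy = np.zeros((n, 2))
    tracks = TrackSet(_track(xy), frame_interval_s=300.0)
    out = window_filter(tracks, 5.0, 10.0)
    assert len(out.table) == 61


def test_empty_window_raises_with_counts():
    tracks = TrackSet(_track(np.zeros((5, 2))), frame_interval_s=300.0)
    with pytest.raises(ValueError, match="retained 0"):
        window_filter(tracks, 10.0, 12.0)


def test_window_then_summarise_equals_pretrimmed(prw_500):
    _, tracks = prw_500
    windowed = window_filter(tracks, 1.0, 4.0)
    direct = summarize(windowed)
    pre = TrackSet(windowed.table.copy(), frame_interval_s=300.0)
    again = summarize(pre)
    np.testing.assert_allclose(direct.speeds_um_h, again.speeds_um_h)


def test_translate_to_origin_preserves_steps(prw_500):
    _, tracks = prw_500
    out = translate_to_origin(tracks)
    for tid in list(tracks.track_ids)[:10]:
        a = tracks.positions(tid)
        b = out.positions(tid)
        np.testing.assert_allclose(b[0], [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.diff(a, axis=0), np.diff(b, axis=0))


def test_straight_track_ends_at_its_path_length_from_origin():
    xy = np.column_stack([np.linspace(50, 150, 11), np.full(11, 30.0)])
    tracks = TrackSet(_track(xy), frame_interval_s=300.0)
    out = translate_to_origin(tracks)
    end = out.positions(0)[-1]
    assert np.linalg.norm(end) == pytest.approx(100.0)


# --------------------------------------------------------------------------
# speed


def test_stationary_track_speed_zero():
    with pytest.raises(ValueError, match="timestamps"):
        track_speed(np.zeros((3, 2)), np.array([0.0, 0.0, 300.0]))
    assert track_speed(np.zeros((3, 2)), np.array([0.0, 300.0, 600.0])) == 0.0


def test_ten_microns_per_five_minutes_is_120_per_hour():
    xy = np.column_stack([np.arange(5) * 10.0, np.zeros(5)])
    t = np.arange(5) * 300.0
    assert track_speed(xy, t) == pytest.approx(120.0)


def test_speed_invariant_under_rigid_motion():
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, 100, (20, 2))
    t = np.arange(20) * 300.0
    base = track_speed(xy, t)
    ang = 0.7
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    moved = xy @ rot.T + [55.0, -12.0]
    assert track_speed(moved, t) == pytest.approx(base)


def test_nominal_speed_recovered_within_two_percent(prw_500):
    params, tracks = prw_500
    speeds = [track_speed(tracks.positions(t), tracks.times(t))
              for t in tracks.track_ids]
    assert np.mean(speeds) == pytest.approx(params.mean_speed_um_h, rel=0.02)


# --------------------------------------------------------------------------
# directional autocorrelation and persistence length


def test_straight_track_fully_persistent():
    xy = np.column_stack([np.arange(10) * 5.0, np.zeros(10)])
    lag, ac = directional_autocorrelation(xy)
    np.testing.assert_allclose(ac, 1.0)
    assert persistence_length(xy) == np.inf


def test_zigzag_alternates_between_zero_and_one():
    steps = [(1, 0), (0, 1)] * 8
    xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
    _, ac = directional_autocorrelation(xy, max_lag=2)
    assert ac[0] == pytest.approx(0.0, abs=1e-12)
    assert ac[1] == pytest.approx(1.0)


def test_zero_length_steps_skipped():
    xy = np.array([[0, 0], [1, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
    _, ac = directional_autocorrelation(xy, max_lag=1)
    assert ac[0] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="zero length"):
        directional_autocorrelation(np.zeros((4, 2)))


def test_persistence_length_recovers_theory(prw_500):
    """xi = 2 d / sigma^2 for Gaussian turning; recovery within 15%."""
    params, tracks = prw_500
    lag, ac, _ = ensemble_autocorrelation(tracks, max_lag=15)
    xi = persistence_length_from_curve(lag, ac)
    theory = params.theoretical_persistence_um
    assert xi == pytest.approx(theory, rel=0.15)


def test_doubling_step_length_doubles_persistence():
    common = dict(n_tracks=300, n_frames=61, turn_sigma_rad=0.5, seed=77)
    slow = syn.generate_tracks(syn.PRWParams(mean_speed_um_h=20.0, **common))
    fast = syn.generate_tracks(syn.PRWParams(mean_speed_um_h=40.0, **common))
    xi = []
    for ts in (slow, fast):
        lag, ac, _ = ensemble_autocorrelation(ts, max_lag=15)
        xi.append(persistence_length_from_curve(lag, ac))
    assert xi[1] / xi[0] == pytest.approx(2.0, rel=0.1)


def test_unusable_curve_reports_missing():
    lag = np.array([1.0, 2.0, 3.0])
    assert np.isnan(persistence_length_from_curve(lag,
                                                  np.array([0.1, 0.05, 0.01])))


# --------------------------------------------------------------------------
# summaries


def test_two_track_summary_hand_numbers():
    a = np.column_stack([np.arange(4) * 100 / 12.0, np.zeros(4)])  # 100 um/h
    b = np.column_stack([np.arange(4) * 140 / 12.0, np.zeros(4)])  # 140 um/h
    table = pd.concat([_track(a, track_id=0), _track(b, track_id=1)])
    stats = summarize(TrackSet(table, frame_interval_s=300.0))
    assert stats.n_tracks == 2
    assert stats.speed_mean == pytest.approx(120.0)
    assert stats.speed_sd == pytest.approx(28.284, abs=1e-3)
    assert stats.speed_sem == pytest.approx(20.0)


def test_summary_warns_below_hundred_cells(caplog):
    p = syn.PRWParams(n_tracks=5, n_frames=10, seed=0)
    with caplog.at_level("WARNING"):
        summarize(syn.generate_tracks(p))
    assert any("100" in rec.message for rec in caplog.records)


def test_frames_must_increase():
    bad = _track(np.zeros((4, 2)))
    bad.loc[2, "frame"] = 1
    with pytest.raises(ValueError, match="strictly increasing"):
        TrackSet(bad, frame_interval_s=300.0)
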