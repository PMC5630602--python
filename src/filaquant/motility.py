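"""Cell-trajectory analysis: speed, directional persistence, summaries.

Trajectories are consumed as tables exported by tracking software (one row
per cell per frame) and summarised per track by mean speed (um/h) and by a
persistence length (um), defined here as the contour-length decay constant
of the tangent-direction autocorrelation: for step lag ``k`` the mean of
``cos`` of the angle between step ``i`` and step ``i+k`` is computed,
plotted against contour lag ``k * <step length>``, and the negative inverse
slope of a log-linear fit gives the persistence length.  For a walk with
independent Gaussian heading increments of standard deviation ``sigma`` and
step ``d`` the autocorrelation is ``exp(-k sigma^2 / 2)``, hence the
persistence length is ``2 d / sigma^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]

#: tracks retained for analysis need at least this many positions
MIN_TRACK_POINTS = 3

#: study convention: warn when fewer cells than this are summarised
MIN_CELLS_EXPECTED = 100

#: autocorrelation values at or below this are excluded from the log fit
AUTOCORR_FIT_CUTOFF = 0.2


@dataclass
class TrackSet:
    """Time-stamped 2D trajectories for one experimental condition."""

    table: pd.DataFrame  # columns TRACK_COLUMNS
    frame_interval_s: float
    condition: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        self.table = (
            self.table[TRACK_COLUMNS]
            .sort_values(["track_id", "frame"])
            .reset_index(drop=True)
        )
        for tid, grp in self.table.groupby("track_id", sort=False):
            frames = grp["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise ValueError(f"track {tid}: frames not strictly increasing")

    @property
    def track_ids(self) -> list:
        return list(dict.fromkeys(self.table["track_id"]))

    @property
    def n_tracks(self) -> int:
        return self.table["track_id"].nunique()

    def positions(self, track_id) -> np.ndarray:
        grp = self.table[self.table["track_id"] == track_id]
        return grp[["x_um", "y_um"]].to_numpy(dtype=np.float64)

    def times(self, track_id) -> np.ndarray:
        grp = self.table[self.table["track_id"] == track_id]
        return grp["t_s"].to_numpy(dtype=np.float64)


@dataclass
class MotilityStats:
    """Per-condition motility summary (means are across tracks)."""

    condition: str
    n_tracks: int
    speeds_um_h: np.ndarray
    persistence_lengths_um: np.ndarray  # NaN where not measurable
    speed_mean: float
    speed_sd: float
    speed_sem: float
    persistence_mean: float
    persistence_sd: float
    persistence_sem: float
    ensemble_persistence_um: float  # fit on the track-averaged curve
    per_track: pd.DataFrame = field(repr=False, default=None)


def read_tracks_csv(
    path,
    frame_interval_s: float,
    condition: str = "",
    column_map: dict[str, str] | None = None,
) -> TrackSet:
    """Read a track table (``track_id,frame,t_s,x_um,y_um``).

    ``column_map`` maps our column names to the file's, to accommodate
    tracking-software export dialects, e.g. ``{"x_um": "Position X"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return TrackSet(df, frame_interval_s=frame_interval_s, condition=condition)


def write_tracks_csv(tracks: TrackSet, path) -> None:
    tracks.table.to_csv(path, index=False)


def window_filter(tracks: TrackSet, t_start_h: float, t_end_h: float) -> TrackSet:
    """Restrict to the analysis time window ``[t_start_h, t_end_h]`` hours.

    Tracks left with fewer than 3 positions are dropped.  Raises if the
    window empties the data set.
    """
    if not t_start_h < t_end_h:
        raise ValueError("t_start must be earlier than t_end")
    t = tracks.table["t_s"] / 3600.0
    kept = tracks.table[(t >= t_start_h) & (t <= t_end_h)]
    counts = kept.groupby("track_id")["frame"].size()
    good = counts[counts >= MIN_TRACK_POINTS].index
    dropped = tracks.n_tracks - len(good)
    out = kept[kept["track_id"].isin(good)].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"time window [{t_start_h}, {t_end_h}] h retained 0 of "
            f"{tracks.n_tracks} tracks (dropped {dropped})"
        )
    if dropped:
        logger.info("window_filter dropped %d short tracks", dropped)
    return replace(tracks, table=out)


def translate_to_origin(tracks: TrackSet) -> TrackSet:
    """Map each track's first retained position to (0, 0) — the classic
    'tracings from origin' overlay.  Step vectors are unchanged."""
    df = tracks.table.copy()
    firsts = df.groupby("track_id")[["x_um", "y_um"]].transform("first")
    df[["x_um", "y_um"]] = df[["x_um", "y_um"]] - firsts
    return replace(tracks, table=df)


def _steps(xy: np.ndarray) -> np.ndarray:
    return np.diff(xy, axis=0)


def track_speed(xy: np.ndarray, t_s: np.ndarray) -> float:
    """Mean instantaneous speed in um/h over consecutive steps."""
    if len(xy) < 2:
        raise ValueError("speed needs at least 2 positions")
    dt = np.diff(t_s)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    disp = np.linalg.norm(_steps(xy), axis=1)
    return float(np.mean(disp / dt) * 3600.0)


def directional_autocorrelation(
    xy: np.ndarray, max_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Tangent autocorrelation of one track.

    Returns ``(contour_lag_um, mean_cos)`` for step lags 1..max_lag, where
    the contour lag of step lag ``k`` is ``k`` times the track's mean step
    length.  Zero-length steps carry no direction and are skipped.
    """
    if len(xy) < MIN_TRACK_POINTS:
        raise ValueError("autocorrelation needs at least 3 positions")
    steps = _steps(xy)
    lengths = np.linalg.norm(steps, axis=1)
    keep = lengths > 0
    if not keep.any():
        raise ValueError("all steps have zero length")
    units = steps[keep] / lengths[keep, None]
    mean_step = float(lengths[keep].mean())
    n = len(units)
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    if max_lag < 1:
        raise ValueError("track too short for any lag")
    lags = np.arange(1, max_lag + 1)
    ac = np.array(
        [float(np.einsum("ij,ij->i", units[:-k], units[k:]).mean()) for k in lags]
    )
    return lags * mean_step, ac


def ensemble_autocorrelation(
    tracks: TrackSet, max_lag: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Track-averaged tangent autocorrelation.

    Returns ``(contour_lag_um, mean_cos, sem)`` where the contour lag uses
    the ensemble mean step length and each lag averages the per-track
    values across tracks that reach it.
    """
    per_lag: list[list[float]] = [[] for _ in range(max_lag)]
    step_lengths = []
    for tid in tracks.track_ids:
        xy = tracks.positions(tid)
        if len(xy) < MIN_TRACK_POINTS:
            continue
        steps = _steps(xy)
        ln = np.linalg.norm(steps, axis=1)
        if not (ln > 0).any():
            continue
        step_lengths.append(ln[ln > 0].mean())
        try:
            _, ac = directional_autocorrelation(xy, max_lag=max_lag)
        except ValueError:
            continue
        for k, v in enumerate(ac):
            per_lag[k].append(v)
    if not step_lengths:
        raise ValueError("no usable tracks for autocorrelation")
    mean_step = float(np.mean(step_lengths))
    lags, means, sems = [], [], []
    for k, vals in enumerate(per_lag, start=1):
        if vals:
            lags.append(k * mean_step)
            means.append(float(np.mean(vals)))
            sems.append(float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan)
    return np.array(lags), np.array(means), np.array(sems)


def persistence_length_from_curve(
    contour_lag_um: np.ndarray, autocorr: np.ndarray
) -> float:
    """Persistence length from a tangent-autocorrelation curve.

    Least-squares slope of ``ln(autocorr)`` against contour lag over the
    lags with autocorrelation above the fit cutoff; the persistence length
    is ``-1/slope``.  Returns NaN when fewer than 2 usable lags remain, and
    +inf for a non-decaying (straight-track) curve.
    """
    use = autocorr > AUTOCORR_FIT_CUTOFF
    if use.sum() < 2:
        return float("nan")
    x = contour_lag_um[use]
    y = np.log(autocorr[use])
    slope = np.polyfit(x, y, 1)[0]
    if slope >= 0:
        return float("inf")
    return float(-1.0 / slope)


def persistence_length(xy: np.ndarray, max_lag: int | None = 20) -> float:
    """Persistence length of a single track (um); NaN if not measurable."""
    try:
        lag_um, ac = directional_autocorrelation(xy, max_lag=max_lag)
    except ValueError:
        return float("nan")
    return persistence_length_from_curve(lag_um, ac)


def summarize(tracks: TrackSet, max_lag: int = 20) -> MotilityStats:
    """Per-track speed and persistence length plus condition summary.

    Tracks shorter than 3 positions are skipped.  Logs a warning when the
    retained count falls below the study convention of 100 cells.
    """
    rows = []
    for tid in tracks.track_ids:
        xy = tracks.positions(tid)
        if len(xy) < MIN_TRACK_POINTS:
            continue
        t = tracks.times(tid)
        rows.append(
            {
                "track_id": tid,
                "n_points": len(xy),
                "speed_um_h": track_speed(xy, t),
                "persistence_um": persistence_length(xy, max_lag=max_lag),
            }
        )
    if not rows:
        raise ValueError("no track with >= 3 positions to summarise")
    per_track = pd.DataFrame(rows)
    n = len(per_track)
    if n < MIN_CELLS_EXPECTED:
        logger.warning(
            "only %d tracks summarised (study convention expects >= %d)",
            n,
            MIN_CELLS_EXPECTED,
        )
    speeds = per_track["speed_um_h"].to_numpy()
    pers = per_track["persistence_um"].to_numpy()
    finite = pers[np.isfinite(pers)]
    lag_um, ac, _ = ensemble_autocorrelation(tracks, max_lag=max_lag)
    xi_ens = persistence_length_from_curve(lag_um, ac)

    def _sd(a):
        return float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    return MotilityStats(
        condition=tracks.condition,
        n_tracks=n,
        speeds_um_h=speeds,
        persistence_lengths_um=pers,
        speed_mean=float(speeds.mean()),
        speed_sd=_sd(speeds),
        speed_sem=_sd(speeds) / np.sqrt(n),
        persistence_mean=float(finite.mean()) if finite.size else float("nan"),
        persistence_sd=_sd(finite) if finite.size else float("nan"),
        persistence_sem=(
            _sd(finite) / np.sqrt(len(finite)) if finite.size else float("nan")
        ),
        ensemble_persistence_um=xi_ens,
        per_track=per_track,
    )
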