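"""Per-cell speed and dispersion analysis for tracked cells.

Consumes trajectories produced by an external tracker (e.g. ImageJ
ADAPT exports) and computes, per cell, the mean speed as total path
length over elapsed time; per condition, the mean speed with a 95%
t-interval; and dispersion maps — all trajectories translated to a
common origin to visualize the motility spread of a population.

"Distance traveled" is the total path length (sum of step lengths), not
the net displacement; a separately named net-displacement speed is also
provided. The denominator is the elapsed time between a track's first
and last observation, which tolerates dropped frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from motilitykit.errors import InputError, InsufficientDataError

__all__ = [
    "CellTrack",
    "SpeedSummary",
    "DispersionMap",
    "track_mean_speed",
    "track_net_speed",
    "build_dispersion_map",
    "summarize_condition",
    "filter_tracks",
]


@dataclass(frozen=True)
class CellTrack:
    """Timestamped positions of one tracked cell.

    Times in hours (strictly increasing), positions in pixels;
    ``pixel_size`` converts to micrometers.
    """

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.float64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise InputError(f"track {self.track_id}: t, x, y must be equal-length 1-D")
        if t.size == 0:
            raise InputError(f"track {self.track_id}: empty track")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InputError(
                f"track {self.track_id}: timestamps must be strictly increasing"
            )
        if self.pixel_size <= 0:
            raise InputError(f"track {self.track_id}: pixel_size must be > 0")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_points(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class SpeedSummary:
    """Group mean speed with a two-sided 95% t-interval (um/h)."""

    per_track_speed: np.ndarray
    group_mean: float
    ci95_low: float
    ci95_high: float
    n_tracks: int


@dataclass(frozen=True)
class DispersionMap:
    """Tracks translated to a common origin; step vectors preserved."""

    track_ids: list[str]
    offsets: list[np.ndarray]  # per track, (n, 2) with row 0 == (0, 0)


def _steps(track: CellTrack) -> np.ndarray:
    return np.column_stack([np.diff(track.x), np.diff(track.y)])


def track_mean_speed(track: CellTrack) -> float:
    """Mean speed in um/h: path length x pixel_size over elapsed time."""
    if track.n_points < 2:
        raise InsufficientDataError(
            f"track {track.track_id}: need >= 2 points for a speed"
        )
    path_px = float(np.hypot(np.diff(track.x), np.diff(track.y)).sum())
    elapsed = float(track.t[-1] - track.t[0])
    return path_px * track.pixel_size / elapsed


def track_net_speed(track: CellTrack) -> float:
    """Net-displacement speed in um/h (straight-line start-to-end)."""
    if track.n_points < 2:
        raise InsufficientDataError(
            f"track {track.track_id}: need >= 2 points for a speed"
        )
    net_px = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    return net_px * track.pixel_size / float(track.t[-1] - track.t[0])


def build_dispersion_map(tracks: list[CellTrack]) -> DispersionMap:
    """Translate every track so its first point sits at the origin."""
    if not tracks:
        raise InputError("empty track collection")
    offsets = [
        np.column_stack([tr.x - tr.x[0], tr.y - tr.y[0]]) for tr in tracks
    ]
    return DispersionMap(track_ids=[tr.track_id for tr in tracks], offsets=offsets)


def filter_tracks(
    tracks: list[CellTrack], min_points: int = 3
) -> tuple[list[CellTrack], int]:
    """Drop tracks shorter than ``min_points``; return (kept, n_excluded)."""
    kept = [tr for tr in tracks if tr.n_points >= min_points]
    return kept, len(tracks) - len(kept)


def summarize_condition(speeds: "np.ndarray | list[float]") -> SpeedSummary:
    """Mean and two-sided 95% t-interval of per-track speeds.

    Interval: mean +/- t(0.975, n-1) * sd / sqrt(n), sample SD with the
    N-1 denominator. Identical speeds give a zero-width interval.
    """
    speeds = np.asarray(speeds, dtype=np.float64)
    n = speeds.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 speeds, got {n}")
    mean = float(speeds.mean())
    sem = float(speeds.std(ddof=1) / np.sqrt(n))
    half = float(sps.t.ppf(0.975, n - 1)) * sem
    return SpeedSummary(
        per_track_speed=speeds,
        group_mean=mean,
        ci95_low=mean - half,
        ci95_high=mean + half,
        n_tracks=n,
    )
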