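"""Movement-path processing: deployment window, steps/turns, gap masking.

Locations arrive regularized to a 1-h grid (the continuous-time random
walk regularization itself is upstream of this package; synthetic tracks
are generated on the grid directly).  This module truncates each series to
the analysis window (24 h post-handling to 30 days post-release), derives
step lengths and turning angles, masks intervals estimated across raw-fix
gaps longer than 3 h, and samples the distance-to-shore raster at each
location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from allomove.raster import AsciiRaster

__all__ = [
    "LocationSeries",
    "truncate_deployment",
    "steps_and_turns",
    "gap_mask",
    "apply_gap_mask",
    "distance_to_shore",
    "wrap_angle",
]

HANDLING_EXCLUSION = pd.Timedelta(hours=24)
DEPLOYMENT_WINDOW = pd.Timedelta(days=30)
MAX_RAW_GAP = pd.Timedelta(hours=3)

_EARTH_RADIUS_M = 6_371_000.0


@dataclass
class LocationSeries:
    """Hourly regularized locations for one individual.

    ``frame`` is "planar" (x, y in metres) or "geographic" (x = longitude,
    y = latitude, degrees).  ``raw_fix_times`` are the original
    observation instants, needed for gap masking.
    """

    id: str
    timestamps: pd.DatetimeIndex
    x: np.ndarray
    y: np.ndarray
    frame: str = "planar"
    raw_fix_times: pd.DatetimeIndex | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if not (len(self.timestamps) == len(self.x) == len(self.y)):
            raise ValueError("timestamps, x and y must have equal lengths")
        if self.frame not in ("planar", "geographic"):
            raise ValueError("frame must be 'planar' or 'geographic'")
        if len(self.timestamps) >= 2:
            dt = np.diff(self.timestamps.asi8)
            if (dt <= 0).any():
                raise ValueError("timestamps must be strictly increasing")
            if not (dt == dt[0]).all() or dt[0] != 3_600_000_000_000:
                raise ValueError("timestamps must be on a 1-h grid")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.id, "timestamp": self.timestamps, "x": self.x, "y": self.y}
        )


def truncate_deployment(
    series: LocationSeries, release_time: pd.Timestamp
) -> LocationSeries:
    """Keep locations in (release + 24 h, release + 30 d].

    The first day removes short-term capture-related behaviour; the 30-day
    cap restricts the analysis to the summering period.  Boundaries apply
    to timestamps, never to positional indices.
    """
    release_time = pd.Timestamp(release_time)
    if len(series) and release_time > series.timestamps[0]:
        raise ValueError("release_time must not postdate the first location")
    lo = release_time + HANDLING_EXCLUSION
    hi = release_time + DEPLOYMENT_WINDOW
    keep = (series.timestamps > lo) & (series.timestamps <= hi)
    if not keep.any():
        import logging

        logging.getLogger(__name__).warning(
            "series %s: no locations in the analysis window", series.id
        )
    return LocationSeries(
        id=series.id,
        timestamps=series.timestamps[keep],
        x=series.x[keep],
        y=series.y[keep],
        frame=series.frame,
        raw_fix_times=series.raw_fix_times,
    )


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]; a half-turn maps to +pi, not -pi."""
    w = -(np.mod(-np.asarray(a, dtype=float) + np.pi, 2.0 * np.pi) - np.pi)
    return w


def _headings_planar(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx, dy = np.diff(x), np.diff(y)
    h = np.arctan2(dy, dx)
    h[(dx == 0) & (dy == 0)] = np.nan  # duplicate fix: heading undefined
    return h


def _haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlat, dlon = p2 - p1, np.radians(lon2) - np.radians(lon1)
    a = np.sin(dlat / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlon / 2) ** 2
    return 2.0 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def _bearing(lon1, lat1, lon2, lat2) -> np.ndarray:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlon = np.radians(lon2) - np.radians(lon1)
    return np.arctan2(
        np.sin(dlon) * np.cos(p2),
        np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlon),
    )


def steps_and_turns(series: LocationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Step lengths (m) and turning angles (radians) along the track.

    Both arrays align with ``series.timestamps``: ``step[t]`` is the
    distance from location t to t+1 (NaN at the final point) and
    ``turn[t]`` the signed heading change at vertex t, wrapped to
    (-pi, pi] with a full reversal mapping to +pi (NaN at the first and
    final points, and wherever a duplicate fix leaves a heading
    undefined).
    """
    T = len(series)
    step = np.full(T, np.nan)
    turn = np.full(T, np.nan)
    if T < 2:
        return step, turn
    if series.frame == "planar":
        step[:-1] = np.hypot(np.diff(series.x), np.diff(series.y))
        head = _headings_planar(series.x, series.y)
    else:
        step[:-1] = _haversine_m(
            series.x[:-1], series.y[:-1], series.x[1:], series.y[1:]
        )
        head = _bearing(series.x[:-1], series.y[:-1], series.x[1:], series.y[1:])
        head[step[:-1] == 0] = np.nan
    if T >= 3:
        turn[1:-1] = wrap_angle(head[1:] - head[:-1])
    return step, turn


def gap_mask(
    timestamps: pd.DatetimeIndex,
    raw_fix_times: pd.DatetimeIndex,
    max_gap: pd.Timedelta = MAX_RAW_GAP,
) -> np.ndarray:
    """Boolean mask over hourly intervals lying inside raw-fix gaps > max_gap.

    The interval from ``timestamps[t]`` to ``timestamps[t] + 1 h`` is
    masked iff both endpoints fall strictly inside a gap between
    consecutive raw fixes exceeding ``max_gap`` — such steps and turns are
    pure interpolation artefacts, not observed movement.
    """
    timestamps = pd.DatetimeIndex(timestamps)
    raw = pd.DatetimeIndex(raw_fix_times).sort_values()
    T = len(timestamps)
    mask = np.zeros(T, dtype=bool)
    if len(raw) < 2 or T == 0:
        return mask
    starts = timestamps.asi8
    ends = starts + 3_600_000_000_000
    gap_lo = raw.asi8[:-1]
    gap_hi = raw.asi8[1:]
    big = (gap_hi - gap_lo) > max_gap.value
    for lo, hi in zip(gap_lo[big], gap_hi[big]):
        mask |= (starts > lo) & (ends < hi)
    return mask


def apply_gap_mask(
    step: np.ndarray, turn: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """NaN-out steps in masked intervals and turns at their vertices.

    ``turn[t]`` depends on the headings of intervals t-1 and t, so it is
    removed when either interval is masked.  Dive and shore streams are
    untouched by gap masking (they do not derive from the interpolated
    path).
    """
    step = np.asarray(step, dtype=float).copy()
    turn = np.asarray(turn, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    step[mask] = np.nan
    vertex = mask.copy()
    vertex[1:] |= mask[:-1]
    turn[vertex] = np.nan
    return step, turn


def distance_to_shore(raster: AsciiRaster, x, y) -> np.ndarray:
    """Distance to shore (km) at track locations by bilinear interpolation."""
    return raster.interpolate(x, y)
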