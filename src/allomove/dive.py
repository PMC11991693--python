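"""Time-depth-recorder processing: drift correction, dive detection, metrics.

The depth sensor samples every 75 s and its zero point drifts slowly, so
surface readings wander away from 0 m.  The pipeline is:

1. zero-offset correction — a rolling low-quantile estimate of the
   surface reading is smoothed and subtracted;
2. dive detection — maximal excursions exceeding the 10-m threshold
   (shallower excursions count as surface behaviour and are discarded);
3. per-dive metrics — maximum depth, and "wiggles": the summed absolute
   depth changes over the bottom phase (samples deeper than a fixed
   fraction of the dive's maximum), a proxy for foraging effort at depth;
4. hourly aggregation onto the location grid — max of dive maxima and
   sum of wiggles per hour, missing when no dive started in the hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DepthSeries",
    "DiveRecord",
    "zero_offset_correct",
    "detect_dives",
    "dive_metrics",
    "aggregate_hourly",
]

DEFAULT_SAMPLING_S = 75.0
DEFAULT_DIVE_THRESHOLD_M = 10.0
DEFAULT_BOTTOM_FRACTION = 0.8
DEFAULT_ZOC_WINDOW_S = 7200.0
DEFAULT_ZOC_QUANTILE = 0.05


@dataclass
class DepthSeries:
    """Regularly sampled depth (m, positive down) at 75-s cadence."""

    times_s: np.ndarray  # seconds since deployment start
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.times_s.shape != self.depth.shape or self.times_s.ndim != 1:
            raise ValueError("times and depths must be 1-D arrays of equal length")
        if len(self.times_s) >= 2:
            dt = np.diff(self.times_s)
            if not np.allclose(dt, dt[0]):
                raise ValueError("sampling interval must be constant")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depths must be finite")

    @property
    def sampling_interval(self) -> float:
        return float(self.times_s[1] - self.times_s[0]) if len(self.times_s) > 1 else np.nan

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times_s, "depth_m": self.depth}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "DepthSeries":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["depth_m"].to_numpy())


@dataclass
class DiveRecord:
    """One detected dive with its bottom-phase metrics."""

    start_s: float
    end_s: float
    max_depth: float
    wiggles: float
    bottom_start_s: float
    bottom_end_s: float

    def __post_init__(self) -> None:
        if self.wiggles < 0:
            raise ValueError("wiggles must be non-negative")
        if not (self.start_s <= self.bottom_start_s <= self.bottom_end_s <= self.end_s):
            raise ValueError("bottom phase must lie within the dive")


def zero_offset_correct(
    series: DepthSeries,
    window_s: float = DEFAULT_ZOC_WINDOW_S,
    quantile: float = DEFAULT_ZOC_QUANTILE,
) -> DepthSeries:
    """Remove slow sensor drift by subtracting a rolling surface estimate.

    The surface offset is the rolling ``quantile`` (default 5th
    percentile) of depth over a centred ``window_s`` (default 2 h) window,
    median-smoothed in a second pass.  Corrected depths are clipped at 0.
    A window longer than the record degrades to a single global offset.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    depth = pd.Series(series.depth)
    dt = series.sampling_interval
    n = len(depth)
    w = max(int(round(window_s / dt)), 2) if np.isfinite(dt) else n
    if w >= n:
        offset = np.full(n, float(np.quantile(series.depth, quantile)))
    else:
        first = depth.rolling(w, center=True, min_periods=1).quantile(quantile)
        offset = first.rolling(w, center=True, min_periods=1).median().to_numpy()
    corrected = np.clip(series.depth - offset, 0.0, None)
    return DepthSeries(series.times_s.copy(), corrected)


def dive_metrics(
    depth: np.ndarray, bottom_fraction: float = DEFAULT_BOTTOM_FRACTION
) -> tuple[float, float, int, int]:
    """Maximum depth and bottom-phase wiggles for one dive's samples.

    The bottom phase is the contiguous run of samples at depth >=
    ``bottom_fraction`` x maximum that contains the deepest sample;
    wiggles is the sum of absolute depth changes over that run (0 when the
    run is shorter than two samples).  Returns (max_depth, wiggles,
    bottom_start_index, bottom_end_index).
    """
    depth = np.asarray(depth, dtype=float)
    if len(depth) < 3:
        raise ValueError("a dive needs at least 3 samples")
    imax = int(np.argmax(depth))
    max_depth = float(depth[imax])
    deep = depth >= bottom_fraction * max_depth
    lo = imax
    while lo > 0 and deep[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(depth) - 1 and deep[hi + 1]:
        hi += 1
    wiggles = float(np.abs(np.diff(depth[lo : hi + 1])).sum()) if hi > lo else 0.0
    return max_depth, wiggles, lo, hi


def detect_dives(
    series: DepthSeries,
    threshold_m: float = DEFAULT_DIVE_THRESHOLD_M,
    bottom_fraction: float = DEFAULT_BOTTOM_FRACTION,
) -> list[DiveRecord]:
    """Segment a (zero-offset-corrected) series into dives.

    A dive is a maximal contiguous excursion with depth strictly greater
    than ``threshold_m``; excursions never exceeding the threshold are
    surface behaviour and are discarded.  Excursions of fewer than 3
    samples are too short to score and are also discarded.
    """
    deep = series.depth > threshold_m
    if not deep.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], deep.view(np.int8), [0]])))
    dives = []
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < 3:
            continue
        seg = series.depth[start:stop]
        max_depth, wiggles, lo, hi = dive_metrics(seg, bottom_fraction)
        dives.append(
            DiveRecord(
                start_s=float(series.times_s[start]),
                end_s=float(series.times_s[stop - 1]),
                max_depth=max_depth,
                wiggles=wiggles,
                bottom_start_s=float(series.times_s[start + lo]),
                bottom_end_s=float(series.times_s[start + hi]),
            )
        )
    return dives


def aggregate_hourly(
    dives: list[DiveRecord], n_hours: int, origin_s: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Hourly (max depth, summed wiggles) streams from the dive records.

    A dive belongs to the hour containing its start time.  Hours with no
    dive get NaN in both streams (the model treats them as missing).
    """
    max_depth = np.full(n_hours, np.nan)
    wiggles = np.full(n_hours, np.nan)
    for d in dives:
        h = int((d.start_s - origin_s) // 3600.0)
        if not 0 <= h < n_hours:
            continue
        if np.isnan(max_depth[h]):
            max_depth[h] = d.max_depth
            wiggles[h] = d.wiggles
        else:
            max_depth[h] = max(max_depth[h], d.max_depth)
            wiggles[h] += d.wiggles
    return max_depth, wiggles


def dives_to_frame(dives: list[DiveRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": d.start_s,
                "end_s": d.end_s,
                "max_depth_m": d.max_depth,
                "wiggles_m": d.wiggles,
                "bottom_start_s": d.bottom_start_s,
                "bottom_end_s": d.bottom_end_s,
            }
            for d in dives
        ]
    )
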