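"""Per-individual multistream observation series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from allomove.hmm.params import STREAMS

__all__ = ["ObservationSeries"]

_POSITIVE_STREAMS = ("step", "max_depth", "wiggles", "dist_shore")


@dataclass
class ObservationSeries:
    """Hourly multistream record for one individual, with its covariate.

    Streams are float arrays aligned on ``timestamps``; ``NaN`` marks a
    missing value.  Steps and turns come from consecutive regularized
    locations, maximum depth (m) and wiggles (m) from the dive record of
    the hour, distance to shore (km) from the raster at the location.
    ``csi`` is the individual's composite stress index, the model
    covariate.
    """

    id: str
    csi: float
    step: np.ndarray
    turn: np.ndarray
    max_depth: np.ndarray
    wiggles: np.ndarray
    dist_shore: np.ndarray
    timestamps: pd.DatetimeIndex | None = None
    states: np.ndarray | None = field(default=None, repr=False)  # simulation truth

    def __post_init__(self) -> None:
        lengths = {s: len(getattr(self, s)) for s in STREAMS}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"stream lengths differ: {lengths}")
        for s in STREAMS:
            setattr(self, s, np.asarray(getattr(self, s), dtype=float))
        for s in _POSITIVE_STREAMS:
            v = getattr(self, s)
            if np.any(v[np.isfinite(v)] < 0):
                raise ValueError(f"stream {s} must be positive where observed")
        turn = self.turn[np.isfinite(self.turn)]
        if turn.size and (turn.min() <= -np.pi - 1e-9 or turn.max() > np.pi + 1e-9):
            raise ValueError("turning angles must lie in (-pi, pi]")

    def __len__(self) -> int:
        return len(self.step)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({s: getattr(self, s) for s in STREAMS})
        df.insert(0, "id", self.id)
        df.insert(1, "csi", self.csi)
        if self.timestamps is not None:
            df.insert(2, "timestamp", self.timestamps)
        if self.states is not None:
            df["state"] = self.states
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservationSeries":
        ids = df["id"].unique()
        if len(ids) != 1:
            raise ValueError("frame holds more than one individual")
        ts = None
        if "timestamp" in df.columns:
            ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        states = df["state"].to_numpy(dtype=int) if "state" in df.columns else None
        return cls(
            id=str(ids[0]),
            csi=float(df["csi"].iloc[0]),
            timestamps=ts,
            states=states,
            **{s: df[s].to_numpy(dtype=float) for s in STREAMS},
        )

    @staticmethod
    def list_to_csv(series: list["ObservationSeries"], path) -> None:
        pd.concat([s.to_frame() for s in series]).to_csv(path, index=False)

    @staticmethod
    def list_from_csv(path) -> list["ObservationSeries"]:
        df = pd.read_csv(path)
        return [
            ObservationSeries.from_frame(g) for _, g in df.groupby("id", sort=True)
        ]
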