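"""Shared in-memory containers for recordings and detected events.

A :class:`RecordingSegment` is the canonical wide-band signal container:
channels x samples in microvolts with a sampling rate, mirroring the flat
binary + JSON-sidecar on-disk layout. An :class:`EventSet` holds detected
LFP events (ripples, dentate spikes) as a tidy table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RecordingSegment", "EventSet"]


@dataclass
class RecordingSegment:
    """Channels x samples extracellular signal in microvolts.

    Parameters
    ----------
    data:
        2D float array, shape ``(n_channels, n_samples)``, in uV.
    sampling_rate:
        Samples per second per channel (Hz).
    channel_ids:
        Integer channel ids matching a probe map; defaults to 0..n-1.
    """

    data: np.ndarray
    sampling_rate: float
    channel_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.data.shape[0])
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.channel_ids.shape[0] != self.data.shape[0]:
            raise ValueError("channel_ids length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, channel_id: int) -> int:
        """Row index of *channel_id* in ``data``."""
        idx = np.flatnonzero(self.channel_ids == channel_id)
        if idx.size == 0:
            raise KeyError(f"channel id {channel_id} not in segment")
        return int(idx[0])

    def trace(self, channel_id: int) -> np.ndarray:
        """The 1D signal (uV) of one channel."""
        return self.data[self.channel_index(channel_id)]


_EVENT_COLUMNS = ["start_s", "peak_s", "end_s", "score"]


@dataclass
class EventSet:
    """Detected event intervals of a single class (ripple, dentate spike...).

    ``events`` is a DataFrame with columns start_s, peak_s, end_s, score,
    sorted by start time, non-overlapping within the class.
    """

    events: pd.DataFrame
    label: str = "event"

    def __post_init__(self) -> None:
        ev = pd.DataFrame(self.events, columns=_EVENT_COLUMNS if len(self.events) == 0 else None)
        for col in _EVENT_COLUMNS:
            if col not in ev.columns:
                raise ValueError(f"EventSet missing column {col!r}")
        ev = ev[_EVENT_COLUMNS].reset_index(drop=True)
        if len(ev):
            if not ((ev.start_s <= ev.peak_s) & (ev.peak_s <= ev.end_s)).all():
                raise ValueError("events must satisfy start <= peak <= end")
            if not ev.start_s.is_monotonic_increasing:
                raise ValueError("events must be sorted by start time")
            if (ev.start_s.values[1:] < ev.end_s.values[:-1]).any():
                raise ValueError("events within a class must not overlap")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peak_times(self) -> np.ndarray:
        return self.events.peak_s.to_numpy()

    def to_csv(self, path: str | Path) -> None:
        out = self.events.copy()
        out["class"] = self.label
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventSet":
        df = pd.read_csv(path)
        label = str(df["class"].iloc[0]) if "class" in df.columns and len(df) else "event"
        return cls(df[_EVENT_COLUMNS], label=label)

    def to_json(self, path: str | Path) -> None:
        payload = {"label": self.label, "events": self.events.to_dict(orient="records")}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EventSet":
        payload = json.loads(Path(path).read_text())
        df = pd.DataFrame(payload["events"], columns=_EVENT_COLUMNS)
        return cls(df, label=payload.get("label", "event"))
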