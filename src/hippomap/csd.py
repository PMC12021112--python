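"""Event-triggered LFP averages and 1D current source density maps.

CSD is the negative second spatial difference of the laminar potential
profile along one electrode column, CSD(i) = -(V(i-1) - 2 V(i) + V(i+1)) / h^2,
in arbitrary units proportional to uV/um^2 (tissue conductivity is treated
as constant and omitted). Sinks — inward transmembrane current — are
negative. Edge rows are handled by duplicating the boundary potentials
(Vaknin padding) so the output spans every row of the column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .core import RecordingSegment
from .probe_geometry import ProbeMap

__all__ = ["TriggeredAverage", "CSDMap", "event_triggered_average", "compute_csd"]

logger = logging.getLogger("hippomap")


@dataclass
class TriggeredAverage:
    """Mean LFP snippet per channel around event times."""

    data: np.ndarray  # channels x lags, uV
    lags_ms: np.ndarray
    channel_ids: np.ndarray
    n_events: int

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("lags_ms", data=self.lags_ms)
            f.create_dataset("channel_ids", data=self.channel_ids)
            f.attrs["n_events"] = self.n_events

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TriggeredAverage":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][:],
                lags_ms=f["lags_ms"][:],
                channel_ids=f["channel_ids"][:],
                n_events=int(f.attrs["n_events"]),
            )


@dataclass
class CSDMap:
    """Per-row CSD over lags for one electrode column (sinks negative)."""

    data: np.ndarray  # rows x lags, a.u. ~ uV/um^2
    lags_ms: np.ndarray
    rows: np.ndarray  # lattice row index per output row
    y_um: np.ndarray  # depth of each row
    shank: int
    column: int

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("lags_ms", data=self.lags_ms)
            f.create_dataset("rows", data=self.rows)
            f.create_dataset("y_um", data=self.y_um)
            f.attrs["shank"] = self.shank
            f.attrs["column"] = self.column


def event_triggered_average(
    segment: RecordingSegment,
    event_times: np.ndarray,
    window_ms: tuple[float, float],
    channel_ids: np.ndarray | None = None,
) -> TriggeredAverage:
    """Arithmetic mean of aligned snippets around *event_times*.

    Events whose padded window leaves the recording are dropped (a count
    is logged). The lag axis is symmetric about zero when the window is.
    """
    fs = segment.sampling_rate
    if channel_ids is None:
        channel_ids = segment.channel_ids
    ch_idx = np.array([segment.channel_index(c) for c in channel_ids])
    i0 = int(round(window_ms[0] / 1000 * fs))
    i1 = int(round(window_ms[1] / 1000 * fs))
    if i1 <= i0:
        raise ValueError("window must have positive length")
    centers = np.round(np.asarray(event_times, dtype=float) * fs).astype(np.int64)
    ok = (centers + i0 >= 0) & (centers + i1 < segment.n_samples)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("event_triggered_average: dropped %d event(s) at the edges", dropped)
    centers = centers[ok]
    if centers.size == 0:
        raise ValueError("no usable events inside the recording")
    lags = np.arange(i0, i1 + 1)
    acc = np.zeros((len(ch_idx), len(lags)), dtype=np.float64)
    sub = segment.data[ch_idx]
    for c in centers:
        acc += sub[:, c + i0 : c + i1 + 1]
    acc /= len(centers)
    return TriggeredAverage(
        data=acc,
        lags_ms=lags / fs * 1000.0,
        channel_ids=np.asarray(channel_ids, dtype=int),
        n_events=int(len(centers)),
    )


def compute_csd(
    avg: TriggeredAverage,
    probe: ProbeMap,
    shank: int,
    column: int,
    smooth: bool = False,
) -> CSDMap:
    """1D CSD of one column of one shank from a triggered average.

    ``smooth`` applies a 3-point Hamming kernel across depth before
    differencing (off by default).
    """
    col_ids = probe.column_channels(shank, column)
    missing = [c for c in col_ids if c not in set(avg.channel_ids.tolist())]
    if missing:
        raise ValueError(f"triggered average lacks channels {missing} of the column")
    order = {c: i for i, c in enumerate(avg.channel_ids.tolist())}
    idx = [order[c] for c in col_ids]
    v = np.asarray(avg.data[idx], dtype=np.float64)  # rows (top->tip) x lags
    ys = np.array([probe.channel(c).y for c in col_ids], dtype=float)
    pitches = np.diff(ys)
    if not np.allclose(pitches, pitches[0]):
        raise ValueError("selected column has non-uniform vertical pitch")
    h = float(pitches[0])
    if smooth:
        k = np.hamming(3)
        k /= k.sum()
        v = np.apply_along_axis(lambda col: np.convolve(col, k, mode="same"), 0, v)
    padded = np.vstack([v[0], v, v[-1]])  # Vaknin padding
    csd = -(padded[:-2] - 2 * padded[1:-1] + padded[2:]) / h**2
    rows = np.array([probe.channel(c).row for c in col_ids], dtype=int)
    return CSDMap(
        data=csd, lags_ms=avg.lags_ms.copy(), rows=rows, y_um=ys,
        shank=int(shank), column=int(column),
    )
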