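"""Single-unit characterisation from waveforms and spike trains.

Cell types follow a cascade on two statistics: waveform trough-to-peak
latency on the peak channel, and the rise time (tau_rise) of a triple-
exponential fit to the spike autocorrelogram. Narrow interneuron:
trough-to-peak < 0.425 ms; wide interneuron: >= 0.425 ms with ACG rise
time > 6 ms; everything else (including failed ACG fits) is pyramidal.
Bursts are maximal runs of spikes with inter-spike intervals < 9 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import RecordingSegment
from .probe_geometry import ProbeMap

__all__ = [
    "UnitFootprint",
    "CellTypeLabel",
    "AcgFit",
    "compute_footprint",
    "trough_to_peak",
    "autocorrelogram",
    "fit_acg_triple_exponential",
    "classify_cell_type",
    "detect_bursts",
    "burst_fraction",
    "estimate_soma_channel",
    "peri_event_histogram",
]

NARROW_T2P_MS = 0.425
WIDE_ACG_RISE_MS = 6.0
BURST_ISI_MS = 9.0


@dataclass
class UnitFootprint:
    """Per-unit mean waveform across channels plus its spike train."""

    unit_id: int
    waveform: np.ndarray  # channels x samples, uV
    channel_ids: np.ndarray
    sampling_rate: float
    trough_sample: int  # sample index of the soma trough within the window
    spike_times: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def peak_channel(self) -> int:
        """Channel id maximising peak-to-peak amplitude (tie: lowest id)."""
        ptp = self.waveform.max(axis=1) - self.waveform.min(axis=1)
        if np.all(ptp == 0):
            raise ValueError(f"unit {self.unit_id}: all-zero footprint")
        best = ptp.max()
        candidates = self.channel_ids[np.isclose(ptp, best)]
        return int(candidates.min())

    def channel_waveform(self, channel_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.channel_ids == channel_id)
        if idx.size == 0:
            raise KeyError(f"channel {channel_id} not in footprint")
        return self.waveform[int(idx[0])]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("waveform", data=self.waveform)
            f.create_dataset("channel_ids", data=self.channel_ids)
            f.create_dataset("spike_times", data=self.spike_times)
            f.attrs["unit_id"] = self.unit_id
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["trough_sample"] = self.trough_sample

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "UnitFootprint":
        with h5py.File(path, "r") as f:
            return cls(
                unit_id=int(f.attrs["unit_id"]),
                waveform=f["waveform"][:],
                channel_ids=f["channel_ids"][:],
                sampling_rate=float(f.attrs["sampling_rate"]),
                trough_sample=int(f.attrs["trough_sample"]),
                spike_times=f["spike_times"][:],
            )


@dataclass
class CellTypeLabel:
    label: str  # narrow_interneuron | wide_interneuron | pyramidal
    trough_to_peak_ms: float
    acg_rise_ms: float
    burst_fraction: float = np.nan


@dataclass
class AcgFit:
    lags_ms: np.ndarray
    counts: np.ndarray
    tau_rise: float  # ms; NaN if the fit failed
    tau_decay: float
    tau_burst: float
    amplitude: float
    rise_coeff: float  # weight of the rise exponential within the fit
    burst_amplitude: float
    refractory_ms: float
    asymptote: float
    converged: bool

    def curve(self, lags_ms: np.ndarray | None = None) -> np.ndarray:
        t = self.lags_ms if lags_ms is None else lags_ms
        return _acg_model(
            t, self.tau_decay, self.tau_rise, self.amplitude, self.rise_coeff,
            self.burst_amplitude, self.tau_burst, self.asymptote, self.refractory_ms,
        )


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def compute_footprint(
    segment: RecordingSegment,
    spike_times: np.ndarray,
    unit_id: int = 0,
    window_ms: tuple[float, float] = (-1.0, 2.0),
    channel_ids: np.ndarray | None = None,
) -> UnitFootprint:
    """Spike-triggered mean waveform across channels.

    The default window spans 1 ms before to 2 ms after the trough-aligned
    spike time.
    """
    fs = segment.sampling_rate
    if channel_ids is None:
        channel_ids = segment.channel_ids
    ch_idx = np.array([segment.channel_index(c) for c in channel_ids])
    i0 = int(round(window_ms[0] / 1000 * fs))
    i1 = int(round(window_ms[1] / 1000 * fs))
    centers = np.round(np.asarray(spike_times, dtype=float) * fs).astype(np.int64)
    centers = centers[(centers + i0 >= 0) & (centers + i1 < segment.n_samples)]
    if centers.size == 0:
        raise ValueError("no spikes with a full window inside the recording")
    acc = np.zeros((len(ch_idx), i1 - i0 + 1), dtype=np.float64)
    sub = segment.data[ch_idx]
    for c in centers:
        acc += sub[:, c + i0 : c + i1 + 1]
    acc /= len(centers)
    return UnitFootprint(
        unit_id=unit_id,
        waveform=acc,
        channel_ids=np.asarray(channel_ids, dtype=int),
        sampling_rate=fs,
        trough_sample=-i0,
        spike_times=np.asarray(spike_times, dtype=float),
    )


def trough_to_peak(footprint: UnitFootprint) -> float:
    """Trough-to-peak latency (ms) on the peak channel.

    Time from the waveform minimum to the subsequent maximum. Raises if
    the trough sits at the window end (no post-trough peak).
    """
    w = footprint.channel_waveform(footprint.peak_channel)
    trough = int(np.argmin(w))
    if trough >= len(w) - 1:
        raise ValueError("no post-trough maximum inside the waveform window")
    peak = trough + 1 + int(np.argmax(w[trough + 1 :]))
    return (peak - trough) / footprint.sampling_rate * 1000.0


def estimate_soma_channel(
    footprint: UnitFootprint, probe: ProbeMap
) -> tuple[int, tuple[float, float]]:
    """Soma channel (max peak-to-peak amplitude) and its (x, y) position."""
    ch = footprint.peak_channel
    return ch, probe.position(ch)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def detect_bursts(spike_times: np.ndarray, max_isi_ms: float = BURST_ISI_MS) -> list[np.ndarray]:
    """Maximal runs of >= 2 spikes with consecutive ISIs < *max_isi_ms*.

    Returns spike-index arrays, one per burst. Input must be sorted.
    """
    t = np.asarray(spike_times, dtype=float)
    if len(t) and np.any(np.diff(t) < 0):
        raise ValueError("spike_times must be sorted ascending")
    if len(t) < 2:
        return []
    short = np.diff(t) < max_isi_ms / 1000.0
    bursts = []
    i = 0
    while i < len(short):
        if short[i]:
            j = i
            while j < len(short) and short[j]:
                j += 1
            bursts.append(np.arange(i, j + 1))
            i = j
        else:
            i += 1
    return bursts


def burst_fraction(spike_times: np.ndarray, max_isi_ms: float = BURST_ISI_MS) -> float:
    """Fraction of spikes that participate in bursts."""
    n = len(spike_times)
    if n == 0:
        return np.nan
    in_burst = sum(len(b) for b in detect_bursts(spike_times, max_isi_ms))
    return in_burst / n


def autocorrelogram(
    spike_times: np.ndarray, bin_ms: float = 0.5, span_ms: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided spike-train autocorrelogram (counts per positive lag bin)."""
    t = np.sort(np.asarray(spike_times, dtype=float))
    span = span_ms / 1000.0
    edges = np.arange(0.0, span_ms + bin_ms, bin_ms) / 1000.0
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    ends = np.searchsorted(t, t + span)
    for i in range(len(t)):
        j = ends[i]
        if j > i + 1:
            counts += np.histogram(t[i + 1 : j] - t[i], bins=edges)[0]
    lags = (edges[:-1] + edges[1:]) / 2 * 1000.0
    return lags, counts


def _acg_model(t, tau_decay, tau_rise, c, d, h, tau_burst, r, t0):
    dt = t - t0
    val = (
        c * (np.exp(-dt / tau_decay) - d * np.exp(-dt / tau_rise))
        + h * np.exp(-dt / tau_burst)
        + r
    )
    val = np.where(dt < 0, 0.0, val)
    return np.maximum(val, 0.0)


def fit_acg_triple_exponential(
    spike_times: np.ndarray,
    bin_ms: float = 0.5,
    span_ms: float = 50.0,
    min_spikes: int = 500,
) -> AcgFit:
    """Least-squares triple-exponential fit of the autocorrelogram.

    Model: ``max(c (exp(-(t-t0)/tau_decay) - d exp(-(t-t0)/tau_rise))
    + h exp(-(t-t0)/tau_burst) + r, 0)`` on lags past the refractory offset
    t0. ``tau_rise`` is the rise-time statistic used by the cell-type
    cascade. Deterministic start values; non-convergence returns a flagged
    fit with NaN tau_rise.
    """
    t = np.asarray(spike_times, dtype=float)
    if len(t) < min_spikes:
        raise ValueError(f"need >= {min_spikes} spikes for a stable ACG fit, got {len(t)}")
    lags, counts = autocorrelogram(t, bin_ms, span_ms)
    peak = max(counts.max(), 1.0)
    tail = float(np.median(counts[-10:]))
    bounds = (
        [1.0, 0.1, 0.0, 0.0, 0.0, 0.1, 0.0, 0.0],
        [500.0, 50.0, 5 * peak, 15.0, 5 * peak, 20.0, 5 * peak, 10.0],
    )
    # deterministic multi-start: the surface has local minima where the
    # slow-decay limb absorbs a flat plateau
    starts = [
        [20.0, 1.5, peak * 0.5, 1.0, 0.0, 2.0, tail, 1.0],
        [20.0, 1.5, peak * 0.1, 0.5, 0.0, 2.0, tail, 1.0],
        [50.0, 8.0, peak * 0.5, 1.0, 0.0, 2.0, tail, 1.0],
    ]
    y = counts.astype(float)
    best_popt, best_sse = None, np.inf
    for p0 in starts:
        try:
            popt, _ = curve_fit(_acg_model, lags, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _acg_model(lags, *popt)) ** 2))
        if sse < best_sse - 1e-9:
            best_popt, best_sse = popt, sse
    converged = best_popt is not None

    # model selection: on a flat autocorrelogram the rise limb merely chases
    # noise; keep it only if BIC prefers the full model over a no-rise fit
    if converged:
        def _reduced(tt, tau_decay, c, h, tau_burst, r, t0):
            return _acg_model(tt, tau_decay, 1.0, c, 0.0, h, tau_burst, r, t0)

        red_popt, red_sse = None, np.inf
        for p0r in ([20.0, peak * 0.5, 0.0, 2.0, tail, 1.0],
                    [200.0, peak * 0.1, 0.0, 2.0, tail, 1.0]):
            try:
                pr, _ = curve_fit(
                    _reduced, lags, y, p0=p0r,
                    bounds=([1.0, 0.0, 0.0, 0.1, 0.0, 0.0],
                            [500.0, 5 * peak, 5 * peak, 20.0, 5 * peak, 10.0]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((y - _reduced(lags, *pr)) ** 2))
            if sse < red_sse:
                red_popt, red_sse = pr, sse
        n = len(y)
        if red_popt is not None:
            bic_full = n * np.log(best_sse / n) + 8 * np.log(n)
            bic_red = n * np.log(red_sse / n) + 6 * np.log(n)
            if bic_red <= bic_full:
                # no detectable post-spike suppression: rise time at the floor
                td, c, h, tb, r, t0 = red_popt
                best_popt = [td, 0.1, c, 0.0, h, tb, r, t0]
    popt = best_popt if converged else [np.nan] * 8
    return AcgFit(
        lags_ms=lags,
        counts=counts,
        tau_decay=popt[0],
        tau_rise=popt[1] if converged else np.nan,
        amplitude=popt[2],
        rise_coeff=popt[3],
        burst_amplitude=popt[4],
        tau_burst=popt[5],
        asymptote=popt[6],
        refractory_ms=popt[7],
        converged=converged,
    )


def classify_cell_type(trough_to_peak_ms: float, acg_rise_ms: float) -> CellTypeLabel:
    """Cascade: narrow (< 0.425 ms t2p), wide (>= 0.425 ms and ACG rise
    > 6 ms), otherwise pyramidal. NaN rise time falls through to pyramidal.
    """
    if not np.isfinite(trough_to_peak_ms):
        raise ValueError("trough_to_peak_ms must be finite")
    if trough_to_peak_ms < NARROW_T2P_MS:
        label = "narrow_interneuron"
    elif np.isfinite(acg_rise_ms) and acg_rise_ms > WIDE_ACG_RISE_MS:
        label = "wide_interneuron"
    else:
        label = "pyramidal"
    return CellTypeLabel(label, trough_to_peak_ms, acg_rise_ms)


def peri_event_histogram(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    window_ms: tuple[float, float] = (-500.0, 500.0),
    bin_ms: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Peri-event firing-rate histogram.

    Returns (bin centers in ms, rate in Hz): spike-minus-event lag counts
    per bin divided by n_events x bin width. Bins must tile the window
    exactly.
    """
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("zero events")
    lo, hi = window_ms
    n_bins = (hi - lo) / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin {bin_ms} ms does not tile window {window_ms}")
    edges = lo + np.arange(round(n_bins) + 1) * bin_ms
    t = np.sort(np.asarray(spike_times, dtype=float)) * 1000.0  # ms
    counts = np.zeros(len(edges) - 1)
    ev_ms = events * 1000.0
    for e in ev_ms:
        i0, i1 = np.searchsorted(t, [e + lo, e + hi])
        counts += np.histogram(t[i0:i1] - e, bins=edges)[0]
    rate = counts / (len(events) * bin_ms / 1000.0)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, rate


def unit_metrics_table(
    footprints: list[UnitFootprint], probe: ProbeMap, min_spikes_acg: int = 500
) -> pd.DataFrame:
    """One classified row per unit: t2p, ACG rise, burst fraction, label, soma."""
    rows = []
    for fp in footprints:
        t2p = trough_to_peak(fp)
        try:
            fit = fit_acg_triple_exponential(fp.spike_times, min_spikes=min_spikes_acg)
            rise = fit.tau_rise
        except ValueError:
            rise = np.nan
        label = classify_cell_type(t2p, rise)
        soma_ch, (x, y) = estimate_soma_channel(fp, probe)
        rows.append(
            {
                "unit_id": fp.unit_id,
                "t2p_ms": t2p,
                "acg_rise_ms": rise,
                "burst_fraction": burst_fraction(fp.spike_times),
                "label": label.label,
                "soma_channel": soma_ch,
                "soma_x_um": x,
                "soma_y_um": y,
            }
        )
    return pd.DataFrame(rows)
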