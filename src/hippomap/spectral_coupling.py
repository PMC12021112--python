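"""Spike-LFP phase-locking maps and reference-channel gamma coherence maps.

Phase locking: the LFP on each channel is narrow-band filtered in a 5 Hz
band around each centre frequency (Gaussian frequency-domain filter,
zero-phase), the instantaneous phase taken from the analytic signal, and
the phase-locking value computed as the resultant length
``R = |mean(exp(i phi_k))|`` over the phases at spike times. R is 0 for
uniform phases, 1 for perfect locking, and converges to
``I1(kappa)/I0(kappa)`` for von Mises-locked spiking.

Coherence: signals are Gaussian band-pass filtered (default 30-90 Hz) and
the magnitude-squared coherence against a reference channel is estimated
from interval-averaged tapered cross-spectra, then averaged over the band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps
from scipy.fft import irfft, rfft, rfftfreq

from .core import EventSet, RecordingSegment
from .probe_geometry import ProbeMap

__all__ = [
    "PLVMap",
    "CoherenceMap",
    "gaussian_bandpass_fft",
    "instantaneous_phase",
    "plv",
    "plv_map",
    "coherence_map",
    "select_swr_intervals",
    "decimate_segment",
    "rayleigh_null_floor",
]

DEFAULT_FREQS = np.arange(30.0, 200.0 + 1e-9, 5.0)
PHASE_BANDWIDTH_HZ = 5.0
MIN_SPIKES_PLV = 200


@dataclass
class PLVMap:
    """PLV per (channel, centre frequency) on the probe lattice."""

    values: np.ndarray  # channels x frequencies, in [0, 1]
    channel_ids: np.ndarray
    freqs_hz: np.ndarray
    n_spikes: int
    smoothed: bool = False

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("channel_ids", data=self.channel_ids)
            f.create_dataset("freqs_hz", data=self.freqs_hz)
            f.attrs["n_spikes"] = self.n_spikes
            f.attrs["smoothed"] = self.smoothed


@dataclass
class CoherenceMap:
    """Band-averaged coherence of every channel against a reference."""

    values: np.ndarray  # per channel, in [0, 1]
    channel_ids: np.ndarray
    reference_channel: int
    band_hz: tuple[float, float]
    n_intervals: int
    interval_duration_s: float

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("channel_ids", data=self.channel_ids)
            f.attrs["reference_channel"] = self.reference_channel
            f.attrs["band_hz"] = self.band_hz
            f.attrs["n_intervals"] = self.n_intervals
            f.attrs["interval_duration_s"] = self.interval_duration_s


# ---------------------------------------------------------------------------
# narrow-band phase
# ---------------------------------------------------------------------------

def _gaussian_band_weights(freqs: np.ndarray, center: float, bandwidth: float) -> np.ndarray:
    sigma = bandwidth / 4.0  # +-2 sigma spans the band
    return np.exp(-0.5 * ((freqs - center) / sigma) ** 2)


def gaussian_bandpass_fft(
    x: np.ndarray, fs: float, center: float, bandwidth: float
) -> np.ndarray:
    """Zero-phase Gaussian band-pass via the frequency domain (real output)."""
    _check_band(center, bandwidth, fs)
    X = rfft(np.asarray(x, dtype=np.float64))
    f = rfftfreq(len(x), 1 / fs)
    return irfft(X * _gaussian_band_weights(f, center, bandwidth), n=len(x))


def instantaneous_phase(
    x: np.ndarray, fs: float, center: float, bandwidth: float = PHASE_BANDWIDTH_HZ
) -> np.ndarray:
    """Phase (rad) of the analytic signal of the narrow-band filtered trace.

    The analytic signal is built directly in the frequency domain: the
    Gaussian band weight is applied to positive frequencies only (doubled),
    so the result is the Hilbert analytic signal of the band-passed trace.
    """
    _check_band(center, bandwidth, fs)
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    X = np.fft.fft(x)
    f = np.fft.fftfreq(n, 1 / fs)
    w = np.zeros(n)
    pos = f > 0
    w[pos] = 2.0 * _gaussian_band_weights(f[pos], center, bandwidth)
    analytic = np.fft.ifft(X * w)
    return np.angle(analytic)


def _check_band(center: float, bandwidth: float, fs: float) -> None:
    if center - bandwidth / 2 <= 0 or center + bandwidth / 2 >= fs / 2:
        raise ValueError(
            f"band {center}+-{bandwidth / 2} Hz outside (0, Nyquist={fs / 2})"
        )


# ---------------------------------------------------------------------------
# phase locking
# ---------------------------------------------------------------------------

def plv(spike_times: np.ndarray, phase: np.ndarray, fs: float) -> float:
    """Resultant length of the spike-phase ensemble (nearest-sample lookup)."""
    t = np.asarray(spike_times, dtype=float)
    idx = np.round(t * fs).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < len(phase))]
    if idx.size == 0:
        raise ValueError("no spikes inside the signal span")
    return float(np.abs(np.mean(np.exp(1j * phase[idx]))))


def rayleigh_null_floor(n_spikes: int, n_comparisons: int = 1, alpha: float = 0.01) -> float:
    """Upper quantile of the null resultant length for uncoupled spiking.

    Under independent uniform phases, n R^2 is asymptotically Exp(1), so
    P(R > sqrt(-ln(a)/n)) = a; the floor is Sidak-adjusted for
    *n_comparisons* map cells.
    """
    a = 1 - (1 - alpha) ** (1 / max(n_comparisons, 1))
    return float(np.sqrt(-np.log(a) / n_spikes))


def plv_map(
    spike_times: np.ndarray,
    segment: RecordingSegment,
    probe: ProbeMap,
    freqs_hz: np.ndarray | None = None,
    bandwidth: float = PHASE_BANDWIDTH_HZ,
    min_spikes: int = MIN_SPIKES_PLV,
    smooth: bool = False,
) -> PLVMap:
    """PLV of one unit against every channel and centre frequency.

    Refuses units with fewer than *min_spikes* spikes (the resultant
    length is upward-biased at small n). Optional smoothing replaces each
    value with the mean over its 2x2 lattice block (both columns x two
    adjacent rows of the same shank).
    """
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= 0) & (t < segment.duration)]
    if len(t) < min_spikes:
        raise ValueError(
            f"unit has {len(t)} usable spikes; >= {min_spikes} required for a "
            "usable PLV map (small-sample bias)"
        )
    freqs = DEFAULT_FREQS if freqs_hz is None else np.asarray(freqs_hz, dtype=float)
    fs = segment.sampling_rate
    idx = np.round(t * fs).astype(np.int64)
    values = np.zeros((segment.n_channels, len(freqs)))
    for ci in range(segment.n_channels):
        x = segment.data[ci]
        for fi, f0 in enumerate(freqs):
            phase = instantaneous_phase(x, fs, f0, bandwidth)
            values[ci, fi] = np.abs(np.mean(np.exp(1j * phase[idx])))
    out = PLVMap(
        values=values,
        channel_ids=segment.channel_ids.copy(),
        freqs_hz=freqs,
        n_spikes=int(len(t)),
        smoothed=False,
    )
    return smooth_plv_map(out, probe) if smooth else out


def smooth_plv_map(m: PLVMap, probe: ProbeMap) -> PLVMap:
    """Average the adjacent four pixels (2 columns x 2 adjacent rows)."""
    ch = probe.channels.set_index("channel_id")
    sub = ch.loc[m.channel_ids]
    values = m.values.copy()
    pos = {
        (int(r.shank), int(r.row), int(r.column)): i
        for i, r in enumerate(sub.itertuples())
    }
    max_row = int(sub.row.max())
    for i, r in enumerate(sub.itertuples()):
        r0 = int(r.row) if int(r.row) < max_row else int(r.row) - 1
        block = [
            pos.get((int(r.shank), rr, cc))
            for rr in (r0, r0 + 1)
            for cc in (0, 1)
        ]
        block = [b for b in block if b is not None]
        values[i] = m.values[block].mean(axis=0)
    return PLVMap(values, m.channel_ids.copy(), m.freqs_hz.copy(), m.n_spikes, smoothed=True)


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def select_swr_intervals(
    events: EventSet, n: int = 100, duration_s: float = 1.0,
    recording_duration_s: float | None = None,
) -> list[tuple[float, float]]:
    """Up to *n* non-overlapping windows centred on ripple peaks, earliest first."""
    if len(events) == 0:
        raise ValueError("empty event set")
    half = duration_s / 2
    out: list[tuple[float, float]] = []
    last_end = -np.inf
    for pk in np.sort(events.peak_times):
        start, end = pk - half, pk + half
        if start < 0:
            continue
        if recording_duration_s is not None and end > recording_duration_s:
            continue
        if start < last_end:
            continue
        out.append((start, end))
        last_end = end
        if len(out) == n:
            break
    if len(out) < n:
        warnings.warn(
            f"only {len(out)} of the requested {n} non-overlapping intervals "
            "are available", stacklevel=2,
        )
    return out


def coherence_map(
    segment: RecordingSegment,
    reference_channel: int,
    band_hz: tuple[float, float] = (30.0, 90.0),
    intervals: list[tuple[float, float]] | None = None,
) -> CoherenceMap:
    """Band-averaged magnitude-squared coherence of all channels vs a reference.

    Each interval is one estimation segment: mean-subtracted, Hann-tapered,
    cross- and auto-spectra averaged over intervals, coherence
    ``|Sxy|^2 / (Sxx Syy)`` averaged over the band. Self-coherence is
    exactly 1.
    """
    if intervals is None or len(intervals) < 2:
        raise ValueError("coherence needs >= 2 intervals")
    for (s, e) in intervals:
        if e - s < 0.5:
            raise ValueError(f"interval ({s}, {e}) shorter than 0.5 s")
    fs = segment.sampling_rate
    low, high = band_hz
    center = (low + high) / 2
    width = high - low
    n_len = min(int(round((e - s) * fs)) for s, e in intervals)
    ref = np.asarray(segment.trace(reference_channel), dtype=np.float64)
    filt = np.empty((segment.n_channels, segment.n_samples))
    for ci in range(segment.n_channels):
        filt[ci] = gaussian_bandpass_fft(segment.data[ci], fs, center, width)
    ref_f = filt[segment.channel_index(reference_channel)]
    del ref

    taper = np.hanning(n_len)
    freqs = rfftfreq(n_len, 1 / fs)
    band_mask = (freqs >= low) & (freqs <= high)
    sxx = np.zeros((segment.n_channels, band_mask.sum()))
    syy = np.zeros(band_mask.sum())
    sxy = np.zeros((segment.n_channels, band_mask.sum()), dtype=complex)
    for (s, e) in intervals:
        i0 = int(round(s * fs))
        seg = filt[:, i0 : i0 + n_len]
        seg = (seg - seg.mean(axis=1, keepdims=True)) * taper
        F = rfft(seg, axis=1)[:, band_mask]
        r = rfft((ref_f[i0 : i0 + n_len] - ref_f[i0 : i0 + n_len].mean()) * taper)[band_mask]
        sxx += np.abs(F) ** 2
        syy += np.abs(r) ** 2
        sxy += F * np.conj(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy[None, :])
    values = np.nanmean(coh, axis=1)
    values[segment.channel_index(reference_channel)] = 1.0
    return CoherenceMap(
        values=np.clip(values, 0.0, 1.0),
        channel_ids=segment.channel_ids.copy(),
        reference_channel=int(reference_channel),
        band_hz=(float(low), float(high)),
        n_intervals=len(intervals),
        interval_duration_s=n_len / fs,
    )


def decimate_segment(segment: RecordingSegment, factor: int) -> RecordingSegment:
    """Anti-aliased downsampling (polyphase FIR) for LFP-band analyses."""
    if factor <= 1:
        return segment
    data = sps.resample_poly(np.asarray(segment.data, dtype=np.float64), 1, factor, axis=1)
    return RecordingSegment(
        data.astype(np.float32), segment.sampling_rate / factor, segment.channel_ids.copy()
    )
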