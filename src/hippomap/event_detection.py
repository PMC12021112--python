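"""Sharp-wave-ripple and dentate-spike detection from single-channel LFP.

Ripples: the wide-band signal is band-pass filtered (difference of
Gaussians, zero-phase FIR), an amplitude-clipped copy defines robust
envelope statistics, and threshold crossings of the non-clipped envelope
mark events which are then expanded, duration-filtered and merged.

Dentate spikes: the hilus-minus-molecular 2-50 Hz difference is screened
for positive peaks; a candidate passes only if the molecular-layer LFP
during the event drops below its own pre-event baseline by more than the
configured threshold (default 0.19 mV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import EventSet, RecordingSegment

__all__ = [
    "RippleDetectionParams",
    "DentateSpikeParams",
    "ripple_lowpass_cutoff",
    "dog_bandpass",
    "gaussian_lowpass",
    "detect_ripples",
    "detect_dentate_spikes",
]

logger = logging.getLogger("hippomap")


@dataclass
class RippleDetectionParams:
    band: tuple[float, float] = (80.0, 250.0)
    clip_sd: float = 4.0  # amplitude clip for the normalisation copy
    detect_sd: float = 4.0  # detection threshold on the envelope
    expand_sd: float = 1.0  # event boundaries expand to this level
    min_duration_ms: float = 15.0
    cycles_p: int = 3  # envelope smoothing: p cycles of the mean band-pass

    def validate(self, nyquist: float) -> None:
        low, high = self.band
        if not (0 < low < high < nyquist):
            raise ValueError(f"band {self.band} invalid for Nyquist {nyquist}")
        if self.detect_sd <= self.expand_sd:
            raise ValueError("detect_sd must exceed expand_sd")
        if self.min_duration_ms <= 0:
            raise ValueError("min_duration_ms must be > 0")
        if self.cycles_p < 1:
            raise ValueError("cycles_p must be >= 1")


@dataclass
class DentateSpikeParams:
    band: tuple[float, float] = (2.0, 50.0)
    baseline_window_ms: tuple[float, float] = (-36.0, -16.0)
    mol_threshold_mv: float = 0.19
    prominence_sd: float = 2.0  # pre-criterion screen on the difference trace

    def validate(self) -> None:
        lo, hi = self.baseline_window_ms
        if not (lo < hi <= 0):
            raise ValueError("baseline window must strictly precede the event sample")


def ripple_lowpass_cutoff(band: tuple[float, float], cycles_p: int) -> float:
    """Envelope low-pass cutoff: mean of the band edges divided by p cycles.

    For the 80-250 Hz ripple band and p = 3 this gives 55 Hz.
    """
    if cycles_p < 1:
        raise ValueError("cycles_p must be >= 1")
    return (band[0] + band[1]) / 2.0 / cycles_p


# ---------------------------------------------------------------------------
# zero-phase FIR filters
# ---------------------------------------------------------------------------

def _gauss_kernel(sigma_t: float, fs: float) -> np.ndarray:
    """Unit-area Gaussian FIR kernel, +-4 sigma support."""
    half = max(int(np.ceil(4 * sigma_t * fs)), 1)
    tt = np.arange(-half, half + 1) / fs
    k = np.exp(-0.5 * (tt / sigma_t) ** 2)
    return k / k.sum()


def _sigma_for_cutoff(cutoff_hz: float) -> float:
    # Gaussian lowpass with -3 dB amplitude point at the cutoff
    return np.sqrt(np.log(2) / 2) / (2 * np.pi * cutoff_hz)


def gaussian_lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    """Zero-phase Gaussian FIR low-pass (-3 dB at *cutoff_hz*)."""
    k = _gauss_kernel(_sigma_for_cutoff(cutoff_hz), fs)
    if len(k) > len(x):
        raise ValueError(f"kernel ({len(k)} taps) longer than signal ({len(x)})")
    return signal.fftconvolve(x, k, mode="same")


def dog_bandpass(
    x: np.ndarray, band: tuple[float, float], fs: float
) -> np.ndarray:
    """Difference-of-Gaussians band-pass: zero-phase, linear-phase FIR.

    The kernel is the difference of two Gaussian low-pass kernels with
    -3 dB points at the band edges; DC gain is exactly 0 and the response
    is normalised to unit gain at the band-centre (mean of the edges).
    """
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2})")
    k_hi = _gauss_kernel(_sigma_for_cutoff(high), fs)
    k_lo = _gauss_kernel(_sigma_for_cutoff(low), fs)
    n = max(len(k_hi), len(k_lo))
    kernel = np.zeros(n)
    kernel[(n - len(k_hi)) // 2 : (n - len(k_hi)) // 2 + len(k_hi)] += k_hi
    kernel[(n - len(k_lo)) // 2 : (n - len(k_lo)) // 2 + len(k_lo)] -= k_lo
    if n > len(x):
        raise ValueError(f"kernel ({n} taps) longer than signal ({len(x)})")
    fc = (low + high) / 2.0
    tt = np.arange(n) - n // 2
    gain = np.abs(np.sum(kernel * np.exp(-2j * np.pi * fc * tt / fs)))
    kernel = kernel / gain
    return signal.fftconvolve(x, kernel, mode="same")


# ---------------------------------------------------------------------------
# ripples
# ---------------------------------------------------------------------------

def _envelope(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    return gaussian_lowpass(np.abs(x), cutoff_hz, fs)


def detect_ripples(
    segment: RecordingSegment,
    channel_id: int,
    params: RippleDetectionParams | None = None,
) -> EventSet:
    """Detect sharp-wave ripples on one channel.

    Pipeline: (1) DoG band-pass; (2) a copy clipped at ``clip_sd`` x SD of
    the band-passed signal is rectified and low-pass filtered — its mean
    and SD define the normalisation; (3) the non-clipped signal gets the
    identical envelope; (4) events are normalised-envelope excursions above
    ``detect_sd``; (5) each is expanded until the envelope falls below
    ``expand_sd``; (6) events shorter than ``min_duration_ms`` are dropped;
    (7) overlapping expansions merge. Scores are envelope peaks in SD units.
    """
    params = params or RippleDetectionParams()
    fs = segment.sampling_rate
    params.validate(fs / 2)
    x = np.asarray(segment.trace(channel_id), dtype=np.float64)
    bp = dog_bandpass(x, params.band, fs)
    sd_bp = bp.std()
    if sd_bp == 0:
        raise ValueError(f"channel {channel_id} is silent/flat (SD = 0)")
    cutoff = ripple_lowpass_cutoff(params.band, params.cycles_p)
    clipped = np.clip(bp, -params.clip_sd * sd_bp, params.clip_sd * sd_bp)
    env_clip = _envelope(clipped, cutoff, fs)
    mu, sd = env_clip.mean(), env_clip.std()
    if sd == 0:
        raise ValueError(f"channel {channel_id}: degenerate envelope (SD = 0)")
    env = (_envelope(bp, cutoff, fs) - mu) / sd

    above = env > params.detect_sd
    if not above.any():
        return EventSet(pd.DataFrame(columns=["start_s", "peak_s", "end_s", "score"]),
                        label="ripple")
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(env)]

    below = env < params.expand_sd
    events = []
    for s, e in zip(starts, ends):
        lo = np.flatnonzero(below[:s])
        s_exp = int(lo[-1]) + 1 if lo.size else 0
        hi = np.flatnonzero(below[e:])
        e_exp = e + int(hi[0]) if hi.size else len(env)
        events.append([s_exp, e_exp])

    # merge events whose expansions touch or overlap
    merged: list[list[int]] = []
    for s, e in events:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    min_len = int(params.min_duration_ms / 1000 * fs)
    rows = []
    for s, e in merged:
        if e - s < min_len:
            continue
        pk = s + int(np.argmax(env[s:e]))
        rows.append((s / fs, pk / fs, e / fs, float(env[pk])))
    return EventSet(
        pd.DataFrame(rows, columns=["start_s", "peak_s", "end_s", "score"]),
        label="ripple",
    )


# ---------------------------------------------------------------------------
# dentate spikes
# ---------------------------------------------------------------------------

def detect_dentate_spikes(
    segment: RecordingSegment,
    hilus_channel: int,
    molecular_channel: int,
    params: DentateSpikeParams | None = None,
) -> EventSet:
    """Detect dentate spikes from a hilus / molecular-layer channel pair.

    Candidates are positive peaks of the band-passed (2-50 Hz) hilus-minus-
    molecular difference; each is kept only if the wide-band molecular LFP
    averaged over the event is below its own baseline-window mean by more
    than ``mol_threshold_mv``. The reported peak time is the maximum of the
    wide-band hilus LFP within the candidate window; the score is the
    molecular-layer drop in mV.
    """
    params = params or DentateSpikeParams()
    params.validate()
    if hilus_channel == molecular_channel:
        raise ValueError("hilus and molecular channels must differ")
    fs = segment.sampling_rate
    hil = np.asarray(segment.trace(hilus_channel), dtype=np.float64)
    mol = np.asarray(segment.trace(molecular_channel), dtype=np.float64)
    hil_bp = dog_bandpass(hil, params.band, fs)
    mol_bp = dog_bandpass(mol, params.band, fs)
    diff = hil_bp - mol_bp
    sd = diff.std()
    if sd == 0:
        return EventSet(pd.DataFrame(columns=["start_s", "peak_s", "end_s", "score"]),
                        label="dentate_spike")
    peaks, _ = signal.find_peaks(diff, height=params.prominence_sd * sd,
                                 distance=int(0.05 * fs))
    b0 = int(params.baseline_window_ms[0] / 1000 * fs)
    b1 = int(params.baseline_window_ms[1] / 1000 * fs)
    rows = []
    last_end = -1
    for p in peaks:
        # candidate window: the positive lobe of the difference around the peak
        left = p
        while left > 0 and diff[left - 1] > 0:
            left -= 1
        right = p
        while right < len(diff) - 1 and diff[right + 1] > 0:
            right += 1
        if left <= last_end:
            continue
        if p + b0 < 0:
            logger.warning(
                "dentate-spike candidate at %.3f s skipped: baseline window "
                "precedes recording start", p / fs,
            )
            continue
        baseline = mol[p + b0 : p + b1].mean()
        drop_mv = (baseline - mol[left : right + 1].mean()) / 1000.0
        if drop_mv <= params.mol_threshold_mv:
            continue
        pk = left + int(np.argmax(hil[left : right + 1]))
        rows.append((left / fs, pk / fs, (right + 1) / fs, float(drop_mv)))
        last_end = right
    return EventSet(
        pd.DataFrame(rows, columns=["start_s", "peak_s", "end_s", "score"]),
        label="dentate_spike",
    )
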