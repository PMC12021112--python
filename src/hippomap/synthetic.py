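"""Ground-truthed synthetic multi-shank recordings.

Emulates the statistical structure every downstream stage assumes, on any
probe lattice built by :mod:`hippomap.probe_geometry`:

* band-limited background noise shaped independently to the LFP-band
  (0.1-300 Hz) and AP-band (300-5000 Hz) RMS targets,
* sharp-wave ripples: a ripple-frequency carrier under a Gaussian envelope
  on pyramidal-layer rows plus a concurrent negative sharp-wave deflection
  on radiatum rows (a radiatum sink flanked by sources in CSD),
* dentate spikes: a positive hilar deflection with an opposite-sign
  molecular-layer deflection,
* laminar gamma oscillations confined to configured row ranges,
* unit spike trains with spatial waveform footprints: peak-to-peak
  amplitude decays exponentially with Euclidean distance from the soma and
  the trough is delayed linearly with axial distance (separate slopes above
  and below the soma, in ms/mm), optionally von Mises phase-locked to a
  gamma source and rate-modulated during ripples.

Every injected quantity is recorded in a :class:`GroundTruth` so recovery
can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .core import RecordingSegment
from .probe_geometry import ProbeMap, build_default_probe_map

__all__ = [
    "UnitSpec",
    "GammaSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_layer_rows",
    "simulate_recording",
    "spike_phases_von_mises",
    "band_rms",
    "write_recording",
    "write_spike_table",
    "read_spike_table",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: fractional row positions (of the shank row span) of the named laminae,
#: top of the shank = 0. Chosen so CA1 pyramidale sits superficially, the
#: dentate hilus deep, in the order the probe crosses them.
_LAYER_FRACTIONS = {
    "pyramidale": (0.20, 0.28),
    "radiatum": (0.34, 0.52),
    "lacunosum": (0.55, 0.62),
    "molecular": (0.64, 0.74),
    "hilus": (0.80, 0.92),
}


def default_layer_rows(rows_per_shank: int = 64) -> dict[str, tuple[int, int]]:
    """Named laminar row ranges scaled to a shank of *rows_per_shank* rows."""
    out = {}
    for name, (lo, hi) in _LAYER_FRACTIONS.items():
        a = int(round(lo * (rows_per_shank - 1)))
        b = int(round(hi * (rows_per_shank - 1)))
        out[name] = (a, max(b, a + 1))
    return out


@dataclass
class UnitSpec:
    """Ground-truth parameters of one simulated unit."""

    soma_channel: int
    peak_amplitude: float = 82.0  # uV peak-to-peak at the soma
    amplitude_length_constant: float = 150.0  # um, exponential spatial decay
    slope_above: float = 0.0  # ms/mm trough delay per axial distance above soma
    slope_below: float = 0.0  # ms/mm below soma
    trough_to_peak: float = 0.6  # ms
    firing_rate: float = 5.0  # Hz
    kappa: float = 0.0  # von Mises concentration w.r.t. the gamma source
    gamma_source: int | None = None  # index into SimulationConfig.gamma_specs
    preferred_phase: float = 0.0  # rad
    ripple_gain: float = 1.0  # multiplicative rate gain inside ripple events

    def validate(self) -> None:
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be > 0")
        if self.firing_rate < 0:
            raise ValueError("firing_rate must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.kappa > 0 and self.gamma_source is None:
            raise ValueError("phase-locked unit needs a gamma_source index")


@dataclass
class GammaSpec:
    """One laminar gamma oscillation source."""

    center_freq: float  # Hz
    amplitude: float  # uV at the center of its laminar band
    rows: tuple[int, int]  # inclusive row range the oscillation occupies


@dataclass
class SimulationConfig:
    sampling_rate: float = 20000.0
    duration: float = 10.0  # s
    seed: int = 0
    lfp_noise_rms: float = 16.45  # uV in 0.1-300 Hz
    ap_noise_rms: float = 6.67  # uV in 300-5000 Hz
    ripple_rate: float = 0.0  # events/s
    ripple_freq: float = 150.0  # Hz
    ripple_duration_ms: float = 60.0
    ripple_snr: float = 6.0  # carrier peak over the 80-250 Hz noise SD
    sharp_wave_amplitude: float = 150.0  # uV negative radiatum deflection
    ds_rate: float = 0.0  # events/s
    ds_hilus_amplitude_mv: float = 0.4
    ds_molecular_amplitude_mv: float = 0.3
    ds_duration_ms: float = 30.0
    layer_rows: dict[str, tuple[int, int]] | None = None
    unit_specs: list[UnitSpec] = field(default_factory=list)
    gamma_specs: list[GammaSpec] = field(default_factory=list)
    probe: ProbeMap | None = None  # defaults to the full 8-shank map

    def resolved_probe(self) -> ProbeMap:
        return self.probe if self.probe is not None else build_default_probe_map()

    def resolved_layers(self, probe: ProbeMap) -> dict[str, tuple[int, int]]:
        return (
            dict(self.layer_rows)
            if self.layer_rows is not None
            else default_layer_rows(probe.rows_per_shank)
        )

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        probe = self.resolved_probe()
        injected = [self.ripple_freq] + [g.center_freq for g in self.gamma_specs]
        top = max(injected) if injected else 0.0
        if self.sampling_rate <= 2 * top:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz cannot represent "
                f"injected frequency {top} Hz"
            )
        n_rows = probe.rows_per_shank
        for name, (lo, hi) in self.resolved_layers(probe).items():
            if not (0 <= lo <= hi < n_rows):
                raise ValueError(f"layer {name!r} rows ({lo}, {hi}) outside probe span")
        for g in self.gamma_specs:
            lo, hi = g.rows
            if not (0 <= lo <= hi < n_rows):
                raise ValueError(f"gamma rows {g.rows} outside probe span")
        for u in self.unit_specs:
            u.validate()
            if u.soma_channel not in probe:
                raise ValueError(f"unit soma_channel {u.soma_channel} not in probe map")
            if u.gamma_source is not None and not (
                0 <= u.gamma_source < len(self.gamma_specs)
            ):
                raise ValueError(f"gamma_source {u.gamma_source} out of range")


@dataclass
class UnitGroundTruth:
    unit_id: int
    spike_times: np.ndarray
    soma_channel: int
    slope_above: float
    slope_below: float
    kappa: float
    gamma_source: int | None
    preferred_phase: float
    ripple_gain: float


@dataclass
class GroundTruth:
    """Everything that was injected, for recovery scoring."""

    ripples: list[tuple[float, float, float]]  # (start, peak, end) s
    ds_times: list[float]  # peak times s
    units: list[UnitGroundTruth]
    gamma_phase0: list[float]  # initial phase (rad) of each gamma source

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ripples": [list(r) for r in self.ripples],
            "ds_times": list(self.ds_times),
            "gamma_phase0": list(self.gamma_phase0),
            "units": [
                {**asdict(u), "spike_times": np.asarray(u.spike_times).tolist()}
                for u in self.units
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        units = [
            UnitGroundTruth(
                unit_id=u["unit_id"],
                spike_times=np.asarray(u["spike_times"], dtype=float),
                soma_channel=u["soma_channel"],
                slope_above=u["slope_above"],
                slope_below=u["slope_below"],
                kappa=u["kappa"],
                gamma_source=u["gamma_source"],
                preferred_phase=u["preferred_phase"],
                ripple_gain=u["ripple_gain"],
            )
            for u in payload["units"]
        ]
        return cls(
            ripples=[tuple(r) for r in payload["ripples"]],
            ds_times=list(payload["ds_times"]),
            units=units,
            gamma_phase0=list(payload["gamma_phase0"]),
        )


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def spike_phases_von_mises(
    n: int, kappa: float, mu: float = 0.0, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """I.i.d. von Mises phase sample (rad in (-pi, pi]).

    kappa = 0 is the uniform circular distribution; the population
    resultant length converges to I1(kappa)/I0(kappa).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, size=n)
    return np.angle(np.exp(1j * rng.vonmises(mu, kappa, size=n)))


def band_rms(
    segment: RecordingSegment, channel_id: int, band: tuple[float, float]
) -> float:
    """Band-limited RMS (uV) from the one-sided PSD.

    The Welch PSD of the channel is integrated over *band* and the square
    root returned (Parseval: the full-Nyquist integral is the variance).
    """
    low, high = band
    nyq = segment.sampling_rate / 2
    if not (0 <= low < high <= nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}) or inverted")
    x = segment.trace(channel_id)
    nperseg = min(len(x), 2 ** 17)
    freqs, psd = signal.welch(x, fs=segment.sampling_rate, nperseg=nperseg)
    mask = (freqs >= low) & (freqs <= high)
    power = np.trapezoid(psd[mask], freqs[mask])
    return float(np.sqrt(power))


def _band_limited_noise(
    rng: np.random.Generator, n_samples: int, fs: float,
    band: tuple[float, float], rms: float,
) -> np.ndarray:
    """Gaussian noise confined (frequency-domain mask, smooth 5% raised-
    cosine edges) to *band* and scaled so its standard deviation is *rms*."""
    from scipy.fft import irfft, rfft, rfftfreq

    white = rng.standard_normal(n_samples)
    freqs = rfftfreq(n_samples, 1 / fs)
    low, high = band
    trans = 0.05 * (high - low)
    mask = np.zeros_like(freqs)
    core = (freqs >= low + trans) & (freqs <= high - trans)
    mask[core] = 1.0
    rise = (freqs >= low) & (freqs < low + trans)
    mask[rise] = 0.5 * (1 - np.cos(np.pi * (freqs[rise] - low) / trans))
    fall = (freqs > high - trans) & (freqs <= high)
    mask[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - (high - trans)) / trans))
    x = irfft(rfft(white) * mask, n=n_samples)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _shaped_noise(
    rng: np.random.Generator, n_samples: int, fs: float, lfp_rms: float, ap_rms: float
) -> np.ndarray:
    """One channel of background noise hitting both band RMS targets."""
    out = np.zeros(n_samples, dtype=np.float64)
    nyq = fs / 2
    if lfp_rms > 0:
        out += _band_limited_noise(rng, n_samples, fs, (0.1, min(300.0, 0.9 * nyq)), lfp_rms)
    if ap_rms > 0 and nyq > 400:
        out += _band_limited_noise(rng, n_samples, fs, (300.0, min(5000.0, 0.9 * nyq)), ap_rms)
    return out


def _layer_weight(rows: np.ndarray, layer: tuple[int, int]) -> np.ndarray:
    """Smooth (Gaussian) depth profile centred on a laminar row range."""
    lo, hi = layer
    center = 0.5 * (lo + hi)
    sigma = max((hi - lo) / 2.0, 0.75)
    return np.exp(-0.5 * ((rows - center) / sigma) ** 2)


def _draw_event_times(
    rng: np.random.Generator, rate: float, duration: float, min_sep: float
) -> np.ndarray:
    """`round(rate*duration)` event times, uniform, >= min_sep apart."""
    n = int(round(rate * duration))
    if n == 0:
        return np.array([])
    lo, hi = min_sep, duration - min_sep
    if hi <= lo:
        return np.array([])
    for _ in range(200):
        t = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.diff(t).min() >= min_sep:
            return t
    # fall back to a jittered regular grid if rejection keeps failing
    grid = np.linspace(lo, hi, n)
    return grid + rng.uniform(-0.25, 0.25, size=n) * min(min_sep, (hi - lo) / max(n, 1))


def _tukey_pulse(t_rel: np.ndarray, half_width_s: float, alpha: float = 0.5) -> np.ndarray:
    """Flat-topped (Tukey) pulse on |t| <= half_width, zero outside."""
    u = np.clip((t_rel / half_width_s + 1) / 2, 0, 1)  # 0..1 across the pulse
    w = np.zeros_like(u)
    inside = (u > 0) & (u < 1)
    ui = u[inside]
    wi = np.ones_like(ui)
    edge = alpha / 2
    left = ui < edge
    right = ui > 1 - edge
    wi[left] = 0.5 * (1 + np.cos(np.pi * (ui[left] / edge - 1)))
    wi[right] = 0.5 * (1 + np.cos(np.pi * ((ui[right] - 1 + edge) / edge)))
    w[inside] = wi
    return w


def _spike_template(t_ms: np.ndarray, trough_to_peak_ms: float) -> np.ndarray:
    """Biphasic unit waveform: unit-depth trough at 0, positive peak later.

    Normalised so the peak-to-peak amplitude is 1.
    """
    sig_n, sig_p = 0.10, 0.20  # ms
    neg = np.exp(-0.5 * (t_ms / sig_n) ** 2)
    pos = np.exp(-0.5 * ((t_ms - trough_to_peak_ms) / sig_p) ** 2)
    w = -neg + 0.35 * pos
    return w / 1.35


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate_recording(config: SimulationConfig) -> tuple[RecordingSegment, GroundTruth]:
    """Render a recording and its ground truth. Deterministic given seed."""
    config.validate()
    probe = config.resolved_probe()
    layers = config.resolved_layers(probe)
    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))
    ch = probe.channels
    n_ch = probe.n_channels
    rows = ch.row.to_numpy()
    ys = ch.y.to_numpy()
    xs = ch.x.to_numpy()

    seq = np.random.SeedSequence(config.seed)
    rng_noise, rng_events, rng_units = (np.random.default_rng(s) for s in seq.spawn(3))

    data = np.zeros((n_ch, n_samples), dtype=np.float32)

    # (i) background noise, channel by channel (keeps peak memory flat)
    ripple_band_sd = 0.0
    if config.lfp_noise_rms > 0 or config.ap_noise_rms > 0:
        for i in range(n_ch):
            data[i] += _shaped_noise(
                rng_noise, n_samples, fs, config.lfp_noise_rms, config.ap_noise_rms
            ).astype(np.float32)
        # ripple-band noise floor, for SNR-referenced ripple amplitudes
        nyq = fs / 2
        sos = signal.butter(2, [80 / nyq, min(250, 0.9 * nyq) / nyq], "bandpass", output="sos")
        ripple_band_sd = float(signal.sosfiltfilt(sos, np.asarray(data[0], dtype=np.float64)).std())

    t = np.arange(n_samples) / fs

    # (ii) sharp-wave ripples
    ripple_events: list[tuple[float, float, float]] = []
    if config.ripple_rate > 0:
        half = config.ripple_duration_ms / 2000.0  # s
        peaks = _draw_event_times(rng_events, config.ripple_rate, config.duration, 6 * half + 0.3)
        env_sigma = half / 2  # the configured duration is the +-2 sigma support
        amp = config.ripple_snr * (ripple_band_sd if ripple_band_sd > 0 else 1.0)
        w_pyr = _layer_weight(rows, layers["pyramidale"])
        w_rad = _layer_weight(rows, layers["radiatum"])
        for pk in peaks:
            i0 = max(0, int((pk - 4 * half) * fs))
            i1 = min(n_samples, int((pk + 4 * half) * fs))
            tt = t[i0:i1] - pk
            carrier = np.cos(2 * np.pi * config.ripple_freq * tt)
            env = np.exp(-0.5 * (tt / env_sigma) ** 2)
            ripple = (amp * env * carrier).astype(np.float32)
            spw = (-config.sharp_wave_amplitude * np.exp(-0.5 * (tt / (2 * env_sigma)) ** 2)).astype(
                np.float32
            )
            data[:, i0:i1] += np.outer(w_pyr, ripple).astype(np.float32)
            data[:, i0:i1] += np.outer(w_rad, spw).astype(np.float32)
            ripple_events.append((pk - half, pk, pk + half))

    # (iii) dentate spikes
    ds_times: list[float] = []
    if config.ds_rate > 0:
        half = config.ds_duration_ms / 2000.0
        peaks = _draw_event_times(rng_events, config.ds_rate, config.duration, 8 * half + 0.3)
        w_hil = _layer_weight(rows, layers["hilus"])
        w_mol = _layer_weight(rows, layers["molecular"])
        for pk in peaks:
            i0 = max(0, int((pk - 2 * half) * fs))
            i1 = min(n_samples, int((pk + 2 * half) * fs))
            tt = t[i0:i1] - pk
            # hilus: peaked pulse (well-defined peak time); molecular layer:
            # flat-topped pulse so its mean deflection tracks the configured
            # amplitude over the whole event
            hil_pulse = np.exp(-0.5 * (tt / (half / 2)) ** 2).astype(np.float32)
            mol_pulse = _tukey_pulse(tt, half).astype(np.float32)
            data[:, i0:i1] += np.outer(
                w_hil * (config.ds_hilus_amplitude_mv * 1000.0), hil_pulse
            ).astype(np.float32)
            data[:, i0:i1] -= np.outer(
                w_mol * (config.ds_molecular_amplitude_mv * 1000.0), mol_pulse
            ).astype(np.float32)
            ds_times.append(pk)

    # (iv) laminar gamma oscillations
    gamma_phase0: list[float] = []
    for g in config.gamma_specs:
        phi0 = float(rng_events.uniform(-np.pi, np.pi))
        gamma_phase0.append(phi0)
        w = _layer_weight(rows, g.rows)
        osc = (g.amplitude * np.cos(2 * np.pi * g.center_freq * t + phi0)).astype(np.float32)
        active = w > 0.01
        data[active] += np.outer(w[active], osc).astype(np.float32)

    # (v) unit spike trains + waveform footprints
    units: list[UnitGroundTruth] = []
    for uid, spec in enumerate(config.unit_specs):
        spikes = _draw_spike_train(spec, config, ripple_events, gamma_phase0, rng_units)
        _stamp_unit(data, spec, spikes, probe, xs, ys, fs, n_samples)
        units.append(
            UnitGroundTruth(
                unit_id=uid,
                spike_times=spikes,
                soma_channel=spec.soma_channel,
                slope_above=spec.slope_above,
                slope_below=spec.slope_below,
                kappa=spec.kappa,
                gamma_source=spec.gamma_source,
                preferred_phase=spec.preferred_phase,
                ripple_gain=spec.ripple_gain,
            )
        )

    segment = RecordingSegment(data, fs, ch.channel_id.to_numpy())
    truth = GroundTruth(
        ripples=ripple_events, ds_times=ds_times, units=units, gamma_phase0=gamma_phase0
    )
    return segment, truth


def _draw_spike_train(
    spec: UnitSpec,
    config: SimulationConfig,
    ripple_events: list[tuple[float, float, float]],
    gamma_phase0: list[float],
    rng: np.random.Generator,
) -> np.ndarray:
    duration = config.duration
    n_expect = spec.firing_rate * duration
    if n_expect <= 0:
        return np.array([])
    margin = 0.01  # keep waveforms clear of the recording edges
    if spec.kappa > 0 and spec.gamma_source is not None:
        # place spikes at von Mises phases of the designated gamma source
        f = config.gamma_specs[spec.gamma_source].center_freq
        phi0 = gamma_phase0[spec.gamma_source]
        n = rng.poisson(n_expect)
        theta = spike_phases_von_mises(n, spec.kappa, spec.preferred_phase, rng)
        n_cycles = max(int(np.floor((duration - 2 * margin) * f)), 1)
        cycles = rng.integers(0, n_cycles, size=n)
        # solve 2*pi*f*t + phi0 = theta (mod 2*pi), one solution per chosen cycle
        frac = (theta - phi0) % (2 * np.pi)
        spikes = (frac + 2 * np.pi * cycles) / (2 * np.pi * f)
        spikes = spikes[(spikes > margin) & (spikes < duration - margin)]
    else:
        n = rng.poisson(n_expect)
        spikes = rng.uniform(margin, duration - margin, size=n)
        if spec.ripple_gain > 1.0 and ripple_events:
            extra = []
            for start, _, end in ripple_events:
                lam = (spec.ripple_gain - 1.0) * spec.firing_rate * (end - start)
                k = rng.poisson(lam)
                extra.append(rng.uniform(start, end, size=k))
            spikes = np.concatenate([spikes] + extra)
    spikes = np.sort(spikes)
    if len(spikes) > 1:  # 1.5 ms refractory
        keep = np.concatenate([[True], np.diff(spikes) >= 0.0015])
        spikes = spikes[keep]
    return spikes


def _stamp_unit(
    data: np.ndarray,
    spec: UnitSpec,
    spikes: np.ndarray,
    probe: ProbeMap,
    xs: np.ndarray,
    ys: np.ndarray,
    fs: float,
    n_samples: int,
) -> None:
    if len(spikes) == 0:
        return
    soma = probe.channel(spec.soma_channel)
    sx, sy, sshank = float(soma.x), float(soma.y), int(soma.shank)
    shanks = probe.channels.shank.to_numpy()
    dist = np.hypot(xs - sx, ys - sy)
    amps = spec.peak_amplitude * np.exp(-dist / spec.amplitude_length_constant)
    stamp = (amps > 0.02 * spec.peak_amplitude) & (shanks == sshank)
    pre_ms, post_ms = 1.5, max(2.5, spec.trough_to_peak + 1.5)
    win = int(round((pre_ms + post_ms) / 1000 * fs))
    for i in np.flatnonzero(stamp):
        dy = ys[i] - sy  # positive below the soma
        slope = spec.slope_below if dy > 0 else spec.slope_above
        delay_ms = slope * abs(dy) / 1000.0
        t_trough = spikes + delay_ms / 1000.0
        starts = np.round((t_trough - pre_ms / 1000.0) * fs).astype(np.int64)
        offs = np.arange(win)
        idx = starts[:, None] + offs[None, :]
        valid = (idx[:, 0] >= 0) & (idx[:, -1] < n_samples)
        if not valid.any():
            continue
        idx = idx[valid]
        tm = (idx / fs - t_trough[valid, None]) * 1000.0  # ms relative to trough
        wave = amps[i] * _spike_template(tm, spec.trough_to_peak)
        np.add.at(data[i], idx.ravel(), wave.ravel().astype(np.float32))


# ---------------------------------------------------------------------------
# on-disk outputs
# ---------------------------------------------------------------------------

def write_recording(
    segment: RecordingSegment,
    binary_path: str | Path,
    sidecar_path: str | Path,
    gain_uv_per_bit: float = 0.2,
    extra_meta: dict | None = None,
) -> None:
    """Write int16 flat binary (channel-major frames) + JSON sidecar."""
    quant = np.clip(
        np.round(segment.data / gain_uv_per_bit), -32768, 32767
    ).astype("<i2")
    # frame order: sample-major, channels interleaved within a frame
    quant.T.tofile(str(binary_path))
    meta = {
        "sampling_rate": segment.sampling_rate,
        "n_channels": segment.n_channels,
        "gain_uv_per_bit": gain_uv_per_bit,
        "dtype": "int16",
        "channel_ids": segment.channel_ids.tolist(),
    }
    if extra_meta:
        meta.update(extra_meta)
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def write_spike_table(truth: GroundTruth, path: str | Path) -> None:
    """Two-column CSV (time_s, unit_id), sorted by time."""
    rows = [
        (float(ts), u.unit_id) for u in truth.units for ts in np.asarray(u.spike_times)
    ]
    df = pd.DataFrame(rows, columns=["time_s", "unit_id"]).sort_values("time_s")
    df.to_csv(path, index=False)


def read_spike_table(path: str | Path) -> dict[int, np.ndarray]:
    """Spike table CSV -> {unit_id: sorted spike times (s)}."""
    df = pd.read_csv(path)
    return {
        int(uid): np.sort(sub.time_s.to_numpy())
        for uid, sub in df.groupby("unit_id")
    }
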