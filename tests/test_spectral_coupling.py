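"""Instantaneous phase, PLV calibration and maps, gamma coherence."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import iv

from hippomap import (
    instantaneous_phase,
    plv,
    plv_map,
    select_swr_intervals,
    spike_phases_von_mises,
)
from hippomap.core import EventSet, RecordingSegment
from hippomap.spectral_coupling import (
    PLVMap,
    coherence_map,
    decimate_segment,
    rayleigh_null_floor,
    smooth_plv_map,
)
from hippomap.synthetic import _band_limited_noise


class TestInstantaneousPhase:
    fs = 2000.0

    def test_pure_tone_phase_slope(self):
        t = np.arange(int(20 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 60.0 * t)
        phase = np.unwrap(instantaneous_phase(x, self.fs, 60.0))
        core = slice(2000, -2000)
        slope = np.polyfit(t[core], phase[core], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 60.0, rel=0.001)

    def test_amplitude_invariance(self):
        t = np.arange(int(10 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 60.0 * t)
        a = instantaneous_phase(x, self.fs, 60.0)
        b = instantaneous_phase(2 * x, self.fs, 60.0)
        assert np.allclose(a, b, atol=1e-9)

    def test_filter_selectivity_two_tones(self):
        t = np.arange(int(20 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 60.0 * t) + 2.0 * np.sin(2 * np.pi * 200.0 * t)
        phase = np.unwrap(instantaneous_phase(x, self.fs, 60.0, bandwidth=5.0))
        core = slice(2000, -2000)
        slope = np.polyfit(t[core], phase[core], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 60.0, rel=0.001)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(1000), 100.0, 49.0, bandwidth=5.0)


class TestPlv:
    def test_identical_phases_give_one(self):
        phase = np.full(1000, 0.4)
        spikes = np.arange(10) * 0.01
        assert plv(spikes, phase, 1000.0) == pytest.approx(1.0)

    def test_symmetric_phases_cancel(self):
        phase = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        spikes = np.array([0.0, 0.001, 0.002, 0.003])
        assert plv(spikes, phase, 1000.0) == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_kappa_two(self, rng):
        phases = spike_phases_von_mises(200_000, 2.0, rng=rng)
        spikes = np.arange(200_000) * 1e-3
        assert plv(spikes, phases, 1000.0) == pytest.approx(
            iv(1, 2.0) / iv(0, 2.0), abs=0.005
        )

    def test_no_spikes_in_span_rejected(self):
        with pytest.raises(ValueError, match="no spikes"):
            plv(np.array([99.0]), np.zeros(1000), 1000.0)


class TestPlvMap:
    def test_locked_unit_peaks_at_source(self, gamma_recording):
        """A kappa=3 unit locked to a 60 Hz source on rows 8-12 peaks there."""
        probe, _, segment, truth = gamma_recording
        seg = decimate_segment(segment, 10)
        freqs = np.arange(30.0, 200.1, 5.0)
        m = plv_map(truth.units[0].spike_times, seg, probe, freqs_hz=freqs)
        ci, fi = np.unravel_index(np.argmax(m.values), m.values.shape)
        assert freqs[fi] == 60.0
        row = int(probe.channel(int(m.channel_ids[ci])).row)
        assert 8 <= row <= 12
        expected = iv(1, 3.0) / iv(0, 3.0)
        assert m.values[ci, fi] == pytest.approx(expected, abs=0.07)

    def test_uncoupled_unit_stays_under_null_floor(self, gamma_recording):
        probe, _, segment, truth = gamma_recording
        seg = decimate_segment(segment, 10)
        m = plv_map(truth.units[1].spike_times, seg, probe,
                    freqs_hz=np.arange(30.0, 200.1, 5.0))
        floor = rayleigh_null_floor(m.n_spikes, n_comparisons=m.values.size)
        assert m.values.max() < floor

    def test_too_few_spikes_refused(self, gamma_recording):
        probe, _, segment, _ = gamma_recording
        with pytest.raises(ValueError, match="spikes"):
            plv_map(np.array([1.0, 2.0]), segment, probe)

    def test_smoothing_preserves_constant_maps(self, gamma_recording):
        probe, _, _, _ = gamma_recording
        values = np.full((probe.n_channels, 3), 0.42)
        m = PLVMap(values=values, channel_ids=probe.channels.channel_id.to_numpy(),
                   freqs_hz=np.array([40.0, 60.0, 80.0]), n_spikes=500)
        sm = smooth_plv_map(m, probe)
        assert np.allclose(sm.values, 0.42)
        assert sm.smoothed

    def test_bounds_and_scale_invariance(self, gamma_recording):
        probe, _, segment, truth = gamma_recording
        seg = decimate_segment(segment, 10)
        freqs = np.array([60.0])
        m1 = plv_map(truth.units[0].spike_times, seg, probe, freqs_hz=freqs)
        assert np.all((m1.values >= 0) & (m1.values <= 1))
        scaled = RecordingSegment(seg.data * 5.0, seg.sampling_rate, seg.channel_ids)
        m2 = plv_map(truth.units[0].spike_times, scaled, probe, freqs_hz=freqs)
        assert np.allclose(m1.values, m2.values, atol=1e-7)


def _event_set(peaks):
    df = pd.DataFrame({
        "start_s": np.asarray(peaks) - 0.02,
        "peak_s": peaks,
        "end_s": np.asarray(peaks) + 0.02,
        "score": 5.0,
    })
    return EventSet(df, label="ripple")


class TestIntervalSelection:
    def test_plenty_of_ripples_give_requested_count(self):
        events = _event_set(1.0 + np.arange(150) * 1.5)
        got = select_swr_intervals(events, n=100, duration_s=1.0)
        assert len(got) == 100
        assert got[0][0] == pytest.approx(0.5)

    def test_shortage_warns(self):
        events = _event_set(np.array([1.0, 3.0, 5.0]))
        with pytest.warns(UserWarning, match="3 of the requested"):
            got = select_swr_intervals(events, n=100)
        assert len(got) == 3

    def test_overlap_rejected(self):
        events = _event_set(np.array([2.0, 2.4]))
        with pytest.warns(UserWarning):
            got = select_swr_intervals(events, n=100)
        assert len(got) == 1

    def test_empty_rejected(self):
        empty = EventSet(pd.DataFrame(columns=["start_s", "peak_s", "end_s", "score"]))
        with pytest.raises(ValueError, match="empty"):
            select_swr_intervals(empty)


@pytest.fixture(scope="module")
def shared_source_segment():
    rng = np.random.default_rng(0)
    fs = 2000.0
    n = int(fs * 125)
    common = _band_limited_noise(rng, n, fs, (25.0, 95.0), 10.0)
    data = np.vstack([
        common + _band_limited_noise(rng, n, fs, (1.0, 900.0), 1.0),
        common + _band_limited_noise(rng, n, fs, (1.0, 900.0), 1.0),
        _band_limited_noise(rng, n, fs, (1.0, 900.0), 10.0),
        _band_limited_noise(rng, n, fs, (1.0, 900.0), 10.0),
    ])
    return RecordingSegment(data.astype(np.float32), fs)


@pytest.fixture(scope="module")
def intervals():
    return [(i * 1.2 + 0.1, i * 1.2 + 1.1) for i in range(100)]


class TestCoherence:
    def test_self_coherence_is_one(self, shared_source_segment, intervals):
        m = coherence_map(shared_source_segment, 0, (30.0, 90.0), intervals)
        assert m.values[0] == 1.0

    def test_shared_source_high_coherence(self, shared_source_segment, intervals):
        m = coherence_map(shared_source_segment, 0, (30.0, 90.0), intervals)
        assert m.values[1] > 0.9

    def test_independent_channels_low_coherence(self, shared_source_segment, intervals):
        m = coherence_map(shared_source_segment, 0, (30.0, 90.0), intervals)
        assert m.values[2] < 0.1 and m.values[3] < 0.1

    def test_symmetry(self, shared_source_segment, intervals):
        a = coherence_map(shared_source_segment, 0, (30.0, 90.0), intervals)
        b = coherence_map(shared_source_segment, 1, (30.0, 90.0), intervals)
        assert a.values[1] == pytest.approx(b.values[0], abs=1e-9)

    def test_fewer_than_two_intervals_rejected(self, shared_source_segment):
        with pytest.raises(ValueError, match="2 intervals"):
            coherence_map(shared_source_segment, 0, (30.0, 90.0), [(0.0, 1.0)])

    def test_short_interval_rejected(self, shared_source_segment):
        with pytest.raises(ValueError, match="0.5"):
            coherence_map(shared_source_segment, 0, (30.0, 90.0),
                          [(0.0, 0.3), (1.0, 2.0)])

    def test_values_bounded(self, shared_source_segment, intervals):
        m = coherence_map(shared_source_segment, 0, (30.0, 90.0), intervals)
        assert np.all((m.values >= 0) & (m.values <= 1))
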