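"""Waveform metrics, ACG fits, the cell-type cascade, bursts, PSTHs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippomap import (
    SimulationConfig,
    UnitSpec,
    build_probe_map,
    burst_fraction,
    classify_cell_type,
    compute_footprint,
    detect_bursts,
    estimate_soma_channel,
    fit_acg_triple_exponential,
    peri_event_histogram,
    simulate_recording,
    trough_to_peak,
)
from hippomap.unit_metrics import UnitFootprint


def _footprint(waveforms, fs=20000.0, channel_ids=None):
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    ids = np.arange(w.shape[0]) if channel_ids is None else np.asarray(channel_ids)
    return UnitFootprint(unit_id=0, waveform=w, channel_ids=ids,
                         sampling_rate=fs, trough_sample=int(np.argmin(w[0])))


class TestTroughToPeak:
    def test_constructed_waveform(self):
        """Trough at 1.0 ms, peak at 1.3 ms -> 0.3 ms."""
        fs = 20000.0
        t = np.arange(int(0.003 * fs)) / fs * 1000.0
        w = -np.exp(-0.5 * ((t - 1.0) / 0.08) ** 2) + 0.5 * np.exp(
            -0.5 * ((t - 1.3) / 0.1) ** 2
        )
        assert trough_to_peak(_footprint(w, fs)) == pytest.approx(0.3, abs=1000.0 / fs)

    def test_trough_at_window_end_errors(self):
        w = -np.arange(60.0)  # monotonically descending: trough at the end
        with pytest.raises(ValueError, match="post-trough"):
            trough_to_peak(_footprint(w))

    def test_generator_round_trip(self):
        probe = build_probe_map(n_shanks=1, rows_per_shank=8)
        unit = UnitSpec(soma_channel=4, trough_to_peak=0.5, firing_rate=10.0)
        config = SimulationConfig(duration=10.0, seed=6, probe=probe, layer_rows={},
                                  unit_specs=[unit])
        segment, truth = simulate_recording(config)
        fp = compute_footprint(segment, truth.units[0].spike_times)
        fs = segment.sampling_rate
        assert trough_to_peak(fp) == pytest.approx(0.5, abs=2 * 1000.0 / fs)


class TestAcgFit:
    def test_poisson_train_small_rise_flat_asymptote(self, rng):
        t = np.sort(rng.uniform(0, 600.0, size=6000))  # ~10 Hz Poisson
        fit = fit_acg_triple_exponential(t)
        assert fit.converged
        assert fit.tau_rise < 3.0
        expected_per_bin = 6000 * 10.0 * 0.5e-3  # rate x bin width x n spikes
        plateau = fit.curve(np.array([40.0, 45.0, 50.0])).mean()
        assert plateau == pytest.approx(expected_per_bin, rel=0.25)

    def test_slow_recovery_train_has_slow_rise(self, rng):
        """A renewal train whose rate recovers with a ~12 ms time constant
        after each spike produces an ACG rise time beyond 6 ms."""
        rate, tau_rec = 25.0, 0.012
        t, last = [], -10.0
        for x in np.cumsum(rng.exponential(1 / rate, size=60000)):
            if rng.uniform() < 1.0 - np.exp(-(x - last) / tau_rec):
                t.append(x)
                last = x
        fit = fit_acg_triple_exponential(np.array(t))
        assert fit.converged
        assert fit.tau_rise > 6.0

    def test_deterministic_fit(self, rng):
        t = np.sort(rng.uniform(0, 300.0, size=3000))
        a = fit_acg_triple_exponential(t)
        b = fit_acg_triple_exponential(t)
        assert a.tau_rise == b.tau_rise and a.tau_decay == b.tau_decay

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError, match="500"):
            fit_acg_triple_exponential(np.arange(100) * 0.1)


class TestCellTypeCascade:
    @pytest.mark.parametrize(
        "t2p, rise, expected",
        [
            (0.30, 2.0, "narrow_interneuron"),
            (0.50, 7.0, "wide_interneuron"),
            (0.50, 3.0, "pyramidal"),
            (0.424, 99.0, "narrow_interneuron"),  # t2p rule wins first
            (0.425, 6.0, "pyramidal"),  # boundary: rise must exceed 6
            (0.60, np.nan, "pyramidal"),  # failed fit falls through
        ],
    )
    def test_truth_table(self, t2p, rise, expected):
        assert classify_cell_type(t2p, rise).label == expected

    def test_every_unit_gets_exactly_one_label(self, rng):
        labels = {
            classify_cell_type(t2p, rise).label
            for t2p, rise in zip(rng.uniform(0.1, 1.0, 300), rng.uniform(0, 20, 300))
        }
        assert labels <= {"narrow_interneuron", "wide_interneuron", "pyramidal"}


def _brute_force_bursts(times_ms, max_isi=9.0):
    runs, current = [], [0]
    for i in range(1, len(times_ms)):
        if times_ms[i] - times_ms[i - 1] < max_isi:
            current.append(i)
        else:
            if len(current) >= 2:
                runs.append(current)
            current = [i]
    if len(current) >= 2:
        runs.append(current)
    return runs


class TestBursts:
    def test_pair_is_one_burst(self):
        bursts = detect_bursts(np.array([0.0, 5.0, 50.0]) / 1000.0)
        assert len(bursts) == 1 and list(bursts[0]) == [0, 1]

    def test_slow_train_has_none(self):
        assert detect_bursts(np.array([0.0, 20.0, 40.0]) / 1000.0) == []

    def test_chained_isis_form_one_burst(self):
        bursts = detect_bursts(np.array([0.0, 5.0, 8.0, 100.0]) / 1000.0)
        assert len(bursts) == 1 and list(bursts[0]) == [0, 1, 2]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            detect_bursts(np.array([0.010, 0.005]))

    def test_matches_brute_force_on_1000_random_trains(self, rng):
        for _ in range(1000):
            n = rng.integers(2, 60)
            t_ms = np.sort(rng.uniform(0, n * rng.uniform(4, 25), size=n))
            got = [list(b) for b in detect_bursts(t_ms / 1000.0)]
            assert got == _brute_force_bursts(t_ms)

    def test_burst_fraction_accounting(self):
        t = np.array([0.0, 5.0, 8.0, 100.0, 200.0]) / 1000.0
        assert burst_fraction(t) == pytest.approx(3 / 5)


class TestSomaLocalisation:
    probe = build_probe_map(n_shanks=1, rows_per_shank=16)

    def test_generator_round_trip(self):
        soma = self.probe.channel_at(0, 5, 1)
        unit = UnitSpec(soma_channel=soma, firing_rate=10.0)
        config = SimulationConfig(duration=10.0, seed=8, probe=self.probe,
                                  layer_rows={}, unit_specs=[unit])
        segment, truth = simulate_recording(config)
        fp = compute_footprint(segment, truth.units[0].spike_times)
        ch, (x, y) = estimate_soma_channel(fp, self.probe)
        assert ch == soma
        assert (x, y) == self.probe.position(soma)

    def test_tie_break_lowest_id(self):
        w = np.zeros((4, 40))
        w[1, 10], w[1, 20] = -50.0, 30.0
        w[3] = w[1]
        fp = _footprint(w, channel_ids=np.array([4, 7, 9, 12]))
        assert fp.peak_channel == 7

    def test_scale_invariance(self):
        w = np.zeros((3, 40))
        w[2, 10] = -50.0
        assert _footprint(w).peak_channel == _footprint(2 * w).peak_channel

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            _footprint(np.zeros((3, 40))).peak_channel


class TestPeriEventHistogram:
    def test_poisson_spikes_give_flat_rate(self, rng):
        lam = 20.0
        spikes = np.sort(rng.uniform(0, 500.0, size=int(500 * lam)))
        events = rng.uniform(10.0, 490.0, size=300)
        _, rate = peri_event_histogram(spikes, events, (-500.0, 500.0), 50.0)
        sigma = np.sqrt(lam / (len(events) * 0.050))  # Poisson SE per bin
        assert rate.mean() == pytest.approx(lam, rel=0.03)
        assert np.max(np.abs(rate - lam)) < 5 * sigma

    def test_delta_locked_spikes(self):
        events = np.arange(1.0, 50.0)
        _, rate = peri_event_histogram(events.copy(), events, (-50.0, 50.0), 10.0)
        peak_bin = np.argmax(rate)
        assert rate[peak_bin] == pytest.approx(1.0 / 0.010)
        assert rate[peak_bin - 1] == 0.0

    def test_ripple_gain_recovered(self, event_recording, probe64):
        """A unit with 3x rate gain inside ripples shows ~3x in-event rate."""
        config, _, truth = event_recording
        gain_unit = UnitSpec(soma_channel=0, firing_rate=8.0, ripple_gain=3.0)
        cfg = SimulationConfig(
            duration=config.duration, seed=31, probe=probe64,
            ripple_rate=config.ripple_rate, unit_specs=[gain_unit],
        )
        _, truth2 = simulate_recording(cfg)
        spikes = truth2.units[0].spike_times
        peaks = np.array([p for (_, p, _) in truth2.ripples])
        centers, rate = peri_event_histogram(spikes, peaks, (-500.0, 500.0), 20.0)
        inside = np.abs(centers) <= 20.0
        outside = np.abs(centers) >= 300.0
        ratio = rate[inside].mean() / rate[outside].mean()
        assert ratio == pytest.approx(3.0, rel=0.35)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            peri_event_histogram(np.array([1.0]), np.array([]), (-100.0, 100.0), 10.0)

    def test_non_tiling_bins_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            peri_event_histogram(np.array([1.0]), np.array([0.5]), (-100.0, 100.0), 33.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_histogram_mass_equals_mean_spikes_per_window(self, seed):
        rng = np.random.default_rng(seed)
        spikes = np.sort(rng.uniform(0, 60.0, size=rng.integers(1, 400)))
        events = rng.uniform(1.0, 59.0, size=rng.integers(1, 20))
        _, rate = peri_event_histogram(spikes, events, (-200.0, 200.0), 20.0)
        mass = rate.sum() * 0.020 / 1.0
        per_window = np.mean(
            [((spikes > e - 0.2) & (spikes <= e + 0.2)).sum() for e in events]
        )
        assert mass * len(events) / len(events) == pytest.approx(per_window, abs=1e-9)
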