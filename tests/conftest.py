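"""Shared fixtures: session-scoped synthetic recordings reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from hippomap import (
    GammaSpec,
    SimulationConfig,
    UnitSpec,
    build_probe_map,
    simulate_recording,
)
from hippomap.synthetic import default_layer_rows


@pytest.fixture(scope="session")
def probe64():
    """One shank with the full 64-row column pair."""
    return build_probe_map(n_shanks=1, rows_per_shank=64)


@pytest.fixture(scope="session")
def layers64():
    return default_layer_rows(64)


@pytest.fixture(scope="session")
def event_recording(probe64):
    """60 s single-shank recording with 20 ripples and 12 dentate spikes.

    Ripples are injected at 6x the ripple-band noise SD; dentate spikes at
    the default 0.4 mV hilar / 0.3 mV molecular amplitudes.
    """
    config = SimulationConfig(
        duration=60.0,
        seed=11,
        probe=probe64,
        ripple_rate=20 / 60.0,
        ripple_snr=6.0,
        ds_rate=12 / 60.0,
    )
    segment, truth = simulate_recording(config)
    return config, segment, truth


@pytest.fixture(scope="session")
def pyramidale_channel(probe64, layers64):
    lo, hi = layers64["pyramidale"]
    return probe64.channel_at(0, (lo + hi) // 2, 0)


@pytest.fixture(scope="session")
def dg_channels(probe64, layers64):
    """(hilus, molecular) detection channel pair."""
    channels = []
    for name in ("hilus", "molecular"):
        lo, hi = layers64[name]
        channels.append(probe64.channel_at(0, (lo + hi) // 2, 0))
    return tuple(channels)


@pytest.fixture(scope="session")
def weak_ds_recording(probe64):
    """30 s recording whose dentate spikes have only a 0.10 mV molecular
    deflection — below the 0.19 mV inclusion criterion."""
    config = SimulationConfig(
        duration=30.0,
        seed=12,
        probe=probe64,
        ds_rate=6 / 30.0,
        ds_molecular_amplitude_mv=0.10,
    )
    segment, truth = simulate_recording(config)
    return config, segment, truth


BACKPROP_SLOPES = [
    (0.0, 0.2), (0.0, 0.5), (0.0, 1.0), (0.0, 2.0),
    (0.2, 0.0), (0.5, 0.0), (1.0, 0.0), (2.0, 0.0),
]


@pytest.fixture(scope="session")
def backprop_recording():
    """45 s battery of units spanning slopes 0.2-2 ms/mm in both directions
    at AP-band SNR 10 (peak-to-peak amplitude 10x the 6.67 uV AP noise)."""
    probe = build_probe_map(n_shanks=1, rows_per_shank=40)
    units = [
        UnitSpec(
            soma_channel=probe.channel_at(0, 14 + i, 0),
            peak_amplitude=10 * 6.67,
            slope_above=sa,
            slope_below=sb,
            firing_rate=12.0,
        )
        for i, (sa, sb) in enumerate(BACKPROP_SLOPES)
    ]
    config = SimulationConfig(duration=45.0, seed=21, probe=probe,
                              unit_specs=units, layer_rows={})
    segment, truth = simulate_recording(config)
    return probe, config, segment, truth


@pytest.fixture(scope="session")
def gamma_recording():
    """20 s two-shank recording with a 60 Hz gamma source on rows 8-12 of
    both shanks, one strongly locked unit (kappa = 3) and one uncoupled."""
    probe = build_probe_map(n_shanks=2, rows_per_shank=16)
    gamma = [GammaSpec(center_freq=60.0, amplitude=25.0, rows=(8, 12))]
    units = [
        UnitSpec(soma_channel=probe.channel_at(0, 4, 0), firing_rate=25.0,
                 kappa=3.0, gamma_source=0, preferred_phase=1.0),
        UnitSpec(soma_channel=probe.channel_at(0, 6, 0), firing_rate=25.0),
    ]
    config = SimulationConfig(duration=20.0, seed=4, probe=probe,
                              unit_specs=units, gamma_specs=gamma, layer_rows={})
    segment, truth = simulate_recording(config)
    return probe, config, segment, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
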