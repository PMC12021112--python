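"""End-to-end orchestration: config, recording IO, staged runs, manifest.

A run executes the enabled stages in dependency order — event detection,
triggered averages / CSD, unit metrics, backpropagation, coupling maps —
writing each artifact plus a JSON manifest (package version, parameter
echo, input checksums, per-stage status and counts). Re-running on the
same inputs and seed reproduces byte-identical event tables and metric
CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .backpropagation import analyze_backpropagation, backprop_table
from .core import RecordingSegment
from .csd import compute_csd, event_triggered_average
from .event_detection import (
    DentateSpikeParams,
    RippleDetectionParams,
    detect_dentate_spikes,
    detect_ripples,
)
from .probe_geometry import ProbeMap, read_probe_map, write_probe_map
from .spectral_coupling import (
    coherence_map,
    decimate_segment,
    plv_map,
    select_swr_intervals,
)
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    read_spike_table,
    simulate_recording,
    write_recording,
    write_spike_table,
)
from .unit_metrics import compute_footprint, unit_metrics_table

__all__ = ["PipelineConfig", "run_pipeline", "read_recording", "simulate_to_dir"]

logger = logging.getLogger("hippomap")


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Structured per-stage log lines to stderr and optionally a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    logger.setLevel(level)
    logger.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


# ---------------------------------------------------------------------------
# recording IO
# ---------------------------------------------------------------------------

def read_recording(binary_path: str | Path, sidecar_path: str | Path) -> RecordingSegment:
    """Flat int16 binary + JSON sidecar -> RecordingSegment in uV."""
    meta = json.loads(Path(sidecar_path).read_text())
    n_ch = int(meta["n_channels"])
    frame_bytes = 2 * n_ch
    size = Path(binary_path).stat().st_size
    if size % frame_bytes:
        raise ValueError(
            f"corrupt recording {binary_path}: {size} bytes is not a multiple "
            f"of the {frame_bytes}-byte frame ({n_ch} int16 channels)"
        )
    raw = np.fromfile(str(binary_path), dtype="<i2").reshape(-1, n_ch).T
    gain = float(meta["gain_uv_per_bit"])
    return RecordingSegment(
        (raw * gain).astype(np.float32),
        float(meta["sampling_rate"]),
        np.asarray(meta.get("channel_ids", np.arange(n_ch)), dtype=int),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths, stage toggles and per-stage parameters for one run."""

    recording: str
    sidecar: str
    probe_map: str
    spike_table: str | None = None
    output_dir: str = "hippomap_out"
    seed: int = 0

    # stage toggles
    run_ripples: bool = True
    run_dentate_spikes: bool = True
    run_csd: bool = True
    run_unit_metrics: bool = True
    run_backprop: bool = True
    run_plv: bool = False
    run_coherence: bool = True

    # stage parameters
    ripple_channel: int | None = None
    ripple_params: RippleDetectionParams = field(default_factory=RippleDetectionParams)
    hilus_channel: int | None = None
    molecular_channel: int | None = None
    ds_params: DentateSpikeParams = field(default_factory=DentateSpikeParams)
    csd_window_ms: tuple[float, float] = (-100.0, 100.0)
    csd_shank: int = 0
    csd_column: int = 0
    plv_unit: int | None = None
    plv_fmin: float = 30.0
    plv_fmax: float = 200.0
    plv_decimate: int = 10
    coherence_reference: int | None = None
    coherence_band: tuple[float, float] = (30.0, 90.0)
    coherence_n_intervals: int = 100
    min_spikes_acg: int = 500

    def validate(self) -> None:
        for name in ("recording", "sidecar", "probe_map"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file {p!r} does not exist")
        if self.spike_table is not None and not Path(self.spike_table).exists():
            raise FileNotFoundError(f"spike_table file {self.spike_table!r} does not exist")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the run manifest.

    A failed stage is recorded in the manifest and aborts its dependents
    while independent stages still complete.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_jsonable(),
        "inputs": {
            "recording": _sha256(Path(config.recording)),
            "sidecar": _sha256(Path(config.sidecar)),
            "probe_map": _sha256(Path(config.probe_map)),
        },
        "stages": {},
    }
    if config.spike_table:
        manifest["inputs"]["spike_table"] = _sha256(Path(config.spike_table))

    segment = read_recording(config.recording, config.sidecar)
    probe = read_probe_map(config.probe_map)
    spikes = read_spike_table(config.spike_table) if config.spike_table else {}

    def _stage(name: str, enabled: bool, deps_ok: bool, fn):
        rec: dict = {"status": "skipped"}
        result = None
        if enabled and not deps_ok:
            rec = {"status": "aborted", "reason": "dependency failed"}
        elif enabled:
            t0 = time.monotonic()
            try:
                result, counts = fn()
                rec = {"status": "complete", "wall_s": round(time.monotonic() - t0, 3)}
                rec.update(counts)
                logger.info("stage=%s status=complete %s", name, counts)
            except Exception as exc:  # noqa: BLE001 - recorded, run continues
                rec = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
                logger.error("stage=%s status=failed error=%s", name, exc)
        manifest["stages"][name] = rec
        return result, rec["status"] == "complete"

    # --- event detection
    def _ripples():
        ch = config.ripple_channel
        if ch is None:
            raise ValueError("ripple_channel is required for ripple detection")
        ev = detect_ripples(segment, ch, config.ripple_params)
        ev.to_csv(out_dir / "ripples.csv")
        return ev, {"n_events": len(ev)}

    ripples, ripples_ok = _stage("ripples", config.run_ripples, True, _ripples)

    def _ds():
        if config.hilus_channel is None or config.molecular_channel is None:
            raise ValueError("hilus_channel and molecular_channel are required")
        ev = detect_dentate_spikes(
            segment, config.hilus_channel, config.molecular_channel, config.ds_params
        )
        ev.to_csv(out_dir / "dentate_spikes.csv")
        return ev, {"n_events": len(ev)}

    _stage("dentate_spikes", config.run_dentate_spikes, True, _ds)

    # --- triggered average + CSD (depends on ripples)
    def _csd():
        avg = event_triggered_average(
            segment, ripples.peak_times, config.csd_window_ms,
            probe.column_channels(config.csd_shank, config.csd_column),
        )
        m = compute_csd(avg, probe, config.csd_shank, config.csd_column)
        avg.to_hdf5(out_dir / "ripple_triggered_lfp.h5")
        m.to_hdf5(out_dir / "ripple_triggered_csd.h5")
        return m, {"n_events": avg.n_events}

    _stage("csd", config.run_csd, ripples_ok and ripples is not None and len(ripples) > 0, _csd)

    # --- unit metrics (needs spike table)
    footprints = None

    def _units():
        nonlocal footprints
        footprints = [
            compute_footprint(segment, st, unit_id=uid) for uid, st in sorted(spikes.items())
        ]
        table = unit_metrics_table(footprints, probe, config.min_spikes_acg)
        table.to_csv(out_dir / "unit_metrics.csv", index=False)
        return table, {"n_units": len(table)}

    _, units_ok = _stage("unit_metrics", config.run_unit_metrics and bool(spikes), True, _units)

    def _backprop():
        results = [analyze_backpropagation(fp, probe) for fp in footprints]
        table = backprop_table(results)
        table.to_csv(out_dir / "backpropagation.csv", index=False)
        return table, {"n_units": len(table)}

    _stage("backprop", config.run_backprop and bool(spikes), units_ok, _backprop)

    # --- coupling maps
    def _plv():
        uid = config.plv_unit if config.plv_unit is not None else sorted(spikes)[0]
        seg = decimate_segment(segment, config.plv_decimate)
        freqs = np.arange(config.plv_fmin, config.plv_fmax + 1e-9, 5.0)
        m = plv_map(spikes[uid], seg, probe, freqs_hz=freqs)
        m.to_hdf5(out_dir / f"plv_unit{uid}.h5")
        return m, {"n_spikes": m.n_spikes}

    _stage("plv", config.run_plv and bool(spikes), True, _plv)

    def _coherence():
        ref = config.coherence_reference
        if ref is None:
            raise ValueError("coherence_reference channel is required")
        intervals = select_swr_intervals(
            ripples, n=config.coherence_n_intervals,
            recording_duration_s=segment.duration,
        )
        m = coherence_map(segment, ref, config.coherence_band, intervals)
        m.to_hdf5(out_dir / "coherence_map.h5")
        return m, {"n_intervals": m.n_intervals}

    _stage(
        "coherence", config.run_coherence,
        ripples_ok and ripples is not None and len(ripples) >= 2, _coherence,
    )

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# synthetic session on disk (used by `hippomap simulate` / `demo`)
# ---------------------------------------------------------------------------

def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a recording and write the full input file set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    segment, truth = simulate_recording(config)
    paths = {
        "recording": out / "recording.bin",
        "sidecar": out / "recording.json",
        "probe_map": out / "probe_map.json",
        "spike_table": out / "spikes.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_recording(segment, paths["recording"], paths["sidecar"],
                    extra_meta={"seed": config.seed})
    write_probe_map(config.resolved_probe(), paths["probe_map"])
    write_spike_table(truth, paths["spike_table"])
    truth.to_json(paths["ground_truth"])
    return paths


def load_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(path)
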