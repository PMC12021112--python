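"""Geometry of the 8-shank, 1024-channel electrode-pixel probe.

The probe is a lattice of 8 parallel shanks at 300 um pitch; each shank
carries 4 frontend modules of 32 electrode-pixels arranged as 2 columns x
64 rows with 30 um vertical pitch, 27 um column-center separation and
14 um square platinum contacts. Channels are numbered shank-major, then
row-major, then column. y = 0 is the topmost (most superficial) row and
increases toward the tip; x = 0 is shank 0's left column.

The builder generalises to smaller lattices (fewer shanks / rows) so that
synthetic studies can run on scaled-down probes with identical geometry
rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMap",
    "build_default_probe_map",
    "build_probe_map",
    "channels_within_radius",
    "read_probe_map",
    "write_probe_map",
    "export_prb",
    "module_throughput",
    "recording_span_um",
    "recording_area_mm2",
]

_CHANNEL_FIELDS = ["channel_id", "shank", "module", "row", "column", "x", "y"]

#: rows of electrode-pixels multiplexed into one output line per module
CHANNELS_PER_MODULE = 32


@dataclass(frozen=True)
class ProbeMap:
    """Per-channel lattice geometry.

    ``channels`` has one row per channel with columns channel_id, shank,
    module, row, column, x (um) and y (um, increasing toward the tip).
    """

    channels: pd.DataFrame
    pitch_um: float = 30.0
    shank_pitch_um: float = 300.0
    column_sep_um: float = 27.0
    electrode_size_um: float = 14.0
    _by_id: pd.DataFrame = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ch = pd.DataFrame(self.channels)[_CHANNEL_FIELDS].reset_index(drop=True)
        if ch.channel_id.duplicated().any():
            dup = int(ch.channel_id[ch.channel_id.duplicated()].iloc[0])
            raise ValueError(f"duplicate channel_id {dup} in probe map")
        triples = ch[["shank", "row", "column"]]
        if triples.duplicated().any():
            raise ValueError("duplicate (shank, row, column) triple in probe map")
        object.__setattr__(self, "channels", ch)
        object.__setattr__(self, "_by_id", ch.set_index("channel_id"))

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_shanks(self) -> int:
        return int(self.channels.shank.nunique())

    @property
    def rows_per_shank(self) -> int:
        return int(self.channels.row.nunique())

    def __contains__(self, channel_id: int) -> bool:
        return channel_id in self._by_id.index

    def channel(self, channel_id: int) -> pd.Series:
        try:
            return self._by_id.loc[channel_id]
        except KeyError:
            raise KeyError(f"channel id {channel_id} not in probe map") from None

    def position(self, channel_id: int) -> tuple[float, float]:
        rec = self.channel(channel_id)
        return float(rec.x), float(rec.y)

    def channel_at(self, shank: int, row: int, column: int) -> int:
        sel = self.channels[
            (self.channels.shank == shank)
            & (self.channels.row == row)
            & (self.channels.column == column)
        ]
        if sel.empty:
            raise KeyError(f"no channel at shank={shank}, row={row}, column={column}")
        return int(sel.channel_id.iloc[0])

    def column_channels(self, shank: int, column: int) -> np.ndarray:
        """Channel ids of one column of one shank, ordered top to tip."""
        sel = self.channels[(self.channels.shank == shank) & (self.channels.column == column)]
        if sel.empty:
            raise KeyError(f"no channels on shank {shank} column {column}")
        return sel.sort_values("y").channel_id.to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        return (
            self.channels.equals(other.channels)
            and self.pitch_um == other.pitch_um
            and self.shank_pitch_um == other.shank_pitch_um
            and self.column_sep_um == other.column_sep_um
            and self.electrode_size_um == other.electrode_size_um
        )


def build_probe_map(
    n_shanks: int = 8,
    rows_per_shank: int = 64,
    pitch_um: float = 30.0,
    shank_pitch_um: float = 300.0,
    column_sep_um: float = 27.0,
    electrode_size_um: float = 14.0,
    rows_per_module: int = 16,
) -> ProbeMap:
    """Build a regular two-column multi-shank lattice.

    Channel ordering is shank-major, then row-major, then column; the
    module index groups ``rows_per_module`` consecutive rows (32 channels
    per module with the default 16 rows x 2 columns).
    """
    if n_shanks < 1 or rows_per_shank < 1:
        raise ValueError("n_shanks and rows_per_shank must be >= 1")
    records = []
    cid = 0
    for shank in range(n_shanks):
        for row in range(rows_per_shank):
            for column in range(2):
                records.append(
                    {
                        "channel_id": cid,
                        "shank": shank,
                        "module": row // rows_per_module,
                        "row": row,
                        "column": column,
                        "x": shank * shank_pitch_um + column * column_sep_um,
                        "y": row * pitch_um,
                    }
                )
                cid += 1
    return ProbeMap(
        pd.DataFrame.from_records(records),
        pitch_um=pitch_um,
        shank_pitch_um=shank_pitch_um,
        column_sep_um=column_sep_um,
        electrode_size_um=electrode_size_um,
    )


def build_default_probe_map() -> ProbeMap:
    """The canonical 8-shank x 128-channel (1024 total) map."""
    return build_probe_map()


def channels_within_radius(
    probe: ProbeMap, center_channel: int, radius: float, same_shank: bool = True
) -> set[int]:
    """Channels whose axial (|dy|) distance from *center_channel* is <= radius.

    Always contains the center channel (and its same-row neighbours at
    dy = 0). With ``same_shank`` the search is restricted to the center
    channel's shank.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    rec = probe.channel(center_channel)
    ch = probe.channels
    mask = (ch.y - float(rec.y)).abs() <= radius
    if same_shank:
        mask &= ch.shank == int(rec.shank)
    return set(ch.channel_id[mask].astype(int))


# ---------------------------------------------------------------------------
# file IO: JSON dialect + PRB export
# ---------------------------------------------------------------------------

def write_probe_map(probe: ProbeMap, path: str | Path) -> None:
    payload = {
        "pitch_um": probe.pitch_um,
        "shank_pitch_um": probe.shank_pitch_um,
        "column_sep_um": probe.column_sep_um,
        "electrode_size_um": probe.electrode_size_um,
        "channels": probe.channels.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_probe_map(path: str | Path) -> ProbeMap:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"probe map {path}: not valid JSON ({exc})") from exc
    for key in ("pitch_um", "shank_pitch_um", "electrode_size_um", "channels"):
        if key not in payload:
            raise ValueError(f"probe map {path}: missing required key {key!r}")
    channels = payload["channels"]
    for i, entry in enumerate(channels):
        for fieldname in _CHANNEL_FIELDS:
            if fieldname not in entry:
                raise ValueError(f"probe map {path}: channel entry {i} missing {fieldname!r}")
            if not isinstance(entry[fieldname], (int, float)):
                raise ValueError(
                    f"probe map {path}: channel entry {i} key {fieldname!r} is non-numeric"
                )
    df = pd.DataFrame(channels)
    df[["channel_id", "shank", "module", "row", "column"]] = df[
        ["channel_id", "shank", "module", "row", "column"]
    ].astype(int)
    df[["x", "y"]] = df[["x", "y"]].astype(float)
    return ProbeMap(
        df,
        pitch_um=float(payload["pitch_um"]),
        shank_pitch_um=float(payload["shank_pitch_um"]),
        column_sep_um=float(payload.get("column_sep_um", 27.0)),
        electrode_size_um=float(payload["electrode_size_um"]),
    )


def export_prb(probe: ProbeMap, path: str | Path) -> None:
    """Export to the PRB group/geometry dialect used by sorting tools."""
    groups = {}
    for shank, sub in probe.channels.groupby("shank"):
        groups[int(shank)] = {
            "channels": sub.channel_id.astype(int).tolist(),
            "geometry": {
                int(r.channel_id): (float(r.x), float(r.y)) for r in sub.itertuples()
            },
        }
    Path(path).write_text("channel_groups = " + repr(groups) + "\n")


# ---------------------------------------------------------------------------
# probe accounting
# ---------------------------------------------------------------------------

def module_throughput(sampling_rate: float = 20000.0) -> float:
    """Multiplexed pixel throughput of one 32:1 frontend module (pixels/s)."""
    return CHANNELS_PER_MODULE * sampling_rate


def recording_span_um(probe: ProbeMap) -> tuple[float, float]:
    """Edge-to-edge (width, depth) span of the active area in um.

    Contact centers span (max - min) in each axis; the 14 um contact side
    is added to convert center span to edge span.
    """
    ch = probe.channels
    width = float(ch.x.max() - ch.x.min()) + probe.electrode_size_um
    depth = float(ch.y.max() - ch.y.min()) + probe.electrode_size_um
    return width, depth


def recording_area_mm2(probe: ProbeMap) -> float:
    """Active recording area (width x depth) in mm^2."""
    width, depth = recording_span_um(probe)
    return width * depth / 1e6
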