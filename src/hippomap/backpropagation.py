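"""Direction and speed of extracellular action-potential backpropagation.

Starting from a unit's multi-channel mean waveform, same-shank channels
within +-250 um axially of the dominant (soma) channel whose trough depth
exceeds 12% of the dominant trough are selected; per-channel trough times
are refined by 3-point parabolic interpolation (the 50 us sample period
would otherwise quantise delays coarsely against the 30 um pitch). Delays
are re-referenced to the earliest trough — that channel is the putative
AP initiation site — and delay (ms) vs |axial distance| (mm) is fitted by
ordinary least squares separately above and below the initiation site.
The slope is the inverse propagation speed in ms/mm. Cells are classified
ascending (above-side propagation only), descending (below only), curved
(both) or undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .probe_geometry import ProbeMap
from .unit_metrics import UnitFootprint

__all__ = [
    "BackpropResult",
    "detect_trough_channels",
    "fit_backprop_slopes",
    "classify_backprop",
    "analyze_backpropagation",
]

THRESHOLD_FRAC = 0.12
SEARCH_RADIUS_UM = 250.0
MIN_SIDE_CHANNELS = 3
#: slopes below a quarter sample period (at 20 kHz) across the 250 um
#: search radius are indistinguishable from simultaneous troughs
MIN_SLOPE_MS_PER_MM = 0.05


@dataclass
class BackpropResult:
    unit_id: int
    soma_channel: int
    initiation_channel: int
    trough_table: pd.DataFrame  # channel_id, trough_ms, amplitude, y_um, delay_ms
    slope_above: float  # ms/mm, NaN if the side was not fitted
    slope_below: float
    r2_above: float
    r2_below: float
    direction: str  # ascending | descending | curved | undetermined
    simultaneous: bool = False  # all passing troughs at the same time

    @property
    def speed_above(self) -> float:
        """mm/ms; inf when troughs are simultaneous (slope 0)."""
        return 1.0 / self.slope_above if self.slope_above else np.inf

    @property
    def speed_below(self) -> float:
        return 1.0 / self.slope_below if self.slope_below else np.inf


def _parabolic_trough(
    w: np.ndarray, fs: float, search: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Sub-sample trough time (ms) and depth via 3-point parabola.

    ``search`` restricts the trough to a sample range (the same AP as on
    the dominant channel, rather than any noise dip in the window).
    """
    if search is not None:
        lo = max(search[0], 0)
        hi = min(search[1], len(w))
        i = lo + int(np.argmin(w[lo:hi]))
    else:
        i = int(np.argmin(w))
    if 0 < i < len(w) - 1:
        y0, y1, y2 = w[i - 1], w[i], w[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        depth = y1 - 0.25 * (y0 - y2) * shift
    else:
        shift, depth = 0.0, w[i]
    return (i + shift) / fs * 1000.0, -float(depth)


def detect_trough_channels(
    footprint: UnitFootprint,
    probe: ProbeMap,
    threshold_frac: float = THRESHOLD_FRAC,
    radius_um: float = SEARCH_RADIUS_UM,
    trough_search_ms: float = 0.7,
) -> pd.DataFrame:
    """Above-threshold trough times/amplitudes near the dominant channel.

    Returns a table (channel_id, trough_ms, amplitude, y_um) of same-shank
    channels within +-radius axially whose trough depth exceeds
    ``threshold_frac`` x the dominant trough depth. Each channel's trough
    is searched within +-``trough_search_ms`` of the dominant trough so a
    weak channel's measurement tracks the same action potential.
    """
    soma = footprint.peak_channel
    soma_rec = probe.channel(soma)
    fs = footprint.sampling_rate
    soma_t_ms, soma_depth = _parabolic_trough(footprint.channel_waveform(soma), fs)
    half = int(round(trough_search_ms / 1000 * fs))
    center = int(round(soma_t_ms / 1000 * fs))
    search = (center - half, center + half + 1)
    rows = []
    for cid in footprint.channel_ids:
        if cid not in probe:
            continue
        rec = probe.channel(cid)
        if int(rec.shank) != int(soma_rec.shank):
            continue
        if abs(float(rec.y) - float(soma_rec.y)) > radius_um:
            continue
        t_ms, depth = _parabolic_trough(footprint.channel_waveform(cid), fs, search)
        if depth >= threshold_frac * soma_depth and depth > 0:
            rows.append((int(cid), t_ms, depth, float(rec.y)))
    table = pd.DataFrame(rows, columns=["channel_id", "trough_ms", "amplitude", "y_um"])
    assert (table.channel_id == soma).any(), "dominant channel must pass its own threshold"
    return table


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """slope, R^2 and one-sided p-value (slope > 0) of y ~ a + b x."""
    b, a = np.polyfit(x, y, 1)
    pred = a + b * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = len(x) - 2
    sxx = float(np.sum((x - x.mean()) ** 2))
    if dof <= 0 or sxx == 0:
        return float(b), r2, np.nan
    se = np.sqrt(ss_res / dof / sxx)
    if se == 0:  # perfect fit
        return float(b), r2, 0.0 if b > 0 else 1.0
    p_one_sided = float(stats.t.sf(b / se, dof))
    return float(b), r2, p_one_sided


def fit_backprop_slopes(
    trough_table: pd.DataFrame,
    soma_y_um: float,
    min_side_channels: int = MIN_SIDE_CHANNELS,
    alpha: float = 0.01,
    min_slope: float = MIN_SLOPE_MS_PER_MM,
) -> dict:
    """Per-side OLS of trough delay vs |axial distance| from the soma.

    Delays are re-referenced to the earliest trough (min delay 0); that
    channel is reported as the putative initiation site (ties: closest to
    the soma, then lowest id). The two fits split at the soma location —
    the regression intercept absorbs the re-referencing, so the slope is
    insensitive to which channel happened to fire earliest. A side is
    fitted only with >= ``min_side_channels`` channels (the soma row
    anchors both sides); a side is counted as propagating only if its
    slope is positive and significantly so (one-sided t-test, p < alpha),
    which keeps measurement jitter on a simultaneous side from
    masquerading as slow propagation.
    """
    tbl = trough_table.copy()
    t_min = tbl.trough_ms.min()
    tbl["delay_ms"] = tbl.trough_ms - t_min
    earliest = tbl[np.isclose(tbl.trough_ms, t_min)]
    earliest = earliest.assign(_soma_dist=(earliest.y_um - soma_y_um).abs())
    earliest = earliest.sort_values(["_soma_dist", "channel_id"])
    init = earliest.iloc[0]

    out = {
        "initiation_channel": int(init.channel_id),
        "table": tbl,
        "simultaneous": bool(np.allclose(tbl.delay_ms, 0.0)),
        "slope_above": np.nan, "r2_above": np.nan,
        "slope_below": np.nan, "r2_below": np.nan,
    }
    for side, mask in (
        ("above", tbl.y_um <= soma_y_um),  # smaller y = more superficial
        ("below", tbl.y_um >= soma_y_um),
    ):
        sub = tbl[mask]
        if len(sub) < min_side_channels:
            continue
        if np.allclose(sub.delay_ms, 0.0):
            # simultaneous troughs: infinite speed, reported as slope 0 but
            # not counted as propagation by the classifier
            out[f"slope_{side}"], out[f"r2_{side}"] = 0.0, 1.0
            continue
        dist_mm = (sub.y_um - soma_y_um).abs().to_numpy() / 1000.0
        slope, r2, p = _ols(dist_mm, sub.delay_ms.to_numpy())
        if slope < min_slope or not (p < alpha):
            continue
        out[f"slope_{side}"] = slope
        out[f"r2_{side}"] = r2
    return out


def classify_backprop(slope_above: float, slope_below: float) -> str:
    """ascending = propagation above the soma only, descending = below only,
    curved = both, undetermined = neither."""
    up = np.isfinite(slope_above) and slope_above > 0
    down = np.isfinite(slope_below) and slope_below > 0
    if up and down:
        return "curved"
    if up:
        return "ascending"
    if down:
        return "descending"
    return "undetermined"


def analyze_backpropagation(
    footprint: UnitFootprint,
    probe: ProbeMap,
    threshold_frac: float = THRESHOLD_FRAC,
    radius_um: float = SEARCH_RADIUS_UM,
    min_side_channels: int = MIN_SIDE_CHANNELS,
) -> BackpropResult:
    """Full per-unit backpropagation quantification."""
    soma = footprint.peak_channel
    table = detect_trough_channels(footprint, probe, threshold_frac, radius_um)
    fit = fit_backprop_slopes(table, probe.channel(soma).y, min_side_channels)
    direction = classify_backprop(fit["slope_above"], fit["slope_below"])
    return BackpropResult(
        unit_id=footprint.unit_id,
        soma_channel=int(soma),
        initiation_channel=fit["initiation_channel"],
        trough_table=fit["table"],
        slope_above=fit["slope_above"],
        slope_below=fit["slope_below"],
        r2_above=fit["r2_above"],
        r2_below=fit["r2_below"],
        direction=direction,
        simultaneous=fit["simultaneous"],
    )


def backprop_table(results: list[BackpropResult]) -> pd.DataFrame:
    """Flat results table for CSV export."""
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "soma_channel": r.soma_channel,
                "initiation_channel": r.initiation_channel,
                "slope_above_ms_per_mm": r.slope_above,
                "slope_below_ms_per_mm": r.slope_below,
                "r2_above": r.r2_above,
                "r2_below": r.r2_below,
                "direction": r.direction,
            }
            for r in results
        ]
    )
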