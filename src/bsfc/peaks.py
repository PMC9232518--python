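"""Peak detection, characterization and physics-based width gating.

Detection runs on the cumulative scattering signal and, independently,
on the green-fluorescence (FP1) channel of each segment:

1. threshold at mean + 3*sigma of the whole segment,
2. find all strict local maxima,
3. define threshold-crossing ranges (maximal runs above threshold),
4. keep exactly one peak per range (the tallest; leftmost on ties),
5. extract characteristics (height, FWHM, AUC, per-channel intensity).

The slit-transit physics connects a pulse width in samples to the size
of the object that produced it: an object of diameter d crossing an
illumination slit of width s at flow velocity v = Q/A occupies the slit
for dt = (d + s)/v, i.e. width_points = floor(dt * fs). A 20-point
minimum-width gate separates cluster candidates from single cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CHANNELS

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "segment_threshold",
    "find_candidate_maxima",
    "define_ranges",
    "deduplicate",
    "peak_characteristics",
    "detect_peaks",
    "flow_velocity",
    "transit_time",
    "width_in_points",
    "points_to_object_size",
    "width_gate",
    "peaks_to_frame",
]

#: Samples at each segment edge excluded from peak calling (filter
#: transients from the forward-backward pass live here).
EDGE_GUARD = 1000


@dataclass
class Peak:
    """A detected event on one source signal.

    ``range_start``/``range_end`` bound the half-open interval of samples
    above the detection threshold; ``location`` is the index of the
    maximum inside that interval.
    """

    channel_source: str  # "CUMULATIVE" or "FP1"
    location: int
    height: float
    range_start: int
    range_end: int
    fwhm_points: float = 0.0
    auc: float = 0.0
    per_channel_intensity: dict[str, float] = field(default_factory=dict)
    per_channel_fwhm: dict[str, float] = field(default_factory=dict)
    per_channel_auc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.range_start <= self.location < self.range_end):
            raise ValueError("peak location must lie inside its range")


# ---------------------------------------------------------------------------
# detection primitives


def segment_threshold(signal: np.ndarray, n_sigma: float = 3.0) -> float:
    """Detection threshold: mean + n_sigma * std over the whole segment.

    After band-pass filtering the segment mean is ~0, so this reduces to
    the classic 3-sigma rule while staying well defined for raw inputs.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise ValueError("segment must have at least 2 samples")
    return float(np.mean(signal) + n_sigma * np.std(signal))


def find_candidate_maxima(signal: np.ndarray) -> np.ndarray:
    """Indices of all strict local maxima; plateaus resolve to their
    leftmost sample."""
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 3:
        return np.array([], dtype=int)
    # collapse plateaus into runs of equal value; a run is a maximum when
    # it rises from the previous distinct value and falls to the next
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [n - 1]))
    vals = x[starts]
    prev_vals = x[np.maximum(starts - 1, 0)]
    next_vals = x[np.minimum(ends + 1, n - 1)]
    is_max = (starts > 0) & (ends < n - 1) & (prev_vals < vals) & (next_vals < vals)
    return starts[is_max].astype(int)


def define_ranges(signal: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal half-open runs of consecutive samples with signal > threshold."""
    above = np.asarray(signal, dtype=float) > threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def deduplicate(
    candidates: np.ndarray,
    ranges: list[tuple[int, int]],
    signal: np.ndarray,
    channel_source: str = "CUMULATIVE",
) -> list[Peak]:
    """One peak per threshold-crossing range.

    Within a range the tallest candidate survives (leftmost on a tie);
    candidates outside every range — i.e. maxima that never crossed the
    threshold — are discarded.
    """
    x = np.asarray(signal, dtype=float)
    cands = np.asarray(candidates, dtype=int)
    peaks: list[Peak] = []
    for start, end in ranges:
        inside = cands[(cands >= start) & (cands < end)]
        if inside.size == 0:
            # range crossed threshold but holds no strict maximum
            # (e.g. clipped plateau): take the argmax of the run
            loc = start + int(np.argmax(x[start:end]))
        else:
            heights = x[inside]
            loc = int(inside[np.argmax(heights)])  # argmax is leftmost on ties
        peaks.append(
            Peak(
                channel_source=channel_source,
                location=loc,
                height=float(x[loc]),
                range_start=int(start),
                range_end=int(end),
            )
        )
    return peaks


def _fwhm_at(x: np.ndarray, loc: int, half_level: float) -> float:
    """Width in points of the region around ``loc`` above ``half_level``,
    with linear interpolation at the two crossings."""
    n = x.size
    # walk left
    i = loc
    while i > 0 and x[i - 1] > half_level:
        i -= 1
    if i == 0 or x[i - 1] == x[i]:
        left = float(i)
    else:
        frac = (x[i] - half_level) / (x[i] - x[i - 1])
        left = i - frac
    # walk right
    j = loc
    while j < n - 1 and x[j + 1] > half_level:
        j += 1
    if j == n - 1 or x[j + 1] == x[j]:
        right = float(j)
    else:
        frac = (x[j] - half_level) / (x[j] - x[j + 1])
        right = j + frac
    return right - left


def peak_characteristics(
    peak: Peak,
    signal: np.ndarray,
    channel_signals: dict[str, np.ndarray] | None = None,
) -> Peak:
    """Fill in FWHM, AUC and per-channel values for a located peak.

    FWHM is measured at (height + segment mean)/2 above the segment mean
    baseline, interpolated linearly at the crossings. AUC is the sum of
    (signal - segment mean) over the threshold-crossing range.
    """
    x = np.asarray(signal, dtype=float)
    baseline = float(np.mean(x))
    half_level = (peak.height + baseline) / 2.0
    if half_level <= baseline:
        logger.warning(
            "half-max level below baseline at sample %d; falling back to range width",
            peak.location,
        )
        peak.fwhm_points = float(peak.range_end - peak.range_start)
    else:
        peak.fwhm_points = _fwhm_at(x, peak.location, half_level)
    peak.auc = float(np.sum(x[peak.range_start : peak.range_end] - baseline))
    if channel_signals:
        for name, sig in channel_signals.items():
            sig = np.asarray(sig, dtype=float)
            val = float(sig[peak.location])
            peak.per_channel_intensity[name] = val
            ch_base = float(np.mean(sig))
            ch_half = (val + ch_base) / 2.0
            if ch_half > ch_base:
                peak.per_channel_fwhm[name] = _fwhm_at(sig, peak.location, ch_half)
            else:
                peak.per_channel_fwhm[name] = 0.0
            peak.per_channel_auc[name] = float(
                np.sum(sig[peak.range_start : peak.range_end] - ch_base)
            )
    return peak


def detect_peaks(
    signal: np.ndarray,
    n_sigma: float = 3.0,
    channel_source: str = "CUMULATIVE",
    channel_signals: dict[str, np.ndarray] | None = None,
    edge_guard: int = EDGE_GUARD,
) -> list[Peak]:
    """Full detection pass on one segment signal.

    Peaks whose range touches the first/last ``edge_guard`` samples are
    dropped (filter edge transients).
    """
    threshold = segment_threshold(signal, n_sigma)
    candidates = find_candidate_maxima(signal)
    ranges = define_ranges(signal, threshold)
    peaks = deduplicate(candidates, ranges, signal, channel_source)
    n = np.asarray(signal).size
    kept = [
        p
        for p in peaks
        if p.range_start >= edge_guard and p.range_end <= n - edge_guard
    ]
    return [peak_characteristics(p, signal, channel_signals) for p in kept]


# ---------------------------------------------------------------------------
# slit-transit flow physics


def flow_velocity(flow_rate_ul_min: float, channel_area_um2: float) -> float:
    """Mean flow velocity v = Q/A in mm/s.

    Q in uL/min converts to mm^3/s (1 uL = 1 mm^3); A in um^2 converts
    to mm^2.
    """
    if flow_rate_ul_min <= 0 or channel_area_um2 <= 0:
        raise ValueError("flow rate and channel area must be positive")
    q_mm3_s = flow_rate_ul_min / 60.0
    a_mm2 = channel_area_um2 * 1e-6
    return q_mm3_s / a_mm2


def transit_time(
    object_diameter_um: float, slit_width_um: float, velocity_mm_s: float
) -> float:
    """Time (s) for an object to cross the slit: (d + s)/v."""
    if velocity_mm_s <= 0:
        raise ValueError("flow velocity must be positive")
    if object_diameter_um < 0 or slit_width_um < 0:
        raise ValueError("diameters must be non-negative")
    d_eff_mm = (object_diameter_um + slit_width_um) * 1e-3
    return d_eff_mm / velocity_mm_s


def width_in_points(transit_time_s: float, sample_rate_hz: float) -> int:
    """Pulse width in digitized samples: floor(dt * fs)."""
    if transit_time_s < 0:
        raise ValueError("transit time must be non-negative")
    return int(np.floor(transit_time_s * sample_rate_hz))


def points_to_object_size(
    width_points: float,
    sample_rate_hz: float,
    velocity_mm_s: float,
    slit_width_um: float,
) -> float:
    """Invert the transit relation: object diameter (um) from pulse width.

    Negative results (object smaller than the slit) clamp to 0 with a
    warning.
    """
    d_eff_um = (width_points / sample_rate_hz) * velocity_mm_s * 1e3
    size = d_eff_um - slit_width_um
    if size < 0:
        warnings.warn(
            f"width {width_points} points implies a sub-slit object; clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return size


def width_gate(peaks: list[Peak], min_width_points: float = 20.0) -> list[Peak]:
    """Retain cluster candidates: peaks with FWHM >= min_width_points.

    Narrower pulses are consistent with single cells or white blood
    cells and are removed before classification.
    """
    return [p for p in peaks if p.fwhm_points >= min_width_points]


# ---------------------------------------------------------------------------
# tabular export


def peaks_to_frame(peaks: list[Peak], segment_id: str = "") -> pd.DataFrame:
    """Flatten a peak list to the CSV-ready table layout."""
    rows = []
    for p in peaks:
        row = {
            "segment_id": segment_id,
            "channel_source": p.channel_source,
            "location": p.location,
            "height": p.height,
            "fwhm_points": p.fwhm_points,
            "auc": p.auc,
            "range_start": p.range_start,
            "range_end": p.range_end,
        }
        for ch in CHANNELS:
            row[f"i{ch[1:] if ch.startswith('S') else ch}"] = (
                p.per_channel_intensity.get(ch, np.nan)
            )
        rows.append(row)
    cols = [
        "segment_id", "channel_source", "location", "height", "fwhm_points",
        "auc", "range_start", "range_end",
        "i405", "i488", "i633", "iFP1", "iFP2",
    ]
    return pd.DataFrame(rows, columns=cols)
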