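"""Ground-truth labeling of scattering events and the GFP
spike-in sensitivity report.

GFP fluorescence (FP1) is the ground truth: a gated scattering event
whose threshold-crossing range overlaps an FP1 peak's range is a tumor
cell cluster (CTCC); one with no corresponding FP1 peak is a non-cluster
(NC) event. FP1 peaks that match no scattering event are returned
separately — these are fluorescent cells whose scattering signature was
lost in the blood background.

The spike-in module quantifies how reliably the FP1 channel itself
detects labelled cells: known concentrations of GFP-labelled single
cells are flowed, the expected count is concentration x volume, and the
per-day detection sensitivity and percent error are summarized across
days. The packaged table ``data/gfp_spikein_counts.csv`` holds the
five-day spike-in validation counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .peaks import Peak

__all__ = [
    "LabeledEvent",
    "SpikeInRecord",
    "match_and_label",
    "percent_error",
    "expected_count",
    "gfp_sensitivity_report",
    "load_spikein_table",
]

CTCC, NC = "CTCC", "NC"


@dataclass
class LabeledEvent:
    """A gated scattering candidate with its ground-truth class.

    ``center_for_features`` is the sample index the feature window is
    anchored on: the FP1 peak location for CTCC events (the fluorescence
    channel localizes the cluster better than the noisy cumulative
    scatter) and the scattering peak location for NC events.
    """

    peak: Peak
    label: str
    center_for_features: int
    day_id: str = ""
    segment_index: int = 0


def _overlap(a: Peak, b: Peak) -> int:
    return max(
        0, min(a.range_end, b.range_end) - max(a.range_start, b.range_start)
    )


def match_and_label(
    scatter_candidates: list[Peak],
    fp1_peaks: list[Peak],
    day_id: str = "",
    segment_index: int = 0,
) -> tuple[list[LabeledEvent], list[Peak]]:
    """Label gated scattering candidates by FP1 range overlap.

    Returns ``(labeled_events, unmatched_fp1)``. A scattering candidate
    overlapping several FP1 peaks is matched to the one with maximal
    overlap (earlier FP1 peak on a tie).
    """
    labeled: list[LabeledEvent] = []
    matched_fp1: set[int] = set()
    for cand in scatter_candidates:
        best_i, best_ov = -1, 0
        for i, fp in enumerate(fp1_peaks):
            ov = _overlap(cand, fp)
            if ov > best_ov:  # strict: earlier peak wins ties
                best_i, best_ov = i, ov
        if best_i >= 0:
            matched_fp1.add(best_i)
            labeled.append(
                LabeledEvent(
                    peak=cand,
                    label=CTCC,
                    center_for_features=fp1_peaks[best_i].location,
                    day_id=day_id,
                    segment_index=segment_index,
                )
            )
        else:
            labeled.append(
                LabeledEvent(
                    peak=cand,
                    label=NC,
                    center_for_features=cand.location,
                    day_id=day_id,
                    segment_index=segment_index,
                )
            )
    unmatched = [fp for i, fp in enumerate(fp1_peaks) if i not in matched_fp1]
    return labeled, unmatched


# ---------------------------------------------------------------------------
# spike-in sensitivity


@dataclass(frozen=True)
class SpikeInRecord:
    """One day of the GFP spike-in validation."""

    day_id: str
    concentration_per_ul: float
    volume_ul: float
    expected: int
    detected: int

    def __post_init__(self) -> None:
        if self.expected < 0 or self.detected < 0:
            raise ValueError("counts must be non-negative")
        if self.volume_ul <= 0:
            raise ValueError("volume must be positive")


def expected_count(concentration_per_ul: float, volume_ul: float) -> int:
    """Expected number of spiked cells: concentration x volume, rounded
    to the nearest integer."""
    if concentration_per_ul <= 0 or volume_ul <= 0:
        raise ValueError("concentration and volume must be positive")
    return int(round(concentration_per_ul * volume_ul))


def percent_error(expected: float, detected: float) -> float:
    """Detection percent error: |expected - detected| / detected * 100,
    rounded to 2 decimals."""
    if detected <= 0:
        raise ValueError("percent error undefined for zero detected count")
    return round(abs(expected - detected) / detected * 100.0, 2)


def gfp_sensitivity_report(records: list[SpikeInRecord]) -> dict:
    """Summarize per-day GFP detection sensitivity and percent error.

    Sensitivity = detected/expected * 100 per day; the summary reports
    the mean and sample (n-1) standard deviation across days. Days with
    zero expected count are excluded with a warning.
    """
    usable = []
    for rec in records:
        if rec.expected == 0:
            warnings.warn(f"day {rec.day_id} excluded: zero expected count")
            continue
        usable.append(rec)
    if len(usable) < 2:
        raise ValueError("need at least 2 usable days for a summary")
    sens = np.array([r.detected / r.expected * 100.0 for r in usable])
    errs = np.array([percent_error(r.expected, r.detected) for r in usable])
    return {
        "per_day": [
            {
                "day_id": r.day_id,
                "sensitivity": float(s),
                "percent_error": float(e),
            }
            for r, s, e in zip(usable, sens, errs)
        ],
        "sensitivity_mean": float(np.mean(sens)),
        "sensitivity_std": float(np.std(sens, ddof=1)),
        "percent_error_mean": float(np.mean(errs)),
        "percent_error_std": float(np.std(errs, ddof=1)),
        "n_days": len(usable),
    }


def load_spikein_table(path: str | None = None) -> list[SpikeInRecord]:
    """Load spike-in records from a CSV (defaults to the packaged
    five-day validation table)."""
    if path is None:
        ref = resources.files("bsfc") / "data" / "gfp_spikein_counts.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    df["day"] = df["day"].astype(str)
    return [
        SpikeInRecord(
            day_id=str(row["day"]),
            concentration_per_ul=float(row["concentration_per_ul"]),
            volume_ul=float(row["volume_ul"]),
            expected=int(row["expected_count"]),
            detected=int(row["detected_count"]),
        )
        for _, row in df.iterrows()
    ]
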