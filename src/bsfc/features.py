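"""Segment normalization and windowed feature extraction.

Each 1.5-min segment is normalized per scattering channel by one of
four methods before fixed-length windows are cut around event centers:

MAX_PEAK          divide by the height of the tallest detected peak.
MEAN_PEAK_5SIGMA  divide by the mean height of peaks above mean+5*sigma.
ZERO_MEAN         (x - mean) / std of the whole segment.
ZERO_MEDIAN       (x - median) / std of the whole segment.

ZERO_MEAN and ZERO_MEDIAN are affine-invariant: they give identical
features whatever the day's illumination power or detector offset,
which is why they travel across experiment days without calibration.

A feature vector is the concatenation of 2*13+1 = 27 consecutive
samples per scattering channel, in fixed channel order (405, 488, 633),
all cut at the same center index; with all three channels that is an
81-dimensional vector. Events whose window would cross a segment edge
are discarded (never padded).
"""

from __future__ import annotations

import logging
from enum import Enum

import numpy as np

from .config import SCATTER_CHANNELS
from .labeling import CTCC, LabeledEvent
from .peaks import detect_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationMethod",
    "HALF_WINDOW",
    "normalize_channel",
    "normalize_segment",
    "extract_window",
    "build_dataset",
]

HALF_WINDOW = 13  # samples either side of the event center


class NormalizationMethod(str, Enum):
    MAX_PEAK = "max_peak"
    MEAN_PEAK_5SIGMA = "mean_peak_5sigma"
    ZERO_MEAN = "zero_mean"
    ZERO_MEDIAN = "zero_median"


def normalize_channel(
    x: np.ndarray, method: NormalizationMethod, segment_name: str = ""
) -> np.ndarray:
    """Normalize one channel of one segment."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError(f"empty segment {segment_name!r}")
    method = NormalizationMethod(method)
    if method in (NormalizationMethod.ZERO_MEAN, NormalizationMethod.ZERO_MEDIAN):
        std = float(np.std(x))
        if std == 0:
            raise ValueError(f"zero-variance channel in segment {segment_name!r}")
        center = np.mean(x) if method is NormalizationMethod.ZERO_MEAN else np.median(x)
        return (x - center) / std
    # peak-referenced methods need the segment's own detected peaks
    if method is NormalizationMethod.MAX_PEAK:
        peaks = detect_peaks(x, n_sigma=3.0, channel_source="CHANNEL", edge_guard=0)
        if not peaks:
            raise ValueError(
                f"no peaks above 3-sigma in segment {segment_name!r}; "
                "max-peak normalization undefined"
            )
        return x / max(p.height for p in peaks)
    # MEAN_PEAK_5SIGMA
    peaks = detect_peaks(x, n_sigma=5.0, channel_source="CHANNEL", edge_guard=0)
    if not peaks:
        raise ValueError(
            f"no peaks above 5-sigma in segment {segment_name!r}; "
            "mean-peak normalization undefined"
        )
    return x / float(np.mean([p.height for p in peaks]))


def normalize_segment(
    channels: dict[str, np.ndarray],
    method: NormalizationMethod,
    segment_name: str = "",
) -> dict[str, np.ndarray]:
    """Normalize every scattering channel of a segment independently;
    other channels pass through."""
    out = {}
    for name, sig in channels.items():
        if name in SCATTER_CHANNELS:
            out[name] = normalize_channel(
                sig, method, f"{segment_name}/{name}"
            )
        else:
            out[name] = np.asarray(sig, dtype=float)
    return out


def extract_window(
    channels: dict[str, np.ndarray],
    center: int,
    half_window: int = HALF_WINDOW,
    use_channels: tuple[str, ...] = SCATTER_CHANNELS,
) -> np.ndarray | None:
    """Cut one feature vector: (2*half_window+1) samples per channel,
    concatenated in fixed channel order at a common center.

    Returns ``None`` when the window would cross a segment edge.
    """
    ordered = [c for c in SCATTER_CHANNELS if c in use_channels]
    if not ordered:
        raise ValueError("no scattering channels selected")
    n = np.asarray(channels[ordered[0]]).size
    if center - half_window < 0 or center + half_window + 1 > n:
        logger.warning("event at sample %d too close to segment edge; skipped", center)
        return None
    parts = [
        np.asarray(channels[c], dtype=float)[
            center - half_window : center + half_window + 1
        ]
        for c in ordered
    ]
    return np.concatenate(parts)


def build_dataset(
    labeled_events: list[LabeledEvent],
    segments: dict[tuple[str, int], dict[str, np.ndarray]],
    method: NormalizationMethod = NormalizationMethod.ZERO_MEAN,
    use_channels: tuple[str, ...] = SCATTER_CHANNELS,
    half_window: int = HALF_WINDOW,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the training matrix from labeled events.

    ``segments`` maps (day_id, segment_index) to the *filtered* channel
    dict; normalization is applied here, once per segment. Returns
    ``(X, y, days)`` with ``y`` in {+1 (CTCC), -1 (NC)} and rows in
    deterministic (day, segment, center) order.
    """
    n_ch = len([c for c in SCATTER_CHANNELS if c in use_channels])
    width = (2 * half_window + 1) * n_ch
    normalized: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    rows, labels, days = [], [], []
    for ev in sorted(
        labeled_events,
        key=lambda e: (e.day_id, e.segment_index, e.center_for_features),
    ):
        key = (ev.day_id, ev.segment_index)
        if key not in normalized:
            if key not in segments:
                raise KeyError(f"no segment data for {key}")
            normalized[key] = normalize_segment(
                segments[key], method, f"{key[0]}[{key[1]}]"
            )
        vec = extract_window(
            normalized[key], ev.center_for_features, half_window, use_channels
        )
        if vec is None:
            continue
        rows.append(vec)
        labels.append(1 if ev.label == CTCC else -1)
        days.append(ev.day_id)
    X = np.array(rows, dtype=float).reshape(len(rows), width)
    return X, np.array(labels, dtype=int), np.array(days, dtype=object)
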