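"""End-to-end orchestration: simulate -> filter -> detect -> label ->
featurize -> train -> evaluate.

`process_day` turns one day of raw traces into labeled events exactly
as the instrument pipeline would: band-pass filter every channel,
apply daily power normalization (identity for synthetic data, which is
generated on a common scale), sum the scattering channels, detect peaks
on the cumulative and FP1 signals, gate scattering peaks by the
20-point minimum width, and label the survivors by FP1 overlap.

`run_benchmark` wires the whole chain into a seeded synthetic
experiment (cluster spike-ins on several "days", a held-out test-day
set, a balanced cascade) and reports the four metrics — the package's
reference end-to-end computation.

`run_pipeline` does the same from a RunConfig and writes every stage
artifact (traces, truth, peak and label tables, features, the
serialized cascade, metrics and a stage-count log) into a run
directory; re-running with the same config reproduces metrics
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .cascade import (
    evaluate_cascade,
    metrics_by_stage,
    train_cascade,
)
from .config import (
    SCATTER_CHANNELS,
    AcquisitionConfig,
    BoostHyperparams,
    FilterSpec,
)
from .features import NormalizationMethod, build_dataset
from .labeling import LabeledEvent, match_and_label
from .metrics import all_metrics, confusion
from .peaks import detect_peaks, peaks_to_frame, width_gate
from .preprocess import apply_normalization, cumulative_scatter, filter_segment
from .simulate import DayData, NoiseModel, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "process_day", "build_experiment_dataset",
           "run_benchmark", "run_pipeline"]


@dataclass
class RunConfig:
    """Master configuration for one reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "bsfc_run"
    acquisition: AcquisitionConfig = field(
        default_factory=lambda: AcquisitionConfig(segment_duration_s=10.0)
    )
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    n_sigma: float = 3.0
    min_width_points: float = 20.0
    normalization: str = "zero_mean"
    channels: tuple[str, ...] = SCATTER_CHANNELS
    hyperparams: BoostHyperparams = field(default_factory=BoostHyperparams)
    n_models: int = 50
    n_train_days: int = 5
    n_test_days: int = 2
    n_segments_per_day: int = 3
    n_tumor_per_segment: int = 10
    n_nc_per_segment: int = 100
    min_cells: int | None = 3  # cluster-only spike-in
    gfp_only_prob: float = 0.05

    def to_yaml(self) -> str:
        # json round-trip turns tuples into lists, which yaml can emit
        plain = json.loads(json.dumps(dataclasses.asdict(self)))
        return yaml.safe_dump(plain, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        plain = json.loads(json.dumps(dataclasses.asdict(self)))
        plain.pop("out_dir", None)
        blob = yaml.safe_dump(plain, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def process_day(
    day: DayData,
    filter_spec: FilterSpec | None = None,
    norm_factors: dict[int, float] | None = None,
    n_sigma: float = 3.0,
    min_width_points: float = 20.0,
) -> tuple[list[LabeledEvent], dict[tuple[str, int], dict[str, np.ndarray]], dict]:
    """Filter, detect, gate and label one day of traces.

    Returns the labeled events, the map of filtered segments keyed by
    (day_id, segment_index) for feature extraction, and a funnel-stats
    dict (detected -> gated -> labeled counts).
    """
    filter_spec = filter_spec or FilterSpec()
    fs = day.config.sample_rate_hz
    labeled: list[LabeledEvent] = []
    segments_map: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    stats = {"detected": 0, "gated": 0, "ctcc": 0, "nc": 0, "unmatched_fp1": 0}
    for i, raw in enumerate(day.segments):
        filtered = filter_segment(raw, filter_spec, fs)
        if norm_factors:
            filtered = apply_normalization(filtered, norm_factors)
        cum = cumulative_scatter(filtered)
        scatter_peaks = detect_peaks(
            cum,
            n_sigma=n_sigma,
            channel_source="CUMULATIVE",
            channel_signals=filtered,
        )
        fp1_peaks = detect_peaks(
            filtered["FP1"], n_sigma=n_sigma, channel_source="FP1"
        )
        gated = width_gate(scatter_peaks, min_width_points)
        events, unmatched = match_and_label(
            gated, fp1_peaks, day_id=day.day_id, segment_index=i
        )
        labeled.extend(events)
        segments_map[(day.day_id, i)] = filtered
        stats["detected"] += len(scatter_peaks)
        stats["gated"] += len(gated)
        stats["ctcc"] += sum(1 for e in events if e.label == "CTCC")
        stats["nc"] += sum(1 for e in events if e.label == "NC")
        stats["unmatched_fp1"] += len(unmatched)
    logger.info(
        "%s: detected %d -> gated %d -> CTCC %d / NC %d (unmatched FP1 %d)",
        day.day_id, stats["detected"], stats["gated"],
        stats["ctcc"], stats["nc"], stats["unmatched_fp1"],
    )
    return labeled, segments_map, stats


def build_experiment_dataset(
    days: list[DayData],
    filter_spec: FilterSpec | None = None,
    n_sigma: float = 3.0,
    min_width_points: float = 20.0,
    normalization: str | NormalizationMethod = NormalizationMethod.ZERO_MEAN,
    channels: tuple[str, ...] = SCATTER_CHANNELS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Process several days and assemble one feature matrix."""
    all_events: list[LabeledEvent] = []
    all_segments: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    funnel: dict[str, dict] = {}
    for day in days:
        events, segs, stats = process_day(
            day, filter_spec, None, n_sigma, min_width_points
        )
        all_events.extend(events)
        all_segments.update(segs)
        funnel[day.day_id] = stats
    X, y, day_idx = build_dataset(
        all_events, all_segments, NormalizationMethod(normalization), channels
    )
    return X, y, day_idx, funnel


def run_benchmark(config: RunConfig | None = None, noise: NoiseModel | None = None) -> dict:
    """Seeded end-to-end synthetic benchmark.

    Simulates ``n_train_days + n_test_days`` cluster spike-in days,
    trains the balanced cascade on the training days and evaluates on
    the held-out days. Returns the four metrics, the per-stage
    convergence curve, and event counts.
    """
    cfg = config or RunConfig()
    n_days = cfg.n_train_days + cfg.n_test_days
    days = simulate_experiment(
        n_days,
        cfg.acquisition,
        seed=cfg.seed,
        n_segments=cfg.n_segments_per_day,
        n_tumor_per_segment=cfg.n_tumor_per_segment,
        n_nc_per_segment=cfg.n_nc_per_segment,
        noise=noise,
        min_cells=cfg.min_cells,
        gfp_only_prob=cfg.gfp_only_prob,
    )
    train_days = days[: cfg.n_train_days]
    test_days = days[cfg.n_train_days :]
    Xtr, ytr, _, funnel_tr = build_experiment_dataset(
        train_days, cfg.filter_spec, cfg.n_sigma, cfg.min_width_points,
        cfg.normalization, cfg.channels,
    )
    Xte, yte, _, funnel_te = build_experiment_dataset(
        test_days, cfg.filter_spec, cfg.n_sigma, cfg.min_width_points,
        cfg.normalization, cfg.channels,
    )
    cascade = train_cascade(
        Xtr, ytr, cfg.hyperparams, cfg.n_models, seed=cfg.seed + 1
    )
    pred, survivors = evaluate_cascade(cascade, Xte)
    final = all_metrics(confusion(yte, pred))
    curve = metrics_by_stage(cascade, Xte, yte)
    return {
        "metrics": final,
        "stage_curve": curve,
        "n_train": {"ctcc": int((ytr == 1).sum()), "nc": int((ytr == -1).sum())},
        "n_test": {"ctcc": int((yte == 1).sum()), "nc": int((yte == -1).sum())},
        "survivor_sizes": [int(s.size) for s in survivors],
        "funnel": {"train": funnel_tr, "test": funnel_te},
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline and persist every stage artifact.

    Returns the run directory. Artifacts: per-day trace HDF5 + ground
    truth CSV, labeled-event CSV, feature HDF5 for train/test, the
    serialized cascade (JSON) and ``metrics.json`` stamped with the
    config hash and seed.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(cfg.to_yaml())

    n_days = cfg.n_train_days + cfg.n_test_days
    days = simulate_experiment(
        n_days,
        cfg.acquisition,
        seed=cfg.seed,
        n_segments=cfg.n_segments_per_day,
        n_tumor_per_segment=cfg.n_tumor_per_segment,
        n_nc_per_segment=cfg.n_nc_per_segment,
        min_cells=cfg.min_cells,
        gfp_only_prob=cfg.gfp_only_prob,
    )
    truth_frames = []
    for day in days:
        bio.write_traces(
            out / f"traces_{day.day_id}.h5", day.segments,
            cfg.acquisition.sample_rate_hz,
        )
        truth_frames.append(day.truth)
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out / "ground_truth.csv", index=False
    )

    label_rows = []
    datasets = {}
    for split, subset in (
        ("train", days[: cfg.n_train_days]),
        ("test", days[cfg.n_train_days :]),
    ):
        events_all = []
        segs_all = {}
        for day in subset:
            events, segs, _ = process_day(
                day, cfg.filter_spec, None, cfg.n_sigma, cfg.min_width_points
            )
            events_all.extend(events)
            segs_all.update(segs)
            for ev in events:
                label_rows.append(
                    {
                        "split": split,
                        "day_id": ev.day_id,
                        "segment_index": ev.segment_index,
                        "label": ev.label,
                        "center_for_features": ev.center_for_features,
                        "location": ev.peak.location,
                        "fwhm_points": ev.peak.fwhm_points,
                        "height": ev.peak.height,
                    }
                )
        X, y, day_idx = build_dataset(
            events_all, segs_all,
            NormalizationMethod(cfg.normalization), cfg.channels,
        )
        bio.write_features(out / f"features_{split}.h5", X, y, day_idx)
        datasets[split] = (X, y)
    pd.DataFrame(label_rows).to_csv(out / "labeled_events.csv", index=False)

    Xtr, ytr = datasets["train"]
    Xte, yte = datasets["test"]
    cascade = train_cascade(
        Xtr, ytr, cfg.hyperparams, cfg.n_models, seed=cfg.seed + 1
    )
    cascade.save(out / "cascade.json")
    pred, survivors = evaluate_cascade(cascade, Xte)
    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "metrics": all_metrics(confusion(yte, pred)),
        "survivor_sizes": [int(s.size) for s in survivors],
        "n_train": {"ctcc": int((ytr == 1).sum()), "nc": int((ytr == -1).sum())},
        "n_test": {"ctcc": int((yte == 1).sum()), "nc": int((yte == -1).sum())},
    }
    (out / "metrics.json").write_text(json.dumps(report, indent=2))
    return out
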