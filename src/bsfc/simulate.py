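"""Synthetic five-channel trace generator with ground truth.

Emulates spike-in flow-cytometry experiments: whole blood carrying
GFP-labelled tumor cells and clusters flows past an illumination slit,
and five detectors record three backscattering channels (405/488/633 nm)
plus green (FP1) and red (FP2) fluorescence at 60 kHz. Every generated
event is recorded in a ground-truth table so each downstream stage
(filtering, peak detection, labeling, classification) can be tested
without instrument data.

Event taxonomy
--------------
CTC       single tumor cell: narrow scattering pulse + co-located FP1.
CTCC      tumor cell cluster (>= 2 cells): wide scattering pulse + FP1.
NC        non-cluster scattering event (debris, clots): scattering
          pulse, no FP1 signal.
GFP_ONLY  green-fluorescent event with no detectable scattering pulse.

Pulse model
-----------
An object of effective diameter d_eff (object + slit width) crossing the
slit at velocity v = Q/A produces a unimodal pulse of duration
dt = d_eff / v, i.e. FWHM = dt * fs samples. The pulse shape is
Gaussian with sigma = FWHM / 2.355 — the simplest unimodal form
consistent with the slit convolution. Scattering channels may be
jittered by a few samples relative to each other, mimicking the small
inter-wavelength time shifts seen on real instruments.

Spectral signatures are phenomenological, not optical: cluster events
scatter strongest at 405 nm (ratio 1 : 0.6 : 0.5 across 405:488:633)
while non-cluster events are 633-dominant, so the classes are separable
from the per-channel window shape but not from the cumulative signal
alone.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawns, one child stream per operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import CHANNELS, SCATTER_CHANNELS, AcquisitionConfig
from .peaks import flow_velocity

__all__ = [
    "ClusterSizeDistribution",
    "NoiseModel",
    "EventSpec",
    "DayData",
    "sample_cluster_size",
    "cluster_diameter",
    "event_pulse",
    "render_trace",
    "random_events",
    "simulate_day",
    "simulate_experiment",
]

GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355

#: Relative scattering amplitude across (405, 488, 633) for each class.
CTCC_SPECTRAL_RATIO = (1.0, 0.6, 0.5)
NC_SPECTRAL_RATIO = (0.5, 0.6, 1.0)


@dataclass(frozen=True)
class ClusterSizeDistribution:
    """Probabilities over spike-in cluster-size categories.

    Defaults reproduce the measured composition of trypsin-generated
    cluster suspensions: 65.8% single cells, 17.1% two-cell clusters,
    15.0% 3-6 cells, 1.4% 7-9 cells, 0.7% larger.
    """

    p_single: float = 0.658
    p_two: float = 0.171
    p_three_six: float = 0.150
    p_seven_nine: float = 0.014
    p_ten_plus: float = 0.007

    def probabilities(self) -> np.ndarray:
        p = np.array(
            [self.p_single, self.p_two, self.p_three_six,
             self.p_seven_nine, self.p_ten_plus]
        )
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        total = p.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")
        return p


#: (low, high) inclusive cell-count range per category.
_CATEGORY_RANGES = ((1, 1), (2, 2), (3, 6), (7, 9), (10, 15))


def sample_cluster_size(
    dist: ClusterSizeDistribution, rng: np.random.Generator | int
) -> int:
    """Draw a cluster cell count: category per the distribution, then
    uniform within the category's range (the open-ended "9+" category
    spans 10-15 cells)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = dist.probabilities()
    cat = rng.choice(len(p), p=p)
    lo, hi = _CATEGORY_RANGES[cat]
    return int(rng.integers(lo, hi + 1))


@dataclass(frozen=True)
class NoiseModel:
    """Background model for one rendered segment.

    ``blood_background_scale`` multiplies the white-noise sigma of the
    scattering channels only: whole blood scatters far more than growth
    media, degrading scattering SNR while leaving fluorescence SNR
    untouched.
    """

    baseline: dict[str, float] = field(
        default_factory=lambda: {c: 0.5 for c in CHANNELS}
    )
    drift_amplitude: float = 0.05
    drift_period_s: float = 30.0
    white_sigma: dict[str, float] = field(
        default_factory=lambda: {c: 0.01 for c in CHANNELS}
    )
    blood_background_scale: float = 2.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.white_sigma.values()):
            raise ValueError("noise sigmas must be non-negative")
        if self.blood_background_scale < 1:
            raise ValueError("blood_background_scale must be >= 1")

    def effective_sigma(self, channel: str) -> float:
        s = self.white_sigma[channel]
        if channel in SCATTER_CHANNELS:
            s *= self.blood_background_scale
        return s


_KINDS = ("CTC", "CTCC", "NC", "GFP_ONLY")


@dataclass(frozen=True)
class EventSpec:
    """One simulated transit event."""

    kind: str
    center_time_s: float
    effective_diameter_um: float  # object diameter + slit width
    amplitudes: dict[str, float]
    n_cells: int = 1
    channel_jitter: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "CTCC" and self.n_cells < 2:
            raise ValueError("a CTCC must have at least 2 cells")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        fp1 = self.amplitudes.get("FP1", 0.0)
        scatter = [self.amplitudes.get(c, 0.0) for c in SCATTER_CHANNELS]
        if self.kind == "GFP_ONLY" and any(a != 0 for a in scatter):
            raise ValueError("GFP_ONLY events must have zero scattering amplitude")
        if self.kind in ("CTC", "CTCC", "GFP_ONLY") and fp1 <= 0:
            raise ValueError(f"{self.kind} events must have positive FP1 amplitude")
        if self.kind == "NC" and fp1 != 0:
            raise ValueError("NC events must have zero FP1 amplitude")


def cluster_diameter(n_cells: int, rng: np.random.Generator) -> float:
    """Object diameter (um) for an n-cell object.

    Singles draw uniformly from 7-13 um. Two-cell clusters draw from
    one to two single-cell lengths, reflecting orientation ambiguity
    when crossing the slit. Larger clusters scale as
    12.2 um * n^(1/3) (volume-conserving packing), which places 3-4
    cell clusters near 24-point pulses and 6+ clusters near 30 points
    at the default flow settings.
    """
    if n_cells == 1:
        return float(rng.uniform(7.0, 13.0))
    if n_cells == 2:
        d1 = rng.uniform(7.0, 13.0)
        return float(rng.uniform(d1, 2 * d1))
    return float(12.2 * n_cells ** (1.0 / 3.0) * rng.uniform(0.95, 1.05))


def event_pulse(
    spec: EventSpec, config: AcquisitionConfig
) -> dict[str, np.ndarray]:
    """Render one event as per-channel Gaussian snippets.

    Each snippet's FWHM in samples is d_eff / v * fs; scattering
    channels are shifted by their integer jitter. Snippets span +-4
    sigma around the (jittered) center.
    """
    v = flow_velocity(config.flow_rate_ul_min, config.channel_area_um2)  # mm/s
    dt = spec.effective_diameter_um * 1e-3 / v  # s
    fwhm_samples = dt * config.sample_rate_hz
    sigma = max(fwhm_samples / GAUSS_FWHM_FACTOR, 1e-6)
    half = int(np.ceil(4 * sigma)) + max(
        (abs(j) for j in spec.channel_jitter.values()), default=0
    )
    rel = np.arange(-half, half + 1, dtype=float)
    out: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        amp = spec.amplitudes.get(ch, 0.0)
        if amp == 0.0:
            out[ch] = np.zeros(rel.size)
            continue
        shift = spec.channel_jitter.get(ch, 0) if ch in SCATTER_CHANNELS else 0
        out[ch] = amp * np.exp(-0.5 * ((rel - shift) / sigma) ** 2)
    return out


def _truth_row(
    spec: EventSpec, event_id: int, config: AcquisitionConfig
) -> dict:
    v = flow_velocity(config.flow_rate_ul_min, config.channel_area_um2)
    fwhm = spec.effective_diameter_um * 1e-3 / v * config.sample_rate_hz
    row = {
        "event_id": event_id,
        "kind": spec.kind,
        "n_cells": spec.n_cells,
        "center_sample": int(round(spec.center_time_s * config.sample_rate_hz)),
        "fwhm_samples": fwhm,
    }
    for ch in CHANNELS:
        row[f"amp_{ch}"] = spec.amplitudes.get(ch, 0.0)
    return row


def render_trace(
    events: list[EventSpec],
    noise: NoiseModel,
    config: AcquisitionConfig,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render a full segment: baseline + drift + white noise + pulses.

    Returns the per-channel trace dict and the ground-truth event table
    (one row per requested event, in input order). Bit-identical for
    identical seeds.
    """
    n = config.segment_length
    t = np.arange(n) / config.sample_rate_hz
    duration = config.segment_duration_s
    for ev in events:
        if not (0 <= ev.center_time_s <= duration):
            raise ValueError(
                f"event center {ev.center_time_s}s outside segment [0, {duration}]s"
            )
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    channel_seeds = ss.spawn(len(CHANNELS))
    traces: dict[str, np.ndarray] = {}
    for ch, child in zip(CHANNELS, channel_seeds):
        rng = np.random.default_rng(child)
        sig = np.full(n, noise.baseline.get(ch, 0.0))
        if noise.drift_amplitude:
            sig = sig + noise.drift_amplitude * np.sin(
                2 * np.pi * t / noise.drift_period_s
            )
        sigma = noise.effective_sigma(ch)
        if sigma > 0:
            sig = sig + rng.normal(0.0, sigma, n)
        traces[ch] = sig
    for ev in events:
        pulse = event_pulse(ev, config)
        center = int(round(ev.center_time_s * config.sample_rate_hz))
        half = (next(iter(pulse.values())).size - 1) // 2
        lo = max(0, center - half)
        hi = min(n, center + half + 1)
        for ch in CHANNELS:
            traces[ch][lo:hi] += pulse[ch][lo - (center - half) : hi - (center - half)]
    truth = pd.DataFrame(
        [_truth_row(ev, i, config) for i, ev in enumerate(events)],
        columns=[
            "event_id", "kind", "n_cells", "center_sample", "fwhm_samples",
            *(f"amp_{c}" for c in CHANNELS),
        ],
    )
    return traces, truth


# ---------------------------------------------------------------------------
# day-level generation


def _event_amplitudes(
    kind: str, n_cells: int, rng: np.random.Generator, base_amplitude: float
) -> dict[str, float]:
    """Per-channel amplitudes with class-specific spectral ratio.

    Cluster scattering scales with projected area (~ n^(2/3)); each
    channel gets mild independent lognormal variation so the ratios are
    informative but noisy.
    """
    amps = {c: 0.0 for c in CHANNELS}
    if kind in ("CTC", "CTCC", "GFP_ONLY"):
        amps["FP1"] = float(0.8 * rng.lognormal(0.0, 0.2))
    if kind == "GFP_ONLY":
        return amps
    ratio = NC_SPECTRAL_RATIO if kind == "NC" else CTCC_SPECTRAL_RATIO
    scale = base_amplitude * n_cells ** (2.0 / 3.0) * rng.lognormal(0.0, 0.25)
    for ch, r in zip(SCATTER_CHANNELS, ratio):
        amps[ch] = float(scale * r * rng.lognormal(0.0, 0.1))
    return amps


def random_events(
    n_tumor: int,
    n_nc: int,
    config: AcquisitionConfig,
    rng: np.random.Generator,
    size_dist: ClusterSizeDistribution | None = None,
    min_cells: int | None = None,
    gfp_only_prob: float = 0.05,
    base_amplitude: float = 0.1,
    max_jitter: int = 2,
    min_gap_s: float = 0.02,
) -> list[EventSpec]:
    """Draw a randomly placed event population for one segment.

    ``n_tumor`` tumor events (CTC or CTCC depending on the drawn cell
    count, or GFP_ONLY with probability ``gfp_only_prob``) plus ``n_nc``
    non-cluster events. ``min_cells`` forces every tumor event to have
    at least that many cells (used to build cluster-only benchmarks).
    Centers are uniform over the segment with a minimum gap so pulses
    rarely overlap.
    """
    size_dist = size_dist or ClusterSizeDistribution()
    total = n_tumor + n_nc
    margin = 0.005 * config.segment_duration_s + 0.02
    usable = config.segment_duration_s - 2 * margin
    if total * min_gap_s > usable:
        raise ValueError("too many events for the segment at the requested gap")
    # stick-breaking placement: sorted uniform draws with enforced gap
    slack = usable - total * min_gap_s
    gaps = rng.dirichlet(np.ones(total + 1)) * slack
    centers = margin + np.cumsum(gaps[:-1] + min_gap_s) - min_gap_s / 2
    order = rng.permutation(total)
    kinds = ["tumor"] * n_tumor + ["NC"] * n_nc
    events: list[EventSpec] = []
    for idx, center in zip(order, centers):
        role = kinds[idx]
        if role == "tumor":
            n_cells = sample_cluster_size(size_dist, rng)
            if min_cells is not None:
                while n_cells < min_cells:
                    n_cells = sample_cluster_size(size_dist, rng)
            if rng.uniform() < gfp_only_prob:
                kind = "GFP_ONLY"
            else:
                kind = "CTC" if n_cells == 1 else "CTCC"
            diameter = cluster_diameter(n_cells, rng)
        else:
            kind, n_cells = "NC", 1
            diameter = float(rng.uniform(14.0, 25.0))
        jitter = {
            ch: int(rng.integers(-max_jitter, max_jitter + 1))
            for ch in SCATTER_CHANNELS
        }
        events.append(
            EventSpec(
                kind=kind,
                center_time_s=float(center),
                effective_diameter_um=diameter + config.slit_width_um,
                amplitudes=_event_amplitudes(kind, n_cells, rng, base_amplitude),
                n_cells=n_cells,
                channel_jitter=jitter,
            )
        )
    return events


@dataclass
class DayData:
    """One simulated experiment day: raw segments plus ground truth."""

    day_id: str
    config: AcquisitionConfig
    segments: list[dict[str, np.ndarray]]
    truth: pd.DataFrame  # includes a segment_index column


def simulate_day(
    day_id: str,
    config: AcquisitionConfig,
    seed: int | np.random.SeedSequence,
    n_segments: int = 1,
    n_tumor_per_segment: int = 30,
    n_nc_per_segment: int = 100,
    noise: NoiseModel | None = None,
    **event_kwargs,
) -> DayData:
    """Simulate one experiment day of ``n_segments`` segments."""
    noise = noise or NoiseModel()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(2 * n_segments)
    segments = []
    truths = []
    for i in range(n_segments):
        rng = np.random.default_rng(children[2 * i])
        events = random_events(
            n_tumor_per_segment, n_nc_per_segment, config, rng, **event_kwargs
        )
        traces, truth = render_trace(events, noise, config, children[2 * i + 1])
        truth.insert(0, "segment_index", i)
        segments.append(traces)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)
    truth.insert(0, "day_id", day_id)
    return DayData(day_id=day_id, config=config, segments=segments, truth=truth)


def simulate_experiment(
    n_days: int,
    config: AcquisitionConfig,
    seed: int,
    day_prefix: str = "day",
    **day_kwargs,
) -> list[DayData]:
    """Simulate a multi-day spike-in experiment from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_days)
    return [
        simulate_day(f"{day_prefix}{i:02d}", config, child, **day_kwargs)
        for i, child in enumerate(children)
    ]
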