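# Methods

This note documents the models, parameter choices and numerical
conventions behind `bsfc`, and the limits of what its synthetic
validation shows.

## Signal model and preprocessing

Traces are processed in fixed-length segments (default 90 s at 60 kHz;
the test suite and benchmark use 10-s segments, which exercise the same
code on ~600k-sample arrays at a fraction of the cost). Segment-wise
processing exists so that baseline drift and day-specific statistics
are always estimated locally.

The band-pass (2nd-order Butterworth, 50–6000 Hz) removes baseline
wander and high-frequency detector noise. Transit pulses have
characteristic durations of 0.2–0.6 ms (Gaussian σ of 7–13 samples),
placing their spectral energy near 0.4–1.5 kHz, comfortably inside the
band. The filter is applied forward-backward (`sosfiltfilt`): zero
phase means detected peak locations are unbiased, at the price of an
effectively 4th-order magnitude response. Fluorescence channels pass
through the same filter as the scattering channels. The first and last
1000 samples of each segment are excluded from peak calling because the
forward-backward pass leaves edge transients there.

Daily power normalization divides each scattering channel by
`Norm(λ) = Intensity_spectralon · Power_sample / Power_spectralon`.
The direction (division) is a design choice: it makes traces
dimensionless and comparable across days, and two days whose raw
signals differ only by delivered power normalize to identical traces
(asserted in the tests). Since filtering and scaling are both linear,
filtering and normalization commute; the pipeline filters first only
by convention.

## Peak detection

The detection threshold is `mean + 3σ` of the whole segment. After
band-pass filtering the mean is ≈ 0, so this is the classic 3σ rule
while remaining well defined for unfiltered inputs. Candidate maxima
are all strict local maxima, with plateaus resolved to their leftmost
sample. Threshold-crossing ranges are maximal runs above threshold;
each range keeps exactly one peak (the tallest candidate, leftmost on
ties), and candidates that never crossed the threshold are dropped.

FWHM is measured at `(height + segment mean)/2` above the segment-mean
baseline — robust to residual offsets — with linear interpolation at
the two crossings; the width is the distance between the interpolated
crossings. If the half-max level falls below the baseline (degenerate
peak), the range width is used instead and a warning logged. AUC is
the sum of (signal − segment mean) over the range.

Gating uses the cumulative-signal FWHM (per-channel widths are stored
but not gated on): the cumulative signal is what detection ran on, and
its SNR is the highest. `width_in_points` uses `floor(Δt·fs)`, the
conservative choice for a minimum-width gate; it maps the 15-µm
largest-single-cell case to 21 points, hence the ≥ 20-point cluster
gate (~14 µm). A 5σ threshold variant for the fluorescence channel is
exposed as an option (`n_sigma` argument) but 3σ is the default; on
high-SNR fluorescence both find the same peaks.

## Labeling

A gated scattering candidate is a CTCC iff its threshold-crossing range
overlaps the range of some FP1 peak; overlap is parameter-free, unlike
a tolerance window, and tolerant of the few-sample inter-channel time
shifts the simulator reproduces. Ambiguities resolve to maximal
overlap, then the earlier FP1 peak. CTCC feature windows are centered
on the FP1 peak location (fluorescence localizes the event more
sharply); NC windows on the scattering peak location. FP1 peaks with
no scattering match are reported separately — fluorescent events whose
scattering signature drowned in the blood background.

The spike-in sensitivity report uses per-day
`sensitivity = detected/expected · 100` and
`% error = |expected − detected| / detected · 100` with sample (n−1)
standard deviations across days. The percent-error denominator is the
*detected* count; this convention reproduces every per-day value of
the packaged five-day validation table, whose printed expected counts
are themselves inconsistently rounded (e.g. 3.13 × 160 = 500.8 printed
as 500) — tests therefore allow ±1 on recomputed expected counts.

## Features

Normalization statistics are computed per scattering channel per
segment. The peak-referenced methods (max-peak, mean-peak>5σ) rerun
detection on the single channel being normalized and fail loudly when
a segment has no qualifying peaks. The zero-mean and zero-median
methods use the moments of *all* raw samples, peaks included. Only
zero-mean/zero-median are invariant to channel gain and offset — the
property that makes features comparable across days with different
illumination power — and zero-mean is the default.

Windows are ±13 points per channel around a common center (27 samples
per channel; 81 features for three channels, ordered 405, 488, 633).
±13 covers the full extent of the smallest gated cluster (20-point
FWHM). Events whose window would cross a segment edge are discarded,
never padded: padding would fabricate signal, and the expected loss is
a vanishing fraction of events.

## Classifier

Gentle AdaBoost is implemented in `bsfc.boost` because mainstream
libraries ship the discrete/real/SAMME variants: each cycle fits a
regression tree to the ±1 labels by weighted least squares (the tree
fit delegates to `sklearn.tree.DecisionTreeRegressor` with sample
weights, which is exactly that), adds it to the additive model with
shrinkage ν = 0.899, and reweights
`w_i ← w_i · exp(−y_i ν f_m(x_i))`. "102 splits" is interpreted as a
per-tree cap of 102 internal splits (`max_leaf_nodes = 103`), "84
learning cycles" as 84 boosting iterations, and the learning rate as
shrinkage on the weak learner (the convention of the toolbox the
hyperparameters originate from). Boosting stops early only if the
weight vector degenerates to zero (perfect fit at machine precision).

The class imbalance (roughly 20 NC per CTCC) is handled by ensemble
balancing, not reweighting: each of the 50 models trains on all CTCC
rows plus an equal-size NC sample drawn uniformly without replacement,
independently per model. Evaluation is a sequential cascade — only
events predicted positive survive to the next model — so survivor sets
are nested: specificity is monotonically non-decreasing and
sensitivity non-increasing in stage count, and performance converges
as stages accumulate. Model order is the training order and is
seed-controlled, so order sensitivity can be studied. The
choose-k-days harness enumerates all C(n, k) day subsets
lexicographically (286 for 10 of 13) and aggregates metrics with mean
and sample std; validation days are not used for model selection,
since the hyperparameters are fixed.

Undefined metrics (zero denominators, e.g. purity with no predicted
positives) surface as NaN with a warning and are skipped, with a
count, in aggregation.

## Synthetic data: what it emulates and what it does not

The simulator reproduces the *structure* of spike-in experiments:
five channels, 60 kHz, baseline drift, whole-blood scattering noise
(`blood_background_scale` multiplies scattering-channel σ only),
transit pulses of physical width, co-located fluorescence for tumor
events, occasional fluorescence-only events (default 5% of tumor
events — such events exist on real instruments but their rate is
unreported, so the value is a package choice), and inter-channel
jitter of up to ±2 samples.

Pulses are Gaussian with σ = FWHM/2.355 — the simplest unimodal shape
consistent with slit convolution; no optical physics (Mie scattering,
confocal PSF) and no parabolic flow profile is modeled (plug flow, as
the sizing arithmetic itself assumes). Cluster geometry: single cells
draw 7–13 µm; two-cell clusters draw between one and two single-cell
lengths (orientation ambiguity); n ≥ 3 clusters follow
`12.2 µm · n^(1/3)` (volume-conserving packing), which lands 3–4-cell
clusters near 24-point and 6+-cell clusters near 30-point pulses, the
sizes observed on the instrument. Cluster-size frequencies default to
the measured spike-in composition (65.8 / 17.1 / 15.0 / 1.4 / 0.7 %
for 1 / 2 / 3–6 / 7–9 / 9+ cells), with the open-ended category drawn
uniformly from 10–15 cells.

Class spectral signatures are phenomenological: cluster events scatter
405-dominant (1 : 0.6 : 0.5), non-cluster events 633-dominant
(0.5 : 0.6 : 1), with per-event and per-channel lognormal amplitude
variation. This makes the classes separable from per-channel window
shapes but identical in the cumulative signal. Consequently the
benchmark's near-perfect metrics certify the *pipeline machinery* —
detection, gating, labeling, feature extraction, balanced cascade —
not performance on real blood, where the cluster/non-cluster contrast
is far subtler and no quantitative SNR distribution is available to
calibrate against. Published instrument-data performance cannot be
reproduced without the original raw traces, which are not publicly
deposited.

All randomness descends from one integer master seed through
`numpy.random.SeedSequence` spawns (one child per channel, segment,
day and model), making every artifact bit-reproducible.

## Benchmark problem sizes

The reference benchmark simulates 5 training + 2 test days, 3 segments
of 10 s per day, 10 tumor (all ≥ 3 cells) and 100 non-cluster events
per segment — about 200 CTCC and 2000 NC events in total — with
per-channel SNR ≳ 5, and trains the full 50-model cascade. These sizes
keep a complete end-to-end run around half a minute while leaving every
algorithmic path identical to a full-scale run.

## Known limitations

- Overlapping events are rendered additively but detection keeps one
  peak per threshold-crossing range; merged events are not
  deconvolved.
- Fixed-length windows truncate large clusters (a 30-point cluster
  extends beyond ±13 samples); variable-length features are out of
  scope.
- The FP2 (red fluorescence) channel is simulated and stored but never
  used in features, mirroring its exclusion from analysis upstream.
- Amplitude calibration is phenomenological; absolute signal units are
  arbitrary.
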