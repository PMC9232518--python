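import numpy as np
import pytest

from bsfc.config import CHANNELS, AcquisitionConfig
from bsfc.peaks import detect_peaks, flow_velocity
from bsfc.preprocess import cumulative_scatter
from bsfc.simulate import (
    ClusterSizeDistribution,
    EventSpec,
    NoiseModel,
    event_pulse,
    render_trace,
    sample_cluster_size,
    simulate_day,
)


def measured_fwhm(snippet):
    """Width at half maximum of a clean snippet, linearly interpolated."""
    half = snippet.max() / 2.0
    above = np.flatnonzero(snippet > half)
    i, j = above[0], above[-1]
    left = i - (snippet[i] - half) / (snippet[i] - snippet[i - 1])
    right = j + (snippet[j] - half) / (snippet[j] - snippet[j + 1])
    return right - left


class TestClusterSizeDistribution:
    def test_degenerate_distribution_always_single(self):
        dist = ClusterSizeDistribution(1.0, 0.0, 0.0, 0.0, 0.0)
        rng = np.random.default_rng(0)
        assert all(sample_cluster_size(dist, rng) == 1 for _ in range(100))

    def test_default_single_fraction_matches_spiked_composition(self):
        rng = np.random.default_rng(1)
        n = 10**5
        singles = sum(sample_cluster_size(ClusterSizeDistribution(), rng) == 1
                      for _ in range(n))
        p = 0.658
        assert abs(singles / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_within_category_uniform_mean(self):
        dist = ClusterSizeDistribution(0.0, 0.0, 1.0, 0.0, 0.0)
        rng = np.random.default_rng(2)
        draws = [sample_cluster_size(dist, rng) for _ in range(10**4)]
        assert np.mean(draws) == pytest.approx(4.5, abs=0.05)  # uniform{3..6}
        assert set(draws) == {3, 4, 5, 6}

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            ClusterSizeDistribution(0.5, 0.0, 0.0, 0.0, 0.0).probabilities()


class TestEventPulse:
    def make_spec(self, diameter_um, acq, kind="CTCC", n_cells=3):
        amps = {"S405": 1.0, "S488": 0.6, "S633": 0.5, "FP1": 0.8, "FP2": 0.0}
        if kind == "NC":
            amps["FP1"] = 0.0
        return EventSpec(kind=kind, center_time_s=1.0,
                         effective_diameter_um=diameter_um + acq.slit_width_um,
                         amplitudes=amps, n_cells=n_cells)

    def test_large_single_cell_width(self, acq10s):
        spec = self.make_spec(15.0, acq10s)
        snip = event_pulse(spec, acq10s)["S405"]
        assert 21 <= measured_fwhm(snip) <= 22

    def test_small_cluster_width(self, acq10s):
        spec = self.make_spec(17.2, acq10s)
        assert measured_fwhm(event_pulse(spec, acq10s)["S405"]) == pytest.approx(
            24, abs=1
        )

    def test_zero_amplitude_channel_is_flat(self, acq10s):
        spec = self.make_spec(15.0, acq10s, kind="NC")
        assert np.all(event_pulse(spec, acq10s)["FP1"] == 0.0)

    def test_jitter_shifts_scatter_channel(self, acq10s):
        amps = {"S405": 1.0, "S488": 1.0, "S633": 1.0, "FP1": 0.5, "FP2": 0.0}
        spec = EventSpec(kind="CTCC", center_time_s=1.0,
                         effective_diameter_um=20.0, amplitudes=amps,
                         n_cells=3, channel_jitter={"S488": 2})
        pulse = event_pulse(spec, acq10s)
        assert np.argmax(pulse["S488"]) - np.argmax(pulse["S405"]) == 2

    def test_zero_flow_rate_rejected(self, acq10s):
        with pytest.raises(ValueError):
            bad = AcquisitionConfig(flow_rate_ul_min=0.0)

    def test_event_kind_invariants_enforced(self):
        with pytest.raises(ValueError):  # CTCC needs >= 2 cells
            EventSpec("CTCC", 1.0, 20.0, {"FP1": 1.0}, n_cells=1)
        with pytest.raises(ValueError):  # GFP_ONLY must not scatter
            EventSpec("GFP_ONLY", 1.0, 20.0, {"FP1": 1.0, "S405": 0.5})
        with pytest.raises(ValueError):  # NC must not fluoresce
            EventSpec("NC", 1.0, 20.0, {"S405": 0.5, "FP1": 0.2})


class TestRenderTrace:
    def test_no_events_no_noise_constant_baseline(self, acq10s, silent_noise):
        noise = NoiseModel(
            baseline={c: 0.3 for c in CHANNELS},
            drift_amplitude=0.0,
            white_sigma={c: 0.0 for c in CHANNELS},
            blood_background_scale=1.0,
        )
        traces, truth = render_trace([], noise, acq10s, seed=0)
        assert truth.empty
        for c in CHANNELS:
            np.testing.assert_allclose(traces[c], 0.3)

    def test_single_event_ground_truth_and_colocation(self, acq10s, silent_noise):
        spec = EventSpec(
            "CTCC", 5.0, 22.0,
            {"S405": 1.0, "S488": 0.6, "S633": 0.5, "FP1": 0.8, "FP2": 0.0},
            n_cells=3,
        )
        traces, truth = render_trace([spec], silent_noise, acq10s, seed=0)
        assert len(truth) == 1
        assert np.argmax(traces["FP1"]) == np.argmax(traces["S405"])
        assert truth.center_sample.iloc[0] == np.argmax(traces["S405"])

    def test_seed_determinism(self, acq10s):
        day_a = simulate_day("d", acq10s, seed=9, n_segments=1,
                             n_tumor_per_segment=20, n_nc_per_segment=80)
        day_b = simulate_day("d", acq10s, seed=9, n_segments=1,
                             n_tumor_per_segment=20, n_nc_per_segment=80)
        day_c = simulate_day("d", acq10s, seed=10, n_segments=1,
                             n_tumor_per_segment=20, n_nc_per_segment=80)
        for c in CHANNELS:
            np.testing.assert_array_equal(day_a.segments[0][c],
                                          day_b.segments[0][c])
            assert not np.array_equal(day_a.segments[0][c],
                                      day_c.segments[0][c])
        assert day_a.truth.equals(day_b.truth)

    def test_truth_rows_equal_requested_events(self, acq10s):
        day = simulate_day("d", acq10s, seed=5, n_segments=2,
                           n_tumor_per_segment=15, n_nc_per_segment=60)
        assert len(day.truth) == 2 * (15 + 60)

    def test_event_outside_segment_rejected(self, acq10s, silent_noise):
        spec = EventSpec("NC", 99.0, 20.0, {"S633": 1.0})
        with pytest.raises(ValueError):
            render_trace([spec], silent_noise, acq10s, seed=0)


class TestBloodBackground:
    def test_scatter_snr_decreases_with_background_scale(self):
        base = NoiseModel()
        snrs = []
        for scale in (1.0, 2.0, 4.0):
            nm = NoiseModel(blood_background_scale=scale)
            snrs.append(1.0 / nm.effective_sigma("S405"))
        assert snrs[0] > snrs[1] > snrs[2]

    def test_fluorescence_sigma_unaffected(self):
        a = NoiseModel(blood_background_scale=1.0)
        b = NoiseModel(blood_background_scale=4.0)
        assert a.effective_sigma("FP1") == b.effective_sigma("FP1")

    def test_scale_below_one_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(blood_background_scale=0.5)


class TestDetectorSimulatorOracle:
    def test_noise_free_locations_and_widths_match_ground_truth(
        self, acq10s, silent_noise
    ):
        """Simulator and detector agree on noise-free traces: every
        injected event is recovered at its center with its width."""
        day = simulate_day(
            "d", acq10s, seed=3, n_segments=1, n_tumor_per_segment=10,
            n_nc_per_segment=40, noise=silent_noise, min_cells=3,
            gfp_only_prob=0.0, max_jitter=0,
        )
        cum = cumulative_scatter(day.segments[0])
        peaks = sorted(detect_peaks(cum, edge_guard=0),
                       key=lambda p: p.location)
        truth = day.truth.sort_values("center_sample")
        assert len(peaks) == len(truth)
        for p, (_, row) in zip(peaks, truth.iterrows()):
            assert abs(p.location - row.center_sample) <= 1
            assert abs(p.fwhm_points - row.fwhm_samples) <= 1.0
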