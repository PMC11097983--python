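"""Baseline profiles, potentiation peaks and channel classification."""

import numpy as np
import pytest

import cspot
from cspot.config import AnalysisConfig, ConfigError
from cspot.potentiation import (
    PotentiationModel,
    PotentiationPeak,
    baseline_profile,
    classify_channel,
    detect_peaks,
    quantify,
    subtract_spontaneous,
)
from cspot.psth import PSTH

WINDOW = (-500.0, 100.0)


def make_psth(counts, block_index=None):
    return PSTH(np.asarray(counts, dtype=int), 1.0, WINDOW, 120,
                block_index=block_index)


def flat_profile(mean=0.0, sd=1.0):
    from cspot.potentiation import BaselineProfile

    return BaselineProfile(
        mean=np.full(600, mean), sd=np.full(600, sd),
        contributing_blocks=tuple(range(4, 12)), window_ms=WINDOW, bin_width_ms=1.0,
    )


def peaks_at(spec: dict[int, list[float]], excess=3.0):
    """{block: [latencies]} -> peaks_by_block mapping."""
    return {
        b: [PotentiationPeak(b, lat, excess) for lat in lats]
        for b, lats in spec.items()
    }


class TestSubtractSpontaneous:
    def test_constant_baseline_shifts_bins(self):
        counts = np.full(600, 2, dtype=int)
        counts[500 + 7] = 7
        adj = subtract_spontaneous(make_psth(counts))
        assert adj[500 + 7] == pytest.approx(5.0)
        assert adj[0] == pytest.approx(0.0)

    def test_uniform_psth_adjusts_to_zero(self):
        adj = subtract_spontaneous(make_psth(np.full(600, 4)))
        assert np.allclose(adj, 0.0)

    def test_matches_explicit_loop_oracle(self, rng):
        for _ in range(100):
            counts = rng.poisson(3.0, 600)
            adj = subtract_spontaneous(make_psth(counts))
            m = sum(counts[i] for i in range(500)) / 500.0
            oracle = np.array([c - m for c in counts])
            assert np.allclose(adj, oracle)


class TestBaselineProfile:
    def test_identical_blocks_have_zero_sd(self):
        block = np.arange(600, dtype=float)
        prof = baseline_profile([block] * 8, range(4, 12), WINDOW, 1.0)
        assert np.allclose(prof.sd, 0.0)
        assert np.allclose(prof.mean, block)

    def test_bimodal_bin_values(self):
        """Bin values {1,1,1,1,3,3,3,3} across blocks: mean 2, population SD 1."""
        blocks = [np.full(600, v, dtype=float) for v in (1, 1, 1, 1, 3, 3, 3, 3)]
        prof = baseline_profile(blocks, range(8), WINDOW, 1.0)
        assert prof.mean[510] == pytest.approx(2.0)
        assert prof.sd[510] == pytest.approx(1.0)

    def test_matches_explicit_mean_sd_oracle(self, rng):
        for _ in range(100):
            blocks = [rng.normal(0, 2, 600) for _ in range(8)]
            prof = baseline_profile(blocks, range(8), WINDOW, 1.0)
            stack = np.array(blocks)
            for b in (0, 250, 510, 599):
                vals = stack[:, b]
                m = vals.mean()
                sd = np.sqrt(((vals - m) ** 2).mean())
                assert prof.mean[b] == pytest.approx(m)
                assert prof.sd[b] == pytest.approx(sd)

    def test_wrong_block_count_rejected_but_overridable(self):
        blocks = [np.zeros(600)] * 5
        with pytest.raises(ConfigError):
            baseline_profile(blocks, range(5), WINDOW, 1.0)
        prof = baseline_profile(blocks, range(5), WINDOW, 1.0, expected_n=None)
        assert len(prof.contributing_blocks) == 5


class TestDetectPeaks:
    def test_simple_exceedance(self):
        """Adjusted 5 against mean 2 + 2 x SD 1: peak with excess 3."""
        prof = flat_profile(mean=2.0, sd=1.0)
        adj = np.full(600, 2.0)
        adj[500 + 10] = 5.0
        peaks = detect_peaks(make_psth(np.zeros(600), 13), adj, prof)
        assert len(peaks) == 1
        assert peaks[0].latency_ms == 10.0
        assert peaks[0].excess == pytest.approx(3.0)
        assert peaks[0].block_index == 13

    def test_boundary_value_is_not_a_peak(self):
        prof = flat_profile(mean=2.0, sd=1.0)
        adj = np.full(600, 2.0)
        adj[500 + 10] = 4.0  # exactly mean + 2 SD
        assert detect_peaks(make_psth(np.zeros(600)), adj, prof) == []

    def test_restricted_to_response_window(self):
        prof = flat_profile(mean=0.0, sd=0.5)
        adj = np.zeros(600)
        adj[500 - 20] = 10.0  # pre-stimulus
        adj[500 + 55] = 10.0  # beyond 50 ms
        assert detect_peaks(make_psth(np.zeros(600)), adj, prof) == []

    def test_matches_brute_force_bin_scan(self, rng):
        for _ in range(100):
            prof = flat_profile(0.0, 1.0)
            adj = rng.normal(0, 1.5, 600)
            peaks = detect_peaks(make_psth(np.zeros(600)), adj, prof)
            got = {(p.latency_ms, round(p.excess, 9)) for p in peaks}
            want = set()
            for i in range(500, 550):
                if adj[i] > prof.mean[i] + 2 * prof.sd[i]:
                    want.add((float(i - 500), round(adj[i] - prof.mean[i], 9)))
            assert got == want


class TestClassifyChannel:
    POST = list(range(12, 24))
    PRE = list(range(0, 4))

    def classify(self, peaks, **kw):
        args = dict(
            post_blocks=self.POST, veto_blocks=self.PRE,
            latency_tolerance_ms=2.0, min_run=5, strong_run=7,
        )
        args.update(kw)
        return classify_channel(peaks, **args)

    def test_six_consecutive_blocks_pass_run5(self):
        call = self.classify(peaks_at({b: [10.0] for b in range(13, 19)}))
        assert call.potentiated
        assert call.criterion == "run5"
        assert call.latency_ms == 10.0
        assert call.supporting_blocks == tuple(range(13, 19))

    def test_four_consecutive_blocks_fail(self):
        call = self.classify(peaks_at({b: [10.0] for b in range(13, 17)}))
        assert not call.potentiated
        assert call.criterion == "none"

    def test_pre_drug_peak_at_same_latency_vetoes(self):
        peaks = peaks_at({b: [10.0] for b in range(13, 19)})
        peaks.update(peaks_at({2: [10.0]}))
        call = self.classify(peaks)
        assert not call.potentiated

    def test_pre_drug_peak_within_tolerance_vetoes(self):
        peaks = peaks_at({b: [10.0] for b in range(13, 19)})
        peaks.update(peaks_at({0: [11.5]}))
        assert not self.classify(peaks).potentiated

    def test_novel_latency_not_vetoed_by_distant_pre_drug_peaks(self):
        """A new short-latency response is detected even when the channel
        already fired pre-drug at a much longer latency."""
        peaks = peaks_at({b: [5.0, 18.0] for b in range(12, 20)})
        peaks.update(peaks_at({0: [18.0], 1: [18.0], 2: [18.0], 3: [18.0]}))
        call = self.classify(peaks)
        assert call.potentiated
        assert call.latency_ms == 5.0

    def test_seven_or_more_blocks_labelled_run7(self):
        call = self.classify(peaks_at({b: [8.0] for b in range(12, 19)}))
        assert call.potentiated and call.criterion == "run7"

    def test_run_must_be_strictly_consecutive(self):
        blocks = [12, 13, 14, 16, 17, 18]  # gap at 15
        call = self.classify(peaks_at({b: [8.0] for b in blocks}))
        assert not call.potentiated
        call = self.classify(peaks_at({b: [8.0] for b in blocks}), allow_gap=True)
        assert call.potentiated

    def test_veto_min_run_requires_recurring_pre_drug_peaks(self):
        peaks = peaks_at({b: [10.0] for b in range(13, 19)})
        peaks.update(peaks_at({1: [10.0]}))
        assert not self.classify(peaks).potentiated
        # a single isolated pre-drug peak no longer vetoes at min run 2
        assert self.classify(peaks, veto_min_run=2).potentiated
        peaks.update(peaks_at({2: [10.0]}))
        assert not self.classify(peaks, veto_min_run=2).potentiated

    def test_longest_run_and_earliest_latency_win(self):
        peaks = {}
        peaks.update(peaks_at({b: [30.0] for b in range(12, 17)}))   # run 5
        peaks.update(peaks_at({b: [20.0] for b in range(12, 20)}))   # run 8
        call = self.classify(peaks)
        assert call.latency_ms == 20.0 and call.criterion == "run7"

    def test_no_post_blocks_rejected(self):
        with pytest.raises(ConfigError):
            classify_channel({}, post_blocks=[], veto_blocks=[])


class TestQuantify:
    def test_two_peak_arithmetic(self):
        """Excesses {3, 4} at 10 and 11 ms: total 7, duration 2, average 3.5."""
        peaks = {b: [PotentiationPeak(b, 10.0, 3.0), PotentiationPeak(b, 11.0, 4.0)]
                 for b in range(12, 17)}
        call = classify_channel(peaks, post_blocks=range(12, 24), veto_blocks=range(4))
        lat, dur, total, avg = quantify(call)
        assert (lat, dur) == (10.0, 2)
        assert total == pytest.approx(5 * 7.0)
        assert avg == pytest.approx(5 * 7.0 / 2)

    def test_single_peak(self):
        peaks = {b: [PotentiationPeak(b, 9.0, 5.0)] for b in range(12, 17)}
        call = classify_channel(peaks, post_blocks=range(12, 24), veto_blocks=range(4))
        lat, dur, total, avg = quantify(call)
        assert (lat, dur, total, avg) == (9.0, 1, 25.0, 25.0)

    def test_rejects_non_potentiated_call(self):
        call = classify_channel({}, post_blocks=[12], veto_blocks=[0])
        with pytest.raises(ValueError):
            quantify(call)

    def test_average_is_total_over_duration(self, rng):
        for _ in range(50):
            lats = rng.choice(np.arange(5.0, 30.0), size=3, replace=False)
            peaks = {
                b: [PotentiationPeak(b, lats[0], float(rng.uniform(1, 5)))]
                + [PotentiationPeak(b, l, float(rng.uniform(1, 5)))
                   for l in lats[1:] if abs(l - lats[0]) <= 2.0]
                for b in range(12, 18)
            }
            call = classify_channel(peaks, post_blocks=range(12, 24),
                                    veto_blocks=range(4))
            if not call.potentiated:
                continue
            supporting = [
                p for b in call.supporting_blocks for p in peaks[b]
                if abs(p.latency_ms - call.latency_ms) <= 4.0
            ]
            assert call.average_magnitude == pytest.approx(
                call.total_magnitude / call.duration_bins
            )


class TestPotentiationModel:
    def test_constructed_potentiating_channel_is_called(self):
        proto = cspot.experiment3_protocol()
        onset = 12
        comp = cspot.ResponseComponent(8.5, 0.6, 0.6, potentiable=True)
        model = cspot.ChannelModel(
            20.0, (comp,), potentiation_onset_block=onset,
            potentiation_gain=3.0, ramp_blocks=1,
        )
        ds, truth = cspot.simulate_experiment(proto, [model], seed=77)
        res = PotentiationModel(ds).fit()
        call = res.calls_list[0]
        assert truth.potentiated[0]
        assert call.potentiated
        assert abs(call.latency_ms - 8.5) <= 3.0
        assert call.criterion == "run7"

    def test_schedule_without_drug_blocks_rejected(self):
        proto = cspot.experiment1_protocol(block_size=5)
        sched = cspot.generate_stim_times(proto, 0)
        with pytest.raises(ConfigError):
            PotentiationModel({0: np.array([1.0])}, schedule=sched)

    def test_summary_reports_counts(self):
        proto = cspot.experiment3_protocol(block_size=10)
        models = [cspot.ChannelModel(5.0)] * 3
        ds, _ = cspot.simulate_experiment(proto, models, seed=3)
        res = PotentiationModel(ds).fit()
        text = res.summary()
        assert "channels: 3" in text
        assert "potentiated" in text
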