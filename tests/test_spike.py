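"""Spike-train primitives and the QC/SC heat-response classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prurikit.spike import (
    NOT_REACHED,
    BurstParams,
    FiberClass,
    FiberMetadata,
    HeatLabel,
    HeatStimulus,
    IFSeries,
    MechanoClass,
    SpikeTrain,
    classify_by_cv,
    classify_heat_response,
    classify_mechanosensitivity,
    detect_onset_burst,
    instantaneous_frequency,
    median_smooth3,
    time_of_peak_discharge,
    von_frey_threshold,
)

from conftest import make_online_archetype, make_qc_archetype, make_sc_archetype


class TestInstantaneousFrequency:
    def test_reciprocal_isi_assigned_to_later_spike(self):
        s = instantaneous_frequency(SpikeTrain("f", np.array([1.0, 1.5, 2.0])))
        assert np.allclose(s.times, [1.5, 2.0])
        assert np.allclose(s.frequencies, [2.0, 2.0])

    @pytest.mark.parametrize("ts", [[], [0.7]])
    def test_fewer_than_two_spikes_yield_empty_series(self, ts):
        assert len(instantaneous_frequency(SpikeTrain("f", np.array(ts)))) == 0

    def test_matches_bruteforce_on_random_train(self):
        rng = np.random.default_rng(11)
        ts = np.sort(rng.uniform(0, 10, size=50))
        s = instantaneous_frequency(SpikeTrain("f", ts))
        # element-wise oracle
        expect = [(ts[i + 1], 1.0 / (ts[i + 1] - ts[i])) for i in range(49)]
        assert np.allclose(s.times, [e[0] for e in expect])
        assert np.allclose(s.frequencies, [e[1] for e in expect])

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain("f", np.array([1.0, 1.0, 2.0]))


class TestMedianSmooth3:
    def test_constant_series_unchanged(self):
        s = IFSeries(np.arange(4.0), np.full(4, 5.0))
        out = median_smooth3(s)
        assert np.array_equal(out.frequencies, s.frequencies)

    def test_removes_singleton_spike(self):
        s = IFSeries(np.arange(3.0), np.array([1.0, 100.0, 1.0]))
        assert np.allclose(median_smooth3(s).frequencies, [1.0, 1.0, 1.0])

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0.5, 60, size=20)
        s = IFSeries(np.arange(20.0), f)
        out = median_smooth3(s)
        oracle = f.copy()
        for i in range(1, 19):
            oracle[i] = sorted(f[i - 1 : i + 2])[1]
        assert np.allclose(out.frequencies, oracle)
        assert np.array_equal(out.times, s.times)

    @given(st.lists(st.floats(0.1, 100), min_size=0, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_preserves_length_and_times_and_idempotent_on_monotone(self, freqs):
        s = IFSeries(np.arange(len(freqs), dtype=float), np.array(freqs))
        out = median_smooth3(s)
        assert len(out) == len(s)
        assert np.array_equal(out.times, s.times)
        mono = IFSeries(s.times, np.sort(np.array(freqs))) if freqs else s
        assert np.allclose(
            median_smooth3(mono).frequencies, mono.frequencies
        ), "3-point median must be the identity on a monotone series"


class TestPeakDischarge:
    def test_unique_max(self):
        s = IFSeries(np.array([0.1, 0.3, 1.2]), np.array([10.0, 40.0, 20.0]))
        assert time_of_peak_discharge(s) == pytest.approx(0.3)

    def test_tie_broken_by_earliest(self):
        s = IFSeries(np.array([0.2, 0.9]), np.array([30.0, 30.0]))
        assert time_of_peak_discharge(s) == pytest.approx(0.2)

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 4, 40))
        f = rng.choice([5.0, 10.0, 20.0, 40.0], size=40)  # ties likely
        s = IFSeries(t, f)
        best = min((tt for tt, ff in zip(t, f) if ff == f.max()))
        assert time_of_peak_discharge(s) == pytest.approx(best)

    def test_empty_series_errors(self):
        with pytest.raises(ValueError, match="no discharge"):
            time_of_peak_discharge(IFSeries(np.empty(0), np.empty(0)))


class TestOnsetBurst:
    def test_qc_archetype_bursts(self, stimulus):
        train = make_qc_archetype()
        series = median_smooth3(instantaneous_frequency(train))
        assert detect_onset_burst(series, stimulus, offset_s=0.3)

    def test_sc_archetype_does_not_burst(self, stimulus):
        train = make_sc_archetype()
        series = median_smooth3(instantaneous_frequency(train))
        assert not detect_onset_burst(series, stimulus, offset_s=0.3)

    def test_empty_series_is_no_burst(self, stimulus):
        assert not detect_onset_burst(IFSeries(np.empty(0), np.empty(0)), stimulus)

    def test_sustained_discharge_is_not_adapting(self, stimulus):
        # steady 40 Hz through the plateau: burst-like onset but no adaptation
        ts = np.arange(0.05, 3.2, 0.025)
        series = instantaneous_frequency(SpikeTrain("f", ts))
        assert not detect_onset_burst(series, stimulus)


class TestClassifyHeatResponse:
    def test_qc_archetype(self, stimulus, qc_archetype):
        cls = classify_heat_response(qc_archetype, stimulus)
        assert cls.label is HeatLabel.QC
        assert cls.burst_at_onset
        assert cls.equality_line_s == pytest.approx(0.5)

    def test_sc_archetype(self, stimulus, sc_archetype):
        cls = classify_heat_response(sc_archetype, stimulus)
        assert cls.label is HeatLabel.SC
        assert not cls.burst_at_onset
        assert cls.peak_time_s > cls.equality_line_s

    def test_peak_on_equality_line_unclassified(self, stimulus):
        cls = classify_heat_response(make_online_archetype(), stimulus)
        assert cls.peak_time_s == pytest.approx(cls.equality_line_s)
        assert cls.label is HeatLabel.UNCLASSIFIED

    def test_burst_overrides_late_peak(self, stimulus):
        # burst in the ramp plus a *larger* late peak: still QC
        latency = 0.3
        burst = latency + np.arange(0.05, 0.2, 0.02)
        late = latency + 1.5 + np.arange(0, 0.2, 0.01)  # 100 Hz in plateau
        meta = FiberMetadata(conduction_latency_skin_s=latency)
        train = SpikeTrain("f", np.concatenate([burst, late]), meta)
        cls = classify_heat_response(train, stimulus)
        assert cls.peak_time_s > cls.equality_line_s
        assert cls.label is HeatLabel.QC and cls.burst_at_onset

    def test_too_few_spikes_unclassified(self, stimulus):
        meta = FiberMetadata(conduction_latency_skin_s=0.3)
        cls = classify_heat_response(SpikeTrain("f", np.array([1.0]), meta), stimulus)
        assert cls.label is HeatLabel.UNCLASSIFIED and cls.peak_time_s is None

    def test_missing_latency_errors(self, stimulus):
        train = SpikeTrain("f", np.array([0.5, 1.0]), FiberMetadata())
        with pytest.raises(ValueError, match="latency"):
            classify_heat_response(train, stimulus)

    def test_invariant_to_time_translation(self, stimulus):
        for make in (make_qc_archetype, make_sc_archetype):
            base = classify_heat_response(make(), stimulus)
            shifted = classify_heat_response(make().shifted(7.5), stimulus, onset_s=7.5)
            assert shifted.label is base.label
            assert shifted.peak_time_s == pytest.approx(base.peak_time_s)

    def test_zero_tolerance_no_burst_partitions_by_sign(self, stimulus):
        # with the burst rule disabled and tolerance 0, the label is a pure
        # function of sign(peak - equality line)
        rng = np.random.default_rng(5)
        no_burst = BurstParams(burst_min_freq_hz=1e9)
        for _ in range(25):
            ts = np.sort(rng.uniform(0.0, 3.5, size=rng.integers(2, 40)))
            meta = FiberMetadata(conduction_latency_skin_s=float(rng.uniform(0.1, 0.5)))
            train = SpikeTrain("f", ts, meta)
            cls = classify_heat_response(
                train, stimulus, meta, tolerance_s=0.0, burst_params=no_burst
            )
            if cls.peak_time_s is None:
                assert cls.label is HeatLabel.UNCLASSIFIED
            elif cls.peak_time_s > cls.equality_line_s:
                assert cls.label is HeatLabel.SC
            elif cls.peak_time_s < cls.equality_line_s:
                assert cls.label is HeatLabel.QC
            else:
                assert cls.label is HeatLabel.UNCLASSIFIED


class TestFiberTaxonomy:
    @pytest.mark.parametrize(
        "cv,expected",
        [
            (1.2, FiberClass.C),
            (10.0, FiberClass.A_DELTA),
            (2.0, FiberClass.A_DELTA),
            (25.0, FiberClass.OUT_OF_RANGE),
        ],
    )
    def test_conduction_velocity_classes(self, cv, expected):
        assert classify_by_cv(cv) is expected

    def test_nonpositive_cv_errors(self):
        with pytest.raises(ValueError):
            classify_by_cv(0.0)

    @pytest.mark.parametrize(
        "responses,expected",
        [
            ({4.0: 1, 6.0: 2, 8.9: 4}, 6.0),
            ({4.0: 0, 6.0: 0, 8.9: 0}, NOT_REACHED),
            ({1.0: 2, 4.0: 0}, 1.0),
        ],
    )
    def test_von_frey_threshold(self, responses, expected):
        assert von_frey_threshold(responses) == expected

    def test_von_frey_count_out_of_range_errors(self):
        with pytest.raises(ValueError):
            von_frey_threshold({4.0: 5})

    @pytest.mark.parametrize(
        "threshold,expected",
        [
            (1.5, MechanoClass.MSA),
            (6.0, MechanoClass.MSA),
            (8.9, MechanoClass.MIA),
            (NOT_REACHED, MechanoClass.MIA),
        ],
    )
    def test_mechanosensitivity(self, threshold, expected):
        assert classify_mechanosensitivity(threshold) is expected


def test_heat_stimulus_validation():
    with pytest.raises(ValueError):
        HeatStimulus(baseline_temp_c=49, target_temp_c=38)
    with pytest.raises(ValueError):
        HeatStimulus(rise_time_s=0.0)
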