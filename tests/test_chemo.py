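"""Net-response scoring, time-course binning, and electrophysiology statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prurikit.chemo import (
    ContingencyTable2x2,
    InjectionRecording,
    association_chi_square,
    bin_time_course,
    joint_responsiveness_table,
    mixed_anova_fiber_pruritogen,
    net_response,
    prorated_baseline,
    scheffe_fiber_pruritogen,
)
from prurikit.stats import paired_t


def make_recording(fiber="f1", compound="ALA", baseline=0, spikes=(), inj=(0.0, 5.0)):
    return InjectionRecording(
        fiber_id=fiber,
        compound=compound,
        baseline_count=baseline,
        injection_interval=inj,
        post_spikes=np.array(spikes, dtype=float),
    )


class TestProratedBaseline:
    @pytest.mark.parametrize(
        "count,window,expected", [(6, 300, 30.0), (0, 300, 0.0), (7, 200, 7 * 200 / 60)]
    )
    def test_linear_prorating(self, count, window, expected):
        assert prorated_baseline(count, window) == pytest.approx(expected)

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            prorated_baseline(-1, 300)


class TestNetResponse:
    def test_forced_arithmetic(self):
        # pruritogen: 60 APs in window, baseline 6/min → prorated 30;
        # vehicle: 10 net APs → net = (60-30) - 10 = 20
        prur = make_recording(baseline=6, spikes=np.linspace(6, 290, 60))
        veh = make_recording(compound="ECF", baseline=0, spikes=np.linspace(6, 100, 10))
        net = net_response(prur, veh)
        assert net.net_aps == pytest.approx(20.0)
        assert net.responsive

    def test_identical_recordings_cancel(self):
        spikes = np.linspace(6, 250, 23)
        net = net_response(
            make_recording(baseline=3, spikes=spikes),
            make_recording(compound="ECF", baseline=3, spikes=spikes),
        )
        assert net.net_aps == pytest.approx(0.0)
        assert not net.responsive

    @pytest.mark.parametrize("n_spikes,responsive", [(9, False), (10, True)])
    def test_threshold_boundary_at_ten(self, n_spikes, responsive):
        prur = make_recording(spikes=np.linspace(6, 200, n_spikes))
        veh = make_recording(compound="ECF")
        assert net_response(prur, veh).responsive is responsive

    def test_window_starts_at_injection_end(self):
        # spikes during the 5-s injection are excluded by default
        prur = make_recording(spikes=[1.0, 2.0, 3.0, 10.0, 20.0])
        veh = make_recording(compound="ECF")
        assert net_response(prur, veh).total_aps == 2
        assert net_response(prur, veh, from_injection_end=False).total_aps == 5

    def test_fiber_mismatch_errors(self):
        with pytest.raises(ValueError, match="fiber"):
            net_response(make_recording("f1"), make_recording("f2", compound="ECF"))

    def test_additivity_doubling_counts(self):
        spikes = np.linspace(6, 290, 40)
        veh = make_recording(compound="ECF", baseline=0)
        one = net_response(make_recording(baseline=2, spikes=spikes), veh)
        doubled_spikes = np.sort(np.concatenate([spikes, spikes + 0.001]))
        two = net_response(make_recording(baseline=4, spikes=doubled_spikes), veh)
        assert two.net_aps == pytest.approx(2 * one.net_aps)


class TestBinTimeCourse:
    def test_half_open_convention(self):
        rec = make_recording(spikes=[1.0, 9.99, 10.0], inj=(0.0, 0.0))
        tc = bin_time_course(rec)
        assert tc.counts[0] == 2 and tc.counts[1] == 1 and tc.counts[2:].sum() == 0

    def test_empty_train_zero_bins(self):
        tc = bin_time_course(make_recording())
        assert tc.counts.sum() == 0 and len(tc.counts) == 30

    def test_matches_bruteforce_histogram(self):
        rng = np.random.default_rng(9)
        spikes = np.sort(rng.uniform(0, 320, 200))
        rec = make_recording(spikes=spikes)
        tc = bin_time_course(rec)
        # brute-force oracle with explicit loop over half-open bins
        offset = rec.injection_duration_s
        oracle = [
            sum(1 for t in spikes if offset + 10 * k <= t < offset + 10 * (k + 1))
            for k in range(30)
        ]
        assert np.array_equal(tc.counts, oracle)
        assert tc.counts.sum() == np.count_nonzero(
            (spikes >= offset) & (spikes < offset + 300)
        ), "counts must conserve the spikes inside the window"

    def test_bad_bin_errors(self):
        with pytest.raises(ValueError):
            bin_time_course(make_recording(), bin_s=0)
        with pytest.raises(ValueError):
            bin_time_course(make_recording(), bin_s=7)


class TestChiSquare:
    def test_closed_form_example(self):
        res = association_chi_square(ContingencyTable2x2(10, 0, 0, 10))
        assert res.statistic == pytest.approx(20.0)

    def test_independence_gives_zero(self):
        res = association_chi_square(ContingencyTable2x2(6, 3, 4, 2))  # ad == bc
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            association_chi_square(ContingencyTable2x2(5, 5, 0, 0))

    def test_agrees_with_generic_pearson_sum(self):
        # dual route: closed form vs observed-vs-expected Pearson sum
        rng = np.random.default_rng(21)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, size=4)
            mine = association_chi_square(ContingencyTable2x2(a, b, c, d))
            obs = np.array([[a, b], [c, d]])
            chi2, p, _, _ = sps.chi2_contingency(obs, correction=False)
            assert mine.statistic == pytest.approx(chi2, rel=1e-9)
            assert mine.p_value == pytest.approx(p, rel=1e-9)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t(np.arange(5.0), np.arange(5.0))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_nonzero_difference_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = paired_t(x, y)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(30))
        p = 2 * sps.t.sf(abs(t), 29)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)
        assert res.df == (29.0,)


def toy_mixed_table() -> pd.DataFrame:
    """4 fibers × 2 compounds with hand-computable sums of squares."""
    rows = [
        ("f1", "QC", "ALA", 10.0), ("f1", "QC", "BAM", 6.0),
        ("f2", "QC", "ALA", 14.0), ("f2", "QC", "BAM", 8.0),
        ("f3", "SC", "ALA", 2.0), ("f3", "SC", "BAM", 20.0),
        ("f4", "SC", "ALA", 4.0), ("f4", "SC", "BAM", 26.0),
    ]
    return pd.DataFrame(rows, columns=["fiber_id", "fiber_type", "compound", "net_aps"])


class TestMixedAnova:
    def test_toy_table_matches_hand_computed_sums_of_squares(self):
        # hand oracle: SS_between=24.5 (MS_bs=12.5), SS_within=112.5,
        # SS_interaction=312.5, MS_ws=2.5 → F = 1.96, 45, 125 on (1, 2) df
        res = {r.effect: r for r in mixed_anova_fiber_pruritogen(toy_mixed_table())}
        assert res["fiber_type"].statistic == pytest.approx(1.96, rel=1e-9)
        assert res["compound"].statistic == pytest.approx(45.0, rel=1e-9)
        assert res["Interaction"].statistic == pytest.approx(125.0, rel=1e-9)
        assert res["fiber_type"].df == (1.0, 2.0)

    def test_all_equal_responses_give_zero_f(self):
        df = toy_mixed_table().assign(net_aps=7.0)
        for r in mixed_anova_fiber_pruritogen(df):
            assert r.statistic == 0.0 and r.p_value == 1.0

    def test_incomplete_fibers_excluded_with_warning(self):
        df = pd.concat(
            [toy_mixed_table(),
             pd.DataFrame([("f5", "QC", "ALA", 9.0)], columns=toy_mixed_table().columns)]
        )
        with pytest.warns(UserWarning, match="excluding"):
            res = mixed_anova_fiber_pruritogen(df)
        base = mixed_anova_fiber_pruritogen(toy_mixed_table())
        assert res[0].statistic == pytest.approx(base[0].statistic)

    def test_simulated_interaction_detected(self):
        from prurikit.synth import generate_chemo_cohort

        df = generate_chemo_cohort(29, 31, rng=17)
        res = {r.effect: r for r in mixed_anova_fiber_pruritogen(df)}
        assert res["Interaction"].p_value < 0.001


class TestScheffe:
    def test_toy_table_matches_hand_computed_contrasts(self):
        # hand oracle on toy_mixed_table: MS_ws=2.5, MS_bs=12.5, pooled=7.5;
        # SC-BAM vs SC-ALA: F = 20²/2.5 = 160; QC-ALA vs SC-ALA: 9²/7.5 = 10.8
        res = {r.effect: r for r in scheffe_fiber_pruritogen(toy_mixed_table())}
        within = res["('SC', 'ALA') vs ('SC', 'BAM')"]
        assert within.statistic == pytest.approx(160.0, rel=1e-9)
        assert within.p_value == pytest.approx(
            float(sps.f.sf(160.0 / 3, 3, 2)), rel=1e-9
        )
        between = res["('QC', 'ALA') vs ('SC', 'ALA')"]
        assert between.statistic == pytest.approx(10.8, rel=1e-9)

    def test_equal_cell_means_nonsignificant(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"f{i}", "QC" if i < 10 else "SC", c, 10.0 + rng.normal())
            for i in range(20)
            for c in ("ALA", "BAM")
        ]
        df = pd.DataFrame(rows, columns=["fiber_id", "fiber_type", "compound", "net_aps"])
        for r in scheffe_fiber_pruritogen(df):
            assert r.p_value > 0.05

    def test_generator_effect_detected(self):
        from prurikit.synth import generate_chemo_cohort

        df = generate_chemo_cohort(29, 31, rng=17)
        res = {r.effect: r for r in scheffe_fiber_pruritogen(df)}
        sc_contrast = res["('SC', 'ALA') vs ('SC', 'BAM8_22')"]
        assert sc_contrast.p_value < 0.01

    def test_unknown_contrast_errors(self):
        with pytest.raises(ValueError, match="unknown contrast"):
            scheffe_fiber_pruritogen(
                toy_mixed_table(), comparisons=[(("QC", "ALA"), ("XX", "YY"))]
            )


class TestJointResponsiveness:
    def test_table_from_flags(self):
        from prurikit.chemo import NetResponse

        def nr(fid, comp, net):
            return NetResponse(fid, comp, 0, 0.0, 0.0, net, net >= 10)

        a = [nr("f1", "A", 20), nr("f2", "A", 20), nr("f3", "A", 0), nr("f4", "A", 0)]
        b = [nr("f1", "B", 20), nr("f2", "B", 0), nr("f3", "B", 20), nr("f4", "B", 0)]
        t = joint_responsiveness_table(a, b)
        assert (t.both, t.a_only, t.b_only, t.neither) == (1, 1, 1, 1)
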