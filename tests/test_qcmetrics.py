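"""QC metric suite: detection, efficiency, concordance, ALC, titration,
cross-reactivity, NTC, dynamic range, report assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelqc import Config
from panelqc.chipio import build_default_layout
from panelqc.errors import (
    ChipDataError,
    ConsistencyError,
    FitError,
    PartialReportError,
    UndefinedMetricError,
)
from panelqc.qcmetrics import (
    DetectionCall,
    alc,
    alc_by_ecdf_integration,
    build_mirqc_report,
    call_detection,
    calls_by_assay,
    cross_reactivity,
    dynamic_range,
    expression_range,
    fit_efficiency,
    ntc_positives,
    replicate_concordance,
    titration_auc,
    titration_scores,
)
from panelqc.synthdata import SimConfig, simulate_chip_run, simulate_ntc_run

from conftest import make_cluster_table, make_truth


def call(assay, detected, cq=np.nan, n=9):
    return DetectionCall(assay, detected, cq, n)


class TestCallDetection:
    def make_calls(self, cqs, config=None, **kwargs):
        layout = build_default_layout(n_targets=1, wells_total=99)
        t = make_cluster_table(cqs)
        # only the first cluster carries data in these unit fixtures
        small = build_default_layout(n_targets=1, wells_total=99)
        sub_layout = type(small)(small.chip_id, small.wells_total,
                                 (small.clusters[0],))
        return call_detection(t, sub_layout, config or Config(), **kwargs)

    def test_all_wells_just_below_cutoff_detected(self):
        (c,) = self.make_calls([33.9] * 9)
        assert c.detected and c.collapsed_cq == pytest.approx(33.9)

    def test_cq_exactly_at_cutoff_fails_strict_rule(self):
        (c,) = self.make_calls([34.0] * 9)
        assert not c.detected and np.isnan(c.collapsed_cq)

    def test_minority_amplification_not_detected(self):
        (c,) = self.make_calls([30.0] * 4 + [None] * 5)
        assert c.n_wells_amplified == 4 and not c.detected

    def test_exactly_min_wells_detected(self):
        (c,) = self.make_calls([30.0] * 5 + [None] * 4)
        assert c.detected and c.n_wells_amplified == 5

    def test_collapsed_is_median_of_amplified_only(self):
        (c,) = self.make_calls([30.0, 31.0, 32.0, 33.0, 33.5, None, None, 39.0, None])
        # 39 is above the cutoff; median over {30,31,32,33,33.5}
        assert c.collapsed_cq == pytest.approx(32.0)

    def test_mean_collapse_option(self):
        (c,) = self.make_calls([30.0] * 4 + [32.0], Config(well_collapse="mean"))
        assert c.collapsed_cq == pytest.approx(30.4)

    def test_missing_cluster_raises(self):
        layout = build_default_layout(n_targets=2, wells_total=99)
        t = make_cluster_table([30.0] * 9)  # only mir-001 present
        with pytest.raises(ConsistencyError):
            call_detection(t, layout, Config())


class TestFitEfficiency:
    def test_textbook_slope_is_full_efficiency(self):
        series = [(x, 20.0 - 3.3219 * x) for x in (0.0, -1.0, -2.0, -3.0)]
        fit = fit_efficiency(series)
        assert fit.efficiency_pct == pytest.approx(100.0, abs=0.01)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_threefold_series_exact_log2_spacing(self):
        # E = 1: 3-fold dilution steps Cq by log2(3) = 1.585
        xs = [0.0, -np.log10(3), -2 * np.log10(3), -3 * np.log10(3)]
        series = [(x, 20.0 - x * np.log2(10)) for x in xs]
        fit = fit_efficiency(series)
        assert fit.efficiency_pct == pytest.approx(100.0, abs=1e-9)

    def test_slope_minus_3_5(self):
        series = [(x, 20.0 - 3.5 * x) for x in (0.0, -1.0, -2.0)]
        assert fit_efficiency(series).efficiency_pct == pytest.approx(93.07, abs=0.01)

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(FitError):
            fit_efficiency([(0, 20), (-1, 23)])
        with pytest.raises(FitError):
            fit_efficiency([(0, 20), (0, 21), (0, 22)])

    @pytest.mark.parametrize("true_eff", [0.9, 1.0, 1.1])
    def test_recovers_generator_efficiency_exactly_without_noise(
            self, true_eff, small_layout, noise_free_sim, rng):
        truths = {
            cl.assay_id: make_truth(cl.assay_id, copies_A=1e6, efficiency=true_eff)
            for cl in small_layout.clusters
        }
        series = []
        for i in range(4):
            d = 3.0 ** -i
            copies = {a: t.copies_A * d for a, t in truths.items()}
            t = simulate_chip_run(copies, small_layout, noise_free_sim, rng,
                                  truths=truths)
            c = calls_by_assay(call_detection(t, small_layout, Config()))["mir-001"]
            series.append((np.log10(d), c.collapsed_cq))
        fit = fit_efficiency(series)
        assert fit.efficiency_pct == pytest.approx(true_eff * 100, abs=1e-9)


class TestReplicateConcordance:
    def test_reported_study_bookkeeping(self):
        """131 double + 7 single of 138 detected-in-either assays."""
        calls1, calls2 = [], []
        for i in range(131):
            calls1.append(call(f"a{i}", True, 30.0))
            calls2.append(call(f"a{i}", True, 30.0))
        for i in range(131, 138):
            calls1.append(call(f"a{i}", True, 30.0))
            calls2.append(call(f"a{i}", False))
        for i in range(138, 164):
            calls1.append(call(f"a{i}", False))
            calls2.append(call(f"a{i}", False))
        pd_, ps, pairs, _ = replicate_concordance(calls1, calls2)
        assert round(pd_, 2) == 94.93
        assert round(ps, 2) == 5.07
        assert len(pairs) == 131

    def test_identical_call_sets_fully_concordant(self):
        calls = [call(f"a{i}", True, 25.0 + i) for i in range(5)]
        pd_, ps, pairs, r = replicate_concordance(calls, calls)
        assert pd_ == 100.0 and ps == 0.0
        assert r == pytest.approx(1.0)

    def test_disjoint_detections_all_single(self):
        c1 = [call("a", True, 25.0), call("b", False)]
        c2 = [call("a", False), call("b", True, 26.0)]
        pd_, ps, pairs, r = replicate_concordance(c1, c2)
        assert pd_ == 0.0 and ps == 100.0 and pairs.empty

    def test_empty_denominator_raises(self):
        c = [call("a", False)]
        with pytest.raises(UndefinedMetricError):
            replicate_concordance(c, c)

    def test_mismatched_universe_raises(self):
        with pytest.raises(ConsistencyError):
            replicate_concordance([call("a", True, 25.0)], [call("b", True, 25.0)])


class TestExpressionRangeAndALC:
    def test_range_is_span(self):
        assert expression_range([0.0, 18.64]) == pytest.approx(18.64)
        assert expression_range([-3.0, 2.0, 7.0]) == pytest.approx(10.0)
        assert expression_range([5.0, 5.0]) == 0.0

    def test_range_needs_two_values(self):
        with pytest.raises(UndefinedMetricError):
            expression_range([1.0])

    def test_identical_replicates_alc_zero(self):
        assert alc([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_differences(self):
        assert alc([1.0, 2.0, 3.0], [0.5, 1.5, 2.5]) == pytest.approx(0.5)

    def test_geometric_value(self):
        # d = {0, 1, 2}: area left of the step ECDF is exactly 1.0
        assert alc([0.0, 1.0, 2.0], [0.0, 0.0, 0.0]) == pytest.approx(1.0)
        assert alc_by_ecdf_integration([0.0, 1.0, 2.0], [0.0, 0.0, 0.0]) == (
            pytest.approx(1.0))

    def test_empty_input_raises(self):
        with pytest.raises(UndefinedMetricError):
            alc([], [])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        d=st.lists(st.floats(min_value=0.0, max_value=50.0), min_size=1,
                   max_size=50)
    )
    def test_mean_identity_matches_ecdf_integration(self, d):
        """Closed form (mean |Δ|) vs direct geometric integration."""
        zeros = [0.0] * len(d)
        assert alc(d, zeros) == pytest.approx(
            alc_by_ecdf_integration(d, zeros), abs=1e-9)


class TestTitration:
    def expr(self, a, c, d, b):
        return ({"x": a}, {"x": b}, {"x": c}, {"x": d})

    @pytest.mark.parametrize(
        "acdb,q",
        [
            ((10, 8, 6, 4), 1.0),    # perfect chain
            ((4, 6, 8, 10), 1.0),    # mirrored chain (B > A)
            ((10, 5, 6, 4), 2 / 3),  # C < D breaks one inequality
            ((10, 11, 6, 4), 2 / 3),
            ((10, 11, 12, 4), 1 / 3),
            # mirrored direction with inverted interior: only D > B-side
            # comparison survives (transitivity forbids q=0 on distinct reals)
            ((4, 3, 2, 10), 1 / 3),
        ],
    )
    def test_score_counts_strict_adjacent_inequalities(self, acdb, q):
        scores = titration_scores(*self.expr(*acdb))
        assert scores["x"] == pytest.approx(q)

    def test_tied_reference_assay_excluded(self):
        scores = titration_scores({"x": 5.0}, {"x": 5.0}, {"x": 4.0}, {"x": 3.0})
        assert scores == {}

    def test_missing_reference_assay_skipped(self):
        scores = titration_scores({"x": np.nan}, {"x": 1.0}, {}, {})
        assert scores == {}

    def test_missing_intermediate_counts_as_failed(self):
        scores = titration_scores({"x": 10.0}, {"x": 4.0}, {}, {"x": 6.0})
        assert scores["x"] == pytest.approx(1 / 3)  # only D > B holds

    def test_both_mixtures_missing_scores_zero(self):
        scores = titration_scores({"x": 10.0}, {"x": 4.0}, {}, {})
        assert scores["x"] == 0.0

    def test_auc_is_mean_score(self):
        assert titration_auc({"a": 1.0, "b": 0.0}) == 0.5
        assert titration_auc([1.0] * 5) == 1.0
        assert titration_auc([0.0]) == 0.0

    def test_auc_empty_raises(self):
        with pytest.raises(UndefinedMetricError):
            titration_auc([])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        vals=st.lists(
            st.tuples(*[st.floats(-20, 20)] * 4).filter(
                lambda t: len({round(v, 6) for v in t}) == 4),
            min_size=1, max_size=20),
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 10),
    )
    def test_auc_invariant_under_increasing_monotone_transform(
            self, vals, shift, scale):
        """q depends only on orderings, so any strictly increasing map of
        all expressions leaves the AUC unchanged."""
        def pack(f):
            a = {f"x{i}": f(v[0]) for i, v in enumerate(vals)}
            b = {f"x{i}": f(v[1]) for i, v in enumerate(vals)}
            c = {f"x{i}": f(v[2]) for i, v in enumerate(vals)}
            d = {f"x{i}": f(v[3]) for i, v in enumerate(vals)}
            return a, b, c, d

        raw = titration_scores(*pack(lambda v: v))
        mapped = titration_scores(*pack(lambda v: scale * v + shift))
        if raw:
            assert titration_auc(raw) == pytest.approx(titration_auc(mapped))
        else:
            assert mapped == {}


class TestCrossReactivity:
    def test_identity_pattern(self):
        family = ["l7a", "l7b", "l7c"]
        panels = {
            m: [call(x, x == m, 20.0 if x == m else np.nan) for x in family]
            for m in family
        }
        mat, pct, med = cross_reactivity(panels, family)
        assert (np.diag(mat.to_numpy()) == 100.0).all()
        assert (mat.to_numpy().sum() == 300.0)  # off-diagonals all zero
        assert pct == 0.0 and med == 0.0

    def test_ten_cycle_offset_is_tenth_of_percent(self):
        family = ["on", "off"]
        panels = {
            "on": [call("on", True, 20.0), call("off", True, 30.0)],
            "off": [call("on", False), call("off", True, 20.0)],
        }
        mat, pct, med = cross_reactivity(panels, family)
        assert mat.loc["on", "off"] == pytest.approx(100 * 2**-10)
        assert pct == 50.0

    def test_on_target_not_detected_raises(self):
        panels = {"a": [call("a", False)]}
        with pytest.raises(UndefinedMetricError):
            cross_reactivity(panels, ["a"])

    def test_undetected_off_target_invariant_to_background(self):
        """An undetected off-target scores 0 regardless of its Cq field."""
        family = ["a", "b"]
        for junk in (np.nan, 39.0):
            panels = {
                "a": [call("a", True, 20.0), call("b", False, junk)],
                "b": [call("a", False), call("b", True, 21.0)],
            }
            mat, pct, _ = cross_reactivity(panels, family)
            assert mat.loc["a", "b"] == 0.0


class TestNtcPositives:
    def test_clean_ntc_counts_zero(self, small_layout, config, rng):
        sim = SimConfig(p_ntc=0.0)
        truths = {cl.assay_id: make_truth(cl.assay_id) for cl in small_layout.clusters}
        t = simulate_ntc_run(truths, small_layout, sim, rng)
        assert ntc_positives(t, small_layout, config) == 0

    def test_counts_contaminated_assays(self, small_layout, config):
        sim = SimConfig(p_ntc=1.0)  # every assay contaminated
        truths = {cl.assay_id: make_truth(cl.assay_id) for cl in small_layout.clusters}
        t = simulate_ntc_run(truths, small_layout, sim, np.random.default_rng(5))
        # late positives count as NTC signal even above the Cq-34 cutoff
        assert ntc_positives(t, small_layout, config) == len(small_layout.target_ids)


class TestDynamicRange:
    def series_calls(self, cqs):
        return [
            [call("spike", np.isfinite(c), c)] for c in cqs
        ]

    def test_ideal_seven_order_series(self, config):
        levels = [80.0 * 10**i for i in range(7)]
        cqs = [30.0 - np.log2(10) * i for i in range(7)]
        orders, lo, hi = dynamic_range(self.series_calls(cqs), levels, "spike",
                                       config)
        assert orders == 7
        assert (lo, hi) == (80.0, 8e7)

    def test_undetected_low_level_shortens_run(self, config):
        levels = [8.0 * 10**i for i in range(8)]
        cqs = [np.nan] + [33.0 - np.log2(10) * i for i in range(7)]
        orders, lo, hi = dynamic_range(self.series_calls(cqs), levels, "spike",
                                       config)
        assert orders == 7 and lo == 80.0

    def test_saturated_top_level_breaks_linearity(self, config):
        levels = [80.0 * 10**i for i in range(7)]
        cqs = [30.0 - np.log2(10) * i for i in range(6)]
        cqs.append(cqs[-1] - 0.2)  # saturation: step far below theory
        orders, lo, hi = dynamic_range(self.series_calls(cqs), levels, "spike",
                                       config)
        assert orders == 6 and hi == 8e6

    def test_single_detected_level(self, config):
        cqs = [np.nan, 25.0, np.nan]
        orders, lo, hi = dynamic_range(self.series_calls(cqs),
                                       [1.0, 10.0, 100.0], "spike", config)
        assert orders == 1 and lo == hi == 10.0

    def test_no_detection_raises(self, config):
        with pytest.raises(UndefinedMetricError):
            dynamic_range(self.series_calls([np.nan, np.nan]), [1.0, 10.0],
                          "spike", config)

    def test_monotone_in_added_linear_level(self, config):
        """Appending a detected, linear level never shrinks the run."""
        levels = [80.0 * 10**i for i in range(5)]
        cqs = [30.0 - np.log2(10) * i for i in range(5)]
        base, *_ = dynamic_range(self.series_calls(cqs), levels, "spike", config)
        ext_levels = levels + [levels[-1] * 10]
        ext_cqs = cqs + [cqs[-1] - np.log2(10)]
        ext, *_ = dynamic_range(self.series_calls(ext_cqs), ext_levels, "spike",
                                config)
        assert ext == base + 1


class TestReportAssembly:
    FULL = dict(
        n_clusters_after_cutoff=138, pct_double_positive=94.93,
        pct_single_positive=5.07, expression_range_log2=18.64, alc=0.58,
        titration_auc=0.75, pct_offtarget_crossreactive=0.0,
        median_relative_crossreactivity=0.0, ntc_positive_count=16,
        plasma_detected_count=78)

    def test_full_battery_populates_all_fields(self):
        report = build_mirqc_report(**self.FULL)
        assert report.pct_double_positive + report.pct_single_positive == (
            pytest.approx(100.0))
        for f in report.FIELDS:
            assert getattr(report, f) is not None

    def test_missing_constituent_named(self):
        partial = {k: v for k, v in self.FULL.items() if k != "titration_auc"}
        with pytest.raises(PartialReportError) as exc:
            build_mirqc_report(**partial)
        assert exc.value.missing == ["titration_auc"]

    def test_serialization_round_trip(self, tmp_path):
        import json

        report = build_mirqc_report(**self.FULL)
        report.to_json(tmp_path / "r.json")
        assert json.loads((tmp_path / "r.json").read_text())["alc"] == 0.58
        report.to_csv(tmp_path / "r.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "r.csv")
        assert set(df["name"]) == set(report.FIELDS)
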