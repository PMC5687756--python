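"""Section-level field-vs-video comparison: merging, correlation, recovery,
error profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oystervid as ov
from oystervid.validation import (
    build_comparison,
    correlation_r2,
    error_profile,
    merge_categories,
    recovery_rate,
)


def _readings(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "site", "transect", "section", "observer", "reading",
            "count_probably_living", "count_possibly_living", "count_dead",
        ],
    )


class TestMergeCategories:
    def test_additive_definition(self):
        r = _readings([(1, 1, 1, 1, 1, 3, 2, 1)])
        assert merge_categories(r).iloc[0] == 5

    def test_all_zero(self):
        r = _readings([(1, 1, 1, 1, 1, 0, 0, 0)])
        assert merge_categories(r).iloc[0] == 0

    @given(probably=st.integers(0, 50), possibly=st.integers(0, 50))
    @settings(max_examples=30, deadline=None)
    def test_merged_at_least_probably(self, probably, possibly):
        r = _readings([(1, 1, 1, 1, 1, probably, possibly, 0)])
        assert merge_categories(r).iloc[0] >= probably


class TestBuildComparison:
    def test_means_average_over_replicates(self):
        rows = [(1, 1, 1, ob, rd, ob + rd, 1, 2) for ob in (1, 2) for rd in (1, 2)]
        truth = pd.DataFrame(
            [(1, 1, 1, 10, 4, 0.5)],
            columns=["site", "transect", "section", "true_living", "true_dead", "vegetation_cover"],
        )
        comp = build_comparison(_readings(rows), truth)
        # probably values: 2,3,3,4 -> mean 3; merged adds the constant 1
        assert comp.loc[0, "video_probably_mean"] == 3.0
        assert comp.loc[0, "video_living_mean"] == 4.0
        assert comp.loc[0, "field_living"] == 10
        assert comp.loc[0, "vegetation_cover"] == 0.5

    def test_single_observer_flag(self):
        rows = [(1, 1, 1, 1, 1, 4, 0, 0), (1, 1, 1, 2, 1, 8, 0, 0)]
        truth = pd.DataFrame(
            [(1, 1, 1, 10, 0)],
            columns=["site", "transect", "section", "true_living", "true_dead"],
        )
        both = build_comparison(_readings(rows), truth)
        one = build_comparison(_readings(rows), truth, observer=1)
        assert both.loc[0, "video_living_mean"] == 6.0
        assert one.loc[0, "video_living_mean"] == 4.0

    def test_unmatched_section_names_key(self):
        truth = pd.DataFrame(
            [(1, 1, 1, 10, 0)],
            columns=["site", "transect", "section", "true_living", "true_dead"],
        )
        with pytest.raises(KeyError, match=r"\(1, 1, 2\)"):
            build_comparison(_readings([(1, 1, 2, 1, 1, 0, 0, 0)]), truth)


class TestCorrelation:
    def test_exact_line_gives_one(self):
        x = np.arange(10.0)
        assert correlation_r2(x, 3 * x + 2) == pytest.approx(1.0)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert correlation_r2(x, y) < 0.01

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5), seed=st.integers(0, 100)
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        assert correlation_r2(a * x + b, y) == pytest.approx(correlation_r2(x, y))

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError):
            correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlation_r2([1.0, 2.0], [1.0, 2.0])


def _perfect_survey(seed=3):
    design = ov.reference_design()
    cfg = ov.GeneratorConfig(
        mode="mechanistic", grand_mean=6.0, vc=ov.VarianceComponents(s_se2=9.0),
        p_detect_living=1.0, p_detect_dead=1.0, seed=seed,
    )
    truth = ov.generate_field_truth(design, cfg)
    readings, _ = ov.generate_video_observations(truth, design, cfg)
    return build_comparison(readings, truth[0])


class TestRecoveryRate:
    def test_perfect_observer_recovers_everything(self):
        comp = _perfect_survey()
        assert recovery_rate(comp) == pytest.approx(1.0)
        assert recovery_rate(comp, status="dead") == pytest.approx(1.0)

    def test_detection_probability_sets_recovery(self):
        design = ov.SurveyDesign(n_sites=1, transects_per_site=(20,),
                                 sections_per_transect=10)
        cfg = ov.GeneratorConfig(mode="mechanistic", grand_mean=40.0,
                                 site_effects=(0.0,), p_detect_living=0.8, seed=5)
        truth = ov.generate_field_truth(design, cfg)
        readings, _ = ov.generate_video_observations(truth, design, cfg)
        comp = build_comparison(readings, truth[0])
        assert recovery_rate(comp) == pytest.approx(0.8, rel=0.02)

    def test_merged_at_least_probably(self, mechanistic_survey):
        truth, readings, _ = mechanistic_survey
        comp = build_comparison(readings, truth[0])
        assert recovery_rate(comp, category="merged") >= recovery_rate(
            comp, category="probably"
        )

    def test_zero_field_total_raises(self):
        comp = pd.DataFrame(
            {
                "site": [1], "transect": [1], "section": [1],
                "field_living": [0], "field_dead": [0],
                "video_living_mean": [0.0], "video_probably_mean": [0.0],
                "video_dead_mean": [0.0],
            }
        )
        with pytest.raises(ValueError):
            recovery_rate(comp)


class TestErrorProfile:
    def test_perfect_video_gives_zero_errors(self):
        prof = error_profile(_perfect_survey())
        assert (prof["absolute_error"] == 0).all()
        defined = prof[prof["relative_defined"]]
        assert (defined["relative_error"] == 0).all()

    def test_arithmetic_by_definition(self):
        comp = pd.DataFrame(
            {
                "site": [1], "transect": [1], "section": [1],
                "field_living": [10], "field_dead": [0],
                "video_living_mean": [8.0], "video_probably_mean": [8.0],
                "video_dead_mean": [0.0],
            }
        )
        prof = error_profile(comp)
        assert prof.loc[0, "absolute_error"] == pytest.approx(-2.0)
        assert prof.loc[0, "relative_error"] == pytest.approx(-0.2)

    def test_field_zero_relative_error_flagged_not_infinite(self):
        comp = pd.DataFrame(
            {
                "site": [1], "transect": [1], "section": [1],
                "field_living": [0], "field_dead": [0],
                "video_living_mean": [2.0], "video_probably_mean": [2.0],
                "video_dead_mean": [0.0],
            }
        )
        prof = error_profile(comp)
        assert not prof.loc[0, "relative_defined"]
        assert np.isnan(prof.loc[0, "relative_error"])

    def test_bookkeeping_identity(self, mechanistic_survey):
        truth, readings, _ = mechanistic_survey
        comp = build_comparison(readings, truth[0])
        prof = error_profile(comp)
        assert prof["absolute_error"].sum() == pytest.approx(
            comp["video_living_mean"].sum() - comp["field_living"].sum()
        )

    def test_constant_detection_probability_error_pattern(self):
        # relative error ~ p - 1 across abundance strata; absolute error
        # grows with abundance
        design = ov.SurveyDesign(n_sites=1, transects_per_site=(40,),
                                 sections_per_transect=10)
        cfg = ov.GeneratorConfig(
            mode="mechanistic", grand_mean=25.0, site_effects=(0.0,),
            vc=ov.VarianceComponents(s_se2=150.0), p_detect_living=0.7, seed=8,
        )
        truth = ov.generate_field_truth(design, cfg)
        readings, _ = ov.generate_video_observations(truth, design, cfg)
        prof = error_profile(build_comparison(readings, truth[0]))
        prof = prof[prof["relative_defined"]]
        low = prof[prof["field_count"] <= prof["field_count"].median()]
        high = prof[prof["field_count"] > prof["field_count"].median()]
        assert prof["relative_error"].mean() == pytest.approx(-0.3, abs=0.05)
        assert abs(high["absolute_error"]).mean() > abs(low["absolute_error"]).mean()
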