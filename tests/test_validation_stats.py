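"""Paired tests, prediction intervals and the inclusion audit."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctspacing import (
    MeasurementTable,
    SyntheticMeasurementSpec,
    adjust_p,
    inclusion_audit,
    make_measurement_table,
    paired_t,
    prediction_interval,
    run_validation,
    significance_label,
)
from ctspacing.datasets import audit_published_intervals, load_published_intervals
from ctspacing.errors import DegeneratePairingError
from ctspacing.validation_stats import summarize_audits, write_reports


class TestPairedT:
    def test_closed_form_example(self):
        t, df, p = paired_t([2, 3, 4], [1, 1, 1])  # differences (1, 2, 3)
        assert t == pytest.approx(2 / (1 / math.sqrt(3)), abs=1e-4)
        assert round(t, 4) == 3.4641
        assert df == 2
        assert round(p, 4) == 0.0742

    def test_agrees_with_scipy_on_random_pairs(self, rng):
        for _ in range(25):
            n = rng.integers(3, 30)
            x = rng.normal(120, 2, n)
            y = x + rng.normal(0.5, 0.8, n)
            t, df, p = paired_t(x, y)
            ref = stats.ttest_rel(x, y)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert df == n - 1
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_antisymmetry(self, rng):
        x = rng.normal(120, 1, 10)
        y = rng.normal(121, 1, 10)
        t1, _, p1 = paired_t(x, y)
        t2, _, p2 = paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegeneratePairingError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_gives_infinite_statistic(self):
        t, df, p = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert math.isinf(t) and t > 0
        assert p == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [1, 2])


class TestAdjustP:
    @pytest.mark.parametrize(
        "p, m, expected",
        [(0.5, 40, 1.0), (0.002, 40, 0.08), (0.018, 40, 0.72), (0.005, 40, 0.20)],
    )
    def test_bonferroni_values(self, p, m, expected):
        assert adjust_p([p], m)[0] == pytest.approx(expected)

    def test_m_defaults_to_count(self):
        assert adjust_p([0.01, 0.02]) == pytest.approx([0.02, 0.04])

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            adjust_p([1.5], 2)

    def test_m_smaller_than_count_rejected(self):
        with pytest.raises(ValueError):
            adjust_p([0.1, 0.2, 0.3], m=2)


class TestSignificanceLabel:
    @pytest.mark.parametrize(
        "p, label",
        [
            (0.72, "ns"),
            (0.051, "ns"),
            (0.05, "*"),
            (0.011, "*"),
            (0.01, "**"),
            (0.001, "***"),
            (0.0001, "****"),
            (0.00003, "****"),
            (0.0, "****"),
        ],
    )
    def test_ladder(self, p, label):
        assert significance_label(p) == label


class TestPredictionInterval:
    def test_two_point_closed_form(self):
        # mean 1, sd sqrt(2), t_{0.995,1} = 63.6567...; half-width
        # t * sqrt(2) * sqrt(1 + 1/2) = 110.2567
        pi = prediction_interval([0.0, 2.0], confidence=0.99)
        half = stats.t.ppf(0.995, 1) * math.sqrt(2.0) * math.sqrt(1.5)
        assert pi.mean_mm == pytest.approx(1.0)
        assert half == pytest.approx(110.2567, abs=1e-4)
        assert pi.lower_mm == pytest.approx(1.0 - half, rel=1e-12)
        assert pi.upper_mm == pytest.approx(1.0 + half, rel=1e-12)

    def test_constant_sample_degenerate(self):
        pi = prediction_interval([5.0, 5.0, 5.0])
        assert (pi.lower_mm, pi.upper_mm) == (5.0, 5.0)
        assert pi.degenerate

    def test_contains_mean_and_widens_with_confidence(self, rng):
        x = rng.normal(120, 1, 10)
        pi95 = prediction_interval(x, 0.95)
        pi99 = prediction_interval(x, 0.99)
        assert pi95.lower_mm <= pi95.mean_mm <= pi95.upper_mm
        assert pi99.lower_mm < pi95.lower_mm and pi99.upper_mm > pi95.upper_mm

    def test_matches_intercept_only_ols_oracle(self, rng):
        import statsmodels.api as sm

        x = rng.normal(130, 1.5, 10)
        model = sm.OLS(x, np.ones_like(x)).fit()
        frame = model.get_prediction(np.ones(1)).summary_frame(alpha=0.01)
        pi = prediction_interval(x, 0.99)
        assert pi.lower_mm == pytest.approx(frame["obs_ci_lower"][0], rel=1e-9)
        assert pi.upper_mm == pytest.approx(frame["obs_ci_upper"][0], rel=1e-9)

    def test_insufficient_sample(self):
        with pytest.raises(ValueError):
            prediction_interval([1.0])


class TestInclusionAudit:
    def test_published_row_included(self):
        pi = prediction_interval([0.0, 2.0])
        pi.lower_mm, pi.upper_mm = 121.94, 122.96
        a = inclusion_audit(122.82, pi)
        assert a.included and a.signed_exceedance_mm == 0.0

    def test_boundary_is_closed(self):
        pi = prediction_interval([0.0, 2.0])
        pi.lower_mm, pi.upper_mm = 121.94, 122.96
        assert inclusion_audit(121.94, pi).included
        assert inclusion_audit(122.96, pi).included

    def test_exceedance_above_and_below(self):
        pi = prediction_interval([0.0, 2.0])
        pi.lower_mm, pi.upper_mm = 143.50, 146.34
        above = inclusion_audit(147.20, pi)
        assert not above.included
        assert above.signed_exceedance_mm == pytest.approx(0.86)
        below = inclusion_audit(143.00, pi)
        assert below.signed_exceedance_mm == pytest.approx(-0.50)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        probe=st.floats(100, 150),
        center=st.floats(110, 140),
        half=st.floats(0.1, 10),
        widen=st.floats(0, 10),
    )
    def test_wider_interval_keeps_inclusion(self, probe, center, half, widen):
        pi = prediction_interval([0.0, 2.0])
        pi.lower_mm, pi.upper_mm = center - half, center + half
        wide = prediction_interval([0.0, 2.0])
        wide.lower_mm, wide.upper_mm = center - half - widen, center + half + widen
        if inclusion_audit(probe, pi).included:
            assert inclusion_audit(probe, wide).included


class TestMeasurementTable:
    def test_schema_validation(self):
        with pytest.raises(ValueError):
            MeasurementTable(pd.DataFrame({"specimen_id": ["a"]}))

    def test_duplicate_replicates_rejected(self):
        df = pd.DataFrame(
            {
                "specimen_id": ["a", "a"],
                "group": ["G1", "G1"],
                "modality": ["Original", "Original"],
                "replicate": [1, 1],
                "distance_mm": [120.0, 121.0],
            }
        )
        with pytest.raises(ValueError):
            MeasurementTable(df)

    def test_csv_round_trip(self, tmp_path):
        table = make_measurement_table(SyntheticMeasurementSpec(seed=1))
        path = tmp_path / "table.csv"
        table.to_csv(path)
        reloaded = MeasurementTable.from_csv(path)
        pd.testing.assert_frame_equal(table.df, reloaded.df)


class TestRunValidation:
    def test_synthetic_group3_significance_pattern(self):
        spec = SyntheticMeasurementSpec(
            n_specimens={"G3": 5}, true_distance_range_mm=(110, 155), seed=5
        )
        report = run_validation(make_measurement_table(spec))
        by_pair = {}
        for c in report.comparisons:
            by_pair.setdefault((c.modality_1, c.modality_2), []).append(c.significance)
        # CT at the true (regularized) spacing agrees with calipers ...
        assert all(s == "ns" for s in by_pair[("CT_0.58", "Original")])
        # ... the misassigned 0.60 spacing does not, nor do the two CT grids
        assert all(s != "ns" for s in by_pair[("CT_0.60", "Original")])
        assert all(s != "ns" for s in by_pair[("CT_0.58", "CT_0.60")])

    def test_degenerate_modalities_warn_but_run_continues(self):
        rows = []
        for rep in range(1, 4):
            rows.append(("a", "G1", "CT_0.75", rep, 120.0 + rep))
            rows.append(("a", "G1", "Original", rep, 120.0 + rep))
        rows.append(("a", "G1", "Microscribe", 1, 121.0))
        table = MeasurementTable(
            pd.DataFrame(
                rows,
                columns=["specimen_id", "group", "modality", "replicate",
                         "distance_mm"],
            )
        )
        report = run_validation(table)
        assert any("degenerate" in w for w in report.warnings)
        assert report.summary["n_comparisons"] == 0
        assert report.summary["n_inclusions_total"] == 2

    def test_missing_microscribe_excluded_with_warning(self):
        spec = SyntheticMeasurementSpec(n_specimens={"G1": 2}, seed=2)
        table = make_measurement_table(spec)
        df = table.df[
            ~((table.df.specimen_id == "G1S01") & (table.df.modality == "Microscribe"))
        ]
        report = run_validation(MeasurementTable(df))
        assert any("G1S01" in w and "Microscribe" in w for w in report.warnings)
        audited = {a.specimen_id for a in report.audits}
        assert audited == {"G1S02"}

    def test_report_files_written(self, tmp_path):
        spec = SyntheticMeasurementSpec(n_specimens={"G2": 2}, seed=3)
        report = run_validation(make_measurement_table(spec))
        paths = write_reports(report, tmp_path)
        assert all(p.exists() for p in paths.values())
        frame = pd.read_csv(paths["comparisons"])
        assert list(frame.columns[:5]) == [
            "specimen_id", "modality_1", "modality_2", "n1", "n2",
        ]

    def test_study_design_comparison_count(self):
        table = make_measurement_table(SyntheticMeasurementSpec(seed=4))
        report = run_validation(table)
        # 10 specimens x 1 pair + 5 x 3 pairs + 5 x 3 pairs
        assert report.summary["n_comparisons"] == 40
        assert report.summary["m_comparisons"] == 40


class TestPublishedIntervalAudit:
    def test_reproduces_every_published_inclusion_flag(self):
        df = load_published_intervals()
        audits = audit_published_intervals(df)
        for row, a in zip(df.itertuples(index=False), audits):
            assert a.included == row.included, (row.specimen_id, row.modality)

    def test_original_inclusion_count(self):
        summary = summarize_audits(audit_published_intervals())
        assert summary["inclusions_by_modality"]["Original"] == {
            "true": 17,
            "total": 20,
        }
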