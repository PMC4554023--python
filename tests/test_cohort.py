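"""Cohort statistics: deltas, IR grouping, regressions, tests, full report."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from astigvec import (
    AnalysisConfig,
    CylAstig,
    EyeRecord,
    SpheroCylinder,
    analyze_cohort,
    compare_groups,
    compute_deltas,
    correlate,
    fit_log_linear,
    group_by_ir,
)
from astigvec.errors import EmptyCohortError, PairingError


def _eye(eye_id="e", ak=CylAstig(1.0, 0.0), tcrp3=None, tcrp4=None, ir=0.04, age=65.0):
    return EyeRecord(
        eye_id=eye_id, age=age, ak=ak,
        tcrp3=tcrp3 or ak, tcrp4=tcrp4 or ak, ir=ir, irregular_astig=0.4,
        anterior_radius=7.8, posterior_radius=6.5,
        ra_postop=SpheroCylinder(-0.25, -0.5, 10.0, "negative"),
    )


class TestDeltas:
    def test_identical_measurements_give_zero(self):
        d = compute_deltas(_eye())
        assert d.delta_tcrp3_ak == 0.0 and d.delta_tcrp4_ak == 0.0

    def test_orthogonal_axes_and_zero_tcrp(self):
        eye = _eye(tcrp3=CylAstig(1.0, 90.0), tcrp4=CylAstig(0.0, 0.0))
        d = compute_deltas(eye)
        assert d.delta_tcrp3_ak == pytest.approx(1.0, abs=1e-12)
        assert d.delta_tcrp4_ak == pytest.approx(0.5, abs=1e-12)
        doubled = compute_deltas(eye, as_cylinder=True)
        assert doubled.delta_tcrp3_ak == pytest.approx(2.0, abs=1e-12)


class TestIrGrouping:
    def test_fixed_thresholds_boundary_is_high(self):
        eyes = [_eye(ir=0.077), _eye(ir=0.035)]
        labels, thr = group_by_ir(eyes, method=2, threshold_mode="fixed")
        assert thr == 0.077 and labels == ["high", "low"]
        labels, thr = group_by_ir(eyes, method=1, threshold_mode="fixed")
        assert thr == 0.036 and labels == ["high", "low"]

    def test_cohort_derived_median_and_mean_plus_2sd(self):
        irs = [0.02, 0.03, 0.04, 0.05, 0.10]
        eyes = [_eye(ir=v) for v in irs]
        labels, thr = group_by_ir(eyes, method=1)
        assert thr == pytest.approx(np.median(irs))
        labels2, thr2 = group_by_ir(eyes, method=2)
        assert thr2 == pytest.approx(np.mean(irs) + 2 * np.std(irs, ddof=1))

    def test_identical_ir_cohort_all_high_under_median(self):
        eyes = [_eye(ir=0.04) for _ in range(5)]
        labels, _ = group_by_ir(eyes, method=1)
        assert labels == ["high"] * 5

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyCohortError):
            group_by_ir([], method=1)


class TestLogLinearFit:
    def test_exact_recovery_on_noise_free_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.exp(0.7 - 0.3 * x)
        res = fit_log_linear(y, pd.DataFrame({"x": x}))
        assert res.coefficients["const"] == pytest.approx(0.7, abs=1e-10)
        assert res.coefficients["x"] == pytest.approx(-0.3, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_y_gives_zero_slope_and_r2(self):
        y = np.full(6, 2.0)
        res = fit_log_linear(y, pd.DataFrame({"x": np.arange(6.0)}))
        assert res.coefficients["x"] == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        n = 40
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = np.exp(0.2 + 0.5 * X["a"] - 0.4 * X["b"] + rng.normal(0, 0.3, n))
        res = fit_log_linear(y, X)
        design = np.column_stack([np.ones(n), X["a"], X["b"]])
        beta = np.linalg.solve(design.T @ design, design.T @ np.log(y))
        assert res.coefficients["const"] == pytest.approx(beta[0], abs=1e-8)
        assert res.coefficients["a"] == pytest.approx(beta[1], abs=1e-8)
        assert res.coefficients["b"] == pytest.approx(beta[2], abs=1e-8)

    def test_rejects_nonpositive_y_and_rank_deficiency(self):
        with pytest.raises(ValueError):
            fit_log_linear([1.0, 0.0, 2.0, 1.0], pd.DataFrame({"x": [1.0, 2, 3, 4]}))
        X = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "x2": [2.0, 4, 6, 8, 10]})
        with pytest.raises(np.linalg.LinAlgError):
            fit_log_linear([1.0, 2, 3, 4, 5], X)


class TestCorrelate:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        for method in ("pearson", "spearman"):
            rho, _ = correlate(x, x, method=method)
            assert rho == pytest.approx(1.0)
            rho, _ = correlate(x, -x, method=method)
            assert rho == pytest.approx(-1.0)

    def test_null_simulation_small_rho(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        rho, _ = correlate(x, y)
        assert abs(rho) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareGroups:
    def test_t_statistic_matches_hand_computation(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 4.0, 4.0, 5.0, 7.0]
        # pooled two-sample t computed from first principles
        ma, mb = sum(a) / 5, sum(b) / 5
        va = sum((x - ma) ** 2 for x in a) / 4
        vb = sum((x - mb) ** 2 for x in b) / 4
        sp = math.sqrt(((4 * va) + (4 * vb)) / 8)
        t_hand = (ma - mb) / (sp * math.sqrt(2 / 5))
        t_pkg, _ = compare_groups(a, b, test="t")
        assert t_pkg == pytest.approx(t_hand, abs=1e-10)

    def test_shifted_distributions_detected(self, rng):
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(1.0, 1.0, 100)
        for test in ("t", "mann_whitney"):
            _, p = compare_groups(a, b, test=test)
            assert p < 0.05

    def test_degenerate_paired_test_reports_p_one(self):
        stat, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="paired_t")
        assert (stat, p) == (0.0, 1.0)

    def test_paired_length_mismatch(self):
        with pytest.raises(PairingError):
            compare_groups([1.0, 2.0], [1.0], test="paired_t")


class TestAnalyzeCohort:
    def test_report_structure_and_row_conservation(self, small_cohort):
        rep = analyze_cohort(small_cohort)
        assert len(rep.per_eye) == len(small_cohort)
        assert set(rep.tables) == {
            "table1_wtr_atr", "table3_ir_groups", "table4_ora", "table5_paired_ora",
        }
        c = rep.counts
        assert c["wtr"] + c["atr"] + c["zero_cylinder_excluded"] == c["n"]
        for m in (1, 2):
            sizes = c["ir_group_sizes"][m]
            assert sizes.get("low", 0) + sizes.get("high", 0) == c["n"]
        assert "ln_delta_tcrp3_on_age_ir_ak" in rep.regressions

    def test_deterministic_given_cohort_and_config(self, small_cohort):
        a = analyze_cohort(small_cohort)
        b = analyze_cohort(small_cohort)
        pd.testing.assert_frame_equal(a.per_eye, b.per_eye)
        pd.testing.assert_frame_equal(a.tables["table4_ora"], b.tables["table4_ora"])

    def test_identical_keratometries_give_zero_deltas_and_paired_ties(self):
        eyes = [_eye(eye_id=f"e{i}", ir=0.02 + 0.01 * i) for i in range(12)]
        # median grouping keeps the paired-comparison subgroup nonempty here
        rep = analyze_cohort(eyes, AnalysisConfig(table5_grouping=1))
        assert (rep.per_eye["delta_tcrp3_ak"] == 0).all()
        t5 = rep.tables["table5_paired_ora"]
        assert (t5["mean_diff"].abs() < 1e-12).all()
        assert (t5["p_value"] == 1.0).all()

    def test_zero_cylinder_eyes_excluded_from_axis_tables(self):
        eyes = [_eye(eye_id=f"e{i}") for i in range(6)]
        eyes.append(_eye(eye_id="zero", ak=CylAstig(0.0, 0.0), tcrp3=CylAstig(0.5, 10.0),
                         tcrp4=CylAstig(0.5, 10.0)))
        rep = analyze_cohort(eyes)
        assert rep.counts["zero_cylinder_excluded"] == 1
        assert rep.counts["wtr"] + rep.counts["atr"] == 6

    def test_delta_increases_with_tcrp_axis_rotation(self):
        """Rotating TCRP3 further from AK raises the mean delta (monotone grid)."""
        means = []
        for rot in (5.0, 20.0, 45.0, 80.0):
            eyes = [
                _eye(eye_id=f"r{rot}_{i}", ak=CylAstig(1.0, 10.0),
                     tcrp3=CylAstig(1.0, (10.0 + rot) % 180.0))
                for i in range(5)
            ]
            means.append(np.mean([compute_deltas(e).delta_tcrp3_ak for e in eyes]))
        assert all(x < y for x, y in zip(means, means[1:]))

    def test_save_writes_tables(self, small_cohort, tmp_path):
        rep = analyze_cohort(small_cohort, AnalysisConfig(ir_threshold_mode="fixed"))
        rep.save(tmp_path / "report")
        names = {p.name for p in (tmp_path / "report").iterdir()}
        assert {"per_eye.csv", "table1_wtr_atr.csv", "table3_ir_groups.csv",
                "table4_ora.csv", "table5_paired_ora.csv", "summary.json"} <= names

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyCohortError):
            analyze_cohort([])
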