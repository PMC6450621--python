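"""Non-compartmental analysis: AUC, lambda_z, clearances, ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import renalpk as rp
from renalpk.errors import (
    CoverageError,
    NoValidFitError,
    UndefinedRatioError,
    ValidationError,
)

from conftest import profile_from_sim


def make_profile(times, conc, **kw):
    return rp.ConcentrationTimeProfile(
        kw.get("subject", "s1"), kw.get("group", "control"),
        kw.get("analyte", "drug"), np.asarray(times, float), np.asarray(conc, float))


class TestTrapezoidAUC:
    def test_constant_profile(self):
        assert rp.auc_linear_trapezoid(make_profile([0, 240], [2, 2])) == 480.0

    def test_piecewise_linear(self):
        p = make_profile([0, 60, 120], [10, 5, 0])
        assert rp.auc_linear_trapezoid(p) == 600.0

    def test_dense_monoexponential_matches_quadrature(self):
        # C(t) = 10 exp(-0.01 t) sampled every minute on [0, 240]
        t = np.arange(0, 241, 1.0)
        p = make_profile(t, 10 * np.exp(-0.01 * t))
        expected, _ = quad(lambda x: 10 * np.exp(-0.01 * x), 0, 240)
        assert expected == pytest.approx((10 / 0.01) * (1 - math.exp(-2.4)))
        assert rp.auc_linear_trapezoid(p, 0, 240) == pytest.approx(
            expected, rel=1e-4)

    def test_anchoring_carries_first_sample_to_zero(self):
        p = make_profile([10, 240], [3, 3])
        assert rp.auc_linear_trapezoid(p, 0, 240) == pytest.approx(720.0)
        with pytest.raises(ValidationError):
            rp.auc_linear_trapezoid(p, 0, 240, anchor_t0=False)

    def test_window_beyond_samples_rejected(self):
        p = make_profile([0, 100], [1, 1])
        with pytest.raises(ValidationError):
            rp.auc_linear_trapezoid(p, 0, 200)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            make_profile([0], [1])

    @given(st.lists(st.floats(0.01, 100), min_size=4, max_size=10),
           st.integers(1, 2))
    @settings(max_examples=50, deadline=None)
    def test_additivity_at_sample_time(self, concs, split_idx):
        t = np.arange(len(concs), dtype=float) * 10.0
        p = make_profile(t, concs)
        a = t[split_idx]
        left = rp.auc_linear_trapezoid(p, 0, a)
        right = rp.auc_linear_trapezoid(p, a, t[-1])
        full = rp.auc_linear_trapezoid(p, 0, t[-1])
        assert left + right == pytest.approx(full, rel=1e-12, abs=1e-9)

    @given(st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, k):
        t = np.array([0.0, 30.0, 90.0, 240.0])
        c = np.array([8.0, 4.0, 2.0, 0.5])
        base = rp.auc_linear_trapezoid(make_profile(t, c))
        assert rp.auc_linear_trapezoid(make_profile(t, k * c)) == pytest.approx(
            k * base, rel=1e-12)


class TestLambdaZ:
    def test_exact_on_noiseless_exponential(self):
        t = np.array([10, 30, 60, 120, 180, 240], dtype=float)
        p = make_profile(t, 8 * np.exp(-0.02 * t))
        fit = rp.fit_lambda_z(p)
        assert fit.lambda_z == pytest.approx(0.02, rel=1e-12)
        assert fit.n_points == 3  # ties go to the smallest window

    def test_constant_profile_has_no_valid_fit(self):
        with pytest.raises(NoValidFitError):
            rp.fit_lambda_z(make_profile([0, 60, 120, 240], [5, 5, 5, 5]))

    def test_zero_concentration_windows_skipped(self):
        t = np.array([0, 60, 120, 180, 240], dtype=float)
        with pytest.raises(NoValidFitError):
            rp.fit_lambda_z(make_profile(t, [5, 4, 0, 0, 0]))

    def test_biexponential_window_confined_to_terminal_phase(self):
        # fast phase t1/2 ~ 6.9 min; oracle fits only t > 5 fast half-lives
        t = np.arange(0, 481, 4.0)
        c = 5 * np.exp(-0.1 * t) + 1 * np.exp(-0.01 * t)
        fit = rp.fit_lambda_z(make_profile(t, c))
        oracle_mask = t > 5 * (math.log(2) / 0.1)
        slope, _ = np.polyfit(t[oracle_mask], np.log(c[oracle_mask]), 1)
        assert fit.t_first > 5 * (math.log(2) / 0.1)
        assert fit.lambda_z == pytest.approx(-slope, rel=0.02)
        assert fit.lambda_z == pytest.approx(0.01, rel=0.02)


class TestAUCInf:
    def test_zero_terminal_concentration(self):
        fit = rp.LambdaZFit(0.02, 3, 1.0, 100, 240)
        assert rp.auc_extrapolate_inf(500.0, 0.0, fit) == 500.0

    def test_arithmetic(self):
        fit = rp.LambdaZFit(0.01, 3, 1.0, 100, 240)
        assert rp.auc_extrapolate_inf(100.0, 1.0, fit) == pytest.approx(200.0)

    def test_monoexponential_closed_form(self):
        t = np.arange(0, 361, 2.0)
        c0, k = 12.0, 0.015
        p = make_profile(t, c0 * np.exp(-k * t))
        fit = rp.fit_lambda_z(p)
        auc_t = rp.auc_linear_trapezoid(p)
        auc_inf = rp.auc_extrapolate_inf(auc_t, float(p.conc[-1]), fit)
        assert auc_inf == pytest.approx(c0 / k, rel=1e-3)


class TestClearances:
    def test_cl_total_simple(self):
        # 10 µmol/kg over AUC_inf 1000 µM·min -> 10 mL/min/kg
        dose = rp.DoseRecord(dose_mg_per_kg=1.0, mw=100.0)
        assert dose.dose_umol_per_kg == pytest.approx(10.0)
        assert rp.cl_total(dose, 1000.0) == pytest.approx(10.0)

    def test_cl_total_cephalexin_group_mean_consistency(self):
        # ratio-of-means vs per-animal mean-of-ratios agree to ~3%
        dose = rp.DoseRecord(dose_mg_per_kg=10.0, mw=347.39)
        cl = rp.cl_total(dose, 2770.0)
        assert cl == pytest.approx(10.39, abs=0.01)
        assert cl == pytest.approx(10.6, rel=0.03)

    def test_cl_total_zero_dose(self):
        assert rp.cl_total(rp.DoseRecord(0.0, 100.0), 1000.0) == 0.0

    def test_cl_renal_simple(self):
        u = rp.UrineCollection("s1", "drug", ((0, 240),), [10000.0])
        assert rp.cl_renal(u, 1000.0) == pytest.approx(10.0)
        z = rp.UrineCollection("s1", "drug", ((0, 240),), [0.0])
        assert rp.cl_renal(z, 1000.0) == 0.0

    def test_cl_renal_coverage_gap_reported(self):
        u = rp.UrineCollection("s1", "drug", ((0, 60), (120, 240)), [1.0, 1.0])
        with pytest.raises(CoverageError) as err:
            rp.cl_renal(u, 1000.0, (0, 240))
        assert err.value.missing_spans == [(60.0, 120.0)]

    def test_recovery_bounds(self):
        dose = rp.DoseRecord(1.0, 100.0)  # 10000 nmol/kg
        full = rp.UrineCollection("s1", "drug", ((0, 240),), [10000.0])
        none = rp.UrineCollection("s1", "drug", ((0, 240),), [0.0])
        assert rp.urinary_recovery(full, dose) == pytest.approx(100.0)
        assert rp.urinary_recovery(none, dose) == 0.0
        with pytest.raises(UndefinedRatioError):
            rp.urinary_recovery(full, rp.DoseRecord(0.0, 100.0))

    def test_kp_kidney(self):
        assert rp.kp_kidney(90.0, 10.0) == pytest.approx(9.0)
        assert rp.kp_kidney(5.0, 5.0) == 1.0
        with pytest.raises(UndefinedRatioError):
            rp.kp_kidney(1.0, 0.0)


PRINTED_RATIOS = [
    # (cl_r, fu, cl_inulin, printed ratio, classification)
    (23.0, 0.85, 6.72, 4.03, "net-secretion"),
    (18.3, 0.85, 5.36, 4.01, "net-secretion"),
    (7.96, 0.82, 6.72, 1.44, "net-secretion"),
    (2.87, 0.82, 5.36, 0.65, "net-reabsorption"),
    (10.9, 1.0, 6.72, 1.62, "net-secretion"),
    (5.84, 1.0, 5.36, 1.09, "net-secretion"),
    (1.88, 0.82, 6.72, 0.34, "net-reabsorption"),
]


class TestClearanceRatio:
    @pytest.mark.parametrize("cl_r,fu,gfr,printed,cls", PRINTED_RATIOS)
    def test_published_ratios_reproduced(self, cl_r, fu, gfr, printed, cls):
        res = rp.clearance_ratio(cl_r, fu, gfr)
        assert res.value == pytest.approx(printed, abs=0.01)
        assert res.classification == cls

    def test_unity_is_indeterminate(self):
        assert rp.clearance_ratio(5.0, 1.0, 5.0).classification == "indeterminate"

    def test_strict_mode(self):
        assert rp.clearance_ratio(5.05, 1.0, 5.0, epsilon=0.0).classification \
            == "net-secretion"

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            rp.clearance_ratio(5.0, 0.0, 5.0)
        with pytest.raises(ValidationError):
            rp.clearance_ratio(5.0, 1.0, 0.0)


class TestFoldChange:
    @pytest.mark.parametrize("case,control,expected", [
        (90.3, 16.6, 5.44),   # kidney partition coefficient, metformin
        (9807.0, 5373.0, 1.83),  # creatinine AUC_0-4
        (3.3, 3.3, 1.00),
    ])
    def test_printed_fold_changes(self, case, control, expected):
        assert round(rp.fold_change(case, control), 2) == expected

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            rp.fold_change(1.0, 0.0)


class TestRunNCAStudy:
    def test_noiseless_subject_matches_simulator_truth(self, dense_design):
        from renalpk.simulator import true_clearances
        from renalpk.params import CONTROL_PROFILE

        phys, drug = rp.metformin_like()
        design = dense_design.with_(dose_mg_per_kg=30.0)
        study = rp.simulate_study(phys, drug, CONTROL_PROFILE, CONTROL_PROFILE,
                                  design.with_(n_per_group=1))
        per_animal, _ = rp.run_nca_study(
            study.plasma, study.urine, study.tissue, study.doses,
            fu={"drug": drug.fu}, gfr={"control": phys.gfr,
                                       "hyperuricemic": phys.gfr})
        cl_r_true, cl_tot_true = true_clearances(
            phys, drug, CONTROL_PROFILE, design)
        row = per_animal[per_animal["group"] == "control"].iloc[0]
        assert row["cl_r"] == pytest.approx(cl_r_true, rel=0.02)
        assert row["cl_tot"] == pytest.approx(cl_tot_true, rel=0.05)
        sim = rp.simulate_subject(phys, drug, CONTROL_PROFILE, design)
        assert row["kp_kidney"] == pytest.approx(
            sim.tissue_conc / sim.plasma_conc[-1], rel=1e-6)

    def test_missing_urine_leaves_auc_parameters(self):
        t = np.array([5, 30, 60, 120, 240], dtype=float)
        plasma = _tidy_plasma(t, 10 * np.exp(-0.01 * t))
        doses = _doses()
        per_animal, _ = rp.run_nca_study(plasma, None, None, doses,
                                         fu={"drug": 1.0}, gfr={"control": 6.72})
        row = per_animal.iloc[0]
        assert row["auc_0_t"] > 0 and row["cl_tot"] > 0
        assert math.isnan(row["cl_r"]) and math.isnan(row["urinary_recovery"])

    def test_identical_groups_give_unit_fold_changes(self):
        t = np.array([5, 30, 60, 120, 240], dtype=float)
        c = 10 * np.exp(-0.01 * t)
        plasma = np.concatenate  # noqa: F841  (clarity below)
        import pandas as pd
        frames = []
        for group in ("control", "hyperuricemic"):
            for sid in (f"{group}1", f"{group}2"):
                frames.append(_tidy_plasma(t, c, sid, group))
        plasma = pd.concat(frames, ignore_index=True)
        doses = pd.concat([_doses(sid) for sid in
                           ("control1", "control2", "hyperuricemic1",
                            "hyperuricemic2")], ignore_index=True)
        _, summary = rp.run_nca_study(plasma, None, None, doses,
                                      fu={"drug": 1.0},
                                      gfr={"control": 6.72, "hyperuricemic": 6.72})
        fc = summary[summary["statistic"] == "fold-change"]
        assert np.allclose(fc["auc_0_t"], 1.0)
        assert np.allclose(fc["cl_tot"], 1.0)

    def test_missing_fu_is_a_configuration_error(self):
        t = np.array([5, 30, 240], dtype=float)
        plasma = _tidy_plasma(t, [3, 2, 1])
        with pytest.raises(ValidationError, match="fu"):
            rp.run_nca_study(plasma, None, None, None, fu={},
                             gfr={"control": 6.72})


def _tidy_plasma(t, c, sid="s1", group="control"):
    import pandas as pd
    return pd.DataFrame({"subject_id": sid, "group": group, "analyte": "drug",
                         "time_min": t, "conc_uM": np.asarray(c, float)})


def _doses(sid="s1"):
    import pandas as pd
    return pd.DataFrame({"subject_id": [sid], "analyte": ["drug"],
                         "dose_mg_per_kg": [1.0], "mw_g_per_mol": [100.0]})
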