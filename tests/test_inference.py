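"""Mixed-model orchestration, slope selection, and BH-FDR control."""

import numpy as np
import pandas as pd
import pytest

from formantadapt.config import RunConfig
from formantadapt.inference import (
    ModelSpec,
    bh_fdr,
    build_analysis_table,
    fit_lmm,
    run_full_analysis,
)
from formantadapt.inference import test_slopes as select_random_structure

CASE_ANGLES = {"iy": 112.0, "ih": 133.0, "ey": 104.0, "ae": -43.0,
               "aa": -75.0, "uw": -103.0}
CASE_MAGNITUDE = {"iy": 0.5, "ih": 0.2, "ey": 0.3, "ae": 0.17,
                  "aa": 0.7, "uw": 0.9}


def brute_force_bh(p, alpha):
    """Independent step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    passing = np.nonzero(sorted_p <= (np.arange(1, m + 1) / m) * alpha)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


def lmm_table(rng, n_subjects=6, n_trials=8, beta_angle=0.0, subj_sd=0.05,
              slope_sd=0.0, noise=0.05):
    rows = []
    for i in range(n_subjects):
        b = rng.normal(0.0, subj_sd)
        slope = rng.normal(0.0, slope_sd) if slope_sd > 0 else 0.0
        gender = "F" if i % 2 == 0 else "M"
        for case, ang in CASE_ANGLES.items():
            for _ in range(n_trials):
                cr = (
                    (beta_angle + slope) * ang + b
                    + rng.normal(0.0, noise)
                )
                rows.append(
                    {"participant_id": f"S{i}", "case": case,
                     "angle_deg": ang, "magnitude_norm": CASE_MAGNITUDE[case],
                     "magnitude_mel": 100.0 * CASE_MAGNITUDE[case],
                     "gender": gender, "cr": cr}
                )
    return pd.DataFrame(rows)


SPEC = ModelSpec(response="cr", effects=("angle_deg", "magnitude", "gender"),
                 name="unit")


class TestBhFdr:
    def test_worked_examples(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.5], 0.05).tolist() == [
            True, True, True, False]
        assert not bh_fdr([1.0, 1.0, 1.0], 0.05).any()
        assert bh_fdr([0.04], 0.05).tolist() == [True]

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_brute_force_oracle_and_subset_property(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            m = rng.integers(1, 51)
            p = rng.uniform(0.0, 1.0, m)
            flags = bh_fdr(p, 0.05)
            assert flags.tolist() == brute_force_bh(p, 0.05).tolist()
            # BH rejections are a subset of raw-alpha rejections
            assert not np.any(flags & (p > 0.05))


class TestFitLmm:
    def test_planted_angle_effect(self):
        rng = np.random.default_rng(23)
        table = lmm_table(rng, beta_angle=5e-4)
        res = {r.effect: r for r in fit_lmm(table, SPEC)}
        assert res["angle_deg"].p_value < 0.001

    def test_null_calibration(self):
        """Angle effect rejected in 3-8% of 500 pure-noise simulations."""
        rng = np.random.default_rng(29)
        rejections = 0
        for _ in range(500):
            table = lmm_table(rng, n_subjects=5, n_trials=4)
            res = {r.effect: r for r in fit_lmm(table, SPEC)}
            rejections += res["angle_deg"].p_value < 0.05
        assert 0.03 <= rejections / 500 <= 0.08

    def test_shift_equivariance(self):
        rng = np.random.default_rng(31)
        table = lmm_table(rng, beta_angle=2e-4)
        base = fit_lmm(table, SPEC)
        shifted = fit_lmm(table.assign(cr=table["cr"] + 10.0), SPEC)
        for a, b in zip(base, shifted):
            assert b.f_stat == pytest.approx(a.f_stat, rel=1e-6, abs=1e-8)

    def test_one_subject_errors(self):
        rng = np.random.default_rng(37)
        table = lmm_table(rng, n_subjects=1)
        with pytest.raises(ValueError):
            fit_lmm(table, SPEC)

    def test_df_method_residual(self):
        rng = np.random.default_rng(41)
        table = lmm_table(rng)
        res = fit_lmm(table, SPEC, RunConfig(df_method="residual"))
        n, p = len(table), 4
        assert all(r.df_den == n - p for r in res)

    def test_between_within_partition(self):
        rng = np.random.default_rng(43)
        table = lmm_table(rng)
        res = {r.effect: r for r in fit_lmm(table, SPEC)}
        # gender is constant within subject: tested against subject df
        assert res["gender"].df_den == 6 - 2
        assert res["angle_deg"].df_den > 200


class TestSlopes:
    def run_decisions(self, slope_sd, n=50):
        rng = np.random.default_rng(47)
        out = []
        for _ in range(n):
            table = lmm_table(rng, slope_sd=slope_sd, beta_angle=1e-4)
            out.append(select_random_structure(table, SPEC)["decision"])
        return out

    def test_homogeneous_slopes_prefer_intercepts(self):
        decisions = self.run_decisions(0.0)
        assert decisions.count("intercept_only") >= 45

    def test_heterogeneous_slopes_detected(self):
        decisions = self.run_decisions(3e-3)
        assert decisions.count("slopes") >= 45

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(53)
        table = lmm_table(rng, slope_sd=1e-3)
        a = select_random_structure(table, SPEC)
        b = select_random_structure(table.assign(cr=table["cr"] * 7.5), SPEC)
        assert a["decision"] == b["decision"]


class TestAnalysisTable:
    def test_within_and_cross_shapes(self, small_analysis, small_study):
        tables = build_analysis_table(small_analysis, small_study.participants)
        within, cross = tables["within"], tables["cross"]
        assert set(within["experiment"]) == {1, 2}
        # window trials only, good only
        assert within["trial_index"].between(41, 60).all()
        assert within["good"].all()
        # cross-experiment table restricted to dual-participation subjects
        dual = within.groupby("participant_id")["experiment"].nunique()
        assert set(cross["participant_id"]) == set(dual.index[dual == 2])
        assert {"ncr", "nor", "ntr"} <= set(cross.columns)

    def test_per_case_option(self, small_analysis, small_study):
        cfg = RunConfig(cross_experiment_per_trial=False)
        cross = build_analysis_table(
            small_analysis, small_study.participants, cfg
        )["cross"]
        # one row per participant × experiment × case
        assert not cross.duplicated(
            ["participant_id", "experiment", "case"]).any()

    def test_missing_gender_errors(self, small_analysis, small_study):
        broken = small_study.participants.copy()
        broken.loc[broken["participant_id"] == "P03", "gender"] = np.nan
        with pytest.raises(ValueError, match="P03"):
            build_analysis_table(small_analysis, broken)


class TestRunFullAnalysis:
    def test_deterministic_rerun(self, small_analysis, small_study):
        cfg = RunConfig(rng_seed=5, bootstrap_reps=100)
        a = run_full_analysis(small_analysis, small_study.participants, cfg)
        b = run_full_analysis(small_analysis, small_study.participants, cfg)
        pd.testing.assert_frame_equal(a.fixed_effects, b.fixed_effects)
        pd.testing.assert_frame_equal(a.circular_tests, b.circular_tests)

    def test_bundle_contents(self, small_analysis, small_study):
        cfg = RunConfig(rng_seed=5, bootstrap_reps=50)
        bundle = run_full_analysis(small_analysis, small_study.participants,
                                   cfg)
        models = set(bundle.fixed_effects["model"])
        assert {"exp1_cr_angle", "exp2_or__angle", "cross_ncr_angle"} <= models
        assert (bundle.fixed_effects["p_value"].between(0, 1)).all()
        assert len(bundle.von_mises_fits) == 3  # exp1, exp2, pooled
        assert (bundle.sensitivity["magnitude_scale"] == "mel").all()
        # U2 rows are never confirmatory
        u2 = bundle.circular_tests["test"].str.startswith("watson_u2")
        assert not bundle.circular_tests.loc[u2, "bh_significant"].any()
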