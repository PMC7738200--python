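"""Response-vector decomposition: sign conventions, Pythagoras, rotation
invariance, window aggregation, and normalised ratios."""

import numpy as np
import pandas as pd
import pytest

from formantadapt.config import RunConfig
from formantadapt.decomposition import (
    BaselineCenter,
    InsufficientBaselineError,
    InsufficientWindowError,
    aggregate_window,
    baseline_center,
    decompose_responses,
    normalized_measures,
)
from formantadapt.shift_design import ShiftVector
from tests.conftest import make_case_trials


def make_shift(d1, d2, delta_f=1.0, experiment=1, case="iy"):
    return ShiftVector(
        participant_id="S1", experiment=experiment, case=case,
        d_f1_hz=d1 * delta_f, d_f2_hz=d2 * delta_f, delta_f_hz=delta_f,
        magnitude_mel=1.0,
    )


CENTER = BaselineCenter("S1", 1, "iy", 0.0, 0.0, 10)


def decompose_points(points, shift, center=CENTER):
    pts = np.atleast_2d(points)
    return decompose_responses(pts[:, 0], pts[:, 1], center, shift)


def brute_force_change_of_basis(r, shift_vec):
    """Oracle: rotate r into the shift-aligned frame with an explicit
    rotation matrix; CR is the x-component, OR minus the y-component."""
    phi = np.arctan2(shift_vec[1], shift_vec[0])
    rot = np.array([[np.cos(-phi), -np.sin(-phi)],
                    [np.sin(-phi), np.cos(-phi)]])
    aligned = rot @ np.asarray(r)
    return aligned[0], -aligned[1]


class TestSignConventions:
    def test_pure_opposition(self):
        """r = −0.5·s: CR = TR = −0.5·|s|, OR = 0."""
        s = make_shift(-0.1, 0.2)
        mag = s.magnitude_norm
        out = decompose_points([0.05, -0.1], s).iloc[0]
        assert out["cr"] == pytest.approx(-0.5 * mag)
        assert out["or_"] == pytest.approx(0.0, abs=1e-15)
        assert out["tr"] == pytest.approx(-0.5 * mag)

    def test_pure_following(self):
        """r = +s: CR = TR = +|s|, OR = 0."""
        s = make_shift(-0.1, 0.2)
        out = decompose_points([-0.1, 0.2], s).iloc[0]
        assert out["cr"] == pytest.approx(s.magnitude_norm)
        assert out["or_"] == pytest.approx(0.0, abs=1e-15)
        assert out["tr"] == pytest.approx(s.magnitude_norm)

    def test_pure_orthogonal_quadrant_sign(self):
        """Shift (−0.1, 0.2), r = 0.1·n̂ (quadrant I/II side): CR = 0,
        OR = −0.1, TR = +0.1, ANG = −153.43°."""
        s = make_shift(-0.1, 0.2)
        n_hat = np.array([-0.2, -0.1]) / np.hypot(0.1, 0.2)
        assert np.allclose(n_hat, [-0.8944, -0.4472], atol=5e-5)
        out = decompose_points(0.1 * n_hat, s).iloc[0]
        assert out["cr"] == pytest.approx(0.0, abs=1e-15)
        assert out["or_"] == pytest.approx(-0.1)
        assert out["tr"] == pytest.approx(0.1)  # + sign at CR = 0
        assert out["ang_deg"] == pytest.approx(-153.43, abs=0.01)

    def test_null_response_flag(self):
        s = make_shift(-0.1, 0.2)
        out = decompose_points([0.0, 0.0], s).iloc[0]
        assert out["null_response"]
        assert out["tr"] == out["cr"] == out["or_"] == 0.0
        assert np.isnan(out["ang_deg"])


class TestDecompositionProperties:
    rng = np.random.default_rng(2024)

    def random_pairs(self, n):
        shifts = self.rng.normal(0.0, 0.3, size=(n, 2))
        keep = np.hypot(shifts[:, 0], shifts[:, 1]) > 1e-3
        shifts = shifts[keep]
        responses = self.rng.normal(0.0, 0.2, size=(len(shifts), 2))
        return shifts, responses

    def test_pythagoras_10k(self):
        """TR² = CR² + OR² within 1e-9 relative error on 10⁴ random pairs
        (100 shift directions × 100 responses each)."""
        shifts, _ = self.random_pairs(110)
        shifts = shifts[:100]
        for sv in shifts:
            responses = self.rng.normal(0.0, 0.2, size=(100, 2))
            out = decompose_points(responses, make_shift(*sv))
            lhs = out["tr"].to_numpy() ** 2
            rhs = out["cr"].to_numpy() ** 2 + out["or_"].to_numpy() ** 2
            assert np.all(np.abs(lhs - rhs) <= 1e-9 * np.maximum(lhs, 1e-30))

    def test_rotation_matrix_oracle(self):
        """(CR, OR) matches the explicit change-of-basis on 1000 cases."""
        shifts, responses = self.random_pairs(1000)
        for sv, r in zip(shifts, responses):
            out = decompose_points(r, make_shift(*sv)).iloc[0]
            cr, or_ = brute_force_change_of_basis(r, sv)
            assert out["cr"] == pytest.approx(cr, rel=1e-9, abs=1e-12)
            assert out["or_"] == pytest.approx(or_, rel=1e-9, abs=1e-12)

    def test_joint_rotation_invariance(self):
        """Rotating shift and response together leaves (CR, OR, TR) fixed
        and shifts ANG by the rotation angle."""
        shifts, responses = self.random_pairs(300)
        angles = self.rng.uniform(-180.0, 180.0, len(shifts))
        for sv, r, a in zip(shifts, responses, angles):
            rad = np.radians(a)
            rot = np.array([[np.cos(rad), -np.sin(rad)],
                            [np.sin(rad), np.cos(rad)]])
            base = decompose_points(r, make_shift(*sv)).iloc[0]
            turned = decompose_points(rot @ r, make_shift(*(rot @ sv))).iloc[0]
            for col in ("cr", "or_", "tr"):
                assert turned[col] == pytest.approx(
                    base[col], rel=1e-9, abs=1e-12
                )
            if not base["null_response"]:
                d_ang = (turned["ang_deg"] - base["ang_deg"] - a) % 360.0
                assert min(d_ang, 360.0 - d_ang) < 1e-6

    def test_sign_law(self):
        """CR < 0 exactly when the response/shift angle exceeds 90°."""
        shifts, responses = self.random_pairs(1000)
        for sv, r in zip(shifts, responses):
            out = decompose_points(r, make_shift(*sv)).iloc[0]
            cosang = np.dot(r, sv) / (np.hypot(*r) * np.hypot(*sv))
            if abs(cosang) > 1e-12:
                assert (out["cr"] < 0) == (cosang < 0)


class TestBaseline:
    def test_mean_of_good_baseline(self):
        trials = make_case_trials()
        trials.loc[:9, "f1_norm"] = [0.98, 1.00, 1.02] + [1.0] * 7
        c = baseline_center(trials)
        assert c.f1_norm == pytest.approx(1.0)
        assert c.n_good_baseline == 10

    def test_bad_trials_excluded(self):
        good = np.ones(90, dtype=bool)
        good[9] = False
        trials = make_case_trials(good=good)
        trials.loc[:9, "f1_norm"] = [0.5] * 9 + [9.9]
        c = baseline_center(trials)
        assert c.f1_norm == pytest.approx(0.5)

    def test_insufficient_baseline(self):
        good = np.ones(90, dtype=bool)
        good[:10] = False
        with pytest.raises(InsufficientBaselineError):
            baseline_center(make_case_trials(good=good))


class TestWindowAggregation:
    def test_constant_cr_mean(self, config):
        resp = pd.DataFrame(
            {"trial_index": np.arange(41, 61), "good": True, "cr": -0.1,
             "or_": 0.0, "tr": 0.1, "ang_deg": 5.0}
        )
        out = aggregate_window(resp, config)
        assert out["mean_cr"] == pytest.approx(-0.1)
        assert out["n_good_window"] == 20

    def test_circular_mean_symmetry_and_wraparound(self, config):
        resp = pd.DataFrame(
            {"trial_index": np.arange(41, 61), "good": True, "cr": 0.0,
             "or_": 0.0, "tr": 0.0,
             "ang_deg": [10.0, -10.0] * 10}
        )
        assert aggregate_window(resp, config)["circ_mean_ang_deg"] == (
            pytest.approx(0.0, abs=1e-9)
        )
        resp["ang_deg"] = [179.0, -179.0] * 10
        wrapped = aggregate_window(resp, config)["circ_mean_ang_deg"]
        assert abs(wrapped) == pytest.approx(180.0, abs=1e-9)

    def test_insufficient_window(self, config):
        resp = pd.DataFrame(
            {"trial_index": np.arange(41, 61), "good": False, "cr": 0.0,
             "or_": 0.0, "tr": 0.0, "ang_deg": 0.0}
        )
        with pytest.raises(InsufficientWindowError):
            aggregate_window(resp, config)


class TestNormalizedMeasures:
    def test_ratios_and_homogeneity(self):
        s = make_shift(0.0, 0.2)
        window = {"mean_cr": -0.1, "mean_or": 0.05, "mean_tr": -0.05}
        out = normalized_measures(window, s)
        assert out["ncr"] == pytest.approx(-0.5)
        assert out["ntr"] == pytest.approx(-0.25)
        k = 3.7
        scaled = normalized_measures(
            {key: v * k for key, v in window.items()}, make_shift(0.0, 0.2 * k)
        )
        for key in out:
            assert scaled[key] == pytest.approx(out[key], rel=1e-12)

    def test_tr_sign_propagates(self):
        out = normalized_measures(
            {"mean_cr": 0.0, "mean_or": 0.0, "mean_tr": -0.05},
            make_shift(0.25, 0.0),
        )
        assert out["ntr"] == pytest.approx(-0.2)
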