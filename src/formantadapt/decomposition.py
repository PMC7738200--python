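"""Signed vector decomposition of adaptation responses.

Each trial's production is expressed as a response vector r from the
case's baseline centre in normalised (F1, F2) space and resolved against
the applied shift s:

* CR (compensatory response): scalar projection of r on the shift axis,
  negative when the response opposes the shift;
* OR (orthogonal response): component perpendicular to the shift axis,
  negative on the quadrant-I/II side of the shift axis (the side reached
  by rotating the shift direction +90° in the F1→F2 sense);
* TR (total response): |r| carrying CR's sign (+ when CR = 0);
* ANG: atan2(r_F2, r_F1) in degrees, the response direction relative to
  the F1-axis.

So TR² = CR² + OR² identically, and NCR/NOR/NTR are analysis-window means
of CR/OR/TR divided by the applied shift magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import circ_mean_deg
from .config import RunConfig
from .shift_design import ShiftVector


class InsufficientBaselineError(ValueError):
    """Too few good baseline trials to define a baseline centre."""


class InsufficientWindowError(ValueError):
    """Too few good analysis-window trials to summarise a case."""


@dataclass(frozen=True)
class BaselineCenter:
    """Mean normalised formants over a case's good baseline trials."""

    participant_id: str
    experiment: int
    case: str
    f1_norm: float
    f2_norm: float
    n_good_baseline: int


def baseline_center(
    trials: pd.DataFrame,
    min_good_baseline: int = 3,
) -> BaselineCenter:
    """Baseline centre for one participant × experiment × case.

    Averages ``f1_norm``/``f2_norm`` over good trials with index 1-10.
    """
    keys = trials[["participant_id", "experiment", "case"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("trials must belong to a single case")
    base = trials[(trials["trial_index"] <= 10) & trials["good"]]
    if len(base) < min_good_baseline:
        raise InsufficientBaselineError(
            f"only {len(base)} good baseline trials "
            f"(need {min_good_baseline}) for {keys.iloc[0].tolist()}"
        )
    pid, exp, case = keys.iloc[0]
    return BaselineCenter(
        participant_id=str(pid),
        experiment=int(exp),
        case=str(case),
        f1_norm=float(base["f1_norm"].mean()),
        f2_norm=float(base["f2_norm"].mean()),
        n_good_baseline=int(len(base)),
    )


def _shift_frames(shift: ShiftVector) -> tuple[np.ndarray, np.ndarray]:
    """Unit shift direction and its +90° (F1→F2 sense) normal."""
    s_hat = shift.unit_norm()
    n_hat = np.array([-s_hat[1], s_hat[0]])
    return s_hat, n_hat


def decompose_responses(
    f1_norm,
    f2_norm,
    baseline: BaselineCenter,
    shift: ShiftVector,
) -> pd.DataFrame:
    """Vectorised CR/OR/TR/ANG for arrays of normalised formants.

    Zero-length responses are flagged null: components are 0 and ANG NaN.
    """
    s_hat, n_hat = _shift_frames(shift)
    r1 = np.asarray(f1_norm, dtype=float) - baseline.f1_norm
    r2 = np.asarray(f2_norm, dtype=float) - baseline.f2_norm
    cr = r1 * s_hat[0] + r2 * s_hat[1]
    or_ = -(r1 * n_hat[0] + r2 * n_hat[1])
    norm = np.hypot(r1, r2)
    tr = np.where(cr < 0, -norm, norm)  # sign(CR), + at CR == 0
    ang = np.degrees(np.arctan2(r2, r1))
    null = norm == 0.0
    ang = np.where(null, np.nan, ang)
    return pd.DataFrame(
        {"tr": tr, "cr": cr, "or_": or_, "ang_deg": ang, "null_response": null}
    )


def decompose_trial(
    trial: pd.Series,
    baseline: BaselineCenter,
    shift: ShiftVector,
) -> pd.Series:
    """CR/OR/TR/ANG for a single trial row (convenience scalar form)."""
    out = decompose_responses(
        [trial["f1_norm"]], [trial["f2_norm"]], baseline, shift
    ).iloc[0]
    out["trial_index"] = trial["trial_index"]
    return out


def aggregate_window(
    responses: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Analysis-window aggregates for one case.

    Arithmetic means of CR/OR/TR and the circular mean of ANG over good
    trials in the last ``config.last_n_trials`` trials of the altered
    block (indices 41-60 by default).
    """
    w = responses[
        responses["trial_index"].isin(config.window_trials)
        & responses["good"]
    ]
    if len(w) < config.min_good_window:
        raise InsufficientWindowError(
            f"only {len(w)} good trials in the analysis window "
            f"(need {config.min_good_window})"
        )
    ang = w["ang_deg"].dropna().to_numpy()
    circ_ang, _ = circ_mean_deg(ang) if ang.size else (np.nan, 0.0)
    return {
        "mean_cr": float(w["cr"].mean()),
        "mean_or": float(w["or_"].mean()),
        "mean_tr": float(w["tr"].mean()),
        "circ_mean_ang_deg": float(circ_ang),
        "n_good_window": int(len(w)),
    }


def normalized_measures(window: dict, shift: ShiftVector) -> dict:
    """NCR/NOR/NTR: window means divided by the applied shift magnitude."""
    mag = shift.magnitude_norm
    if mag <= 0:
        raise ValueError("shift magnitude must be positive")
    return {
        "ncr": window["mean_cr"] / mag,
        "nor": window["mean_or"] / mag,
        "ntr": window["mean_tr"] / mag,
    }


def summarize_case(
    trials: pd.DataFrame,
    shift: ShiftVector,
    config: RunConfig,
) -> tuple[pd.DataFrame, dict]:
    """Decompose one case's trials and build its summary row.

    Returns ``(per-trial response table, CaseSummary dict)``.  All 90
    trials (washout included) are decomposed for export; only the analysis
    window enters the summary.
    """
    center = baseline_center(trials, config.min_good_baseline)
    resp = decompose_responses(
        trials["f1_norm"].to_numpy(),
        trials["f2_norm"].to_numpy(),
        center,
        shift,
    )
    resp.index = trials.index
    per_trial = pd.concat(
        [
            trials[
                ["participant_id", "experiment", "case", "trial_index",
                 "block", "good"]
            ].reset_index(drop=True),
            resp.reset_index(drop=True),
        ],
        axis=1,
    )
    window = aggregate_window(per_trial, config)
    ratios = normalized_measures(window, shift)
    summary = {
        "participant_id": center.participant_id,
        "experiment": center.experiment,
        "case": center.case,
        **window,
        **ratios,
        "n_good_baseline": center.n_good_baseline,
        "baseline_f1_norm": center.f1_norm,
        "baseline_f2_norm": center.f2_norm,
        "magnitude_norm": shift.magnitude_norm,
        "magnitude_mel": shift.magnitude_mel,
        "angle_deg": shift.angle_deg,
        "relative_height": shift.relative_height,
        "relative_backness": shift.relative_backness,
    }
    return per_trial, summary
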