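"""Synthetic two-experiment datasets with known adaptation ground truth.

The generator emulates the study design end to end: per-speaker vowel
spaces differing by a vocal-tract-length scale, six shift cases per
experiment (full-vowel shifts in Experiment 1, 50 Hz shifts in the same
directions in Experiment 2), 90-trial cases (10 baseline / 50 altered /
30 washout), trial-level isotropic production noise in normalised formant
space, geometric approach to a per-case adaptation asymptote expressed as
true NCR/NOR fractions, washout decay, and random bad trials.

Truth is planted in the (CR, OR) frame of each participant's own applied
shift, exactly the frame in which the pipeline measures responses, so the
planted NCR/NOR values are recoverable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .config import RunConfig, block_of
from .io import inventory_means
from .normalization import compute_delta_f
from .shift_design import ShiftVector, design_all_shifts, shift_table
from .vowels import ALL_VOWELS, BASE_VOWEL, CASE_VOWELS

#: Template vowel space: typical adult-male American English mean (F1, F2)
#: in Hz for the ten inventory vowels.  This is a documented synthetic
#: fixture spanning the vowel quadrilateral, not a claim about any
#: particular speaker population.
TEMPLATE_VOWELS_HZ: dict[str, tuple[float, float]] = {
    "iy": (270.0, 2290.0),
    "ih": (390.0, 1990.0),
    "ey": (450.0, 2150.0),
    "eh": (530.0, 1840.0),
    "ae": (660.0, 1720.0),
    "aa": (730.0, 1090.0),
    "ao": (570.0, 840.0),
    "ow": (500.0, 910.0),
    "uh": (440.0, 1020.0),
    "uw": (300.0, 870.0),
}


@dataclass(frozen=True)
class SpeakerProfile:
    """Per-speaker generator settings.

    ``vtl_scale`` multiplies the template vocal-tract length (formants are
    divided by it); ``noise_sd_norm`` is the per-formant production-noise
    SD in normalised units; ``bad_trial_prob`` the chance a trial is
    flagged bad.
    """

    participant_id: str
    gender: str
    vtl_scale: float
    noise_sd_norm: float = 0.012
    bad_trial_prob: float = 0.03

    def __post_init__(self) -> None:
        if not 0.8 <= self.vtl_scale <= 1.2:
            raise ValueError("vtl_scale must lie in [0.8, 1.2]")
        if self.noise_sd_norm <= 0:
            raise ValueError("noise_sd_norm must be positive")
        if not 0.0 <= self.bad_trial_prob < 1.0:
            raise ValueError("bad_trial_prob must lie in [0, 1)")


@dataclass(frozen=True)
class AdaptationTruth:
    """Ground-truth asymptotes and dynamics for one participant × case."""

    participant_id: str
    experiment: int
    case: str
    true_ncr: float
    true_nor: float
    learning_rate: float = 0.25
    washout_rate: float = 0.30

    def __post_init__(self) -> None:
        for name in ("learning_rate", "washout_rate"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


# Truth profiles: map (angle_deg, case, experiment) -> (true_ncr, true_nor).
def _truth_null(angle_deg, case, experiment):
    return 0.0, 0.0


def _truth_uniform(angle_deg, case, experiment):
    return -0.15, 0.0


def _truth_front_back(angle_deg, case, experiment):
    # Compensate for shifts that raise F2 (positive angles), follow
    # otherwise — the qualitative small-shift dichotomy.
    return (-0.4, 0.0) if angle_deg > 0 else (0.1, 0.0)


def _truth_experiment_dependent(angle_deg, case, experiment):
    # Uniform compensation in experiment 1, front/back dichotomy in
    # experiment 2: plants an experiment-by-angle interaction.
    if experiment == 1:
        return -0.25, 0.0
    return _truth_front_back(angle_deg, case, experiment)


TRUTH_PROFILES: dict[str, Callable] = {
    "null": _truth_null,
    "uniform_compensation": _truth_uniform,
    "front_back_dichotomy": _truth_front_back,
    "experiment_dependent": _truth_experiment_dependent,
}


@dataclass
class StudyDesign:
    """Generator settings; the defaults are the emulated study conditions
    (18 participants, ten female; 14 in both experiments and two exclusive
    to each; six 90-trial cases per experiment)."""

    n_participants: int = 18
    n_female: int = 10
    n_exclusive_each: int = 2
    vtl_scale_range_female: tuple[float, float] = (0.82, 0.95)
    vtl_scale_range_male: tuple[float, float] = (1.0, 1.15)
    token_noise_sd: float = 0.015
    noise_sd_norm: float = 0.012
    bad_trial_prob: float = 0.03
    learning_rate: float = 0.25
    washout_rate: float = 0.30
    truth_profile: str | Callable = "uniform_compensation"
    #: SD of a per-participant additive offset on true NCR (0 disables).
    participant_truth_sd: float = 0.05
    #: SD of independent per-cell jitter on true NCR/NOR (0 disables).
    cell_truth_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least two participants")
        if self.n_participants - 2 * self.n_exclusive_each < 0:
            raise ValueError("exclusive participants exceed the cohort")

    def truth_fn(self) -> Callable:
        if callable(self.truth_profile):
            return self.truth_profile
        return TRUTH_PROFILES[self.truth_profile]


@dataclass
class SimulatedStudy:
    """Generator output: the same tables the readers consume, plus the
    ground-truth ledger and the design shifts used for planting."""

    tokens: pd.DataFrame
    inventory: pd.DataFrame
    trials: pd.DataFrame
    participants: pd.DataFrame
    truth: pd.DataFrame
    shifts: pd.DataFrame


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Named substream of the master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def generate_inventory(
    profile: SpeakerProfile,
    template: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    token_noise_sd: float = 0.015,
    n_tokens: int = 3,
) -> pd.DataFrame:
    """Baseline vowel tokens for one speaker.

    Template formants are divided by ``vtl_scale`` (formants scale
    inversely with vocal-tract length); each of the ``n_tokens`` tokens
    gets independent multiplicative log-normal noise.  With zero noise and
    unit scale the inventory means equal the template exactly.
    """
    template = template or TEMPLATE_VOWELS_HZ
    if profile.vtl_scale <= 0:
        raise ValueError("vtl_scale must be positive")
    rng = _rng(seed, 1)
    rows = []
    for vowel in ALL_VOWELS:
        if vowel not in template:
            raise ValueError(f"template is missing vowel {vowel!r}")
        f1, f2 = template[vowel]
        for tok in range(1, n_tokens + 1):
            noise = (
                np.exp(rng.normal(0.0, token_noise_sd, size=2))
                if token_noise_sd > 0
                else np.ones(2)
            )
            rows.append(
                {
                    "participant_id": profile.participant_id,
                    "vowel": vowel,
                    "token_index": tok,
                    "f1_hz": f1 / profile.vtl_scale * noise[0],
                    "f2_hz": f2 / profile.vtl_scale * noise[1],
                }
            )
    return pd.DataFrame(rows)


def simulate_case(
    profile: SpeakerProfile,
    truth: AdaptationTruth,
    shift: ShiftVector,
    center_norm: tuple[float, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Ninety trials for one participant × experiment × case.

    The response at trial t is a(t)·|s|·(true_ncr·ŝ − true_nor·n̂) plus
    isotropic noise, where ŝ is the unit shift, n̂ is ŝ rotated +90° in
    the F1→F2 sense, and the minus sign orients the plant so that positive
    ``true_nor`` produces positive measured OR (the decomposition defines
    OR = −r·n̂).  a(t) is 0 in the baseline block, rises geometrically to
    1 at ``learning_rate`` during the altered block, and decays at
    ``washout_rate`` during washout.
    """
    if shift.magnitude_norm <= 0:
        raise ValueError("degenerate shift")
    rng = _rng(seed, 2)
    s_hat = shift.unit_norm()
    n_hat = np.array([-s_hat[1], s_hat[0]])
    t = np.arange(1, 91)
    a = np.zeros(90)
    altered = (t >= 11) & (t <= 60)
    a[altered] = 1.0 - (1.0 - truth.learning_rate) ** (t[altered] - 10)
    a_end = a[t == 60][0]
    washout = t >= 61
    a[washout] = a_end * (1.0 - truth.washout_rate) ** (t[washout] - 60)

    plant = (
        a[:, None]
        * shift.magnitude_norm
        * (truth.true_ncr * s_hat + truth.true_nor * (-n_hat))
    )
    noise = rng.normal(0.0, profile.noise_sd_norm, size=(90, 2))
    norm = np.asarray(center_norm) + plant + noise
    bad = rng.random(90) < profile.bad_trial_prob
    return pd.DataFrame(
        {
            "participant_id": profile.participant_id,
            "experiment": truth.experiment,
            "case": truth.case,
            "trial_index": t,
            "block": [block_of(i) for i in t],
            "good": ~bad,
            "f1_hz": norm[:, 0] * shift.delta_f_hz,
            "f2_hz": norm[:, 1] * shift.delta_f_hz,
        }
    )


def _make_profiles(design: StudyDesign, seed: int) -> list[SpeakerProfile]:
    rng = _rng(seed, 3)
    profiles = []
    for i in range(design.n_participants):
        gender = "F" if i < design.n_female else "M"
        lo, hi = (
            design.vtl_scale_range_female
            if gender == "F"
            else design.vtl_scale_range_male
        )
        profiles.append(
            SpeakerProfile(
                participant_id=f"P{i + 1:02d}",
                gender=gender,
                vtl_scale=float(rng.uniform(lo, hi)),
                noise_sd_norm=design.noise_sd_norm,
                bad_trial_prob=design.bad_trial_prob,
            )
        )
    return profiles


def simulate_study(
    design: StudyDesign | None = None,
    seed: int = 0,
    config: RunConfig | None = None,
) -> SimulatedStudy:
    """Generate a complete two-experiment dataset.

    The first ``n_exclusive_each`` participants run only Experiment 1, the
    last ``n_exclusive_each`` only Experiment 2, and everyone in between
    runs both (default: 14 of 18 in both, 16 per experiment).  Case order
    is randomised per participant and recorded in the truth ledger.
    """
    design = design or StudyDesign()
    truth_fn = design.truth_fn()
    profiles = _make_profiles(design, seed)

    token_frames, trial_frames, truth_rows, shift_rows = [], [], [], []
    participants = []
    n = design.n_participants
    excl = design.n_exclusive_each
    for i, profile in enumerate(profiles):
        if n >= 2 * excl + 1:
            if i < excl:
                experiments = (1,)
            elif i >= n - excl:
                experiments = (2,)
            else:
                experiments = (1, 2)
        else:
            experiments = (1, 2)
        tokens = generate_inventory(
            profile, seed=seed + 31 * (i + 1),
            token_noise_sd=design.token_noise_sd,
        )
        token_frames.append(tokens)
        inv = inventory_means(tokens)
        ctx = compute_delta_f(inv)
        shifts = design_all_shifts(inv, ctx, experiments=experiments)
        shift_rows.extend(shifts)
        center = inv.set_index("vowel").loc[
            BASE_VOWEL, ["f1_hz", "f2_hz"]
        ].to_numpy(dtype=float) / ctx.delta_f_hz
        participants.append(
            {"participant_id": profile.participant_id,
             "gender": profile.gender,
             "vtl_scale": profile.vtl_scale}
        )
        truth_rng = _rng(seed, 4, i)
        subj_offset = (
            truth_rng.normal(0.0, design.participant_truth_sd)
            if design.participant_truth_sd > 0
            else 0.0
        )
        for exp in experiments:
            order = truth_rng.permutation(len(CASE_VOWELS))
            exp_shifts = {s.case: s for s in shifts if s.experiment == exp}
            for pos, case_i in enumerate(order):
                case = CASE_VOWELS[case_i]
                s = exp_shifts[case]
                ncr, nor = truth_fn(s.angle_deg, case, exp)
                if design.cell_truth_sd > 0:
                    ncr += truth_rng.normal(0.0, design.cell_truth_sd)
                    nor += truth_rng.normal(0.0, design.cell_truth_sd)
                ncr += subj_offset
                truth = AdaptationTruth(
                    participant_id=profile.participant_id,
                    experiment=exp,
                    case=case,
                    true_ncr=float(ncr),
                    true_nor=float(nor),
                    learning_rate=design.learning_rate,
                    washout_rate=design.washout_rate,
                )
                trial_frames.append(
                    simulate_case(
                        profile, truth, s, tuple(center),
                        seed=seed + 101 * (i + 1) + 7 * exp + case_i,
                    )
                )
                truth_rows.append(
                    {
                        "participant_id": truth.participant_id,
                        "experiment": exp,
                        "case": case,
                        "true_ncr": truth.true_ncr,
                        "true_nor": truth.true_nor,
                        "learning_rate": truth.learning_rate,
                        "washout_rate": truth.washout_rate,
                        "case_order": pos + 1,
                        "seed": seed,
                    }
                )

    tokens = pd.concat(token_frames, ignore_index=True)
    return SimulatedStudy(
        tokens=tokens,
        inventory=inventory_means(tokens),
        trials=pd.concat(trial_frames, ignore_index=True),
        participants=pd.DataFrame(participants),
        truth=pd.DataFrame(truth_rows),
        shifts=shift_table(shift_rows),
    )
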