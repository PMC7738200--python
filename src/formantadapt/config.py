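"""Run configuration shared by all pipeline stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Block boundaries, fixed by the experimental design: trials 1-10 baseline,
#: 11-60 altered, 61-90 washout.
BASELINE_TRIALS = range(1, 11)
ALTERED_TRIALS = range(11, 61)
WASHOUT_TRIALS = range(61, 91)
N_TRIALS = 90


def block_of(trial_index: int) -> str:
    """Block label as a pure function of the 1-based trial index."""
    if 1 <= trial_index <= 10:
        return "baseline"
    if 11 <= trial_index <= 60:
        return "altered"
    if 61 <= trial_index <= 90:
        return "washout"
    raise ValueError(f"trial_index {trial_index} outside 1..90")


@dataclass
class RunConfig:
    """Analysis settings.

    Parameters
    ----------
    alpha
        Significance level for every inferential decision, including the
        Benjamini-Hochberg step-up.
    last_n_trials
        Length of the analysis window at the end of the altered block
        (trials ``61 - last_n_trials`` .. 60).
    min_good_baseline
        Minimum number of good baseline trials needed to define a case's
        baseline centre.
    min_good_window
        Minimum number of good analysis-window trials for a case to enter
        the summaries.
    rng_seed
        Master seed; every stochastic step derives a named substream.
    bootstrap_reps
        Parametric-bootstrap replicates for the Watson U² p-value.
    magnitude_scale
        Which shift-magnitude covariate the mixed models use:
        ``"normalised"`` (vocal-tract-length-normalised units) or ``"mel"``.
    df_method
        Denominator-degrees-of-freedom rule for Type III F tests:
        ``"between-within"`` (between-subject terms tested against
        subject-level df) or ``"residual"``.
    auto_qc
        If True, additionally mark trials bad when a formant falls outside
        [100, 4000] Hz. Off by default: the good-trial flag in the input is
        authoritative.
    cross_experiment_per_trial
        Cross-experiment models use per-trial normalised responses when
        True (default), per-case window averages when False.
    angle_as_category
        Re-analysis switch: replace the continuous shift-angle covariate by
        the categorical target vowel. Off by default.
    """

    alpha: float = 0.05
    last_n_trials: int = 20
    min_good_baseline: int = 3
    min_good_window: int = 5
    rng_seed: int = 0
    bootstrap_reps: int = 1000
    magnitude_scale: str = "normalised"
    df_method: str = "between-within"
    auto_qc: bool = False
    cross_experiment_per_trial: bool = True
    angle_as_category: bool = False
    #: Include a participant × case variance component in trial-level
    #: mixed models (trials within a case share its estimated baseline).
    case_variance: bool = True
    # Stage switches for the inferential bundle (all on by default).
    include_reduced_models: bool = True
    include_cross_experiment: bool = True
    include_circular_tests: bool = True
    include_von_mises_check: bool = True
    include_mel_sensitivity: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("last_n_trials", "min_good_baseline", "min_good_window"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.last_n_trials > 50:
            raise ValueError("last_n_trials cannot exceed the altered block (50)")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")
        if self.magnitude_scale not in ("normalised", "mel"):
            raise ValueError("magnitude_scale must be 'normalised' or 'mel'")
        if self.df_method not in ("between-within", "residual"):
            raise ValueError("df_method must be 'between-within' or 'residual'")

    @property
    def window_trials(self) -> range:
        """Trial indices of the analysis window (end of the altered block)."""
        return range(61 - self.last_n_trials, 61)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
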