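"""Dataset-level driver: normalise, design shifts, decompose every case."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .decomposition import (
    InsufficientBaselineError,
    InsufficientWindowError,
    summarize_case,
)
from .normalization import compute_delta_f, normalization_table
from .shift_design import design_shift_fixed, design_shift_full, shift_table
from .vowels import CASE_VOWELS

logger = logging.getLogger("formantadapt")


@dataclass
class AnalysisResult:
    """Products of the decomposition stage for a whole dataset."""

    normalization: pd.DataFrame
    shifts: pd.DataFrame
    responses: pd.DataFrame
    summaries: pd.DataFrame
    skipped: list = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "normalization": self.normalization,
            "shifts": self.shifts,
            "responses": self.responses,
            "case_summaries": self.summaries,
        }


def analyze_dataset(
    inventory: pd.DataFrame,
    trials: pd.DataFrame,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Run normalisation, shift design, and decomposition on a dataset.

    ``inventory`` holds per-vowel mean formants per participant (use
    ``io.inventory_means`` on a token table first).  Cases with too few
    good baseline or analysis-window trials are skipped and listed in
    ``skipped`` rather than aborting the run.
    """
    config = config or RunConfig()
    contexts: dict[str, object] = {}
    shift_objs: dict[tuple, object] = {}
    for pid, inv in inventory.groupby("participant_id"):
        ctx = compute_delta_f(inv)
        contexts[str(pid)] = ctx
        for exp in sorted(trials.loc[
            trials["participant_id"] == str(pid), "experiment"
        ].unique()):
            for case in CASE_VOWELS:
                design = design_shift_full if exp == 1 else design_shift_fixed
                shift_objs[(str(pid), int(exp), case)] = design(inv, ctx, case)

    responses, summaries, skipped = [], [], []
    for (pid, exp, case), grp in trials.groupby(
        ["participant_id", "experiment", "case"], sort=True
    ):
        pid = str(pid)
        if pid not in contexts:
            skipped.append(((pid, exp, case), "no inventory"))
            continue
        ctx = contexts[pid]
        shift = shift_objs[(pid, int(exp), case)]
        grp = grp.sort_values("trial_index").reset_index(drop=True)
        grp = grp.assign(
            f1_norm=grp["f1_hz"] / ctx.delta_f_hz,
            f2_norm=grp["f2_hz"] / ctx.delta_f_hz,
        )
        try:
            per_trial, summary = summarize_case(grp, shift, config)
        except (InsufficientBaselineError, InsufficientWindowError) as err:
            skipped.append(((pid, exp, case), str(err)))
            logger.warning("skipping %s exp %s case %s: %s", pid, exp, case, err)
            continue
        responses.append(per_trial)
        summaries.append(summary)

    return AnalysisResult(
        normalization=normalization_table(contexts.values()),
        shifts=shift_table(shift_objs.values()),
        responses=(
            pd.concat(responses, ignore_index=True)
            if responses
            else pd.DataFrame()
        ),
        summaries=pd.DataFrame(summaries),
        skipped=skipped,
    )
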