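"""Descriptive report figures: per-case bar summaries and the shift-vs-
response vector plot in normalised F1-F2 space."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .vowels import CASE_VOWELS


def _sem(x: pd.Series) -> float:
    x = x.dropna()
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def case_summary_panels(summaries: pd.DataFrame, experiment: int,
                        out_path: str | Path) -> Path:
    """Four-panel bar figure: mean CR, OR, TR, and circular-mean ANG per
    case with standard-error bars, averaged across participants."""
    sub = summaries[summaries["experiment"] == experiment]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    panels = [
        ("mean_cr", "Mean CR (normalised)"),
        ("mean_or", "Mean OR (normalised)"),
        ("mean_tr", "Mean TR (normalised)"),
        ("circ_mean_ang_deg", "Circular mean ANG (deg)"),
    ]
    for ax, (col, title) in zip(axes.ravel(), panels):
        means = [sub.loc[sub["case"] == c, col].mean() for c in CASE_VOWELS]
        sems = [_sem(sub.loc[sub["case"] == c, col]) for c in CASE_VOWELS]
        ax.bar(range(len(CASE_VOWELS)), means, yerr=sems, capsize=3,
               color="#4878d0")
        ax.set_xticks(range(len(CASE_VOWELS)))
        ax.set_xticklabels(CASE_VOWELS)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_title(f"{title} — experiment {experiment}")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def shift_response_plot(summaries: pd.DataFrame, shifts: pd.DataFrame,
                        experiment: int, out_path: str | Path) -> Path:
    """Average applied-shift vectors (dashed) and average response vectors
    (solid) from the mean baseline, per case, in normalised F1-F2 space
    (F2 on x, F1 on y, both axes as in vowel charts)."""
    sub = summaries[summaries["experiment"] == experiment]
    sh = shifts[shifts["experiment"] == experiment]
    base = sub[["baseline_f1_norm", "baseline_f2_norm"]].mean()
    fig, ax = plt.subplots(figsize=(7, 6))
    for case in CASE_VOWELS:
        s = sh[sh["case"] == case][["d_f1_norm", "d_f2_norm"]].mean()
        ax.plot(
            [base["baseline_f2_norm"], base["baseline_f2_norm"] + s["d_f2_norm"]],
            [base["baseline_f1_norm"], base["baseline_f1_norm"] + s["d_f1_norm"]],
            "--", color="grey",
        )
        c = sub[sub["case"] == case]
        if not len(c):
            continue
        ang = np.radians(c["circ_mean_ang_deg"].mean())
        tr = c["mean_tr"].abs().mean()
        ax.plot(
            [base["baseline_f2_norm"],
             base["baseline_f2_norm"] + tr * np.sin(ang)],
            [base["baseline_f1_norm"],
             base["baseline_f1_norm"] + tr * np.cos(ang)],
            "-", lw=2, label=case,
        )
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel("normalised F2")
    ax.set_ylabel("normalised F1")
    ax.set_title(f"Applied shifts (dashed) vs mean responses — experiment "
                 f"{experiment}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
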