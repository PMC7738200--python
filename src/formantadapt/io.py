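"""Table readers/writers and dataset validation.

All tables are UTF-8, comma-delimited CSV with a header row and "." as
the decimal separator; vowels use ASCII aliases (see ``vowels``).  The
trials schema carries the block label redundantly: it is always recomputed
from the trial index and checked, so a file whose labels disagree with the
fixed 10/50/30 partition is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, block_of
from .vowels import canonical_vowel

INVENTORY_COLUMNS = ["participant_id", "vowel", "token_index", "f1_hz", "f2_hz"]
TRIAL_COLUMNS = [
    "participant_id", "experiment", "case", "trial_index", "block", "good",
    "f1_hz", "f2_hz",
]
PARTICIPANT_COLUMNS = ["participant_id", "gender"]

#: Automatic QC bounds (only applied when config.auto_qc is on).
AUTO_QC_RANGE_HZ = (100.0, 4000.0)


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """Row-level contents violate a table invariant."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s) {missing}")


def _check_positive_formants(df: pd.DataFrame, what: str) -> None:
    f = df[["f1_hz", "f2_hz"]].to_numpy(dtype=float)
    bad = ~np.isfinite(f).all(axis=1) | (f <= 0).any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{what} row {row}: formants must be finite and positive"
        )
    swapped = f[:, 0] >= f[:, 1]
    if swapped.any():
        row = int(np.flatnonzero(swapped)[0])
        raise ValidationError(f"{what} row {row}: requires f1_hz < f2_hz")


def read_inventory_table(path: str | Path) -> pd.DataFrame:
    """Read a vowel-token table and validate it.

    Columns: participant_id, vowel, token_index (>= 1), f1_hz, f2_hz.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, INVENTORY_COLUMNS, "inventory")
    df["participant_id"] = df["participant_id"].astype(str)
    df["vowel"] = df["vowel"].map(canonical_vowel)
    df["token_index"] = df["token_index"].astype(int)
    if (df["token_index"] < 1).any():
        raise ValidationError("token_index must be >= 1")
    _check_positive_formants(df, "inventory")
    dup = df.duplicated(["participant_id", "vowel", "token_index"])
    if dup.any():
        raise ValidationError(
            f"duplicate (participant, vowel, token) at row {int(dup.idxmax())}"
        )
    return df


def inventory_means(tokens: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-vowel mean formants over tokens."""
    return (
        tokens.groupby(["participant_id", "vowel"], as_index=False)[
            ["f1_hz", "f2_hz"]
        ].mean()
    )


def read_trial_table(path: str | Path, auto_qc: bool = False) -> pd.DataFrame:
    """Read a trial table and validate it.

    The block label is recomputed from ``trial_index`` (1-10 baseline,
    11-60 altered, 61-90 washout) and must agree with any provided label;
    (participant, experiment, case, trial_index) must be unique.  With
    ``auto_qc`` trials whose formants leave [100, 4000] Hz are re-marked
    bad in addition to the authoritative good flag.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, [c for c in TRIAL_COLUMNS if c != "block"], "trials"
    )
    df["participant_id"] = df["participant_id"].astype(str)
    df["experiment"] = df["experiment"].astype(int)
    if not df["experiment"].isin([1, 2]).all():
        raise ValidationError("experiment must be 1 or 2")
    df["case"] = df["case"].map(canonical_vowel)
    df["trial_index"] = df["trial_index"].astype(int)
    if not df["trial_index"].between(1, 90).all():
        row = int((~df["trial_index"].between(1, 90)).idxmax())
        raise ValidationError(f"trials row {row}: trial_index outside 1..90")
    recomputed = df["trial_index"].map(block_of)
    if "block" in df.columns:
        mismatch = df["block"].astype(str) != recomputed
        if mismatch.any():
            row = int(mismatch.idxmax())
            raise ValidationError(
                f"trials row {row}: block label {df['block'].iloc[row]!r} "
                f"contradicts trial_index {df['trial_index'].iloc[row]}"
            )
    df["block"] = recomputed
    df["good"] = df["good"].astype(bool)
    _check_positive_formants(df, "trials")
    dup = df.duplicated(["participant_id", "experiment", "case", "trial_index"])
    if dup.any():
        raise ValidationError(
            "duplicate (participant, experiment, case, trial_index) "
            f"at row {int(dup.idxmax())}"
        )
    if auto_qc:
        lo, hi = AUTO_QC_RANGE_HZ
        in_range = df[["f1_hz", "f2_hz"]].apply(
            lambda c: c.between(lo, hi)
        ).all(axis=1)
        df["good"] = df["good"] & in_range
    return df[TRIAL_COLUMNS]


def read_participant_table(path: str | Path) -> pd.DataFrame:
    """Read participant metadata (participant_id, gender)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PARTICIPANT_COLUMNS, "participants")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> pd.DataFrame:
    """Write one CSV per named table; return the manifest.

    The manifest lists file names and row counts.  Floats are written at
    full round-trip precision so read-back reproduces values exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.17g")
        entries.append({"table": name, "file": path.name, "rows": len(table)})
    manifest = pd.DataFrame(entries, columns=["table", "file", "rows"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


@dataclass
class ValidationReport:
    """Advisory dataset-level issues; downstream stages decide to error."""

    missing_inventory: list = field(default_factory=list)
    baseline_deficits: list = field(default_factory=list)
    window_deficits: list = field(default_factory=list)

    @property
    def issues(self) -> list[str]:
        out = [f"participant {p} has trials but no inventory"
               for p in self.missing_inventory]
        out += [
            f"{key}: only {n} good baseline trials"
            for key, n in self.baseline_deficits
        ]
        out += [
            f"{key}: only {n} good analysis-window trials"
            for key, n in self.window_deficits
        ]
        return out

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(
    trials: pd.DataFrame,
    inventory: pd.DataFrame,
    config: RunConfig | None = None,
) -> ValidationReport:
    """Cross-check trials against inventories and good-trial counts."""
    config = config or RunConfig()
    report = ValidationReport()
    inv_participants = set(inventory["participant_id"].astype(str))
    for pid in sorted(set(trials["participant_id"]) - inv_participants):
        report.missing_inventory.append(pid)
    window = set(config.window_trials)
    for key, grp in trials.groupby(["participant_id", "experiment", "case"]):
        n_base = int(((grp["trial_index"] <= 10) & grp["good"]).sum())
        if n_base < config.min_good_baseline:
            report.baseline_deficits.append((key, n_base))
        n_win = int((grp["trial_index"].isin(window) & grp["good"]).sum())
        if n_win < config.min_good_window:
            report.window_deficits.append((key, n_win))
    return report
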