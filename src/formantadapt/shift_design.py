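"""Per-participant applied-shift vectors for both experiments.

Experiment 1 shifts the feedback from the produced vowel /eh/ all the way
to a target vowel (full-vowel shift); Experiment 2 keeps each target's
direction but fixes the Hz-space magnitude at 50 Hz.  Vectors live in
(F1, F2) order; the angle is measured from the +F1 axis with positive sign
toward +F2, i.e. atan2(ΔF2, ΔF1), so shifts that raise F2 (front-vowel
targets) get positive angles and shifts that lower F2 get negative angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import NormalizationContext, shift_magnitude_mel
from .vowels import (
    BASE_VOWEL,
    CASE_VOWELS,
    canonical_vowel,
    direction_covariates,
    relative_backness,
    relative_height,
)

#: Hz-space magnitude of every Experiment-2 shift.
FIXED_SHIFT_HZ: float = 50.0


class DegenerateShiftError(ValueError):
    """Raised when a target vowel coincides with the produced vowel."""


@dataclass(frozen=True)
class ShiftVector:
    """One applied alteration in F1-F2 space.

    Hz components are the raw applied shift; normalised components are the
    Hz components divided by the speaker's ΔF.  ``angle_deg`` is
    atan2(ΔF2, ΔF1) in degrees, in (−180, 180].
    """

    participant_id: str
    experiment: int
    case: str
    d_f1_hz: float
    d_f2_hz: float
    delta_f_hz: float
    magnitude_mel: float

    @property
    def d_f1_norm(self) -> float:
        return self.d_f1_hz / self.delta_f_hz

    @property
    def d_f2_norm(self) -> float:
        return self.d_f2_hz / self.delta_f_hz

    @property
    def magnitude_hz(self) -> float:
        return float(np.hypot(self.d_f1_hz, self.d_f2_hz))

    @property
    def magnitude_norm(self) -> float:
        return float(np.hypot(self.d_f1_norm, self.d_f2_norm))

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.d_f2_norm, self.d_f1_norm)))

    @property
    def relative_height(self) -> str:
        return relative_height(self.case)

    @property
    def relative_backness(self) -> str:
        return relative_backness(self.case)

    def unit_norm(self) -> np.ndarray:
        """Unit vector along the shift in normalised (F1, F2) space."""
        v = np.array([self.d_f1_norm, self.d_f2_norm])
        return v / np.linalg.norm(v)


def _vowel_means(inventory: pd.DataFrame, vowel: str) -> np.ndarray:
    inv = inventory.assign(vowel=inventory["vowel"].map(canonical_vowel))
    rows = inv.loc[inv["vowel"] == vowel, ["f1_hz", "f2_hz"]]
    if rows.empty:
        raise ValueError(f"inventory has no vowel {vowel!r}")
    return rows.iloc[0].to_numpy(dtype=float)


def design_shift_full(
    inventory: pd.DataFrame,
    ctx: NormalizationContext,
    case: str,
) -> ShiftVector:
    """Experiment-1 shift: target-vowel means minus /eh/ means, per formant."""
    case = canonical_vowel(case)
    if case not in CASE_VOWELS:
        raise ValueError(f"{case!r} is not one of the six shift cases")
    base = _vowel_means(inventory, BASE_VOWEL)
    target = _vowel_means(inventory, case)
    d = target - base
    if np.hypot(*d) == 0.0:
        raise DegenerateShiftError(
            f"target {case!r} coincides with {BASE_VOWEL!r} for "
            f"{ctx.participant_id}"
        )
    return ShiftVector(
        participant_id=ctx.participant_id,
        experiment=1,
        case=case,
        d_f1_hz=float(d[0]),
        d_f2_hz=float(d[1]),
        delta_f_hz=ctx.delta_f_hz,
        magnitude_mel=shift_magnitude_mel(base[0], base[1], d[0], d[1]),
    )


def design_shift_fixed(
    inventory: pd.DataFrame,
    ctx: NormalizationContext,
    case: str,
    magnitude_hz: float = FIXED_SHIFT_HZ,
) -> ShiftVector:
    """Experiment-2 shift: same direction as Experiment 1, fixed Hz length."""
    if magnitude_hz <= 0:
        raise ValueError("magnitude_hz must be positive")
    full = design_shift_full(inventory, ctx, case)
    scale = magnitude_hz / full.magnitude_hz
    base = _vowel_means(inventory, BASE_VOWEL)
    d1, d2 = full.d_f1_hz * scale, full.d_f2_hz * scale
    return ShiftVector(
        participant_id=ctx.participant_id,
        experiment=2,
        case=full.case,
        d_f1_hz=d1,
        d_f2_hz=d2,
        delta_f_hz=ctx.delta_f_hz,
        magnitude_mel=shift_magnitude_mel(base[0], base[1], d1, d2),
    )


def design_all_shifts(
    inventory: pd.DataFrame,
    ctx: NormalizationContext,
    experiments=(1, 2),
) -> list[ShiftVector]:
    """All six case shifts for the requested experiments, one participant."""
    out = []
    for exp in experiments:
        for case in CASE_VOWELS:
            if exp == 1:
                out.append(design_shift_full(inventory, ctx, case))
            elif exp == 2:
                out.append(design_shift_fixed(inventory, ctx, case))
            else:
                raise ValueError(f"unknown experiment {exp!r}")
    return out


def shift_table(shifts) -> pd.DataFrame:
    """Tabulate ShiftVectors with their direction covariates."""
    rows = []
    for s in shifts:
        cov = direction_covariates(s.case)
        rows.append(
            {
                "participant_id": s.participant_id,
                "experiment": s.experiment,
                "case": s.case,
                "d_f1_hz": s.d_f1_hz,
                "d_f2_hz": s.d_f2_hz,
                "d_f1_norm": s.d_f1_norm,
                "d_f2_norm": s.d_f2_norm,
                "magnitude_norm": s.magnitude_norm,
                "magnitude_mel": s.magnitude_mel,
                "angle_deg": s.angle_deg,
                "relative_height": cov["relative_height"],
                "relative_backness": cov["relative_backness"],
            }
        )
    return pd.DataFrame(rows)
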