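"""Vocal-tract-length normalisation and mel conversion.

Speakers differ in vocal tract length, which rescales the whole formant
space.  The ΔF method estimates each speaker's average formant spacing

    ΔF = (1 / (m·n)) · Σ_j Σ_i  F_ij / (i − 0.5)

over n formants (here n = 2, divisors 0.5 and 1.5) and m vowel tokens, and
divides every frequency by it.  For an ideal uniform tube of length L the
formants are F_i = (2i − 1)·c / (4L), so ΔF = c / (2L) and

    vocal tract length  L = c / (2·ΔF),     c = 35 000 cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vowels import DELTA_F_VOWELS, canonical_vowel

#: Speed of sound in warm, moist air (cm/s).
SPEED_OF_SOUND_CM_S: float = 35_000.0

#: Analytic mel-scale constants: mel = MEL_SCALE · log10(1 + f / MEL_BREAK).
MEL_SCALE: float = 2595.0
MEL_BREAK_HZ: float = 700.0


@dataclass(frozen=True)
class NormalizationContext:
    """Per-speaker normalisation constants.

    ``delta_f_hz`` is the average formant spacing; ``vtl_cm`` the implied
    vocal tract length; ``token_vowels`` the vowel set the estimate used;
    ``n_formants``/``n_tokens`` the m·n bookkeeping of the estimator.
    """

    participant_id: str
    delta_f_hz: float
    token_vowels: tuple[str, ...]
    n_formants: int = 2

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_f_hz) or self.delta_f_hz <= 0:
            raise ValueError("delta_f_hz must be finite and positive")

    @property
    def n_tokens(self) -> int:
        return len(self.token_vowels)

    @property
    def vtl_cm(self) -> float:
        """Vocal tract length implied by ΔF (uniform-tube relation)."""
        return SPEED_OF_SOUND_CM_S / (2.0 * self.delta_f_hz)


def compute_delta_f(
    inventory: pd.DataFrame,
    token_vowels=DELTA_F_VOWELS,
) -> NormalizationContext:
    """Estimate ΔF from one participant's mean vowel formants.

    Parameters
    ----------
    inventory
        Per-vowel mean formants for one participant: columns
        ``participant_id, vowel, f1_hz, f2_hz`` (one row per vowel).
    token_vowels
        Vowels entering the estimate (default: the seven-vowel set
        {eh, ih, iy, ey, ae, aa, uw}).

    Returns
    -------
    NormalizationContext
    """
    vowel_set = tuple(sorted(canonical_vowel(v) for v in token_vowels))
    participants = inventory["participant_id"].unique()
    if len(participants) != 1:
        raise ValueError("inventory must contain exactly one participant")
    inv = inventory.assign(vowel=inventory["vowel"].map(canonical_vowel))
    inv = inv.set_index("vowel")
    missing = [v for v in vowel_set if v not in inv.index]
    if missing:
        raise ValueError(f"inventory is missing vowels {missing}")
    f = inv.loc[list(vowel_set), ["f1_hz", "f2_hz"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("formant means must be finite and positive")
    if np.any(f[:, 0] >= f[:, 1]):
        raise ValueError("every token must satisfy f1 < f2")
    m, n = f.shape  # tokens x formants
    divisors = np.arange(1, n + 1) - 0.5  # 0.5, 1.5
    delta_f = float(np.sum(f / divisors) / (m * n))
    return NormalizationContext(
        participant_id=str(participants[0]),
        delta_f_hz=delta_f,
        token_vowels=vowel_set,
        n_formants=n,
    )


def normalize_formants(f_hz, ctx: NormalizationContext):
    """Divide frequencies (Hz) by the speaker's ΔF (dimensionless result)."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("frequencies must be finite and positive")
    out = f / ctx.delta_f_hz
    return float(out) if np.isscalar(f_hz) else out


def hz_to_mel(f_hz):
    """Analytic mel scale: mel = 2595·log10(1 + f/700); mel(0) = 0."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    out = MEL_SCALE * np.log10(1.0 + f / MEL_BREAK_HZ)
    return float(out) if np.isscalar(f_hz) else out


def shift_magnitude_mel(
    base_f1_hz: float,
    base_f2_hz: float,
    d_f1_hz: float,
    d_f2_hz: float,
) -> float:
    """Perceptual (mel) magnitude of a formant shift.

    The mel scale is nonlinear, so the conversion is anchored at the
    operating point of the produced vowel: each component is
    mel(F + ΔF_component) − mel(F) and the magnitude is their Euclidean
    length.
    """
    for base, d in ((base_f1_hz, d_f1_hz), (base_f2_hz, d_f2_hz)):
        if base <= 0 or base + d <= 0:
            raise ValueError("baseline and shifted frequencies must be positive")
    dm1 = hz_to_mel(base_f1_hz + d_f1_hz) - hz_to_mel(base_f1_hz)
    dm2 = hz_to_mel(base_f2_hz + d_f2_hz) - hz_to_mel(base_f2_hz)
    return float(np.hypot(dm1, dm2))


def normalization_table(contexts) -> pd.DataFrame:
    """Tabulate contexts as (participant_id, delta_f_hz, vtl_cm)."""
    return pd.DataFrame(
        [
            {
                "participant_id": c.participant_id,
                "delta_f_hz": c.delta_f_hz,
                "vtl_cm": c.vtl_cm,
            }
            for c in contexts
        ]
    )
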