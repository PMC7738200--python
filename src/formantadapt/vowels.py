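"""Vowel labels and the direction covariates used to group applied shifts.

All tables use ASCII (ARPABET-like) vowel aliases to keep I/O bit-stable
across platforms; the one-to-one mapping to IPA is kept here for display.
"""

from __future__ import annotations

# ASCII alias -> IPA symbol, in the canonical order of the ten-vowel
# baseline inventory (prompt words: bet, fit, meet, late, bad, car, hope,
# bought, book, pool).
ASCII_TO_IPA: dict[str, str] = {
    "eh": "ɛ",  # ɛ
    "ih": "ɪ",  # ɪ
    "iy": "i",
    "ey": "e",
    "ae": "æ",  # æ
    "aa": "ɑ",  # ɑ
    "ow": "o",
    "ao": "ɔ",  # ɔ
    "uh": "ʊ",  # ʊ
    "uw": "u",
}

IPA_TO_ASCII: dict[str, str] = {v: k for k, v in ASCII_TO_IPA.items()}

#: The full baseline inventory.
ALL_VOWELS: tuple[str, ...] = tuple(ASCII_TO_IPA)

#: The produced vowel in every trial (the syllable /bEp/).
BASE_VOWEL: str = "eh"

#: The seven vowels entering the average-formant-spacing (deltaF) estimate.
DELTA_F_VOWELS: frozenset[str] = frozenset(
    {"eh", "ih", "iy", "ey", "ae", "aa", "uw"}
)

#: The six shift targets (cases) used in both experiments.
CASE_VOWELS: tuple[str, ...] = ("ih", "iy", "ey", "ae", "aa", "uw")

# Height/backness of each target relative to the produced vowel /eh/.
HIGHER: frozenset[str] = frozenset({"iy", "ih", "ey", "uw"})
LOWER: frozenset[str] = frozenset({"ae", "aa"})
FRONT: frozenset[str] = frozenset({"iy", "ih", "ey"})
BACK: frozenset[str] = frozenset({"ae", "uw", "aa"})


def canonical_vowel(label: str) -> str:
    """Return the ASCII alias for ``label`` (accepts ASCII or IPA).

    Raises ``ValueError`` for unknown labels.
    """
    label = str(label).strip()
    if label in ASCII_TO_IPA:
        return label
    if label in IPA_TO_ASCII:
        return IPA_TO_ASCII[label]
    raise ValueError(f"unknown vowel label: {label!r}")


def relative_height(case: str) -> str:
    """'higher' or 'lower' relative to /eh/ for a shift-target vowel."""
    case = canonical_vowel(case)
    if case in HIGHER:
        return "higher"
    if case in LOWER:
        return "lower"
    raise ValueError(f"{case!r} is not a shift-target vowel")


def relative_backness(case: str) -> str:
    """'front' or 'back' relative to /eh/ for a shift-target vowel."""
    case = canonical_vowel(case)
    if case in FRONT:
        return "front"
    if case in BACK:
        return "back"
    raise ValueError(f"{case!r} is not a shift-target vowel")


def direction_covariates(case: str) -> dict[str, str]:
    """Both grouping covariates for one shift case.

    Returns ``{"case", "relative_height", "relative_backness"}``.
    """
    case = canonical_vowel(case)
    return {
        "case": case,
        "relative_height": relative_height(case),
        "relative_backness": relative_backness(case),
    }
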