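"""Circular statistics for response-angle (ANG) analyses.

Angles are degrees in (−180, 180] at every public interface; radians are
used internally.  The module provides the circular mean, maximum-likelihood
von Mises fitting, Watson's U² goodness-of-fit test with a parametric
bootstrap p-value, the Watson-Williams one-way circular ANOVA, and the
Harrison-Kanji two-way circular ANOVA in its high-concentration χ² form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "VonMisesFit",
    "CircularTestResult",
    "circ_mean_deg",
    "fit_von_mises",
    "watson_u2_test",
    "watson_williams",
    "harrison_kanji",
]

#: Resultant lengths below this are treated as no preferred direction.
_RBAR_EPS = 1e-12


@dataclass(frozen=True)
class VonMisesFit:
    """Fitted von Mises parameters: mean direction, concentration, and the
    mean resultant length of the sample the fit came from."""

    mu_deg: float
    kappa: float
    r_bar: float
    n: int


@dataclass(frozen=True)
class CircularTestResult:
    """Outcome of one circular test (U², F, or χ² statistic)."""

    test: str
    statistic: float
    df1: float
    df2: float | None
    p_value: float
    method_note: str = ""


def _wrap_rad(theta: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    return np.pi - np.mod(np.pi - theta, 2.0 * np.pi)


def wrap_deg(angle) -> np.ndarray | float:
    """Wrap degrees to (−180, 180]."""
    out = 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)
    return float(out) if np.isscalar(angle) else out


def _resultant(theta: np.ndarray, axis=None) -> tuple[np.ndarray, np.ndarray]:
    """Mean direction and mean resultant length along ``axis``."""
    c = np.cos(theta).mean(axis=axis)
    s = np.sin(theta).mean(axis=axis)
    return np.arctan2(s, c), np.hypot(c, s)


def circ_mean_deg(angles_deg) -> tuple[float, float]:
    """Circular mean direction and mean resultant length.

    Returns ``(mean_deg, r_bar)``.  When r_bar is numerically zero the
    direction is meaningless and NaN is returned for it.
    """
    theta = np.radians(np.asarray(angles_deg, dtype=float))
    if theta.size == 0:
        raise ValueError("empty angle sample")
    if not np.all(np.isfinite(theta)):
        raise ValueError("angles must be finite")
    mu, r_bar = _resultant(theta)
    if r_bar < _RBAR_EPS:
        return float("nan"), float(r_bar)
    return float(np.degrees(mu)), float(r_bar)


def _kappa_from_rbar(r_bar) -> np.ndarray | float:
    """Invert A(κ) = I₁(κ)/I₀(κ) by the standard three-regime approximation."""
    r = np.asarray(r_bar, dtype=float)
    r = np.clip(r, 0.0, 1.0 - 1e-12)
    low = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    mid = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    high = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r + 1e-300)
    out = np.where(r < 0.53, low, np.where(r < 0.85, mid, high))
    out = np.where(r < _RBAR_EPS, 0.0, out)
    return float(out) if np.isscalar(r_bar) else out


def _kappa_bias_corrected(kappa: float, n: int) -> float:
    """Small-sample correction for the concentration estimate."""
    if n >= 16:
        return kappa
    if kappa < 2.0:
        return max(kappa - 2.0 / (n * kappa), 0.0) if kappa > 0 else 0.0
    return kappa * (n - 1) ** 3 / (n**3 + n)


def fit_von_mises(angles_deg, bias_correction: bool = False) -> VonMisesFit:
    """Maximum-likelihood von Mises fit.

    μ is the circular mean; κ inverts the mean resultant length through
    the three-regime approximation of A⁻¹.  ``bias_correction`` applies
    the standard small-sample (n < 16) adjustment to κ.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 2:
        raise ValueError("need at least two angles to fit")
    mu_deg, r_bar = circ_mean_deg(angles)
    kappa = _kappa_from_rbar(r_bar)
    if bias_correction:
        kappa = _kappa_bias_corrected(kappa, angles.size)
    return VonMisesFit(mu_deg=mu_deg, kappa=float(kappa), r_bar=r_bar,
                       n=int(angles.size))


def _u2_statistic(u_sorted: np.ndarray) -> np.ndarray:
    """Watson U² from rows of sorted probability-integral transforms."""
    n = u_sorted.shape[-1]
    k = np.arange(1, n + 1)
    expected = (2.0 * k - 1.0) / (2.0 * n)
    u_mean = u_sorted.mean(axis=-1)
    return (
        np.sum((u_sorted - expected) ** 2, axis=-1)
        - n * (u_mean - 0.5) ** 2
        + 1.0 / (12.0 * n)
    )


def _von_mises_pit(theta: np.ndarray, mu, kappa) -> np.ndarray:
    """Probability-integral transform under von Mises(μ, κ).

    ``mu``/``kappa`` may be scalars or column vectors broadcasting against
    rows of ``theta``.
    """
    kappa = np.maximum(kappa, 1e-8)
    return stats.vonmises.cdf(_wrap_rad(theta - mu), kappa)


def watson_u2_test(
    angles_deg,
    fit: VonMisesFit | None = None,
    bootstrap_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> CircularTestResult:
    """Watson's U² goodness-of-fit test against a fitted von Mises.

    Because μ and κ are estimated from the data, the null distribution of
    U² is obtained by a parametric bootstrap that refits the parameters on
    every replicate.  ``rng`` seeds the bootstrap.
    """
    angles = np.asarray(angles_deg, dtype=float)
    n = angles.size
    if n < 10:
        raise ValueError("Watson U² needs at least 10 angles")
    if fit is None:
        fit = fit_von_mises(angles)
    rng = np.random.default_rng(rng)
    theta = np.radians(angles)
    mu, kappa = np.radians(fit.mu_deg), fit.kappa
    u = np.sort(_von_mises_pit(theta, mu, kappa))
    u2_obs = float(_u2_statistic(u))

    if bootstrap_reps > 0:
        boot = rng.vonmises(mu, max(kappa, 1e-8), size=(bootstrap_reps, n))
        mu_b, rbar_b = _resultant(boot, axis=1)
        kappa_b = _kappa_from_rbar(rbar_b)
        u_b = np.sort(
            _von_mises_pit(boot, mu_b[:, None], kappa_b[:, None]), axis=1
        )
        u2_b = _u2_statistic(u_b)
        p = float((1 + np.sum(u2_b >= u2_obs)) / (bootstrap_reps + 1))
        note = f"parametric bootstrap, {bootstrap_reps} reps"
    else:
        p = float("nan")
        note = "statistic only (bootstrap_reps = 0)"
    return CircularTestResult(
        test="watson_u2", statistic=u2_obs, df1=float(n), df2=None,
        p_value=p, method_note=note,
    )


def _group_resultants(theta: np.ndarray, labels: np.ndarray):
    """Per-group resultant lengths R_g = n_g · r̄_g and counts."""
    r_len, counts = [], []
    for g in np.unique(labels):
        t = theta[labels == g]
        counts.append(t.size)
        _, rbar = _resultant(t)
        r_len.append(t.size * rbar)
    return np.asarray(r_len), np.asarray(counts)


def watson_williams(angles_deg, groups, min_per_group: int = 5) -> CircularTestResult:
    """Watson-Williams one-way ANOVA for circular data.

    Tests equality of mean directions across k groups via the
    between/within resultant decomposition with the 1 + 3/(8κ̂) correction
    (κ̂ from the pooled within-group resultant).  A method note flags the
    low-concentration regime (κ̂ < 1) where the test's assumptions fail.
    """
    theta = np.radians(np.asarray(angles_deg, dtype=float))
    labels = np.asarray(groups)
    if theta.shape != labels.shape:
        raise ValueError("angles and groups must have equal length")
    r_g, n_g = _group_resultants(theta, labels)
    k = len(n_g)
    if k < 2:
        raise ValueError("need at least two groups")
    if np.any(n_g < min_per_group):
        raise ValueError(f"every group needs at least {min_per_group} angles")
    n = int(theta.size)
    _, rbar_all = _resultant(theta)
    r_total = n * rbar_all
    sum_rg = float(np.sum(r_g))
    rbar_w = sum_rg / n
    kappa = float(_kappa_from_rbar(rbar_w))
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else np.inf
    df1, df2 = k - 1, n - k
    denom = n - sum_rg
    f_stat = correction * (df2 * (sum_rg - r_total)) / (df1 * max(denom, 1e-300))
    p = float(stats.f.sf(f_stat, df1, df2))
    note = f"kappa_hat={kappa:.3f}"
    if kappa < 1.0:
        note += "; WARNING: kappa < 1, low-concentration assumption violated"
        warnings.warn(
            "Watson-Williams: pooled concentration below 1; "
            "the F approximation is unreliable",
            stacklevel=2,
        )
    return CircularTestResult(
        test="watson_williams", statistic=float(f_stat), df1=float(df1),
        df2=float(df2), p_value=p, method_note=note,
    )


def harrison_kanji(
    angles_deg,
    factor_a,
    factor_b,
    min_per_cell: int = 5,
) -> tuple[CircularTestResult, CircularTestResult, CircularTestResult]:
    """Harrison-Kanji two-way ANOVA for circular data (χ² form).

    Decomposes resultant-based variation into factor A, factor B, and
    interaction terms.  In the high-concentration regime the statistics

        χ²_A = 2κ̂ (Σ_rows R_row − R),          df = p − 1
        χ²_B = 2κ̂ (Σ_cols R_col − R),          df = q − 1
        χ²_AB = 2κ̂ (Σ_cells R_cell − Σ_rows R_row − Σ_cols R_col + R),
                                                df = (p − 1)(q − 1)

    follow χ² distributions, with κ̂ inverted from the pooled within-cell
    resultant.  Outside the validity regime (κ̂ ≤ 2) a warning is emitted
    and recorded in the method note.

    Returns results for (factor A, factor B, interaction).
    """
    theta = np.radians(np.asarray(angles_deg, dtype=float))
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (theta.shape == fa.shape == fb.shape):
        raise ValueError("angles and both factors must have equal length")
    a_levels, b_levels = np.unique(fa), np.unique(fb)
    p_lv, q_lv = len(a_levels), len(b_levels)
    if p_lv < 2 or q_lv < 2:
        raise ValueError("each factor needs at least two levels")

    n = theta.size
    _, rbar_all = _resultant(theta)
    r_total = n * rbar_all

    sum_r_cells = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = theta[(fa == a) & (fb == b)]
            if cell.size < min_per_cell:
                raise ValueError(
                    f"cell ({a!r}, {b!r}) has {cell.size} angles "
                    f"(need {min_per_cell})"
                )
            _, rbar = _resultant(cell)
            sum_r_cells += cell.size * rbar
    r_rows, _ = _group_resultants(theta, fa)
    r_cols, _ = _group_resultants(theta, fb)
    sum_r_rows, sum_r_cols = float(np.sum(r_rows)), float(np.sum(r_cols))

    # Residual-based concentration estimate.  In the high-κ regime
    # 2κ(N − Σ R_cell) ~ χ²_{N−C} with C fitted cell means, so dividing by
    # N − C (not N) removes the upward bias that the plain resultant
    # inversion incurs from the estimated cell directions.
    n_cells = p_lv * q_lv
    kappa = float((n - n_cells) / (2.0 * max(n - sum_r_cells, 1e-300)))
    note = f"high-concentration chi-square form; kappa_hat={kappa:.3f}"
    if kappa <= 2.0:
        note += "; WARNING: kappa <= 2, outside the validity regime"
        warnings.warn(
            "Harrison-Kanji: pooled concentration at or below 2; the "
            "chi-square approximation is unreliable",
            stacklevel=2,
        )

    effects = {
        "factor_a": (sum_r_rows - r_total, p_lv - 1),
        "factor_b": (sum_r_cols - r_total, q_lv - 1),
        "interaction": (
            sum_r_cells - sum_r_rows - sum_r_cols + r_total,
            (p_lv - 1) * (q_lv - 1),
        ),
    }
    results = []
    for name, (eff, df) in effects.items():
        chi2 = max(2.0 * kappa * eff, 0.0)
        results.append(
            CircularTestResult(
                test=f"harrison_kanji_{name}",
                statistic=float(chi2),
                df1=float(df),
                df2=None,
                p_value=float(stats.chi2.sf(chi2, df)),
                method_note=note,
            )
        )
    return tuple(results)
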