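"""Mixed-model inference on response measures and multiple-testing control.

Within each experiment, trial-level TR/CR/OR from the analysis window are
modelled with linear mixed models (random intercept per subject) with the
shift angle, shift magnitude, and gender as fixed effects; reduced models
swap the angle for the height or backness grouping.  Across experiments,
per-trial normalised responses (NCR/NOR/NTR) are modelled with experiment,
angle, and their interaction, with random slopes and intercepts.  Type III
F tests use Sum-coded factors; denominator degrees of freedom follow a
between/within partition by default.  Benjamini-Hochberg step-up control
is applied across the bundle's effect p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .circular import fit_von_mises, harrison_kanji, watson_u2_test, watson_williams
from .config import RunConfig
from .pipeline import AnalysisResult

RESPONSES = ("tr", "cr", "or_")
NORMALIZED_RESPONSES = ("ncr", "nor", "ntr")
CATEGORICAL_EFFECTS = {
    "gender", "experiment", "relative_height", "relative_backness", "case",
}


class ConvergenceError(RuntimeError):
    """Mixed-model fit failed or produced a singular covariance."""


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification.

    ``effects`` are drawn from {angle_deg, magnitude, gender, experiment,
    relative_height, relative_backness, case} plus ':' interactions;
    ``random`` is 'intercept_only' or 'slopes_and_intercepts' (slope on
    ``slope_var``).
    """

    response: str
    effects: tuple[str, ...]
    random: str = "intercept_only"
    magnitude_scale: str = "normalised"
    slope_var: str = "angle_deg"
    name: str = ""

    def __post_init__(self) -> None:
        if self.response not in RESPONSES + NORMALIZED_RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.random not in ("intercept_only", "slopes_and_intercepts"):
            raise ValueError(f"unknown random structure {self.random!r}")
        for eff in self.effects:
            for part in eff.split(":"):
                if part not in CATEGORICAL_EFFECTS | {"angle_deg", "magnitude"}:
                    raise ValueError(f"unknown effect {part!r}")


@dataclass
class FixedEffectResult:
    """Type III F test for one fixed effect."""

    model: str
    effect: str
    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    bh_significant: bool | None = None


def _term_expr(effect: str, magnitude_scale: str, angle_as_category: bool) -> str:
    def atom(part: str) -> str:
        if part == "magnitude":
            return (
                "magnitude_norm" if magnitude_scale == "normalised"
                else "magnitude_mel"
            )
        if part == "angle_deg":
            return "C(case, Sum)" if angle_as_category else "angle_deg"
        if part in CATEGORICAL_EFFECTS:
            return f"C({part}, Sum)"
        return part
    return ":".join(atom(p) for p in effect.split(":"))


def _is_between_subject(col: np.ndarray, groups: np.ndarray) -> bool:
    """True when a design column is constant within every subject."""
    df = pd.DataFrame({"g": groups, "x": np.round(col, 12)})
    return bool((df.groupby("g")["x"].nunique() <= 1).all())


def _denominator_df(
    term_between: bool,
    col_between: np.ndarray,
    n_obs: int,
    n_subjects: int,
    df_method: str,
) -> float:
    p = col_between.size
    if df_method == "residual":
        return max(n_obs - p, 1)
    n_between = int(col_between.sum())  # includes the intercept column
    if term_between:
        return max(n_subjects - n_between, 1)
    return max(n_obs - n_subjects - (p - n_between), 1)


def _fit_mixed(model: sm.MixedLM, reml: bool):
    """Fit with L-BFGS and fall back to BFGS when the profiled Hessian is
    singular (an occasional optimiser artefact, not a model defect)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs"):
            try:
                return model.fit(reml=reml, method=method, maxiter=200)
            except np.linalg.LinAlgError:
                continue
            except Exception as err:
                raise ConvergenceError(f"mixed model failed: {err}") from err
    raise ConvergenceError("mixed model failed: singular optimisation")


def _cell_vc_formula(data: pd.DataFrame, config: RunConfig):
    """Variance-component formula for participant × case cells.

    Trials within one case share the case's estimated baseline (and any
    case-level fluctuation of the underlying response), so trial-level
    models need a case-within-participant variance component for
    case-level covariates to be tested at their true precision.  The
    component is dropped when it is unidentifiable (single observation per
    cell, or a single cell per participant) or disabled in config.
    """
    if not config.case_variance or "case" not in data.columns:
        return None
    cell = data["case"].astype(str)
    if "experiment" in data.columns:
        cell = cell + "_e" + data["experiment"].astype(str)
    if (
        data.groupby([data["participant_id"], cell]).size().max() < 2
        or cell.groupby(data["participant_id"]).nunique().min() < 2
    ):
        return None
    data["_cell"] = cell
    return {"cell": "0 + C(_cell)"}


def fit_lmm(table: pd.DataFrame, spec: ModelSpec, config: RunConfig | None = None):
    """REML linear mixed model with Type III F tests per fixed effect.

    Subjects enter as a random intercept (plus a random slope on
    ``spec.slope_var`` for the slopes-and-intercepts structure), with a
    participant × case variance component capturing shared baseline error
    within each case (see :func:`_cell_vc_formula`).  Returns one
    :class:`FixedEffectResult` per non-intercept term.
    """
    config = config or RunConfig()
    groups = table["participant_id"].to_numpy()
    n_subjects = len(np.unique(groups))
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    exprs = [
        _term_expr(e, spec.magnitude_scale, config.angle_as_category)
        for e in spec.effects
    ]
    formula = f"{spec.response} ~ " + " + ".join(exprs)
    y, X = patsy.dmatrices(formula, table, return_type="dataframe")
    for name in X.columns:
        if name != "Intercept" and X[name].nunique() < 2:
            raise ValueError(f"effect column {name!r} has no variation")
    # centre the response: only the (unreported) intercept changes, and
    # translation invariance of the F tests becomes exact numerically
    data = table.copy()
    data[spec.response] = data[spec.response] - data[spec.response].mean()
    re_formula = (
        f"1 + {spec.slope_var}"
        if spec.random == "slopes_and_intercepts" else "1"
    )
    vc_formula = _cell_vc_formula(data, config)
    model = sm.MixedLM.from_formula(
        formula, data=data, groups="participant_id",
        re_formula=re_formula, vc_formula=vc_formula,
    )
    fit = _fit_mixed(model, reml=True)
    k_fe = X.shape[1]
    params = np.asarray(fit.params)[:k_fe]
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    if not np.all(np.isfinite(cov)):
        raise ConvergenceError(
            "non-finite fixed-effect covariance (singular fit); "
            f"model {spec.name or formula!r}"
        )
    col_between = np.array(
        [_is_between_subject(X[c].to_numpy(), groups) for c in X.columns]
    )
    results = []
    slices = X.design_info.term_name_slices
    for raw_effect, expr in zip(spec.effects, exprs):
        sl = slices[expr]
        beta = params[sl]
        if beta.size == 0:
            raise ValueError(
                f"effect {raw_effect!r} has no variation in the table"
            )
        v = cov[sl, sl]
        q = beta.size
        try:
            f_stat = float(beta @ np.linalg.solve(v, beta) / q)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(
                f"singular covariance for term {raw_effect!r}"
            ) from err
        term_between = bool(col_between[sl].all())
        df_den = _denominator_df(
            term_between, col_between, len(table), n_subjects, config.df_method
        )
        results.append(
            FixedEffectResult(
                model=spec.name or formula,
                effect=raw_effect,
                f_stat=f_stat,
                df_num=float(q),
                df_den=float(df_den),
                p_value=float(stats.f.sf(f_stat, q, df_den)),
            )
        )
    return results


def test_slopes(
    table: pd.DataFrame,
    spec: ModelSpec,
    config: RunConfig | None = None,
) -> dict:
    """Choose between random-intercept and random-slope structures.

    Both structures are fitted by maximum likelihood and compared with a
    likelihood-ratio test (2 df: slope variance and its covariance with
    the intercept).  Returns the decision, the statistic, and its p-value.
    The decision is scale-invariant because both likelihoods shift equally
    under response rescaling.
    """
    config = config or RunConfig()
    exprs = [
        _term_expr(e, spec.magnitude_scale, config.angle_as_category)
        for e in spec.effects
    ]
    formula = f"{spec.response} ~ " + " + ".join(exprs)
    data = table.copy()
    data[spec.response] = data[spec.response] - data[spec.response].mean()
    vc_formula = _cell_vc_formula(data, config)
    fit_i = _fit_mixed(
        sm.MixedLM.from_formula(
            formula, data=data, groups="participant_id",
            re_formula="1", vc_formula=vc_formula,
        ),
        reml=False,
    )
    fit_s = _fit_mixed(
        sm.MixedLM.from_formula(
            formula, data=data, groups="participant_id",
            re_formula=f"1 + {spec.slope_var}", vc_formula=vc_formula,
        ),
        reml=False,
    )
    lrt = max(2.0 * (fit_s.llf - fit_i.llf), 0.0)
    p = float(stats.chi2.sf(lrt, 2))
    return {
        "decision": "slopes" if p < config.alpha else "intercept_only",
        "statistic": float(lrt),
        "p_value": p,
    }


def bh_fdr(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags, aligned with input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def build_analysis_table(
    result: AnalysisResult,
    participants: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Model-ready tables from the decomposition products.

    Returns ``{"within", "cross"}``: *within* holds good analysis-window
    trials with TR/CR/OR and shift covariates for each experiment; *cross*
    holds normalised responses for the subjects present in both
    experiments (per-trial by default, per-case window averages when
    ``config.cross_experiment_per_trial`` is False).
    """
    config = config or RunConfig()
    need_gender = sorted(
        set(result.responses["participant_id"])
        - set(participants.loc[participants["gender"].notna(), "participant_id"])
    )
    if need_gender:
        raise ValueError(f"missing gender for participants: {need_gender}")
    shift_cols = [
        "participant_id", "experiment", "case", "magnitude_norm",
        "magnitude_mel", "angle_deg", "relative_height", "relative_backness",
    ]
    window = result.responses[
        result.responses["trial_index"].isin(config.window_trials)
        & result.responses["good"]
    ]
    within = (
        window.merge(result.shifts[shift_cols],
                     on=["participant_id", "experiment", "case"])
        .merge(participants[["participant_id", "gender"]], on="participant_id")
    )

    by_exp = within.groupby("participant_id")["experiment"].nunique()
    dual = set(by_exp.index[by_exp == 2])
    if config.cross_experiment_per_trial:
        cross = within[within["participant_id"].isin(dual)].copy()
        for norm, raw in zip(NORMALIZED_RESPONSES, ("cr", "or_", "tr")):
            cross[norm] = cross[raw] / cross["magnitude_norm"]
    else:
        cross = result.summaries[
            result.summaries["participant_id"].isin(dual)
        ].merge(participants[["participant_id", "gender"]], on="participant_id")
    return {"within": within, "cross": cross}


@dataclass
class ResultBundle:
    """Everything run_full_analysis produces."""

    fixed_effects: pd.DataFrame
    circular_tests: pd.DataFrame
    von_mises_fits: pd.DataFrame
    slope_decisions: pd.DataFrame
    sensitivity: pd.DataFrame
    config: RunConfig = field(default_factory=RunConfig)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "fixed_effects": self.fixed_effects,
            "circular_tests": self.circular_tests,
            "von_mises_fits": self.von_mises_fits,
            "slope_decisions": self.slope_decisions,
        }
        if len(self.sensitivity):
            out["sensitivity_mel"] = self.sensitivity
        return out


def _effects_frame(results, df_method: str, scale: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.model,
                "effect": r.effect,
                "f_stat": r.f_stat,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "p_value": r.p_value,
                "bh_significant": r.bh_significant,
                "df_method": df_method,
                "magnitude_scale": scale,
            }
            for r in results
        ]
    )


def _within_specs(scale: str, reduced: bool):
    specs = []
    for exp in (1, 2):
        for resp in RESPONSES:
            specs.append(
                (exp, ModelSpec(
                    response=resp,
                    effects=("angle_deg", "magnitude", "gender"),
                    magnitude_scale=scale,
                    name=f"exp{exp}_{resp}_angle",
                ))
            )
            if reduced:
                for grouping in ("relative_height", "relative_backness"):
                    specs.append(
                        (exp, ModelSpec(
                            response=resp,
                            effects=(grouping, "magnitude", "gender"),
                            magnitude_scale=scale,
                            name=f"exp{exp}_{resp}_{grouping}",
                        ))
                    )
    return specs


def _cross_specs(scale: str, reduced: bool):
    specs = []
    for resp in NORMALIZED_RESPONSES:
        specs.append(
            ModelSpec(
                response=resp,
                effects=("experiment", "angle_deg", "experiment:angle_deg"),
                random="slopes_and_intercepts",
                magnitude_scale=scale,
                name=f"cross_{resp}_angle",
            )
        )
        if reduced:
            for grouping in ("relative_height", "relative_backness"):
                specs.append(
                    ModelSpec(
                        response=resp,
                        effects=(
                            "experiment", grouping, f"experiment:{grouping}"
                        ),
                        random="slopes_and_intercepts",
                        magnitude_scale=scale,
                        name=f"cross_{resp}_{grouping}",
                    )
                )
    return specs


def _circular_block(within: pd.DataFrame, cross: pd.DataFrame, config: RunConfig):
    """WW tests per experiment, von Mises + U² per ANG pool, HK across
    experiments."""
    circ_rows, vm_rows = [], []
    groupings = (
        ("case", "case"),
        ("relative_height", "relative_height"),
        ("relative_backness", "relative_backness"),
    )
    for exp, grp in within.groupby("experiment"):
        ang = grp["ang_deg"].dropna()
        sub = grp.loc[ang.index]
        for label, column in groupings:
            try:
                r = watson_williams(ang.to_numpy(), sub[column].to_numpy())
            except ValueError:
                continue
            circ_rows.append(
                {"test": f"ww_exp{exp}_ang_by_{label}", "statistic": r.statistic,
                 "df1": r.df1, "df2": r.df2, "p_value": r.p_value,
                 "method_note": r.method_note}
            )
    pools = {f"exp{exp}": grp["ang_deg"].dropna().to_numpy()
             for exp, grp in within.groupby("experiment")}
    if len(pools) == 2:
        pools["exp1_vs_exp2"] = np.concatenate(list(pools.values()))
    if config.include_von_mises_check:
        for pool_name, ang in pools.items():
            if ang.size < 10:
                continue
            fit = fit_von_mises(ang)
            vm_rows.append(
                {"pool": pool_name, "mu_deg": fit.mu_deg, "kappa": fit.kappa,
                 "r_bar": fit.r_bar, "n": fit.n}
            )
            r = watson_u2_test(
                ang, fit, bootstrap_reps=config.bootstrap_reps,
                rng=np.random.default_rng(
                    [config.rng_seed & 0x7FFFFFFF, 97, len(pool_name)]
                ),
            )
            circ_rows.append(
                {"test": f"watson_u2_{pool_name}", "statistic": r.statistic,
                 "df1": r.df1, "df2": np.nan, "p_value": r.p_value,
                 "method_note": r.method_note}
            )
    if len(cross) and cross["experiment"].nunique() == 2:
        ang = cross["ang_deg"].dropna() if "ang_deg" in cross else pd.Series(dtype=float)
        sub = cross.loc[ang.index] if len(ang) else cross
        for label, column in groupings:
            if not len(ang):
                break
            try:
                hk = harrison_kanji(
                    ang.to_numpy(), sub["experiment"].to_numpy(),
                    sub[column].to_numpy(),
                )
            except ValueError:
                continue
            for part, r in zip(("experiment", label, "interaction"), hk):
                circ_rows.append(
                    {"test": f"hk_ang_{label}_{part}", "statistic": r.statistic,
                     "df1": r.df1, "df2": np.nan, "p_value": r.p_value,
                     "method_note": r.method_note}
                )
    return pd.DataFrame(circ_rows), pd.DataFrame(vm_rows)


def run_full_analysis(
    result: AnalysisResult,
    participants: pd.DataFrame,
    config: RunConfig | None = None,
) -> ResultBundle:
    """Execute the full inferential bundle on decomposition products.

    Stages (switchable via config): within-experiment LMMs on TR/CR/OR,
    reduced height/backness models, cross-experiment LMMs on NCR/NOR/NTR
    with experiment × angle, WW / von Mises + U² / HK circular analyses,
    Benjamini-Hochberg control across the effect p-values, and the
    mel-scale sensitivity re-run of the magnitude covariate.
    """
    config = config or RunConfig()
    tables = build_analysis_table(result, participants, config)
    within, cross = tables["within"], tables["cross"]

    effect_rows: list[FixedEffectResult] = []
    slope_rows = []
    for exp, spec in _within_specs(config.magnitude_scale,
                                   config.include_reduced_models):
        sub = within[within["experiment"] == exp]
        effect_rows.extend(fit_lmm(sub, spec, config))
    if config.include_cross_experiment and len(cross):
        for spec in _cross_specs(config.magnitude_scale,
                                 config.include_reduced_models):
            effect_rows.extend(fit_lmm(cross, spec, config))
            try:
                dec = test_slopes(cross, spec, config)
            except Exception:
                dec = {"decision": "unavailable", "statistic": np.nan,
                       "p_value": np.nan}
            slope_rows.append({"model": spec.name, **dec})

    if config.include_circular_tests:
        circular_tests, von_mises = _circular_block(within, cross, config)
    else:
        circular_tests, von_mises = pd.DataFrame(), pd.DataFrame()

    fixed = _effects_frame(effect_rows, config.df_method, config.magnitude_scale)
    # BH ledger across effect p-values: fixed effects plus WW/HK tests whose
    # concentration-validity condition held.  U² rows are assumption checks,
    # not effects, and WW/HK results outside their validity regime are
    # reported but never treated as confirmatory findings.
    p_all = list(fixed["p_value"]) if len(fixed) else []
    circ_is_effect = (
        ~circular_tests["test"].str.startswith("watson_u2")
        & ~circular_tests["method_note"].str.contains("WARNING")
        if len(circular_tests) else pd.Series(dtype=bool)
    )
    p_all += list(circular_tests.loc[circ_is_effect, "p_value"]) if len(
        circular_tests) else []
    flags = bh_fdr(p_all, config.alpha)
    n_fixed = len(fixed)
    if n_fixed:
        fixed["bh_significant"] = flags[:n_fixed]
    if len(circular_tests):
        circular_tests["bh_significant"] = False
        circular_tests.loc[circ_is_effect, "bh_significant"] = flags[n_fixed:]

    sensitivity = pd.DataFrame()
    if config.include_mel_sensitivity and config.magnitude_scale == "normalised":
        sens_rows = []
        for exp, spec in _within_specs("mel", reduced=False):
            sub = within[within["experiment"] == exp]
            sens_rows.extend(fit_lmm(sub, spec, config))
        sensitivity = _effects_frame(sens_rows, config.df_method, "mel")

    return ResultBundle(
        fixed_effects=fixed,
        circular_tests=circular_tests,
        von_mises_fits=von_mises,
        slope_decisions=pd.DataFrame(slope_rows),
        sensitivity=sensitivity,
        config=config,
    )
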