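"""Longitudinal, lateralized-prediction and cross-sectional models.

Three model families link lesion quantification to clinical outcomes:

* **Longitudinal change** — a linear mixed-effects model of an outcome on
  months post-injury, with a random intercept per patient and age, sex and
  center as fixed covariates of no interest. Reported effects are the slope
  per month and its standardized counterpart.
* **Lateralized prediction** — a mixed model with one row per patient *side*
  (left / right): tract damage at the 1-month scan predicts the clinical
  score change from 1 to 6 months on the same side, random intercept per
  patient absorbing the within-patient correlation between sides.
* **Cross-sectional association** — an ordinary linear model at a single
  timepoint (one row per patient) with the same covariates.

Standardized coefficients z-score the predictor and outcome only (covariates
enter on their native scales); since that is an affine rescaling, they are
obtained from the raw fit without refitting. Mixed-model fit quality is
summarized by marginal and conditional R² in the Nakagawa–Schielzeth
variance-partition form:

    R2_marginal    = var(fixed) / (var(fixed) + var(random) + var(resid))
    R2_conditional = (var(fixed) + var(random)) / (same denominator)

Covariates that are constant in a given sample (e.g. a single center) are
dropped with a warning rather than producing a singular fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "ModelResult",
    "TTestResult",
    "StatsError",
    "fit_longitudinal",
    "fit_lateralized_prediction",
    "fit_cross_sectional",
    "compare_groups",
    "build_lateralized_table",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "center")


class StatsError(ValueError):
    """Invalid model input."""


@dataclass
class ModelResult:
    """One fitted predictor–outcome relationship."""

    outcome: str
    predictor: str
    coef: float  # raw (per-unit) coefficient
    coef_standardized: float
    ci95: tuple[float, float]  # standardized scale
    ci95_raw: tuple[float, float]
    p_value: float
    n_patients: int
    n_obs: int
    r2_marginal: Optional[float] = None
    r2_conditional: Optional[float] = None
    r2: Optional[float] = None
    r2_adjusted: Optional[float] = None
    dropped_covariates: tuple[str, ...] = ()
    model_kind: str = "mixed"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.coef_standardized <= hi):
            raise StatsError("standardized coefficient outside its own CI")

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "coef": self.coef,
            "coef_standardized": self.coef_standardized,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p_value": self.p_value,
            "n_patients": self.n_patients,
            "n_obs": self.n_obs,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "model_kind": self.model_kind,
            "dropped_covariates": list(self.dropped_covariates),
        }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def _usable_covariates(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[list[str], list[str]]:
    """Split covariates into (kept formula terms, dropped names)."""
    terms: list[str] = []
    dropped: list[str] = []
    for cov in covariates:
        if cov not in df.columns:
            dropped.append(cov)
            continue
        col = df[cov]
        if col.dtype.kind in "ifu":
            if float(np.nanstd(col.to_numpy(dtype=float))) <= 0:
                dropped.append(cov)
            else:
                terms.append(cov)
        else:
            if col.nunique(dropna=True) < 2:
                dropped.append(cov)
            else:
                terms.append(f"C({cov})")
    if dropped:
        logger.warning("dropping degenerate covariates: %s", ", ".join(dropped))
    return terms, dropped


def _standardize(
    coef: float, ci_raw: tuple[float, float], df: pd.DataFrame, predictor: str, outcome: str
) -> tuple[float, tuple[float, float]]:
    """Rescale a raw coefficient and CI to the z-scored predictor/outcome scale."""
    sx = float(df[predictor].std(ddof=1))
    sy = float(df[outcome].std(ddof=1))
    if sy <= 0 or sx <= 0:
        raise StatsError(f"cannot standardize: sd({predictor})={sx}, sd({outcome})={sy}")
    scale = sx / sy
    return coef * scale, (ci_raw[0] * scale, ci_raw[1] * scale)


def _nakagawa_r2(res) -> tuple[float, float]:
    """Marginal / conditional R2 from a fitted MixedLM result."""
    fixed_pred = np.asarray(res.model.exog, dtype=float) @ np.asarray(res.fe_params, dtype=float)
    var_f = float(np.var(fixed_pred))
    var_u = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    var_e = float(res.scale)
    denom = var_f + var_u + var_e
    if denom <= 0:
        return 0.0, 0.0
    r2m = var_f / denom
    r2c = (var_f + var_u) / denom
    return float(np.clip(r2m, 0.0, 1.0)), float(np.clip(r2c, 0.0, 1.0))


def _fit_mixedlm(formula: str, df: pd.DataFrame, groups: pd.Series):
    """Fit a random-intercept model, tolerating near-degenerate data."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=groups)
        try:
            return model.fit(reml=True)
        except Exception:
            return model.fit(reml=True, method="powell")


def _mixed_inference(formula: str, df: pd.DataFrame, groups: pd.Series, term: str):
    """Mixed fit plus fixed-effect inference for one term.

    When the random-intercept variance collapses to the boundary the mixed
    fit's Hessian is singular and the fixed-effect standard errors come out
    NaN; inference then falls back to the OLS fit of the same mean model
    (equivalent at zero random-effect variance). The variance partition for
    R2 always comes from the mixed fit.
    """
    res = _fit_mixedlm(formula, df, groups)
    r2m, r2c = _nakagawa_r2(res)
    coef = float(res.params[term])
    se = float(res.bse[term])
    ci = res.conf_int().loc[term]
    p = float(res.pvalues[term])
    if not np.isfinite(se) or not np.isfinite(float(ci[0])):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, df).fit()
        coef = float(ols.params[term])
        ci = ols.conf_int().loc[term]
        p = float(ols.pvalues[term])
        logger.warning("random-intercept variance at boundary; fixed-effect inference from OLS")
    return coef, (float(ci[0]), float(ci[1])), p, r2m, r2c


def fit_longitudinal(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    time_col: str = "months_post_injury",
) -> ModelResult:
    """Mixed-effects model of an outcome over months post-injury.

    ``table`` is a long-format cohort: one row per patient x timepoint with
    columns ``patient_id``, ``months_post_injury``, the outcome, and the
    covariates. Needs at least 3 patients with at least 2 timepoints each.
    """
    df = table.dropna(subset=[outcome, time_col]).copy()
    if "timepoint" in df.columns and df.duplicated(subset=["patient_id", "timepoint"]).any():
        raise StatsError("duplicate (patient, timepoint) rows in cohort table")
    counts = df.groupby("patient_id")[time_col].nunique()
    if (counts >= 2).sum() < 3:
        raise StatsError("need >= 2 timepoints for >= 3 patients")
    if (df[time_col] <= 0).any():
        raise StatsError("months_post_injury must be > 0")

    cov_terms, dropped = _usable_covariates(df, covariates)
    formula = f"Q('{outcome}') ~ Q('{time_col}')" + "".join(f" + {t}" for t in cov_terms)
    term = f"Q('{time_col}')"
    coef, ci_raw, p, r2m, r2c = _mixed_inference(formula, df, df["patient_id"], term)
    coef_std, ci_std = _standardize(coef, ci_raw, df, time_col, outcome)
    return ModelResult(
        outcome=outcome,
        predictor=time_col,
        coef=coef,
        coef_standardized=coef_std,
        ci95=ci_std,
        ci95_raw=ci_raw,
        p_value=p,
        n_patients=int(df["patient_id"].nunique()),
        n_obs=len(df),
        r2_marginal=r2m,
        r2_conditional=r2c,
        dropped_covariates=tuple(dropped),
        model_kind="mixed",
    )


def build_lateralized_table(
    cohort: pd.DataFrame,
    predictor: str,
    outcome: str,
    predictor_timepoint: str = "month1",
) -> pd.DataFrame:
    """Reshape a cohort into one row per patient x side for prediction fits.

    ``predictor`` and ``outcome`` name column *stems*: the cohort must carry
    ``{predictor}_left`` / ``{predictor}_right`` at the predictor timepoint
    and ``{outcome}_left`` / ``{outcome}_right`` score columns at month1 and
    month6 (the outcome delta is month6 - month1 per side).
    """
    rows = []
    for pid, g in cohort.groupby("patient_id"):
        by_tp = {tp: sub.iloc[0] for tp, sub in g.groupby("timepoint")}
        if predictor_timepoint not in by_tp or "month1" not in by_tp or "month6" not in by_tp:
            continue
        pred_row = by_tp[predictor_timepoint]
        for side in ("left", "right"):
            pcol = f"{predictor}_{side}"
            ocol = f"{outcome}_{side}"
            if pcol not in cohort.columns or ocol not in cohort.columns:
                raise StatsError(f"cohort lacks column {pcol!r} or {ocol!r}")
            rows.append(
                {
                    "patient_id": pid,
                    "side": side,
                    "damage": float(pred_row[pcol]),
                    "delta": float(by_tp["month6"][ocol]) - float(by_tp["month1"][ocol]),
                    "age": pred_row.get("age", np.nan),
                    "sex": pred_row.get("sex", None),
                    "center": pred_row.get("center", None),
                }
            )
    return pd.DataFrame(rows)


def fit_lateralized_prediction(
    table: pd.DataFrame,
    predictor: str = "damage",
    outcome: str = "delta",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> ModelResult:
    """Predict per-side score changes from per-side tract damage.

    ``table`` has one row per patient x side (see
    :func:`build_lateralized_table`): damage at the early timepoint and the
    later score delta on the same side, plus covariates. A random intercept
    per patient links the two sides. The expected sign is negative — more
    damage, less recovery.
    """
    df = table.dropna(subset=[predictor, outcome]).copy()
    both_sides = df.groupby("patient_id")["side"].nunique() if "side" in df.columns else None
    n_complete = int((both_sides == 2).sum()) if both_sides is not None else 0
    if n_complete < 3:
        raise StatsError("need >= 3 patients with both sides observed")

    cov_terms, dropped = _usable_covariates(df, covariates)
    formula = f"Q('{outcome}') ~ Q('{predictor}')" + "".join(f" + {t}" for t in cov_terms)
    term = f"Q('{predictor}')"
    coef, ci_raw, p, r2m, r2c = _mixed_inference(formula, df, df["patient_id"], term)
    coef_std, ci_std = _standardize(coef, ci_raw, df, predictor, outcome)
    return ModelResult(
        outcome=outcome,
        predictor=predictor,
        coef=coef,
        coef_standardized=coef_std,
        ci95=ci_std,
        ci95_raw=ci_raw,
        p_value=p,
        n_patients=int(df["patient_id"].nunique()),
        n_obs=len(df),
        r2_marginal=r2m,
        r2_conditional=r2c,
        dropped_covariates=tuple(dropped),
        model_kind="mixed",
    )


def fit_cross_sectional(
    table: pd.DataFrame,
    predictor: str,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> ModelResult:
    """Ordinary linear model at one timepoint (one row per patient)."""
    df = table.dropna(subset=[predictor, outcome]).copy()
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise StatsError(f"duplicate row for patient {dup!r}; cross-sectional fits need one row per patient")
    if len(df) < 4:
        raise StatsError("too few patients for a cross-sectional fit")

    cov_terms, dropped = _usable_covariates(df, covariates)
    formula = f"Q('{outcome}') ~ Q('{predictor}')" + "".join(f" + {t}" for t in cov_terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.ols(formula, df).fit()
    term = f"Q('{predictor}')"
    coef = float(res.params[term])
    ci = res.conf_int().loc[term]
    ci_raw = (float(ci[0]), float(ci[1]))
    p = float(res.pvalues[term])
    coef_std, ci_std = _standardize(coef, ci_raw, df, predictor, outcome)
    return ModelResult(
        outcome=outcome,
        predictor=predictor,
        coef=coef,
        coef_standardized=coef_std,
        ci95=ci_std,
        ci95_raw=ci_raw,
        p_value=p,
        n_patients=len(df),
        n_obs=len(df),
        r2=float(res.rsquared),
        r2_adjusted=float(res.rsquared_adj),
        dropped_covariates=tuple(dropped),
        model_kind="ols",
    )


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> TTestResult:
    """Independent-samples two-tailed Welch t-test between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs >= 2 observations")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb > 0:
        dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        dof = float(a.size + b.size - 2)
    return TTestResult(
        t=float(t), df=float(dof), p_value=float(p),
        mean_a=float(a.mean()), mean_b=float(b.mean()), n_a=int(a.size), n_b=int(b.size),
    )
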