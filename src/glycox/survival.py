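"""Cox proportional-hazards analyses of stroke risk.

Fits the three nested adjustment models over glucose categories or
within-person-SD quartiles, linear trend tests, and restricted natural
cubic-spline log-hazard curves, for total, nonfatal and fatal stroke and
for cohort strata (all, by diabetes status, by sex, by hypertension).
Outcome-specific analyses are cause-specific: the complementary stroke type
is censored at its event time.  Ties are handled with the Efron
approximation (annual visit schedules produce many tied event times).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from patsy import build_design_matrices, dmatrix

from .errors import DataError, FitError
from .prep import (GLUCOSE_CATEGORIES, REFERENCE_CATEGORY, assign_sd_quartiles)

log = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for Wald confidence intervals.
Z_95 = 1.959964

OUTCOMES = ("total", "nonfatal", "fatal")

#: Nested adjustment sets (design-column names, see :func:`covariate_design`).
ADJUSTMENTS = {
    "model1": [],
    "model2": ["age", "male"],
    "model3": ["age", "male", "no_education", "smoke_current", "smoke_former",
               "alcohol", "regular_exercise", "bmi", "sbp",
               "total_cholesterol"],
}

SPLINE_KNOT_PERCENTILES = (5.0, 35.0, 65.0, 95.0)


@dataclass
class CoxModelSpec:
    outcome: str = "total"          # total | nonfatal | fatal
    exposure: str = "glucose_category"  # glucose_category | sd_quartile | spline
    adjustment: str = "model3"      # model1 | model2 | model3
    stratum: str = "all"            # all | nondiabetic | diabetic | male |
    #                                 female | hypertensive | non-hypertensive

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise DataError(f"unknown outcome {self.outcome!r}")
        if self.adjustment not in ADJUSTMENTS:
            raise DataError(f"unknown adjustment {self.adjustment!r}")
        if self.exposure not in ("glucose_category", "sd_quartile", "spline"):
            raise DataError(f"unknown exposure {self.exposure!r}")


@dataclass
class CoxFitResult:
    """Per-level hazard ratios plus the linear trend test for one model.

    ``levels`` has one row per exposure level: level, n, events, pct, coef,
    se, hr, ci_lower, ci_upper, p.  The reference level has hr exactly 1 and
    no CI; levels with zero events carry absent (NaN) estimates.
    """

    spec: CoxModelSpec
    levels: pd.DataFrame
    trend_p: float
    n_used: int
    n_events: int
    converged: bool
    log_likelihood: float = float("nan")


@dataclass
class SplineCurve:
    """Centered natural-cubic-spline log-hazard-ratio curve in glucose."""

    knots: np.ndarray
    grid: np.ndarray
    log_hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    reference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(glucose=self.grid, log_hr=self.log_hr,
                 ci_lower=self.ci_lower, ci_upper=self.ci_upper)
        )


def covariate_design(rows: pd.DataFrame) -> pd.DataFrame:
    """Numeric adjustment-covariate design (treatment coding, never/none
    and female as reference levels)."""
    return pd.DataFrame(
        {
            "age": rows["age"].astype(float),
            "male": (rows["sex"] == "male").astype(float),
            "no_education": (rows["education"] == "none").astype(float),
            "smoke_current": (rows["smoking"] == "current").astype(float),
            "smoke_former": (rows["smoking"] == "former").astype(float),
            "alcohol": (rows["alcohol"] == "yes").astype(float),
            "regular_exercise": (rows["regular_exercise"] == "yes").astype(float),
            "bmi": rows["bmi"].astype(float),
            "sbp": rows["sbp"].astype(float),
            "total_cholesterol": rows["total_cholesterol"].astype(float),
        },
        index=rows.index,
    )


def _drop_constant(covs: pd.DataFrame) -> pd.DataFrame:
    """Drop adjustment columns that are constant (e.g. sex within a sex
    stratum); a constant column carries no information and breaks the fit."""
    constant = [c for c in covs.columns if covs[c].nunique(dropna=True) <= 1]
    if constant:
        log.info("dropping constant adjustment columns %s", constant)
        covs = covs.drop(columns=constant)
    return covs


def select_stratum(rows: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return rows
    masks = {
        "nondiabetic": rows["diabetes"] == "none",
        "diabetic": rows["diabetes"] == "diagnosed",
        "male": rows["sex"] == "male",
        "female": rows["sex"] == "female",
        "hypertensive": rows["hypertension"].astype(bool),
        "non-hypertensive": ~rows["hypertension"].astype(bool),
    }
    if stratum not in masks:
        raise DataError(f"unknown stratum {stratum!r}")
    return rows[masks[stratum]]


def event_indicator(rows: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "total":
        return (rows["event"] != "none").astype(int)
    return (rows["event"] == outcome).astype(int)


def _exposure_levels(exposure: str):
    if exposure == "glucose_category":
        return list(GLUCOSE_CATEGORIES), REFERENCE_CATEGORY, "glucose_category", "category_ordinal"
    if exposure == "sd_quartile":
        return [1, 2, 3, 4], 1, "sd_quartile", "sd_quartile"
    raise DataError(f"exposure {exposure!r} has no levels")


def _fit_lifelines(design: pd.DataFrame, time, events) -> CoxPHFitter:
    df = design.copy()
    df["__time"] = np.asarray(time, dtype=float)
    df["__event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    try:
        # strict Newton-Raphson tolerance: the default stops one small step
        # short of the partial-likelihood maximizer
        cph.fit(df, duration_col="__time", event_col="__event",
                fit_options={"precision": 1e-14})
    except ConvergenceError as exc:
        raise FitError(f"Cox model failed to converge: {exc}") from exc
    return cph


def fit_cox(rows: pd.DataFrame, spec: CoxModelSpec,
            trend_scores: str = "ordinal") -> CoxFitResult:
    """Fit one categorized Cox model and its trend test.

    ``trend_scores``: "ordinal" enters the 1-based level index as a single
    linear term; "median" uses the per-level median of the underlying
    continuous exposure instead.
    """
    spec.validate()
    data = select_stratum(rows, spec.stratum)
    levels, reference, level_col, ordinal_col = _exposure_levels(spec.exposure)

    data = data[data[level_col].notna()]
    covs = _drop_constant(covariate_design(data)[ADJUSTMENTS[spec.adjustment]])
    keep = covs.notna().all(axis=1) & data["time_years"].notna()
    if (~keep).any():
        log.info("fit_cox: dropped %d rows with missing covariates",
                 int((~keep).sum()))
    data, covs = data[keep], covs[keep]

    events = event_indicator(data, spec.outcome)
    if int(events.sum()) < 2:
        raise DataError(
            f"fewer than 2 {spec.outcome} events in stratum {spec.stratum!r}"
        )

    per_level = []
    for lev in levels:
        mask = data[level_col] == lev
        n_lev = int(mask.sum())
        ev_lev = int(events[mask].sum())
        per_level.append(dict(level=lev, n=n_lev, events=ev_lev,
                              pct=round(100.0 * ev_lev / n_lev, 2) if n_lev else np.nan))
    level_tab = pd.DataFrame(per_level)

    # Levels with zero events cannot support a finite hazard ratio: their
    # rows are left out of the categorical fit and reported with absent HR.
    dead_levels = [r["level"] for r in per_level
                   if r["events"] == 0 and r["level"] != reference]
    fit_data = data[~data[level_col].isin(dead_levels)]
    fit_covs = covs.loc[fit_data.index]
    fit_events = events.loc[fit_data.index]

    dummy_cols = {}
    for lev in levels:
        if lev == reference or lev in dead_levels:
            continue
        dummy_cols[f"level::{lev}"] = (fit_data[level_col] == lev).astype(float)
    design = pd.concat([pd.DataFrame(dummy_cols, index=fit_data.index),
                        fit_covs], axis=1)

    cph = _fit_lifelines(design, fit_data["time_years"], fit_events)

    coefs = cph.params_
    ses = cph.standard_errors_
    pvals = cph.summary["p"]
    out_cols = {c: [] for c in ("coef", "se", "hr", "ci_lower", "ci_upper", "p")}
    for lev in levels:
        key = f"level::{lev}"
        if lev == reference:
            vals = (0.0, np.nan, 1.0, np.nan, np.nan, np.nan)
        elif key in coefs.index:
            b, s = float(coefs[key]), float(ses[key])
            if abs(b) > 15:
                raise FitError(
                    f"apparent complete separation at level {lev!r} (coef={b:.1f})"
                )
            vals = (b, s, float(np.exp(b)), float(np.exp(b - Z_95 * s)),
                    float(np.exp(b + Z_95 * s)), float(pvals[key]))
        else:
            vals = (np.nan,) * 6
        for c, v in zip(out_cols, vals):
            out_cols[c].append(v)
    for c, v in out_cols.items():
        level_tab[c] = v

    trend_p = _trend_test(data, covs, events, level_col, trend_scores,
                          spec.exposure)

    return CoxFitResult(
        spec=spec, levels=level_tab, trend_p=trend_p,
        n_used=int(len(fit_data)), n_events=int(events.sum()),
        converged=True, log_likelihood=float(cph.log_likelihood_),
    )


def _trend_test(data, covs, events, level_col, trend_scores, exposure) -> float:
    """P-for-trend: ordinal (or level-median) score entered as one term."""
    if trend_scores == "ordinal":
        if exposure == "glucose_category":
            score = data[level_col].map(
                {lab: i + 1 for i, lab in enumerate(GLUCOSE_CATEGORIES)}
            ).astype(float)
        else:
            score = data[level_col].astype(float)
    elif trend_scores == "median":
        value_col = "mu_hat" if exposure == "glucose_category" else "within_sd"
        medians = data.groupby(level_col)[value_col].median()
        score = data[level_col].map(medians).astype(float)
    else:
        raise DataError(f"unknown trend_scores {trend_scores!r}")
    design = covs.copy()
    design.insert(0, "trend", score)
    cph = _fit_lifelines(design, data["time_years"], events)
    return float(cph.summary.loc["trend", "p"])


def natural_spline_basis(x: np.ndarray, knots: np.ndarray):
    """Natural cubic-spline design in x with the given knots.

    Returns (basis DataFrame without the redundant leading column,
    design_info) — the dropped column removes the constant direction that a
    partial likelihood cannot identify; the spanned log-hazard space modulo
    constants is unchanged.
    """
    knots = np.asarray(knots, dtype=float)
    if len(np.unique(knots)) != len(knots):
        raise DataError(f"degenerate (tied) spline knots: {knots.tolist()}")
    # patsy's cr() takes interior knots plus explicit boundary knots, so the
    # requested percentile positions form the complete knot set.
    env = {"x": np.asarray(x, float), "inner": knots[1:-1],
           "lb": knots[0], "ub": knots[-1]}
    dm = dmatrix("cr(x, knots=inner, lower_bound=lb, upper_bound=ub) - 1",
                 env, return_type="dataframe")
    basis = dm.iloc[:, 1:].copy()
    basis.columns = [f"spline_{i}" for i in range(1, basis.shape[1] + 1)]
    return basis, dm.design_info


def _spline_basis_at(design_info, x, knots) -> np.ndarray:
    (dm,) = build_design_matrices(
        [design_info],
        {"x": np.asarray(x, float), "inner": knots[1:-1],
         "lb": knots[0], "ub": knots[-1]},
    )
    return np.asarray(dm)[:, 1:]


def fit_spline_curve(rows: pd.DataFrame, spec: CoxModelSpec,
                     reference_glucose: float = 95.0,
                     n_grid: int = 100) -> SplineCurve:
    """Centered log-HR curve in average glucose from a natural-spline Cox fit.

    Knots sit at the 5th/35th/65th/95th percentiles of mu_hat in the analysis
    sample; the curve is the fitted log hazard minus its value at
    ``reference_glucose`` with delta-method 95% bands.
    """
    spec.validate()
    data = select_stratum(rows, spec.stratum)
    covs = _drop_constant(covariate_design(data)[ADJUSTMENTS[spec.adjustment]])
    keep = covs.notna().all(axis=1)
    data, covs = data[keep], covs[keep]
    if len(data) < 50:
        raise DataError(f"need >=50 rows for a spline fit, got {len(data)}")
    x = data["mu_hat"].to_numpy(dtype=float)
    if not (x.min() <= reference_glucose <= x.max()):
        raise DataError(
            f"reference glucose {reference_glucose} outside observed range "
            f"[{x.min():.1f}, {x.max():.1f}]"
        )
    knots = np.percentile(x, SPLINE_KNOT_PERCENTILES)
    basis, dinfo = natural_spline_basis(x, knots)
    basis.index = data.index
    design = pd.concat([basis, covs], axis=1)
    events = event_indicator(data, spec.outcome)
    cph = _fit_lifelines(design, data["time_years"], events)

    spline_cols = list(basis.columns)
    beta = cph.params_[spline_cols].to_numpy()
    V = cph.variance_matrix_.loc[spline_cols, spline_cols].to_numpy()

    grid = np.union1d(np.linspace(x.min(), x.max(), n_grid),
                      [reference_glucose])
    B = _spline_basis_at(dinfo, grid, knots)
    B0 = _spline_basis_at(dinfo, [reference_glucose], knots)
    D = B - B0
    log_hr = D @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", D, V, D))
    return SplineCurve(
        knots=knots, grid=grid, log_hr=log_hr,
        ci_lower=log_hr - Z_95 * se, ci_upper=log_hr + Z_95 * se,
        reference=float(reference_glucose),
    )


def incidence_summary(rows: pd.DataFrame, group_by: str | None = None,
                      ) -> pd.DataFrame:
    """Event bookkeeping per group: n, events by type, percent (2 decimals),
    median follow-up in years."""
    if rows.empty:
        raise DataError("no rows")
    groups = rows.groupby(group_by) if group_by else [("all", rows)]
    out = []
    for name, g in groups:
        n = len(g)
        ev = int((g["event"] != "none").sum())
        out.append(
            dict(group=name, n=n,
                 events=ev,
                 nonfatal=int((g["event"] == "nonfatal").sum()),
                 fatal=int((g["event"] == "fatal").sum()),
                 pct=round(100.0 * ev / n, 2),
                 median_followup_years=float(g["time_years"].median()))
        )
    return pd.DataFrame(out)


def run_all_models(rows: pd.DataFrame, reference_glucose: float = 95.0,
                   ) -> dict:
    """Execute the full analysis grid.

    Returns a dict with:
      table2: {(outcome, model): CoxFitResult} on all participants
      table3: same grid on the nondiabetic stratum
      table4: {(outcome, stratum): CoxFitResult} SD-quartile model-3 fits
              (quartiles recomputed within the nondiabetic stratum)
      splines: {stratum: SplineCurve} total-stroke model-3 curves
      subgroups: {(outcome, stratum): CoxFitResult} model-3 category fits
                 for sex and hypertension strata
      failures: {key: message} for grid cells that could not be fit
    """
    results = {"table2": {}, "table3": {}, "table4": {}, "splines": {},
               "subgroups": {}, "failures": {}}

    def attempt(bucket, key, fn):
        try:
            results[bucket][key] = fn()
        except (DataError, FitError) as exc:
            log.warning("model %s/%s skipped: %s", bucket, key, exc)
            results["failures"][f"{bucket}:{key}"] = str(exc)

    for table, stratum in (("table2", "all"), ("table3", "nondiabetic")):
        for outcome in OUTCOMES:
            for model in ADJUSTMENTS:
                spec = CoxModelSpec(outcome=outcome,
                                    exposure="glucose_category",
                                    adjustment=model, stratum=stratum)
                attempt(table, (outcome, model), lambda s=spec: fit_cox(rows, s))

    # SD-quartile fits; the nondiabetic stratum gets its own quartile cuts.
    nondiab = select_stratum(rows, "nondiabetic")
    requartiled = (assign_sd_quartiles(nondiab)
                   if nondiab["within_sd"].notna().sum() >= 4 else nondiab)
    for stratum, data in (("all", rows), ("nondiabetic", requartiled)):
        for outcome in OUTCOMES:
            spec = CoxModelSpec(outcome=outcome, exposure="sd_quartile",
                                adjustment="model3", stratum="all")
            attempt("table4", (outcome, stratum),
                    lambda d=data, s=spec: fit_cox(d, s))

    for stratum in ("all", "nondiabetic"):
        spec = CoxModelSpec(outcome="total", exposure="spline",
                            adjustment="model3", stratum=stratum)
        attempt("splines", stratum,
                lambda s=spec: fit_spline_curve(rows, s, reference_glucose))

    for stratum in ("male", "female", "hypertensive", "non-hypertensive"):
        for outcome in OUTCOMES:
            spec = CoxModelSpec(outcome=outcome, exposure="glucose_category",
                                adjustment="model3", stratum=stratum)
            attempt("subgroups", (outcome, stratum),
                    lambda s=spec: fit_cox(rows, s))

    return results


def result_table(fits: dict, outcomes=OUTCOMES,
                 models=tuple(ADJUSTMENTS)) -> pd.DataFrame:
    """Flatten {(outcome, model): CoxFitResult} into a long result table."""
    rows = []
    for (outcome, model), fit in fits.items():
        for _, r in fit.levels.iterrows():
            rows.append(
                dict(outcome=outcome, model=model, level=r["level"],
                     n=r["n"], events=r["events"], pct=r["pct"],
                     hr=r["hr"], ci_lower=r["ci_lower"],
                     ci_upper=r["ci_upper"], p=r["p"],
                     trend_p=fit.trend_p)
            )
    return pd.DataFrame(rows)
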