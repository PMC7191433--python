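"""Hierarchical empirical-Bayes estimation of long-term average glucose.

Repeated clinical glucose measurements X_ij and HbA1c-derived glucose
equivalents Y_ij are modelled as noisy observations of a latent per-person
average mu_i:

    X_ij ~ N(mu_i, sigma_x^2),   Y_ij ~ N(mu_i, sigma_y^2),
    mu_i ~ N(theta, tau^2).

The population parameters (theta, tau^2, sigma_x^2, sigma_y^2) are estimated
by maximizing the marginal likelihood obtained by integrating mu_i out, so
each participant contributes a multivariate normal with mean theta*1 and
covariance tau^2*J + diag of channel variances.  Each participant's exposure
is then the plug-in posterior (precision-weighted) mean

    mu_hat_i = (n_x xbar / sx2 + n_y ybar / sy2 + theta / tau2)
               / (n_x / sx2 + n_y / sy2 + 1 / tau2),

which shrinks sparse participants toward the population mean.  The
within-person SD — the glycemic-variability exposure — is the sample SD of
the participant's pooled glucose-equivalent values when at least two exist.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DataError, FitError, IdentifiabilityError

log = logging.getLogger(__name__)

#: Linear map from HbA1c (%) to estimated daily average glucose (mg/dL):
#: glucose = 28.7 * HbA1c - 46.7.
HBA1C_SLOPE = 28.7
HBA1C_INTERCEPT = 46.7

DAYS_PER_YEAR = 365.25

_LOG2PI = np.log(2.0 * np.pi)


def hba1c_to_glucose(hba1c):
    """Convert HbA1c (%) to estimated daily average glucose (mg/dL)."""
    arr = np.asarray(hba1c, dtype=float)
    if np.any(arr <= 0):
        raise DataError("HbA1c must be > 0 %")
    out = HBA1C_SLOPE * arr - HBA1C_INTERCEPT
    return float(out) if np.isscalar(hba1c) else out


@dataclass
class VarianceComponents:
    """Population-level parameters of the hierarchical model (mg/dL scale)."""

    theta: float
    tau2: float
    sigma_x2: float
    sigma_y2: float
    log_marginal_likelihood: float = float("nan")
    sigma_y2_fixed: bool = False  # True when sigma_y2 was pinned to a
    #                               multiple of sigma_x2 for lack of replication

    def validate(self) -> None:
        if not np.isfinite(self.theta):
            raise DataError("theta must be finite")
        for name in ("tau2", "sigma_x2", "sigma_y2"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def to_glucose_equivalents(measurements: pd.DataFrame) -> pd.DataFrame:
    """Convert a long measurement table to glucose-equivalent records.

    Input columns: participant_id, day, kind in {glucose, hba1c}
    (case-insensitive), value.  Output columns: participant_id, day,
    channel in {X, Y}, value (mg/dL); channel Y values are the converted
    HbA1c records.
    """
    kind = measurements["kind"].str.lower()
    bad = ~kind.isin(["glucose", "hba1c"])
    if bad.any():
        raise DataError(
            f"unknown measurement kinds: {sorted(measurements.loc[bad, 'kind'].unique())}"
        )
    value = measurements["value"].to_numpy(dtype=float)
    if np.any(value <= 0):
        raise DataError("measurement values must be > 0")
    is_y = (kind == "hba1c").to_numpy()
    out_val = value.copy()
    out_val[is_y] = HBA1C_SLOPE * value[is_y] - HBA1C_INTERCEPT
    return pd.DataFrame(
        {
            "participant_id": measurements["participant_id"].to_numpy(),
            "day": measurements["day"].to_numpy(),
            "channel": np.where(is_y, "Y", "X"),
            "value": out_val,
        }
    )


def _sufficient_stats(equivalents: pd.DataFrame) -> pd.DataFrame:
    """Per-participant counts, sums and sums of squares for both channels."""
    df = pd.DataFrame(
        {
            "participant_id": equivalents["participant_id"].to_numpy(),
            "channel": equivalents["channel"].to_numpy(),
            "v": equivalents["value"].to_numpy(dtype=float),
        }
    )
    df["v2"] = df["v"] ** 2
    agg = (
        df.groupby(["participant_id", "channel"], sort=True)
        .agg(n=("v", "count"), s=("v", "sum"), ss=("v2", "sum"))
        .unstack("channel", fill_value=0.0)
    )
    stats = pd.DataFrame(index=agg.index)
    for suffix, channel in (("x", "X"), ("y", "Y")):
        for out_col, in_col in ((f"n_{suffix}", "n"), (f"sum_{suffix}", "s"),
                                (f"ss_{suffix}", "ss")):
            key = (in_col, channel)
            stats[out_col] = agg[key] if key in agg.columns else 0.0
    stats["n_x"] = stats["n_x"].astype(int)
    stats["n_y"] = stats["n_y"].astype(int)
    return stats.reset_index()


def _marginal_loglik(stats, theta, tau2, sigma_x2, sigma_y2) -> float:
    """Log marginal likelihood of all participants, mu_i integrated out.

    Uses the rank-one structure: for one participant the covariance is
    tau2*J + D with D diagonal per channel, so
      logdet = sum(log d_k) + log(1 + tau2 * w),  w = n_x/sx2 + n_y/sy2
      quad   = sum(r_k^2 / d_k) - tau2 * s^2 / (1 + tau2 * w),
               s = sum(r_k / d_k),  r = values - theta.
    """
    n_x = stats["n_x"].to_numpy()
    n_y = stats["n_y"].to_numpy()
    sum_x = stats["sum_x"].to_numpy()
    ss_x = stats["ss_x"].to_numpy()
    sum_y = stats["sum_y"].to_numpy()
    ss_y = stats["ss_y"].to_numpy()

    w = n_x / sigma_x2 + n_y / sigma_y2
    sq_x = ss_x - 2.0 * theta * sum_x + n_x * theta**2
    sq_y = ss_y - 2.0 * theta * sum_y + n_y * theta**2
    s = (sum_x - n_x * theta) / sigma_x2 + (sum_y - n_y * theta) / sigma_y2

    logdet = (
        n_x * np.log(sigma_x2) + n_y * np.log(sigma_y2) + np.log1p(tau2 * w)
    )
    quad = sq_x / sigma_x2 + sq_y / sigma_y2 - tau2 * s**2 / (1.0 + tau2 * w)
    ll = -0.5 * np.sum((n_x + n_y) * _LOG2PI + logdet + quad)
    return float(ll)


def _moment_start(stats) -> tuple[float, float, float, float]:
    """Method-of-moments starting values for the optimizer."""
    tot = stats["sum_x"] + stats["sum_y"]
    n_tot = stats["n_x"] + stats["n_y"]
    theta0 = float(tot.sum() / n_tot.sum())

    def within_var(prefix):
        n = stats[f"n_{prefix}"]
        rep = n >= 2
        if not rep.any():
            return None
        ss = stats.loc[rep, f"ss_{prefix}"]
        sm = stats.loc[rep, f"sum_{prefix}"]
        nn = stats.loc[rep, f"n_{prefix}"]
        num = (ss - sm**2 / nn).sum()
        den = (nn - 1).sum()
        return max(float(num / den), 1e-6)

    sx0 = within_var("x") or 25.0
    sy0 = within_var("y") or 1.5 * sx0
    with_x = stats["n_x"] >= 1
    means = stats.loc[with_x, "sum_x"] / stats.loc[with_x, "n_x"]
    inv_n = (1.0 / stats.loc[with_x, "n_x"]).mean() if with_x.any() else 1.0
    tau0 = max(float(means.var(ddof=1) - sx0 * inv_n) if with_x.sum() > 1 else 25.0,
               1.0)
    return theta0, tau0, sx0, sy0


def fit_variance_components(
    equivalents: pd.DataFrame,
    sigma_y_ratio: float = 1.5,
    min_y_informative: int = 3,
    fatol: float = 1e-8,
    maxiter: int = 500,
) -> VarianceComponents:
    """Maximum marginal-likelihood estimates of (theta, tau2, sigma_x2, sigma_y2).

    Positivity is enforced by optimizing on the log-variance scale with a
    derivative-free simplex started from method-of-moments values.  When too
    few participants carry information about sigma_y2 (fewer than
    ``min_y_informative`` participants with an HbA1c-derived value alongside
    another measurement), sigma_y2 is fixed at ``sigma_y_ratio * sigma_x2``
    and flagged on the result.
    """
    if equivalents.empty:
        raise DataError("no measurements")
    stats = _sufficient_stats(equivalents)
    if len(stats) < 2:
        raise DataError("need >= 2 participants to fit variance components")
    replicated = ((stats["n_x"] >= 2) | (stats["n_y"] >= 2)
                  | ((stats["n_x"] >= 1) & (stats["n_y"] >= 1)))
    if not replicated.any():
        raise IdentifiabilityError(
            "every participant has a single measurement; within-person "
            "variances are unidentifiable"
        )

    values = equivalents["value"].to_numpy(dtype=float)
    if np.ptp(values) == 0.0:
        # Degenerate data: all measurements identical; the likelihood is
        # maximized on the boundary.
        v = float(values[0])
        return VarianceComponents(theta=v, tau2=0.0, sigma_x2=0.0,
                                  sigma_y2=0.0,
                                  log_marginal_likelihood=float("inf"))

    y_informative = int(((stats["n_y"] >= 2)
                         | ((stats["n_y"] >= 1) & (stats["n_x"] >= 1))).sum())
    fix_sigma_y = y_informative < min_y_informative or stats["n_y"].sum() == 0
    if fix_sigma_y:
        warnings.warn(
            "insufficient HbA1c replication; fixing sigma_y2 = "
            f"{sigma_y_ratio} * sigma_x2",
            UserWarning,
            stacklevel=2,
        )

    theta0, tau0, sx0, sy0 = _moment_start(stats)

    if fix_sigma_y:
        def neg_ll(p):
            theta, lt, lx = p
            sx2 = np.exp(lx)
            return -_marginal_loglik(stats, theta, np.exp(lt), sx2,
                                     sigma_y_ratio * sx2)

        x0 = np.array([theta0, np.log(tau0), np.log(sx0)])
    else:
        def neg_ll(p):
            theta, lt, lx, ly = p
            return -_marginal_loglik(stats, theta, np.exp(lt), np.exp(lx),
                                     np.exp(ly))

        x0 = np.array([theta0, np.log(tau0), np.log(sx0), np.log(sy0)])

    res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                            options=dict(fatol=fatol, xatol=1e-8,
                                         maxiter=maxiter * len(x0),
                                         maxfev=maxiter * len(x0)))
    if not np.isfinite(res.fun):
        raise FitError("variance-component fit diverged", last_iterate=res.x)

    if fix_sigma_y:
        theta, lt, lx = res.x
        sx2 = float(np.exp(lx))
        vc = VarianceComponents(theta=float(theta), tau2=float(np.exp(lt)),
                                sigma_x2=sx2, sigma_y2=sigma_y_ratio * sx2,
                                log_marginal_likelihood=-float(res.fun),
                                sigma_y2_fixed=True)
    else:
        theta, lt, lx, ly = res.x
        vc = VarianceComponents(theta=float(theta), tau2=float(np.exp(lt)),
                                sigma_x2=float(np.exp(lx)),
                                sigma_y2=float(np.exp(ly)),
                                log_marginal_likelihood=-float(res.fun))
    if not res.success:
        log.warning("variance-component optimizer hit the iteration cap; "
                    "returning last iterate (ll=%.6f)", -res.fun)
    return vc


def log_marginal_likelihood(equivalents: pd.DataFrame,
                            vc: VarianceComponents) -> float:
    """Evaluate the integrated log-likelihood at given components."""
    stats = _sufficient_stats(equivalents)
    return _marginal_loglik(stats, vc.theta, vc.tau2, vc.sigma_x2, vc.sigma_y2)


def posterior_mean(participant_measures: pd.DataFrame,
                   vc: VarianceComponents,
                   posterior_predictive_sd: bool = False) -> dict:
    """Empirical-Bayes posterior summary for one participant.

    ``participant_measures`` holds the participant's glucose-equivalent rows
    (columns channel, value).  Returns a dict with participant_id (when
    present), n_x, n_y, mu_hat, posterior_var and within_sd (None when fewer
    than two pooled values exist).  With no measurements the prior is
    returned: mu_hat = theta, posterior_var = tau2.

    ``posterior_predictive_sd`` switches within_sd from the observed-value
    sample SD to the posterior-predictive SD sqrt(posterior_var + sigma_x2).
    """
    vc.validate()
    is_x = participant_measures["channel"] == "X" if len(participant_measures) else pd.Series(dtype=bool)
    x = participant_measures.loc[is_x, "value"].to_numpy(dtype=float) if len(participant_measures) else np.array([])
    y = participant_measures.loc[~is_x, "value"].to_numpy(dtype=float) if len(participant_measures) else np.array([])
    n_x, n_y = len(x), len(y)

    if vc.tau2 == 0.0:
        mu_hat, post_var = vc.theta, 0.0
    elif n_x + n_y == 0:
        mu_hat, post_var = vc.theta, vc.tau2
    else:
        precision = 1.0 / vc.tau2
        weighted = vc.theta / vc.tau2
        if n_x:
            if vc.sigma_x2 == 0.0:
                # exact measurements dominate: posterior collapses on xbar
                return _degenerate_posterior(participant_measures, x, y, vc)
            precision += n_x / vc.sigma_x2
            weighted += x.sum() / vc.sigma_x2
        if n_y:
            if vc.sigma_y2 == 0.0:
                return _degenerate_posterior(participant_measures, x, y, vc)
            precision += n_y / vc.sigma_y2
            weighted += y.sum() / vc.sigma_y2
        mu_hat = weighted / precision
        post_var = 1.0 / precision

    pooled = np.concatenate([x, y])
    if posterior_predictive_sd:
        within = float(np.sqrt(post_var + vc.sigma_x2)) if n_x + n_y >= 2 else None
    else:
        within = float(np.std(pooled, ddof=1)) if n_x + n_y >= 2 else None

    out = dict(n_x=n_x, n_y=n_y, mu_hat=float(mu_hat),
               posterior_var=float(post_var), within_sd=within)
    if "participant_id" in participant_measures.columns and len(participant_measures):
        out["participant_id"] = participant_measures["participant_id"].iloc[0]
    return out


def _degenerate_posterior(measures, x, y, vc):
    vals = np.concatenate([x, y]) if len(y) else x
    mu = float(np.mean(x)) if len(x) else float(np.mean(y))
    within = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    out = dict(n_x=len(x), n_y=len(y), mu_hat=mu, posterior_var=0.0,
               within_sd=within)
    if "participant_id" in measures.columns and len(measures):
        out["participant_id"] = measures["participant_id"].iloc[0]
    return out


def estimate_all(measurements: pd.DataFrame, window_years: float = 5.0,
                 posterior_predictive_sd: bool = False,
                 **fit_kwargs) -> tuple[VarianceComponents, pd.DataFrame]:
    """End-to-end exposure estimation over a measurement window.

    Converts HbA1c records to glucose equivalents, restricts to days in
    [0, 365.25 * window_years] (closed on both ends), fits the variance
    components once across all participants, then produces one exposure
    estimate per participant, sorted by id.
    """
    if measurements.empty:
        raise DataError("no measurements")
    if window_years <= 0:
        raise DataError("window_years must be > 0")
    eq = to_glucose_equivalents(measurements)
    horizon = DAYS_PER_YEAR * window_years
    eq = eq[(eq["day"] >= 0) & (eq["day"] <= horizon)]
    if eq.empty:
        raise DataError("no measurements inside the estimation window")

    vc = fit_variance_components(eq, **fit_kwargs)

    # Vectorized posterior means over all participants at once.
    stats = _sufficient_stats(eq)
    n_x = stats["n_x"].to_numpy()
    n_y = stats["n_y"].to_numpy()
    if vc.tau2 == 0.0:
        mu_hat = np.full(len(stats), vc.theta)
        post_var = np.zeros(len(stats))
    else:
        sx2 = vc.sigma_x2 if vc.sigma_x2 > 0 else np.inf
        sy2 = vc.sigma_y2 if vc.sigma_y2 > 0 else np.inf
        precision = n_x / sx2 + n_y / sy2 + 1.0 / vc.tau2
        weighted = (stats["sum_x"].to_numpy() / sx2
                    + stats["sum_y"].to_numpy() / sy2 + vc.theta / vc.tau2)
        mu_hat = weighted / precision
        post_var = 1.0 / precision

    n_tot = n_x + n_y
    ss = stats["ss_x"].to_numpy() + stats["ss_y"].to_numpy()
    sm = stats["sum_x"].to_numpy() + stats["sum_y"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        sample_var = (ss - sm**2 / np.maximum(n_tot, 1)) / np.maximum(n_tot - 1, 1)
    sample_var = np.clip(sample_var, 0.0, None)
    if posterior_predictive_sd:
        within = np.sqrt(post_var + vc.sigma_x2)
    else:
        within = np.sqrt(sample_var)
    within = np.where(n_tot >= 2, within, np.nan)

    estimates = pd.DataFrame(
        {
            "participant_id": stats["participant_id"],
            "n_x": n_x,
            "n_y": n_y,
            "mu_hat": mu_hat,
            "posterior_var": post_var,
            "within_sd": within,
        }
    ).sort_values("participant_id").reset_index(drop=True)
    return vc, estimates


def read_measurements(path) -> pd.DataFrame:
    """Read measurements.csv (participant_id, day, type/kind, value)."""
    df = pd.read_csv(path)
    if "type" in df.columns and "kind" not in df.columns:
        df = df.rename(columns={"type": "kind"})
    required = {"participant_id", "day", "kind", "value"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"measurements file missing columns {sorted(missing)}")
    return df


def write_estimates(estimates: pd.DataFrame, path) -> None:
    estimates.to_csv(path, index=False)
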