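"""Assembly of the per-participant analysis table.

Takes the three upstream tables — baseline covariates, empirical-Bayes
exposure estimates and stroke outcomes — and produces one analysis row per
retained participant: glucose exposure category, within-person-SD quartile,
derived clinical flags (hypertension, hypercholesterolemia) and the
time-to-event columns the survival models consume.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)

#: Half-open bin edges for average-glucose categories, mg/dL.  A value of
#: exactly 126 falls in the fifth bin, exactly 140 in the top bin.
GLUCOSE_BIN_EDGES = np.array([80.0, 90.0, 100.0, 110.0, 126.0, 140.0, np.inf])

#: Category labels, ordinal 1-6.  The reference category is "90-99.9".
GLUCOSE_CATEGORIES = (
    "80-89.9",
    "90-99.9",
    "100-109.9",
    "110-125.9",
    "126-139.9",
    ">=140",
)

REFERENCE_CATEGORY = "90-99.9"
REFERENCE_ORDINAL = 2

#: Clinical thresholds, inclusive ("140/90 mmHg or higher", "240 mg/dL or higher").
HYPERTENSION_SBP = 140.0
HYPERTENSION_DBP = 90.0
HIGH_CHOLESTEROL = 240.0


def categorize_glucose(mu_hat: float) -> str:
    """Return the glucose category label for a single average-glucose value.

    Bins are half-open ``[lo, hi)`` so 126.0 maps to "126-139.9" and 140.0
    to ">=140".  Values below 80 mg/dL are outside the categorization range
    and raise :class:`DataError`; at the table level such rows are excluded
    with a logged count (see :func:`assemble`).
    """
    if not np.isfinite(mu_hat):
        raise DataError(f"cannot categorize non-finite glucose value {mu_hat!r}")
    if mu_hat < GLUCOSE_BIN_EDGES[0]:
        raise DataError(
            f"glucose value {mu_hat:.2f} mg/dL is below the 80 mg/dL category range"
        )
    idx = int(np.searchsorted(GLUCOSE_BIN_EDGES, mu_hat, side="right")) - 1
    return GLUCOSE_CATEGORIES[idx]


def category_ordinal(label: str) -> int:
    """1-based ordinal of a category label (used as the linear trend score)."""
    return GLUCOSE_CATEGORIES.index(label) + 1


def categorize_glucose_series(mu_hat: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Vectorized categorization; below-range values map to <NA>."""
    vals = mu_hat.to_numpy(dtype=float)
    idx = np.searchsorted(GLUCOSE_BIN_EDGES, vals, side="right") - 1
    ok = vals >= GLUCOSE_BIN_EDGES[0]
    labels = pd.Series(
        [GLUCOSE_CATEGORIES[i] if o else None for i, o in zip(idx, ok)],
        index=mu_hat.index,
        dtype="object",
    )
    ordinals = pd.Series(np.where(ok, idx + 1, np.nan), index=mu_hat.index)
    return labels, ordinals.astype("Int64", errors="ignore")


def quartile_cutpoints(values: np.ndarray) -> np.ndarray:
    """Empirical quartile cutpoints using the median-unbiased quantile rule."""
    return np.quantile(np.asarray(values, dtype=float), [0.25, 0.5, 0.75],
                       method="median_unbiased")


def assign_sd_quartiles(rows: pd.DataFrame, sd_col: str = "within_sd",
                        out_col: str = "sd_quartile") -> pd.DataFrame:
    """Assign within-person-SD quartiles (1-4) over rows where the SD exists.

    Cutpoints are the empirical quartiles of ``sd_col`` among eligible rows
    (median-unbiased convention); values tied with a cutpoint go to the lower
    quartile.  Rows without a within-person SD get <NA>.  The realized
    cutpoints are logged — they are data-dependent, not constants.
    """
    eligible = rows[sd_col].notna()
    n_eligible = int(eligible.sum())
    if n_eligible < 4:
        raise DataError(
            f"need >=4 rows with {sd_col} to form quartiles, got {n_eligible}"
        )
    vals = rows.loc[eligible, sd_col].to_numpy(dtype=float)
    cuts = quartile_cutpoints(vals)
    if not np.all(np.diff(cuts) > 0):
        warnings.warn(
            f"degenerate SD quartile cutpoints {cuts.tolist()}; "
            "tied groups collapse into the lower quartile",
            UserWarning,
            stacklevel=2,
        )
    log.info("SD quartile cutpoints: %.4g / %.4g / %.4g over %d rows",
             *cuts, n_eligible)
    out = rows.copy()
    q = np.searchsorted(cuts, vals, side="left") + 1
    out[out_col] = np.nan
    out.loc[eligible, out_col] = q
    out[out_col] = out[out_col].astype("Int64")
    out.attrs = dict(rows.attrs)
    out.attrs["sd_quartile_cutpoints"] = cuts.tolist()
    return out


def derive_flags(baselines: pd.DataFrame) -> pd.DataFrame:
    """Derive hypertension and hypercholesterolemia flags from a baseline table.

    Hypertension: systolic >= 140 mmHg, or diastolic >= 90 mmHg, or a
    reported history of hypertension.  High cholesterol: total cholesterol
    >= 240 mg/dL (boundary inclusive in both definitions).
    """
    history = baselines.get("hypertension_history")
    if history is None:
        history = pd.Series(False, index=baselines.index)
    else:
        history = history.map(lambda v: v in (True, 1, "yes", "Yes", "true"))
    hypertension = (
        (baselines["sbp"] >= HYPERTENSION_SBP)
        | (baselines["dbp"] >= HYPERTENSION_DBP)
        | history
    )
    high_chol = baselines["total_cholesterol"] >= HIGH_CHOLESTEROL
    return pd.DataFrame(
        {"hypertension": hypertension, "high_cholesterol": high_chol},
        index=baselines.index,
    )


def _check_unique(df: pd.DataFrame, name: str) -> None:
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if len(dup):
        raise DataError(
            f"duplicate participant ids in {name}: {sorted(set(dup))[:10]}"
        )


def assemble(baselines: pd.DataFrame, estimates: pd.DataFrame,
             outcomes: pd.DataFrame, compute_sd_quartiles: bool = True,
             ) -> pd.DataFrame:
    """Inner-join baselines, exposure estimates and outcomes into analysis rows.

    Participants missing from any input are excluded, as are participants
    whose estimated average glucose falls below the 80 mg/dL category floor;
    exclusion counts are logged and recorded in ``result.attrs['exclusions']``.
    Diabetes strata follow end-of-study status carried in the baseline table:
    undiagnosed high-glucose participants remain in the nondiabetic stratum.
    """
    for df, name in ((baselines, "baselines"), (estimates, "estimates"),
                     (outcomes, "outcomes")):
        _check_unique(df, name)

    ids = [set(df["participant_id"]) for df in (baselines, estimates, outcomes)]
    common = ids[0] & ids[1] & ids[2]
    exclusions = {
        "missing_exposure": sorted(ids[0] - ids[1]),
        "missing_outcome": sorted(ids[0] - ids[2]),
        "missing_baseline": sorted((ids[1] | ids[2]) - ids[0]),
    }

    rows = (
        baselines.merge(estimates, on="participant_id", how="inner")
        .merge(outcomes, on="participant_id", how="inner")
    )

    labels, ordinals = categorize_glucose_series(rows["mu_hat"])
    rows = rows.assign(glucose_category=labels, category_ordinal=ordinals)
    below = rows["glucose_category"].isna()
    exclusions["below_range"] = sorted(rows.loc[below, "participant_id"])
    rows = rows.loc[~below].reset_index(drop=True)

    flags = derive_flags(rows)
    rows = pd.concat([rows, flags], axis=1)

    if compute_sd_quartiles and rows["within_sd"].notna().sum() >= 4:
        rows = assign_sd_quartiles(rows)
    else:
        rows["sd_quartile"] = pd.array([pd.NA] * len(rows), dtype="Int64")

    for key, members in exclusions.items():
        if members:
            log.info("assemble: excluded %d participants (%s)", len(members), key)
    rows.attrs["exclusions"] = exclusions
    return rows


def write_analysis_table(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False)


def write_exclusions_log(rows: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for key, members in rows.attrs.get("exclusions", {}).items():
            fh.write(f"{key}\t{len(members)}\t{','.join(map(str, members))}\n")
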