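"""Tests of the hierarchical exposure model: the HbA1c conversion, the
normal-normal posterior against quadrature and hand calculations, variance
component estimation against closed-form oracles, and shrinkage behaviour."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycox.errors import DataError, IdentifiabilityError
from glycox.exposure import (VarianceComponents, estimate_all,
                             fit_variance_components, hba1c_to_glucose,
                             log_marginal_likelihood, posterior_mean,
                             to_glucose_equivalents)
from glycox.simulate import default_config, simulate_cohort


def eq_frame(x=(), y=(), pid="P1"):
    """Glucose-equivalent frame for one participant."""
    vals = list(x) + list(y)
    return pd.DataFrame(
        {
            "participant_id": [pid] * len(vals),
            "day": range(len(vals)),
            "channel": ["X"] * len(x) + ["Y"] * len(y),
            "value": vals,
        }
    )


# ---------------------------------------------------------------- conversion

@pytest.mark.parametrize("hba1c, glucose", [
    (7.0, 154.2),
    (6.0, 125.5),
    (46.7 / 28.7, 0.0),
])
def test_hba1c_conversion(hba1c, glucose):
    assert hba1c_to_glucose(hba1c) == pytest.approx(glucose, abs=1e-9)


def test_hba1c_conversion_rejects_nonpositive():
    with pytest.raises(DataError):
        hba1c_to_glucose(0.0)


def test_equivalents_channel_values():
    meas = pd.DataFrame(
        {
            "participant_id": ["A", "A", "B"],
            "day": [0, 10, 5],
            "kind": ["glucose", "HbA1c", "glucose"],
            "value": [100.0, 7.0, 120.0],
        }
    )
    eq = to_glucose_equivalents(meas)
    y = eq[eq["channel"] == "Y"]
    assert y["value"].iloc[0] == pytest.approx(28.7 * 7.0 - 46.7)
    assert (eq[eq["channel"] == "X"]["value"] == [100.0, 120.0]).all()


# ------------------------------------------------------------ posterior mean

def test_posterior_prior_only():
    vc = VarianceComponents(theta=100.0, tau2=80.0, sigma_x2=90.0, sigma_y2=120.0)
    est = posterior_mean(eq_frame(), vc)
    assert est["mu_hat"] == 100.0 and est["posterior_var"] == 80.0
    assert est["within_sd"] is None


def test_posterior_equal_precision_hand_case():
    """Equal prior and datum precision average the two: (100+120)/2 = 110."""
    vc = VarianceComponents(theta=100.0, tau2=100.0, sigma_x2=100.0,
                            sigma_y2=150.0)
    est = posterior_mean(eq_frame(x=[120.0]), vc)
    assert est["mu_hat"] == pytest.approx(110.0)
    assert est["posterior_var"] == pytest.approx(50.0)


def test_posterior_flat_prior_limit():
    vc = VarianceComponents(theta=100.0, tau2=1e12, sigma_x2=100.0,
                            sigma_y2=150.0)
    x = [95.0, 105.0, 118.0]
    est = posterior_mean(eq_frame(x=x), vc)
    assert est["mu_hat"] == pytest.approx(np.mean(x), rel=1e-6)


def test_posterior_zero_tau_returns_prior_mean():
    vc = VarianceComponents(theta=107.0, tau2=0.0, sigma_x2=100.0, sigma_y2=1.0)
    est = posterior_mean(eq_frame(x=[150.0]), vc)
    assert est["mu_hat"] == 107.0 and est["posterior_var"] == 0.0


def test_posterior_rejects_negative_variance():
    vc = VarianceComponents(theta=100.0, tau2=-1.0, sigma_x2=100.0, sigma_y2=1.0)
    with pytest.raises(DataError):
        posterior_mean(eq_frame(x=[100.0]), vc)


def quadrature_posterior(x, y, vc, n_grid=40001):
    """Independent oracle: posterior mean of mu by trapezoidal quadrature of
    the model densities on a fine grid."""
    lo = vc.theta - 12 * math.sqrt(vc.tau2)
    hi = vc.theta + 12 * math.sqrt(vc.tau2)
    mu = np.linspace(lo, hi, n_grid)
    logpost = -0.5 * (mu - vc.theta) ** 2 / vc.tau2
    for v in x:
        logpost = logpost - 0.5 * (v - mu) ** 2 / vc.sigma_x2
    for v in y:
        logpost = logpost - 0.5 * (v - mu) ** 2 / vc.sigma_y2
    w = np.exp(logpost - logpost.max())
    return float(np.trapezoid(mu * w, mu) / np.trapezoid(w, mu))


def test_posterior_matches_quadrature_small_sample():
    rng = np.random.default_rng(42)
    for _ in range(10):
        vc = VarianceComponents(
            theta=rng.uniform(90, 120), tau2=rng.uniform(50, 400),
            sigma_x2=rng.uniform(50, 200), sigma_y2=rng.uniform(50, 300),
        )
        x = rng.uniform(70, 160, rng.integers(0, 4)).tolist()
        y = rng.uniform(70, 160, rng.integers(0, 3)).tolist()
        est = posterior_mean(eq_frame(x=x, y=y), vc)
        assert est["mu_hat"] == pytest.approx(
            quadrature_posterior(x, y, vc), abs=1e-6
        )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(60, 200), min_size=1, max_size=6), st.integers(0, 2**31 - 1))
def test_posterior_order_invariant_and_bounded(xs, seed):
    """The posterior mean ignores measurement order and lies weakly between
    the prior mean and the participant's pooled sample mean."""
    vc = VarianceComponents(theta=106.7, tau2=300.0, sigma_x2=100.0,
                            sigma_y2=150.0)
    a = posterior_mean(eq_frame(x=xs), vc)
    perm = list(np.random.default_rng(seed).permutation(xs))
    b = posterior_mean(eq_frame(x=perm), vc)
    assert a["mu_hat"] == pytest.approx(b["mu_hat"], abs=1e-9)
    lo, hi = sorted((vc.theta, float(np.mean(xs))))
    assert lo - 1e-9 <= a["mu_hat"] <= hi + 1e-9
    assert a["posterior_var"] <= vc.tau2 + 1e-12


def test_posterior_var_decreases_with_more_measurements():
    vc = VarianceComponents(theta=100.0, tau2=200.0, sigma_x2=100.0,
                            sigma_y2=150.0)
    variances = [
        posterior_mean(eq_frame(x=[100.0] * n), vc)["posterior_var"]
        for n in range(5)
    ]
    assert all(a > b for a, b in zip(variances, variances[1:]))


# ------------------------------------------------------- variance components

def test_fit_degenerate_identical_values():
    eq = pd.concat([eq_frame(x=[100.0, 100.0], pid="A"),
                    eq_frame(x=[100.0], pid="B")])
    vc = fit_variance_components(eq)
    assert vc.theta == 100.0 and vc.tau2 == 0.0 and vc.sigma_x2 == 0.0


def test_fit_unidentifiable_single_measurements():
    eq = pd.concat([eq_frame(x=[100.0], pid="A"), eq_frame(x=[110.0], pid="B")])
    with pytest.raises(IdentifiabilityError):
        fit_variance_components(eq)


def balanced_ml_oracle(values):
    """Closed-form ML estimators for a balanced one-way random-effects
    layout: values is an (a, m) array."""
    a, m = values.shape
    grand = values.mean()
    means = values.mean(axis=1)
    ssw = ((values - means[:, None]) ** 2).sum()
    sigma2 = ssw / (a * (m - 1))
    v_between = m * ((means - grand) ** 2).sum() / a  # ML divisor a
    tau2 = max((v_between - sigma2) / m, 0.0)
    return grand, tau2, sigma2


def test_fit_matches_balanced_anova_oracle():
    rng = np.random.default_rng(11)
    a, m = 400, 4
    mu = rng.normal(106.7, 15.0, a)
    values = mu[:, None] + rng.normal(0.0, 10.0, (a, m))
    eq = pd.DataFrame(
        {
            "participant_id": np.repeat([f"P{i}" for i in range(a)], m),
            "day": np.tile(np.arange(m), a),
            "channel": "X",
            "value": values.ravel(),
        }
    )
    with pytest.warns(UserWarning, match="sigma_y2"):
        vc = fit_variance_components(eq)
    theta0, tau20, sigma20 = balanced_ml_oracle(values)
    assert vc.theta == pytest.approx(theta0, rel=1e-4)
    assert vc.tau2 == pytest.approx(tau20, rel=1e-3)
    assert vc.sigma_x2 == pytest.approx(sigma20, rel=1e-3)


def test_fit_recovers_two_channel_truth():
    """Parameter recovery within 10% relative error on a 2,000-participant
    cohort with four measures each (two per channel)."""
    rng = np.random.default_rng(7)
    n = 2000
    theta, tau, sx, sy = 106.7, 15.0, 10.0, 12.0
    mu = rng.normal(theta, tau, n)
    frames = []
    for chan, sd in (("X", sx), ("Y", sy)):
        vals = mu[:, None] + rng.normal(0, sd, (n, 2))
        frames.append(pd.DataFrame(
            {
                "participant_id": np.repeat([f"P{i:05d}" for i in range(n)], 2),
                "day": 0,
                "channel": chan,
                "value": vals.ravel(),
            }
        ))
    vc = fit_variance_components(pd.concat(frames))
    assert vc.theta == pytest.approx(theta, rel=0.1)
    assert vc.tau2 == pytest.approx(tau**2, rel=0.1)
    assert vc.sigma_x2 == pytest.approx(sx**2, rel=0.1)
    assert vc.sigma_y2 == pytest.approx(sy**2, rel=0.1)


def test_fit_is_local_optimum(small_cohort):
    """The attained log marginal likelihood beats 100 random perturbations
    of the fitted components."""
    eq = to_glucose_equivalents(small_cohort.measurements)
    vc = fit_variance_components(eq)
    best = log_marginal_likelihood(eq, vc)
    assert best == pytest.approx(vc.log_marginal_likelihood, rel=1e-9)
    rng = np.random.default_rng(3)
    for _ in range(100):
        pert = VarianceComponents(
            theta=vc.theta + rng.normal(0, 1.0),
            tau2=vc.tau2 * math.exp(rng.normal(0, 0.1)),
            sigma_x2=vc.sigma_x2 * math.exp(rng.normal(0, 0.1)),
            sigma_y2=vc.sigma_y2 * math.exp(rng.normal(0, 0.1)),
        )
        assert log_marginal_likelihood(eq, pert) <= best + 1e-6


# ----------------------------------------------------------------- pipeline

def test_estimate_all_shrinks_toward_truth(small_config, small_cohort):
    vc, est = estimate_all(small_cohort.measurements,
                           small_config.followup_years)
    merged = est.merge(small_cohort.truth, on="participant_id")
    glu = small_cohort.measurements[small_cohort.measurements["kind"] == "glucose"]
    raw = glu.groupby("participant_id")["value"].mean().rename("raw_mean")
    merged = merged.join(raw, on="participant_id")
    mse_eb = ((merged["mu_hat"] - merged["mu_true"]) ** 2).mean()
    mse_raw = ((merged["raw_mean"] - merged["mu_true"]) ** 2).mean()
    assert mse_eb < mse_raw


def test_more_measurements_less_shrinkage():
    rng = np.random.default_rng(21)
    many = eq_frame(x=(120 + rng.normal(0, 10, 100)).tolist(), pid="A")
    one = eq_frame(x=[120.0], pid="B")
    filler = pd.concat(
        [eq_frame(x=(100 + rng.normal(0, 10, 3)).tolist(), pid=f"F{i}")
         for i in range(50)]
    )
    eq = pd.concat([many, one, filler], ignore_index=True)
    vc = fit_variance_components(eq)
    est_many = posterior_mean(many, vc)
    est_one = posterior_mean(one, vc)
    gap_many = abs(est_many["mu_hat"] - many["value"].mean())
    gap_one = abs(est_one["mu_hat"] - 120.0)
    assert gap_many < gap_one


def test_estimate_all_empty_window_raises():
    meas = pd.DataFrame(
        {
            "participant_id": ["A", "A", "B"],
            "day": [400, 500, 450],
            "kind": "glucose",
            "value": [100.0, 110.0, 105.0],
        }
    )
    with pytest.raises(DataError, match="window"):
        estimate_all(meas, window_years=1.0)


def test_estimate_all_sorted_and_complete(small_config, small_cohort):
    vc, est = estimate_all(small_cohort.measurements,
                           small_config.followup_years)
    assert list(est["participant_id"]) == sorted(est["participant_id"])
    assert est["within_sd"].notna().equals((est["n_x"] + est["n_y"]) >= 2)
    assert (est["posterior_var"] <= vc.tau2 + 1e-9).all()
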