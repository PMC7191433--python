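"""Fit the categorized Cox models and the trend test.

Assembles the analysis table (glucose categories, SD quartiles, clinical
flags), then fits the fully adjusted proportional-hazards model for total
stroke over the six average-glucose categories, reference 90-99.9 mg/dL.
"""

from dataclasses import replace

from glycox import (CoxModelSpec, assemble, default_config, estimate_all,
                    fit_cox, incidence_summary, simulate_cohort)

cfg = replace(default_config(), n_participants=5000, seed=23)
cohort = simulate_cohort(cfg)
vc, estimates = estimate_all(cohort.measurements, window_years=5.0)
rows = assemble(cohort.baselines, estimates, cohort.outcomes)

print(incidence_summary(rows, group_by="diabetes"))

fit = fit_cox(rows, CoxModelSpec(outcome="total", exposure="glucose_category",
                                 adjustment="model3", stratum="all"))
print(fit.levels[["level", "n", "events", "pct", "hr", "ci_lower",
                  "ci_upper"]].round(2))
print(f"P for trend: {fit.trend_p:.4f}  (events: {fit.n_events})")

# Hazard ratios are relative to the 90-99.9 mg/dL reference (HR fixed at 1).
# Because categories come from estimated rather than latent glucose, the
# fitted HRs are attenuated toward 1 relative to the generating values --
# the regression-dilution effect the empirical-Bayes pooling mitigates but
# cannot remove with ~3 measurements per participant.
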