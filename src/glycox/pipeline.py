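"""End-to-end pipeline orchestration.

Chains simulate (optional) -> exposure estimation -> analysis-table assembly
-> survival-model grid -> report, writing each stage's artifact to the output
directory and recording row counts, seeds, checksums and convergence flags
in a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, GlycoxError
from .exposure import estimate_all, read_measurements
from .prep import assemble, write_exclusions_log
from .simulate import SimulationConfig, default_config, simulate_cohort
from .survival import incidence_summary, result_table, run_all_models

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulate`` / ``input_dir`` is active: either a synthetic
    cohort is generated, or measurements.csv / baseline.csv / outcomes.csv
    are read from ``input_dir``.
    """

    outdir: Path = Path("glycox_run")
    simulate: bool = True
    sim_config: SimulationConfig | None = None
    input_dir: Path | None = None
    window_years: float = 5.0
    reference_glucose: float = 95.0
    seed: int | None = None

    def validate(self) -> None:
        if self.simulate and self.input_dir is not None:
            raise ConfigurationError(
                "exactly one of simulate / input_dir may be active"
            )
        if not self.simulate and self.input_dir is None:
            raise ConfigurationError("input_dir required when simulate is off")
        if self.window_years <= 0:
            raise ConfigurationError("window_years must be > 0")


class StageError(GlycoxError):
    """An error tagged with the pipeline stage that raised it."""

    def __init__(self, stage, original):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "window_years": config.window_years,
        "reference_glucose": config.reference_glucose,
        "stages": {},
        "outputs": {},
        "convergence": {},
        "failures": {},
    }

    def record(stage, **info):
        manifest["stages"][stage] = info

    def register(path: Path):
        manifest["outputs"][path.name] = _sha256(path)

    # ---- stage: simulate / load ------------------------------------------
    try:
        if config.simulate:
            sim = config.sim_config or default_config()
            if config.seed is not None:
                from dataclasses import replace

                sim = replace(sim, seed=config.seed)
            cohort = simulate_cohort(sim)
            paths = cohort.write_csvs(outdir)
            for p in paths.values():
                register(p)
            measurements = cohort.measurements
            baselines = cohort.baselines
            outcomes = cohort.outcomes
            record("simulate", n_participants=len(baselines),
                   n_measurements=len(measurements), seed=sim.seed)
        else:
            indir = Path(config.input_dir)
            measurements = read_measurements(indir / "measurements.csv")
            baselines = pd.read_csv(indir / "baseline.csv")
            outcomes = pd.read_csv(indir / "outcomes.csv")
            record("load", n_participants=len(baselines),
                   n_measurements=len(measurements))
    except FileNotFoundError as exc:
        raise StageError("simulate" if config.simulate else "load", exc)
    except GlycoxError as exc:
        raise StageError("simulate" if config.simulate else "load", exc)

    # ---- stage: estimate --------------------------------------------------
    try:
        vc, estimates = estimate_all(measurements, config.window_years)
        estimates.to_csv(outdir / "exposure_estimates.csv", index=False)
        vc.to_json(outdir / "variance_components.json")
        register(outdir / "exposure_estimates.csv")
        register(outdir / "variance_components.json")
        record("estimate", n_estimates=len(estimates), theta=vc.theta,
               tau2=vc.tau2, sigma_x2=vc.sigma_x2, sigma_y2=vc.sigma_y2,
               sigma_y2_fixed=vc.sigma_y2_fixed)
    except GlycoxError as exc:
        _dump_manifest(manifest, outdir)
        raise StageError("estimate", exc)

    # ---- stage: assemble --------------------------------------------------
    try:
        rows = assemble(baselines, estimates, outcomes)
        rows.to_csv(outdir / "analysis_table.csv", index=False)
        write_exclusions_log(rows, outdir / "exclusions.log")
        register(outdir / "analysis_table.csv")
        record("assemble", n_rows=len(rows),
               exclusions={k: len(v) for k, v in
                           rows.attrs.get("exclusions", {}).items()},
               sd_quartile_cutpoints=rows.attrs.get("sd_quartile_cutpoints"))
    except GlycoxError as exc:
        _dump_manifest(manifest, outdir)
        raise StageError("assemble", exc)

    # ---- stage: analyze ---------------------------------------------------
    try:
        _write_characteristics(rows, outdir)
        incidence = incidence_summary(rows, group_by="diabetes")
        overall = incidence_summary(rows)
        pd.concat([overall, incidence]).to_csv(outdir / "incidence.csv",
                                               index=False)
        register(outdir / "incidence.csv")

        results = run_all_models(rows, config.reference_glucose)
        for name in ("table2", "table3", "table4"):
            tab = result_table(results[name])
            tab.to_csv(outdir / f"{name}.csv", index=False)
            register(outdir / f"{name}.csv")
        curves = []
        for stratum, curve in results["splines"].items():
            f = curve.to_frame()
            f.insert(0, "stratum", stratum)
            curves.append(f)
        if curves:
            pd.concat(curves).to_csv(outdir / "spline_curve.csv", index=False)
            register(outdir / "spline_curve.csv")
        sub = result_table(results["subgroups"])
        sub.to_csv(outdir / "subgroups.csv", index=False)
        register(outdir / "subgroups.csv")

        manifest["failures"] = results["failures"]
        for bucket in ("table2", "table3", "table4", "subgroups"):
            for key, fit in results[bucket].items():
                manifest["convergence"][f"{bucket}:{key}"] = fit.converged
        record("analyze",
               n_fits=sum(len(results[b]) for b in
                          ("table2", "table3", "table4", "subgroups")),
               n_splines=len(results["splines"]),
               trend_p_total_model3=_maybe_trend(results))
    except GlycoxError as exc:
        _dump_manifest(manifest, outdir)
        raise StageError("analyze", exc)

    _dump_manifest(manifest, outdir)
    return manifest


def _maybe_trend(results):
    fit = results["table2"].get(("total", "model3"))
    return None if fit is None else fit.trend_p


def _write_characteristics(rows: pd.DataFrame, outdir: Path) -> None:
    """Cohort-characteristics artifact (means/SDs and prevalences by stratum)."""
    out = []
    strata = [("all", rows),
              ("nondiabetic", rows[rows["diabetes"] == "none"]),
              ("diabetic", rows[rows["diabetes"] == "diagnosed"])]
    for name, g in strata:
        if g.empty:
            continue
        out.append(
            dict(stratum=name, n=len(g),
                 age_mean=g["age"].mean(), age_sd=g["age"].std(),
                 female_pct=100.0 * (g["sex"] == "female").mean(),
                 bmi_mean=g["bmi"].mean(), bmi_sd=g["bmi"].std(),
                 sbp_mean=g["sbp"].mean(), sbp_sd=g["sbp"].std(),
                 glucose_mean=g["mu_hat"].mean(), glucose_sd=g["mu_hat"].std(),
                 tc_mean=g["total_cholesterol"].mean(),
                 tc_sd=g["total_cholesterol"].std(),
                 hypertension_pct=100.0 * g["hypertension"].mean(),
                 high_cholesterol_pct=100.0 * g["high_cholesterol"].mean())
        )
    pd.DataFrame(out).round(2).to_csv(outdir / "cohort_characteristics.csv",
                                      index=False)


def _dump_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
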