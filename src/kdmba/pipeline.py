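"""End-to-end pipeline: simulate, preprocess, fit BA, associate, discriminate.

A single seeded configuration drives every stage; the global seed is fanned
out into stable per-stage child seeds so stages are independently
re-runnable.  ``run_pipeline`` returns an in-memory report bundle and
``write_report`` serializes it (delimited tables + YAML models + a JSON
manifest and machine-readable summary that round-trips losslessly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import GROUPS, SimulationConfig, child_seed
from .kdm import SexStratifiedFit, ba_diagnostics, fit_biological_age, project_control_model
from .preprocess import (
    activity_medians,
    analysis_marker_columns,
    apply_exclusions,
    compute_dietary_score,
    compute_lifestyle_score,
    harmonize_measurements,
)
from .simulate import generate_cohort
from .survival import (
    CoxResult,
    CoxSpec,
    add_derived_columns,
    check_proportional_hazards,
    event_summary,
    fit_stratified_cox,
    interaction_test,
    subgroup_hr,
)
from .discrimination import compare_models


@dataclass
class PipelineConfig:
    """Options for one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    outlier_sd: float = 4.0
    screen_threshold: float = 0.10
    r_char_mode: str = "rms"
    s_ba2_mode: str = "plugin"
    pc_cap: int | None = None
    nri_threshold: float = 0.50
    bootstrap_reps: int = 200
    discrimination_ci: bool = True
    sensitivity_control_derived: bool = True
    sensitivity_exclude_antihypertensive: bool = True

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["simulation"]["age_range"] = list(d["simulation"]["age_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


SUBGROUP_FACTORS = ("age_60", "sex", "urban", "smoking_current", "risky_lifestyle")


def derive_lifestyle_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach the derived covariates the association and prediction models use."""
    out = add_derived_columns(cohort)
    out["age_60"] = np.where(out["ca"] < 60, "<60", ">=60")
    out["smoking_current"] = (out["smoking_status"] == "current") | (
        (out["smoking_status"] == "former") & out["quit_for_illness"].astype(bool)
    )
    limit = np.where(out["sex"] == "male", 30.0, 15.0)
    out["excessive_alcohol"] = (out["alcohol_g_day"].to_numpy() >= limit) | out[
        "past_drinker"
    ].astype(bool).to_numpy()
    out["dietary_score"] = compute_dietary_score(out)
    out["diet_risky"] = out["dietary_score"] >= 4
    med = activity_medians(out)
    score, risky = compute_lifestyle_score(out, med)
    out["lifestyle_score"] = score
    out["risky_lifestyle"] = risky
    band_med = np.array(
        [med[k] for k in zip(
            pd.cut(out["ca"], [-np.inf, 50, 60, np.inf], right=False,
                   labels=["<50", "50-59", ">=60"]).astype(str),
            out["sex"],
        )]
    )
    out["low_activity"] = out["total_activity"].to_numpy() < band_med
    return out


BASIC_COVARIATES = [
    "sex", "fasting_8h", "education", "urban",
    "smoking_current", "excessive_alcohol", "diet_risky", "low_activity",
]


@dataclass
class PipelineResult:
    """Everything a pipeline run computed, ready for reporting."""

    config: PipelineConfig
    cohort: pd.DataFrame            # analysis set with ba/aa columns attached
    truth: pd.DataFrame
    exclusion_log: object
    fit: SexStratifiedFit
    diagnostics: pd.DataFrame       # per-group AA mean/SD, r, RMSE
    events: pd.DataFrame
    associations: pd.DataFrame      # overall / per-group / subgroup HRs
    interactions: pd.DataFrame
    ph_p_value: float
    discrimination: pd.DataFrame
    sensitivity: pd.DataFrame
    manifest: dict


def _cox_row(label: str, res: CoxResult | None) -> dict:
    if res is None:
        return {"model": label, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "log_hr": np.nan, "se": np.nan, "n": 0, "events": 0}
    return {
        "model": label, "hr": res.hr, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
        "log_hr": res.log_hr, "se": res.se, "n": res.n, "events": res.events,
    }


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage under a single seed and return the report bundle."""
    cfg = config or PipelineConfig()
    sim_cfg = cfg.simulation
    sim_cfg.seed = child_seed(cfg.seed, "simulate")

    # -- simulate ---------------------------------------------------------
    raw, truth = generate_cohort(sim_cfg)

    # -- preprocess -------------------------------------------------------
    panel = sim_cfg.marker_panel
    harmonized = harmonize_measurements(raw, panel)
    markers = analysis_marker_columns(panel)
    cohort, excl_log = apply_exclusions(harmonized, markers, outlier_k=cfg.outlier_sd)
    cohort = derive_lifestyle_columns(cohort)
    truth = truth.set_index("id").loc[cohort["id"]].reset_index()

    # -- fit biological age ----------------------------------------------
    fit = fit_biological_age(
        cohort, markers,
        threshold=cfg.screen_threshold, r_char_mode=cfg.r_char_mode,
        s_ba2_mode=cfg.s_ba2_mode, pc_cap=cfg.pc_cap,
    )
    cohort = cohort.assign(
        ba=fit.result.ba, aa=fit.result.aa, aa_standardized=fit.result.aa_standardized
    )

    diag_rows = []
    for label, sub in [("all", cohort)] + [(g, cohort[cohort["group"] == g]) for g in GROUPS]:
        if len(sub) < 3:
            continue
        r, rmse = ba_diagnostics(sub["ba"], sub["ca"])
        diag_rows.append({
            "group": label, "n": len(sub),
            "ca_mean": sub["ca"].mean(), "ba_mean": sub["ba"].mean(),
            "aa_mean": sub["aa"].mean(), "aa_sd": sub["aa"].std(),
            "pearson_r": r, "rmse_years": rmse,
        })
    diagnostics = pd.DataFrame(diag_rows).set_index("group")

    # -- associate --------------------------------------------------------
    spec = CoxSpec()
    overall = fit_stratified_cox(cohort, spec)
    spec_sd = CoxSpec(exposure="aa_standardized")
    per_sd = fit_stratified_cox(cohort, spec_sd)
    assoc_rows = [_cox_row("all:aa_per_year", overall), _cox_row("all:aa_per_sd", per_sd)]

    group_spec = CoxSpec(strata=["age_band_5yr", "area"])
    for g, res in subgroup_hr(cohort, group_spec, "group").items():
        assoc_rows.append(_cox_row(f"group:{g}", res))
    inter_rows = []
    for factor in SUBGROUP_FACTORS:
        for level, res in subgroup_hr(cohort, spec, factor).items():
            assoc_rows.append(_cox_row(f"{factor}:{level}", res))
        lrt, p = interaction_test(cohort, spec, factor)
        inter_rows.append({"factor": factor, "lrt": lrt, "p_value": p})
    associations = pd.DataFrame(assoc_rows).set_index("model")
    interactions = pd.DataFrame(inter_rows).set_index("factor")
    ph_p = check_proportional_hazards(cohort, spec)
    events = event_summary(cohort)

    # -- discriminate -----------------------------------------------------
    reps = cfg.bootstrap_reps if cfg.discrimination_ci else 0
    disc_rows = []
    spec_ref = CoxSpec(exposure="ca", covariates=BASIC_COVARIATES,
                       strata=["area", "group"], time_scale="time-on-study")
    spec_new = CoxSpec(exposure="aa", covariates=["ca"] + BASIC_COVARIATES,
                       strata=["area", "group"], time_scale="time-on-study")
    rows = [("all", cohort, ["area", "group"])] + [
        (g, cohort[cohort["group"] == g].reset_index(drop=True), ["area"]) for g in GROUPS
    ]
    for label, sub, strata in rows:
        if len(sub) == 0 or sub["died"].sum() == 0:
            continue
        sr = CoxSpec(exposure="ca", covariates=BASIC_COVARIATES, strata=strata,
                     time_scale="time-on-study")
        sn = CoxSpec(exposure="aa", covariates=["ca"] + BASIC_COVARIATES, strata=strata,
                     time_scale="time-on-study")
        if reps:
            d = compare_models(sub, sr, sn, threshold=cfg.nri_threshold, reps=reps,
                               seed=child_seed(cfg.seed, f"disc:{label}"))
            disc_rows.append({
                "group": label, "c_basic_ca": d.c_ref, "c_basic_ca_lo": d.c_ref_ci[0],
                "c_basic_ca_hi": d.c_ref_ci[1], "c_with_aa": d.c_new,
                "c_with_aa_lo": d.c_new_ci[0], "c_with_aa_hi": d.c_new_ci[1],
                "nri": d.nri, "nri_lo": d.nri_ci[0], "nri_hi": d.nri_ci[1],
                "n": d.n, "events": d.events,
            })
        else:
            from .discrimination import harrell_c, nri_binary, predict_risk_10yr, status_10yr
            r0 = predict_risk_10yr(sub, sr, "ref").risk.to_numpy()
            r1 = predict_risk_10yr(sub, sn, "new").risk.to_numpy()
            t = sub["followup_years"].to_numpy(float)
            e = sub["died"].to_numpy(bool)
            ok = ~np.isnan(r0) & ~np.isnan(r1)
            disc_rows.append({
                "group": label,
                "c_basic_ca": harrell_c(t[ok], e[ok], r0[ok]),
                "c_with_aa": harrell_c(t[ok], e[ok], r1[ok]),
                "nri": nri_binary(r0, r1, status_10yr(t, e), cfg.nri_threshold),
                "n": len(sub), "events": int(e.sum()),
            })
    discrimination = pd.DataFrame(disc_rows).set_index("group")

    # -- sensitivity ------------------------------------------------------
    sens_rows = []
    if cfg.sensitivity_control_derived:
        is_control = (cohort["group"] == "control").to_numpy()
        ctrl_fit = fit_biological_age(
            cohort[is_control], markers,
            threshold=cfg.screen_threshold, r_char_mode=cfg.r_char_mode,
        s_ba2_mode=cfg.s_ba2_mode, pc_cap=cfg.pc_cap,
        )
        parts = []
        for sex, model in ctrl_fit.models.items():
            sub = cohort[cohort["sex"] == sex]
            parts.append(project_control_model(model, ctrl_fit.aa_model, sub).to_frame())
        proj = pd.concat(parts).loc[cohort.index]
        sens = cohort.assign(aa=proj["aa"], aa_standardized=proj["aa_standardized"])
        res = fit_stratified_cox(sens, CoxSpec(exposure="aa_standardized"))
        sens_rows.append(_cox_row("control_derived:aa_per_sd", res))
        for g, r in subgroup_hr(sens, CoxSpec(exposure="aa_standardized",
                                              strata=["age_band_5yr", "area"]), "group").items():
            sens_rows.append(_cox_row(f"control_derived:{g}", r))
    if cfg.sensitivity_exclude_antihypertensive:
        sub = cohort[~cohort["antihypertensive"].astype(bool)].reset_index(drop=True)
        refit = fit_biological_age(
            sub, markers,
            threshold=cfg.screen_threshold, r_char_mode=cfg.r_char_mode,
        s_ba2_mode=cfg.s_ba2_mode, pc_cap=cfg.pc_cap,
        )
        sub = sub.assign(aa=refit.result.aa, aa_standardized=refit.result.aa_standardized)
        res = fit_stratified_cox(sub, CoxSpec())
        sens_rows.append(_cox_row("no_antihypertensive:aa_per_year", res))
    sensitivity = pd.DataFrame(sens_rows).set_index("model") if sens_rows else pd.DataFrame()

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: child_seed(cfg.seed, s) for s in ("simulate",)},
        "n_initial": int(excl_log.input_n),
        "n_analysis": int(excl_log.output_n),
        "exclusions": dict(excl_log.removed),
        "retained_markers": {s: m.retained_markers for s, m in fit.models.items()},
    }
    return PipelineResult(
        config=cfg, cohort=cohort, truth=truth, exclusion_log=excl_log, fit=fit,
        diagnostics=diagnostics, events=events, associations=associations,
        interactions=interactions, ph_p_value=ph_p, discrimination=discrimination,
        sensitivity=sensitivity, manifest=manifest,
    )


def write_report(result: PipelineResult, outdir) -> dict:
    """Serialize the bundle; returns the machine-readable summary dict.

    Human-readable delimited tables mirror the shapes of the study's event,
    BA-diagnostic, and discrimination tables; the JSON summary round-trips
    losslessly via ``json.load``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(out / "analysis_cohort.csv", index=False)
    result.truth.to_csv(out / "ground_truth.csv", index=False)
    result.exclusion_log.to_frame().to_csv(out / "exclusion_log.csv", index=False)
    result.diagnostics.to_csv(out / "ba_diagnostics.csv")
    result.events.to_csv(out / "event_summary.csv")
    result.associations.to_csv(out / "associations.csv")
    result.interactions.to_csv(out / "interactions.csv")
    result.discrimination.to_csv(out / "discrimination.csv")
    if len(result.sensitivity):
        result.sensitivity.to_csv(out / "sensitivity.csv")
    for sex, model in result.fit.models.items():
        model.to_yaml(out / f"kdm_model_{sex}.yaml")

    summary = {
        "manifest": result.manifest,
        "hr_per_year_aa": result.associations.loc["all:aa_per_year", "hr"],
        "hr_per_sd_aa": result.associations.loc["all:aa_per_sd", "hr"],
        "ph_p_value": result.ph_p_value,
        "diagnostics": result.diagnostics.reset_index().to_dict(orient="records"),
        "discrimination": result.discrimination.reset_index().to_dict(orient="records"),
    }

    def _py(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_py)
    with open(out / "summary.json") as fh:
        roundtrip = json.load(fh)
    if json.dumps(roundtrip, sort_keys=True, default=_py) != json.dumps(
        json.loads(json.dumps(summary, default=_py)), sort_keys=True
    ):
        raise RuntimeError("summary round-trip mismatch")
    return summary
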