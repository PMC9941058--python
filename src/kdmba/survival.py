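"""Association of age acceleration with all-cause mortality.

Cox proportional-hazards models with stratum-specific baseline hazards
(jointly stratified by 5-year age band, study area, and cohort group where
applicable), Efron tie handling, and either chronological age as the
underlying time scale (delayed entry at baseline CA) or time-on-study.
Subgroup fits, product-term likelihood-ratio interaction tests, and
person-year event summaries round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._coxfit import fit_cox, schoenfeld_trend_test
from .config import GROUPS

_MIN_FOLLOWUP = 1e-6  # avoid zero-length risk intervals


@dataclass
class CoxSpec:
    """Specification of one proportional-hazards model."""

    exposure: str = "aa"
    covariates: list[str] = field(default_factory=lambda: ["sex", "fasting_8h", "education"])
    strata: list[str] = field(default_factory=lambda: ["age_band_5yr", "area", "group"])
    time_scale: str = "attained-age"  # or "time-on-study"

    def __post_init__(self) -> None:
        if self.time_scale not in ("attained-age", "time-on-study"):
            raise ValueError(f"unknown time scale {self.time_scale!r}")


@dataclass
class CoxResult:
    """Wald summary for the exposure coefficient of one fitted model."""

    log_hr: float
    se: float
    hr: float
    ci95: tuple[float, float]
    loglik: float
    n: int
    events: int

    @classmethod
    def from_fit(cls, cph: "FittedCox", exposure: str, n: int, events: int) -> "CoxResult":
        b = float(cph.params_[exposure])
        se = float(cph.standard_errors_[exposure])
        return cls(
            log_hr=b,
            se=se,
            hr=float(np.exp(b)),
            ci95=(float(np.exp(b - 1.959964 * se)), float(np.exp(b + 1.959964 * se))),
            loglik=float(cph.log_likelihood_),
            n=n,
            events=events,
        )


# ---------------------------------------------------------------------------
# model-frame construction
# ---------------------------------------------------------------------------

def age_band_5yr(ca: pd.Series) -> pd.Series:
    """5-year age bands as strings ('30-34', ..., '75-79')."""
    lo = (np.floor(ca / 5.0) * 5).astype(int)
    return pd.Series([f"{a}-{a + 4}" for a in lo], index=ca.index, name="age_band_5yr")


def add_derived_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add the analysis columns models refer to (age bands, fasting flag)."""
    out = cohort.copy()
    if "age_band_5yr" not in out.columns and "ca" in out.columns:
        out["age_band_5yr"] = age_band_5yr(out["ca"])
    if "fasting_8h" not in out.columns and "fasting_hours" in out.columns:
        out["fasting_8h"] = out["fasting_hours"] >= 8.0
    return out


def _dummify(df: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Expand non-numeric covariates into drop-first dummies."""
    keep: list[str] = []
    out = {}
    for c in columns:
        col = df[c]
        if col.dtype == bool:
            out[c] = col.astype(float)
            keep.append(c)
        elif pd.api.types.is_numeric_dtype(col):
            out[c] = col.astype(float)
            keep.append(c)
        else:
            d = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            for dc in d.columns:
                out[dc] = d[dc]
                keep.append(dc)
    return pd.DataFrame(out, index=df.index), keep


def build_model_frame(
    cohort: pd.DataFrame, spec: CoxSpec, extra_covariates: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the solver input frame for a spec.

    Returns (frame, covariate column names); the frame carries duration/event
    (plus entry for the attained-age scale) and stratum columns.
    """
    df = add_derived_columns(cohort)
    cov_frame, cov_cols = _dummify(df, [spec.exposure] + list(spec.covariates))
    frame = cov_frame
    if extra_covariates is not None:
        frame = pd.concat([frame, extra_covariates], axis=1)
        cov_cols = cov_cols + list(extra_covariates.columns)

    fu = df["followup_years"].clip(lower=_MIN_FOLLOWUP)
    if spec.time_scale == "attained-age":
        frame["entry"] = df["ca"].astype(float)
        frame["duration"] = df["ca"].astype(float) + fu
    else:
        frame["duration"] = fu
    frame["event"] = df["died"].astype(bool)
    for s in spec.strata:
        if s not in df.columns:
            raise KeyError(f"stratum factor {s!r} absent from cohort")
        frame[s] = df[s].astype(str)
    return frame, cov_cols


def _check_identifiable(frame: pd.DataFrame, spec: CoxSpec, exposure: str) -> None:
    strata = spec.strata or []
    if strata:
        nun = frame.groupby(strata, observed=True)[exposure].nunique()
        if (nun <= 1).all():
            raise ValueError("exposure is constant within every stratum; not identifiable")
    elif frame[exposure].nunique() <= 1:
        raise ValueError("exposure is constant; not identifiable")


class FittedCox:
    """A fitted stratified Cox model (in-package Newton/Efron solver)."""

    def __init__(self, frame: pd.DataFrame, spec: CoxSpec, cov_cols: list[str]):
        entry = frame["entry"].to_numpy(dtype=float) if "entry" in frame.columns else None
        if spec.strata:
            sid = pd.factorize(
                frame[spec.strata].astype(str).agg("|".join, axis=1), sort=True
            )[0]
        else:
            sid = None
        # a column constant within every stratum is absorbed by the stratified
        # baseline and carries no partial-likelihood information: drop it
        self.dropped_cols: list[str] = []
        kept: list[str] = []
        for c in cov_cols:
            v = frame[c].groupby(sid).nunique() if sid is not None else frame[c].nunique()
            informative = (v > 1).any() if sid is not None else v > 1
            (kept if informative else self.dropped_cols).append(c)
        self.cov_cols = kept
        x = frame[self.cov_cols].to_numpy(dtype=float)
        self._args = (x, frame["duration"].to_numpy(dtype=float),
                      frame["event"].to_numpy(dtype=bool), entry, sid)
        beta, cov, ll = fit_cox(x, *self._args[1:3], entry=entry, strata_ids=sid)
        self.params_ = pd.Series(beta, index=self.cov_cols)
        diag = np.diag(cov).copy() if len(cov) else np.zeros(0)
        diag[diag <= 0] = np.nan  # unidentified directions
        self.standard_errors_ = pd.Series(np.sqrt(diag), index=self.cov_cols)
        self.covariance_ = cov
        self.log_likelihood_ = ll

    def schoenfeld_p(self, column: str) -> float:
        x, dur, evt, entry, sid = self._args
        return schoenfeld_trend_test(
            x, dur, evt, self.params_.to_numpy(), entry=entry, strata_ids=sid,
            column=self.cov_cols.index(column),
        )


def _fit(frame: pd.DataFrame, spec: CoxSpec, cov_cols: list[str]) -> FittedCox:
    return FittedCox(frame, spec, cov_cols)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_stratified_cox(cohort: pd.DataFrame, spec: CoxSpec) -> CoxResult:
    """Partial-likelihood estimate of the exposure log-hazard ratio."""
    frame, cov_cols = build_model_frame(cohort, spec)
    _check_identifiable(frame, spec, spec.exposure)
    cph = _fit(frame, spec, cov_cols)
    return CoxResult.from_fit(cph, spec.exposure, n=len(frame), events=int(frame["event"].sum()))


def subgroup_hr(
    cohort: pd.DataFrame, spec: CoxSpec, stratifier: str
) -> dict[str, CoxResult | None]:
    """Independent exposure fits within each level of a stratifying factor.

    A level with zero events is reported as None rather than raising.
    """
    df = add_derived_columns(cohort)
    if stratifier not in df.columns:
        raise KeyError(f"stratifier {stratifier!r} absent from cohort")
    out: dict[str, CoxResult | None] = {}
    for level, sub in df.groupby(df[stratifier].astype(str)):
        if int(sub["died"].sum()) == 0:
            out[level] = None
            continue
        out[level] = fit_stratified_cox(sub, spec)
    return out


def interaction_test(
    cohort: pd.DataFrame, spec: CoxSpec, stratifier: str
) -> tuple[float, float]:
    """Likelihood-ratio test for exposure-by-factor product terms.

    Compares nested models with and without exposure x level products (level
    main effects in both); statistic ~ chi-square with (levels - 1) degrees
    of freedom under the null of a common exposure effect.
    """
    df = add_derived_columns(cohort)
    if stratifier not in df.columns:
        raise KeyError(f"stratifier {stratifier!r} absent from cohort")
    levels = pd.get_dummies(df[stratifier].astype(str), prefix=stratifier, drop_first=True, dtype=float)
    dof = levels.shape[1]
    if dof == 0:
        raise ValueError("stratifier has a single level; no product terms to test")

    base_cov = levels if stratifier not in spec.covariates else None
    frame_red, cols_red = build_model_frame(cohort, spec, extra_covariates=base_cov)
    _check_identifiable(frame_red, spec, spec.exposure)
    ll_red = float(_fit(frame_red, spec, cols_red).log_likelihood_)

    exposure = df[spec.exposure].astype(float)
    products = levels.mul(exposure, axis=0)
    products.columns = [f"{c}_x_{spec.exposure}" for c in levels.columns]
    extra_full = pd.concat([levels, products], axis=1) if base_cov is not None else products
    frame_full, cols_full = build_model_frame(cohort, spec, extra_covariates=extra_full)
    ll_full = float(_fit(frame_full, spec, cols_full).log_likelihood_)

    lrt = max(2.0 * (ll_full - ll_red), 0.0)
    p = float(stats.chi2.sf(lrt, df=dof))
    return lrt, p


def check_proportional_hazards(cohort: pd.DataFrame, spec: CoxSpec) -> float:
    """Scaled-Schoenfeld-residual trend test p-value for the exposure.

    Reported for diagnostics only; the pipeline never acts on it.
    """
    frame, cov_cols = build_model_frame(cohort, spec)
    cph = _fit(frame, spec, cov_cols)
    return cph.schoenfeld_p(spec.exposure)


def event_summary(cohort: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Per-group mortality rate (per 1000 person-years) and follow-up summary.

    Rate = 1000 * events / total person-years; median and IQR describe the
    follow-up time to death or censoring.
    """
    rows = []
    df = cohort
    groups = [("all", df)] + [(g, df[df[by] == g]) for g in GROUPS if (df[by] == g).any()]
    for label, sub in groups:
        py = float(sub["followup_years"].sum())
        if py <= 0:
            raise ValueError(f"zero person-years in group {label!r}")
        t = sub["followup_years"]
        rows.append(
            {
                "group": label,
                "n": len(sub),
                "events": int(sub["died"].sum()),
                "person_years": py,
                "rate_per_1000py": 1000.0 * sub["died"].sum() / py,
                "median_years": float(t.median()),
                "iqr_years": float(t.quantile(0.75) - t.quantile(0.25)),
            }
        )
    return pd.DataFrame(rows).set_index("group")
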