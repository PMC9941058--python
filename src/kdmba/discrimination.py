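"""Discrimination of 10-year mortality: Harrell's C and binary NRI.

Compares prediction models with and without age acceleration.  Risks come
from time-on-study Cox models stratified by study area and cohort group,
with the stratum-specific Breslow baseline survival evaluated at 10 years:
``risk_i = 1 - S0_stratum(10) ** exp(lp_i)``.  Harrell's C uses the original
pairwise definition over the full follow-up with half credit for risk ties;
the net reclassification improvement is the two-category version at a 50%
predicted-risk threshold, with subjects censored before 10 years (without
death) excluded from the classification table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import CoxSpec, _fit, build_model_frame

RISK_HORIZON_YEARS = 10.0


@dataclass
class RiskPrediction:
    """Per-subject predicted 10-year mortality probability for one model."""

    label: str
    risk: pd.Series  # in [0, 1]; NaN where the stratum has no 10-year information

    def __post_init__(self) -> None:
        ok = self.risk.dropna()
        if ((ok < 0) | (ok > 1)).any():
            raise ValueError("predicted risks must lie in [0, 1]")


@dataclass
class DiscriminationResult:
    """C-index for a model pair plus NRI, each with a bootstrap 95% CI."""

    c_ref: float
    c_ref_ci: tuple[float, float]
    c_new: float
    c_new_ci: tuple[float, float]
    nri: float
    nri_ci: tuple[float, float]
    threshold: float
    n: int
    events: int


# ---------------------------------------------------------------------------
# risk prediction
# ---------------------------------------------------------------------------

def predict_risk_10yr(
    cohort: pd.DataFrame,
    spec: CoxSpec,
    label: str = "model",
    horizon: float = RISK_HORIZON_YEARS,
) -> RiskPrediction:
    """Fit a time-on-study Cox model and convert it to 10-year risks.

    The Breslow baseline cumulative hazard is accumulated per stratum at the
    uncentred linear predictor, so ``risk = 1 - exp(-H0_s(t) * exp(lp))`` is
    internally consistent.  Members of a stratum whose follow-up never
    reaches the horizon get NaN risk.
    """
    if spec.time_scale != "time-on-study":
        raise ValueError("risk prediction requires a time-on-study spec")
    frame, cov_cols = build_model_frame(cohort, spec)
    cph = _fit(frame, spec, cov_cols)
    beta = cph.params_.reindex(cov_cols).fillna(0.0).to_numpy()
    lp = frame[cov_cols].to_numpy(dtype=float) @ beta

    strata = spec.strata or []
    if strata:
        group_ids = frame[strata].astype(str).agg("|".join, axis=1)
    else:
        group_ids = pd.Series("all", index=frame.index)

    risk = np.full(len(frame), np.nan)
    dur = frame["duration"].to_numpy(dtype=float)
    evt = frame["event"].to_numpy(dtype=bool)
    for _, idx in pd.Series(np.arange(len(frame)), index=group_ids.to_numpy()).groupby(level=0):
        rows = idx.to_numpy()
        t, e, xb = dur[rows], evt[rows], lp[rows]
        if t.max() < horizon:
            continue  # no baseline information at the horizon
        h0 = _breslow_cumhaz(t, e, xb, horizon)
        risk[rows] = 1.0 - np.exp(-h0 * np.exp(xb))
    return RiskPrediction(label=label, risk=pd.Series(risk, index=cohort.index, name=label))


def _breslow_cumhaz(t: np.ndarray, e: np.ndarray, lp: np.ndarray, horizon: float) -> float:
    """Breslow baseline cumulative hazard at `horizon` within one stratum."""
    w = np.exp(lp)
    order = np.argsort(t)
    t, e, w = t[order], e[order], w[order]
    # risk-set sums: subjects with time >= t_k
    cum_from_right = np.cumsum(w[::-1])[::-1]
    h0 = 0.0
    i = 0
    n = len(t)
    while i < n and t[i] <= horizon:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += int(e[j])
            j += 1
        if d > 0:
            h0 += d / cum_from_right[i]
        i = j
    return h0


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def harrell_c(time: np.ndarray, event: np.ndarray, risk: np.ndarray) -> float:
    """Harrell's concordance index.

    Usable pairs: i died at t_i while j was still at risk (t_j > t_i, or
    t_j == t_i with j censored).  Concordant when risk_i > risk_j; risk ties
    earn half credit.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    r = np.asarray(risk, dtype=float)
    if len(t) < 2:
        raise ValueError("need n >= 2")
    if not e.any():
        raise ValueError("no events; concordance undefined")
    conc = ties = usable = 0.0
    ev = np.flatnonzero(e)
    for i in ev:
        at_risk = (t > t[i]) | ((t == t[i]) & ~e)
        at_risk[i] = False
        m = int(at_risk.sum())
        if m == 0:
            continue
        usable += m
        conc += float((r[i] > r[at_risk]).sum())
        ties += float((r[i] == r[at_risk]).sum())
    if usable == 0:
        raise ValueError("no usable pairs")
    return (conc + 0.5 * ties) / usable


# ---------------------------------------------------------------------------
# NRI
# ---------------------------------------------------------------------------

def status_10yr(time: np.ndarray, event: np.ndarray, horizon: float = RISK_HORIZON_YEARS) -> np.ndarray:
    """10-year status: 1 died within horizon, 0 survived past it, NaN if
    censored earlier without death (excluded from the NRI table)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    out = np.full(len(t), np.nan)
    out[t >= horizon] = 0.0
    # a death exactly at the horizon counts as an event, not a survivor
    out[(t <= horizon) & e] = 1.0
    return out


def nri_binary(
    risk_ref: np.ndarray,
    risk_new: np.ndarray,
    status: np.ndarray,
    threshold: float = 0.50,
) -> float:
    """Two-category net reclassification improvement at a risk threshold.

    NRI = [P(up|event) - P(down|event)] - [P(up|non-event) - P(down|non-event)]
    where up/down means crossing the threshold between the reference and new
    model.  ``status`` entries of NaN are dropped.
    """
    r0 = np.asarray(risk_ref, dtype=float)
    r1 = np.asarray(risk_new, dtype=float)
    st = np.asarray(status, dtype=float)
    keep = ~np.isnan(st) & ~np.isnan(r0) & ~np.isnan(r1)
    r0, r1, st = r0[keep], r1[keep], st[keep]
    ev = st == 1.0
    if not ev.any() or ev.all():
        raise ValueError("NRI needs both events and non-events")
    up = (r0 < threshold) & (r1 >= threshold)
    down = (r0 >= threshold) & (r1 < threshold)
    p_up_e = up[ev].mean()
    p_dn_e = down[ev].mean()
    p_up_ne = up[~ev].mean()
    p_dn_ne = down[~ev].mean()
    return float((p_up_e - p_dn_e) - (p_up_ne - p_dn_ne))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    statistic,
    cohort: pd.DataFrame,
    reps: int = 200,
    seed: int = 0,
    stratify_by: str | None = "group",
    max_failures: float = 0.10,
) -> tuple[float, float]:
    """Percentile 2.5/97.5 bounds of a statistic over subject resamples.

    Resampling is nonparametric at the subject level, stratified by cohort
    group by default to preserve the sampling design.  ``statistic`` takes a
    resampled DataFrame and returns a float; resamples where it raises are
    dropped, but more than ``max_failures`` of them is an error.
    """
    if reps < 50:
        raise ValueError("need reps >= 50")
    rng = np.random.default_rng(seed)
    if stratify_by is not None and stratify_by in cohort.columns:
        blocks = [np.flatnonzero(cohort[stratify_by].to_numpy() == g)
                  for g in pd.unique(cohort[stratify_by])]
    else:
        blocks = [np.arange(len(cohort))]
    vals = []
    failures = 0
    for _ in range(reps):
        rows = np.concatenate([b[rng.integers(0, len(b), size=len(b))] for b in blocks])
        sample = cohort.iloc[rows].reset_index(drop=True)
        try:
            vals.append(float(statistic(sample)))
        except Exception:
            failures += 1
    if failures > max_failures * reps:
        raise RuntimeError(f"statistic failed on {failures}/{reps} resamples")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# model-pair comparison
# ---------------------------------------------------------------------------

def compare_models(
    cohort: pd.DataFrame,
    spec_ref: CoxSpec,
    spec_new: CoxSpec,
    threshold: float = 0.50,
    reps: int = 200,
    seed: int = 0,
    horizon: float = RISK_HORIZON_YEARS,
) -> DiscriminationResult:
    """C-index of both models and the NRI of new vs reference, with CIs."""

    def _metrics(df: pd.DataFrame) -> tuple[float, float, float]:
        r0 = predict_risk_10yr(df, spec_ref, "ref", horizon).risk.to_numpy()
        r1 = predict_risk_10yr(df, spec_new, "new", horizon).risk.to_numpy()
        t = df["followup_years"].to_numpy(dtype=float)
        e = df["died"].to_numpy(dtype=bool)
        ok = ~np.isnan(r0) & ~np.isnan(r1)
        c0 = harrell_c(t[ok], e[ok], r0[ok])
        c1 = harrell_c(t[ok], e[ok], r1[ok])
        nri = nri_binary(r0, r1, status_10yr(t, e, horizon), threshold)
        return c0, c1, nri

    c0, c1, nri = _metrics(cohort)

    # one resampling pass covering all three statistics
    rng = np.random.default_rng(seed)
    blocks = [
        np.flatnonzero(cohort["group"].to_numpy() == g) for g in pd.unique(cohort["group"])
    ] if "group" in cohort.columns else [np.arange(len(cohort))]
    draws: list[tuple[float, float, float]] = []
    failures = 0
    for _ in range(reps):
        rows = np.concatenate([b[rng.integers(0, len(b), size=len(b))] for b in blocks])
        try:
            draws.append(_metrics(cohort.iloc[rows].reset_index(drop=True)))
        except Exception:
            failures += 1
    if failures > 0.10 * reps:
        raise RuntimeError(f"discrimination metrics failed on {failures}/{reps} resamples")
    arr = np.asarray(draws)
    c0_ci, c1_ci, nri_ci = (
        tuple(np.percentile(arr[:, j], [2.5, 97.5]).astype(float)) for j in range(3)
    )
    return DiscriminationResult(
        c_ref=c0,
        c_ref_ci=c0_ci,
        c_new=c1,
        c_new_ci=c1_ci,
        nri=nri,
        nri_ci=nri_ci,
        threshold=threshold,
        n=len(cohort),
        events=int(cohort["died"].sum()),
    )
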