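"""Klemera-Doubal biological age (KDM-BA) and age acceleration.

The estimator treats each marker (here: each principal component of the
screened marker panel) as a noisy linear readout of biological age,
``x_j = q_j + k_j * BA + Normal(0, s_j^2)``, fitted by regressing the
component on chronological age (CA).  The uncorrected estimate is the
inverse-variance-weighted inversion

    BA_E = sum_j (x_j - q_j) k_j / s_j^2  /  sum_j k_j^2 / s_j^2,

and the corrected estimate adds CA itself as one more composite marker whose
noise variance is s_BA^2, the estimated population variance of true
biological age around CA:

    BA_EC = [ sum_j (x_j - q_j) k_j / s_j^2 + CA / s_BA^2 ]
            / [ sum_j k_j^2 / s_j^2 + 1 / s_BA^2 ].

s_BA^2 is estimated as Var(BA_E - CA) minus a sampling-noise term driven by
the characteristic marker-age correlation r_char (root-mean-square of the
component correlations by default) and the CA range.  Age acceleration (AA)
is the residual of BA regressed on CA; positive AA means aging faster than
same-aged peers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class KDMModel:
    """One sex's fitted KDM-BA construction, sufficient to score new data."""

    sex: str
    retained_markers: list[str]
    candidate_correlations: dict[str, float]
    means: np.ndarray          # per retained marker, fitting sample
    sds: np.ndarray
    loadings: np.ndarray       # markers x components, orthonormal columns
    eigenvalues: np.ndarray
    q: np.ndarray              # per-component intercept (component units)
    k: np.ndarray              # slope (component units / year)
    s: np.ndarray              # residual SD (component units)
    r: np.ndarray              # component-CA Pearson correlation
    r_char: float
    s_ba2: float               # years^2
    ca_range: tuple[float, float]
    s_ba2_floored: bool = False

    @property
    def m(self) -> int:
        return len(self.q)

    def transform(self, cohort: pd.DataFrame) -> np.ndarray:
        """Standardize this model's markers and project onto its loadings."""
        missing = [c for c in self.retained_markers if c not in cohort.columns]
        if missing:
            raise KeyError(f"marker columns absent from cohort: {missing}")
        x = cohort[self.retained_markers].to_numpy(dtype=float)
        z = (x - self.means) / self.sds
        return z @ self.loadings

    # round-trippable plain-text serialization
    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("means", "sds", "loadings", "eigenvalues", "q", "k", "s", "r"):
            d[key] = np.asarray(d[key]).tolist()
        d["ca_range"] = list(self.ca_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KDMModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("means", "sds", "loadings", "eigenvalues", "q", "k", "s", "r"):
            d[key] = np.asarray(d[key], dtype=float)
        d["ca_range"] = tuple(d["ca_range"])
        return cls(**d)


@dataclass
class AAModel:
    """The BA-on-CA regression defining age acceleration."""

    intercept: float
    slope: float
    aa_sd: float  # SD of AA within the fitting pool, years

    def residuals(self, ba: np.ndarray, ca: np.ndarray) -> np.ndarray:
        return np.asarray(ba) - (self.intercept + self.slope * np.asarray(ca))


@dataclass
class BAResult:
    """Per-subject biological age, age acceleration, and standardized AA."""

    ba: pd.Series
    aa: pd.Series
    aa_standardized: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ba": self.ba, "aa": self.aa, "aa_standardized": self.aa_standardized}
        )


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _half_split_monotone(x: np.ndarray, ca: np.ndarray) -> bool:
    """Deterministic monotonicity check: OLS slopes on the two CA halves.

    Non-monotone when the slopes differ in sign and each is significant at
    the two-sided 0.05 level.
    """
    med = np.median(ca)
    lo, hi = ca <= med, ca > med
    if lo.sum() < 3 or hi.sum() < 3:
        return True
    f_lo = stats.linregress(ca[lo], x[lo])
    f_hi = stats.linregress(ca[hi], x[hi])
    opposite = np.sign(f_lo.slope) * np.sign(f_hi.slope) < 0
    return not (opposite and f_lo.pvalue < 0.05 and f_hi.pvalue < 0.05)


def screen_markers(
    cohort: pd.DataFrame,
    marker_columns: list[str],
    ca_col: str = "ca",
    threshold: float = 0.10,
) -> tuple[list[str], dict[str, float]]:
    """Retain markers with |Pearson r vs CA| > threshold and a monotone
    age response; report the correlation of every candidate.

    Zero-variance markers are excluded with a warning rather than an error.
    """
    if len(marker_columns) < 2:
        raise ValueError("need at least 2 candidate markers")
    ca = cohort[ca_col].to_numpy(dtype=float)
    retained: list[str] = []
    corr: dict[str, float] = {}
    for m in marker_columns:
        x = cohort[m].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"marker {m!r} has zero variance; excluded", stacklevel=2)
            corr[m] = np.nan
            continue
        r = float(stats.pearsonr(x, ca).statistic)
        corr[m] = r
        if abs(r) > threshold and _half_split_monotone(x, ca):
            retained.append(m)
    return retained, corr


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(
    cohort: pd.DataFrame,
    marker_columns: list[str],
    rank_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Correlation-matrix PCA of the retained markers.

    Markers are standardized to zero mean / unit SD, the correlation matrix
    eigendecomposed, and components beyond numerical rank dropped.  Returns
    ``(loadings, eigenvalues, scores, means, sds)`` with orthonormal loading
    columns, eigenvalues non-increasing, and ``scores = Z @ loadings``.
    """
    x = cohort[marker_columns].to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need n > number of markers ({n} <= {p})")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [m for m, s in zip(marker_columns, sds) if s == 0]
        raise ValueError(f"zero-variance markers cannot enter PCA: {bad}")
    z = (x - means) / sds
    corr = (z.T @ z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rank_tol * max(evals[0], 1.0)
    evals, evecs = evals[keep], evecs[:, keep]
    # deterministic sign: largest-|.| loading entry positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = z @ evecs
    return evecs, evals, scores, means, sds


# ---------------------------------------------------------------------------
# KDM fit
# ---------------------------------------------------------------------------

def _ols_on_ca(x: np.ndarray, ca: np.ndarray) -> tuple[float, float, float, float]:
    """Per-component regression on CA: (q, k, s, r)."""
    vca = np.var(ca)
    if vca == 0:
        raise ValueError("CA has no variation")
    k = float(np.cov(x, ca, ddof=0)[0, 1] / vca)
    q = float(np.mean(x) - k * np.mean(ca))
    resid = x - (q + k * ca)
    dof = max(len(x) - 2, 1)
    s = float(np.sqrt(np.sum(resid**2) / dof))
    sx = np.std(x)
    r = float(k * np.sqrt(vca) / sx) if sx > 0 else 0.0
    return q, k, s, r


def fit_kdm(
    scores: np.ndarray,
    ca: np.ndarray,
    *,
    sex: str = "all",
    retained_markers: list[str] | None = None,
    candidate_correlations: dict[str, float] | None = None,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
    loadings: np.ndarray | None = None,
    eigenvalues: np.ndarray | None = None,
    r_char_mode: str = "rms",
    s_ba2_mode: str = "plugin",
    s_ba2_floor: float = 0.01,
    component_threshold: float | None = None,
) -> KDMModel:
    """Fit the KDM parameters on component scores against CA.

    Each component is regressed on CA for (q_j, k_j, s_j, r_j); r_char is the
    root-mean-square of r_j by default ("mean_abs" is available).

    s_BA^2 estimates the population variance of true biological age around
    CA.  The default ``s_ba2_mode="plugin"`` takes Var(BA_E - CA) directly:
    a conservative upper bound (it retains the sampling noise of BA_E) that
    is always positive and keeps the corrected estimator well defined.  Two
    noise-subtracting modes are available: ``"information"`` subtracts the
    closed-form noise variance ``1 / sum_j k_j^2 / s_j^2`` and ``"kd"``
    subtracts the classical approximation
    ``(1 - r_char^2)/r_char^2 * range(CA)^2 / (12 m)``.  Both are exact only
    when components are comparably informative; because each s_j already
    contains the latent-aging signal, they can cancel it entirely when one
    component dominates, so they are opt-in.  The estimate is floored at
    ``s_ba2_floor`` (flagged on the model when the floor binds).  ``component_threshold``
    optionally re-screens components by |r_j| the same way markers are
    screened (off by default).
    """
    scores = np.asarray(scores, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 1:
        raise ValueError("scores must be a 2-D array with >= 1 component")
    p = scores.shape[1]

    params = np.array([_ols_on_ca(scores[:, j], ca) for j in range(p)])
    q, k, s, r = (params[:, i].copy() for i in range(4))
    s = np.maximum(s, 1e-12)  # guard exact-zero residuals

    keep = np.ones(p, dtype=bool)
    if component_threshold is not None:
        keep = np.abs(r) > component_threshold
        if not keep.any():
            raise ValueError("component screening removed every component")
    if np.all(k[keep] == 0):
        raise ValueError("all component slopes are zero; KDM is degenerate")

    q, k, s, r = q[keep], k[keep], s[keep], r[keep]
    m = keep.sum()
    loadings_kept = loadings[:, keep] if loadings is not None else np.eye(p)[:, keep]
    eig_kept = eigenvalues[keep] if eigenvalues is not None else np.ones(m)

    ba_e = _ba_uncorrected(scores[:, keep], q, k, s)
    if r_char_mode == "rms":
        r_char = float(np.sqrt(np.mean(r**2)))
    elif r_char_mode == "mean_abs":
        r_char = float(np.mean(np.abs(r)))
    else:
        raise ValueError(f"unknown r_char_mode {r_char_mode!r}")
    r_char = min(max(r_char, 1e-6), 1.0)

    ca_min, ca_max = float(ca.min()), float(ca.max())
    if s_ba2_mode == "plugin":
        noise_term = 0.0
    elif s_ba2_mode == "information":
        noise_term = 1.0 / float(np.sum(k**2 / s**2))
    elif s_ba2_mode == "kd":
        noise_term = ((1.0 - r_char**2) / r_char**2) * (ca_max - ca_min) ** 2 / (12.0 * m)
    else:
        raise ValueError(f"unknown s_ba2_mode {s_ba2_mode!r}")
    s_ba2_raw = float(np.var(ba_e - ca) - noise_term)
    floored = s_ba2_raw < s_ba2_floor
    if floored:
        warnings.warn(
            f"s_BA^2 estimate {s_ba2_raw:.4g} floored at {s_ba2_floor}", stacklevel=2
        )
    s_ba2 = max(s_ba2_raw, s_ba2_floor)

    nmark = loadings_kept.shape[0]
    return KDMModel(
        sex=sex,
        retained_markers=retained_markers or [f"m{i}" for i in range(nmark)],
        candidate_correlations=candidate_correlations or {},
        means=means if means is not None else np.zeros(nmark),
        sds=sds if sds is not None else np.ones(nmark),
        loadings=loadings_kept,
        eigenvalues=eig_kept,
        q=q,
        k=k,
        s=s,
        r=r,
        r_char=r_char,
        s_ba2=s_ba2,
        ca_range=(ca_min, ca_max),
        s_ba2_floored=bool(floored),
    )


def _ba_uncorrected(scores, q, k, s) -> np.ndarray:
    w = k / s**2
    return (scores - q) @ w / np.sum(k * w)


def estimate_ba(model: KDMModel, scores: np.ndarray, ca: np.ndarray) -> pd.Series:
    """Corrected KDM biological age BA_EC, in years.

    Tends to the uncorrected BA_E as s_BA^2 -> infinity and to CA as
    s_BA^2 -> 0.
    """
    scores = np.asarray(scores, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != model.m:
        raise ValueError(
            f"score columns ({scores.shape[1] if scores.ndim == 2 else '?'}) "
            f"do not match model components ({model.m})"
        )
    w = model.k / model.s**2
    num = (scores - model.q) @ w + ca / model.s_ba2
    den = np.sum(model.k * w) + 1.0 / model.s_ba2
    return pd.Series(num / den, name="ba")


# ---------------------------------------------------------------------------
# age acceleration & diagnostics
# ---------------------------------------------------------------------------

def compute_aa(
    ba: pd.Series,
    ca: pd.Series,
    fit_pool: pd.Series | np.ndarray | None = None,
) -> tuple[BAResult, AAModel]:
    """Age acceleration: residual of the BA-on-CA regression.

    The regression is fitted within ``fit_pool`` (default: all subjects) and
    applied to everyone; standardized AA divides by the pool SD of AA.
    Within the pool the residuals have mean 0 and zero correlation with CA by
    the OLS normal equations.
    """
    ba = pd.Series(np.asarray(ba, dtype=float), index=getattr(ba, "index", None), name="ba")
    ca_arr = np.asarray(ca, dtype=float)
    mask = np.ones(len(ba), dtype=bool) if fit_pool is None else np.asarray(fit_pool, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 subjects in the AA fitting pool")
    ca_p, ba_p = ca_arr[mask], ba.to_numpy()[mask]
    if np.var(ca_p) == 0:
        raise ValueError("CA is constant within the fitting pool")
    slope = float(np.cov(ba_p, ca_p, ddof=0)[0, 1] / np.var(ca_p))
    intercept = float(np.mean(ba_p) - slope * np.mean(ca_p))
    aa = ba.to_numpy() - (intercept + slope * ca_arr)
    aa_sd = float(np.std(aa[mask], ddof=1))
    if aa_sd == 0:
        aa_sd = 1.0  # degenerate noiseless fit: AA identically zero
    model = AAModel(intercept=intercept, slope=slope, aa_sd=aa_sd)
    res = BAResult(
        ba=ba,
        aa=pd.Series(aa, index=ba.index, name="aa"),
        aa_standardized=pd.Series(aa / aa_sd, index=ba.index, name="aa_standardized"),
    )
    return res, model


def ba_diagnostics(ba: pd.Series, ca: pd.Series) -> tuple[float, float]:
    """(Pearson r between BA and CA, RMSE in years of regressing CA on BA)."""
    ba = np.asarray(ba, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if len(ba) < 3:
        raise ValueError("need n >= 3")
    if np.std(ba) == 0 or np.std(ca) == 0:
        raise ValueError("constant input vector")
    r = float(stats.pearsonr(ba, ca).statistic)
    slope = float(np.cov(ca, ba, ddof=0)[0, 1] / np.var(ba))
    intercept = float(np.mean(ca) - slope * np.mean(ba))
    resid = ca - (intercept + slope * ba)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return r, rmse


def project_control_model(
    model: KDMModel,
    aa_model: AAModel,
    cohort: pd.DataFrame,
    ca_col: str = "ca",
) -> BAResult:
    """Score a cohort with a model fitted elsewhere (e.g., on controls only).

    Markers are standardized with the fitting sample's means/SDs, projected
    through its loadings, BA_EC evaluated with its parameters, and AA taken
    from its BA-on-CA regression (standardized by its pool AA SD).
    """
    scores = model.transform(cohort)
    ca = cohort[ca_col].to_numpy(dtype=float)
    ba = estimate_ba(model, scores, ca)
    ba.index = cohort.index
    aa = aa_model.residuals(ba.to_numpy(), ca)
    return BAResult(
        ba=ba,
        aa=pd.Series(aa, index=cohort.index, name="aa"),
        aa_standardized=pd.Series(aa / aa_model.aa_sd, index=cohort.index, name="aa_standardized"),
    )


# ---------------------------------------------------------------------------
# sex-stratified front door
# ---------------------------------------------------------------------------

@dataclass
class SexStratifiedFit:
    """Per-sex KDM models plus cohort-aligned BA/AA."""

    models: dict[str, KDMModel]
    result: BAResult
    aa_model: AAModel
    screening: dict[str, dict[str, float]] = field(default_factory=dict)


def fit_biological_age(
    cohort: pd.DataFrame,
    marker_columns: list[str],
    ca_col: str = "ca",
    sex_col: str = "sex",
    threshold: float = 0.10,
    by_sex: bool = True,
    aa_fit_pool: pd.Series | np.ndarray | None = None,
    r_char_mode: str = "rms",
    s_ba2_mode: str = "plugin",
    pc_cap: int | None = None,
    component_threshold: float | None = None,
) -> SexStratifiedFit:
    """Screen markers, fit correlation-matrix PCA and the KDM estimator per
    sex, and derive age acceleration on the pooled cohort.

    ``aa_fit_pool`` restricts the BA-on-CA regression (e.g., to controls for
    the control-derived sensitivity construction); AA is still evaluated for
    every subject.
    """
    groups = cohort.groupby(cohort[sex_col]) if by_sex else [("all", cohort)]
    ba = pd.Series(np.nan, index=cohort.index, name="ba")
    models: dict[str, KDMModel] = {}
    screening: dict[str, dict[str, float]] = {}
    for sex, sub in groups:
        retained, corr = screen_markers(sub, marker_columns, ca_col, threshold)
        if not retained:
            raise ValueError(f"no markers retained for sex={sex!r}")
        loadings, evals, scores, means, sds = fit_pca(sub, retained)
        if pc_cap is not None:
            loadings, evals, scores = loadings[:, :pc_cap], evals[:pc_cap], scores[:, :pc_cap]
        ca = sub[ca_col].to_numpy(dtype=float)
        model = fit_kdm(
            scores,
            ca,
            sex=str(sex),
            retained_markers=retained,
            candidate_correlations=corr,
            means=means,
            sds=sds,
            loadings=loadings,
            eigenvalues=evals,
            r_char_mode=r_char_mode,
            s_ba2_mode=s_ba2_mode,
            component_threshold=component_threshold,
        )
        models[str(sex)] = model
        screening[str(sex)] = corr
        ba.loc[sub.index] = estimate_ba(model, model.transform(sub), ca).to_numpy()

    result, aa_model = compute_aa(ba, cohort[ca_col], fit_pool=aa_fit_pool)
    return SexStratifiedFit(models=models, result=result, aa_model=aa_model, screening=screening)
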