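"""Synthetic cohort generation.

Generates seeded participant tables with the latent-aging structure the
biological-age analysis assumes: per-group latent age acceleration
``delta ~ Normal(group mean, aa_sd^2)``, markers linear in latent biological
age ``BA = CA + delta`` with marker-specific noise, all-cause mortality from a
proportional-hazards model multiplicative in ``delta``, administrative
censoring, and the categorical covariates the downstream models adjust for.
Ground truth (latent delta, BA, hazard multiplier) is returned alongside for
recovery tests.

All marker distributions are synthetic stand-ins shaped like a clinical
panel; no real cohort's assay values are reproduced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    EXCLUSION_CATEGORIES,
    GROUPS,
    MarkerSpec,
    SimulationConfig,
)

DIET_LEVELS = ("never_rarely", "monthly", "1_3_per_week", "4_6_per_week", "daily")

#: Sampling-frame group sizes used to apportion exclusion-fixture cohorts.
FRAME_SIZES = {"control": 6341, "MCE": 1319, "IS": 5467, "ICH_SAH": 5045}


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(
    linear_predictor: np.ndarray,
    baseline_rate: float | np.ndarray,
    censor_years: float | np.ndarray,
    seed: int,
    family: str = "exponential",
    gompertz_shape: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) pairs from a proportional-hazards model.

    The hazard is ``baseline(t) * exp(linear_predictor)`` with an exponential
    (constant-rate) or Gompertz baseline, administratively censored at
    ``censor_years`` (scalar, or per-subject for staggered entry).

    Returns
    -------
    time : float array, years (``min(T, censor_years)``)
    event : bool array, True when death precedes censoring
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    rate = np.broadcast_to(np.asarray(baseline_rate, dtype=float), lp.shape)
    if np.any(rate <= 0):
        raise ValueError("baseline rate must be > 0")
    censor = np.broadcast_to(np.asarray(censor_years, dtype=float), lp.shape)
    if np.any(censor < 0):
        raise ValueError("censor_years must be >= 0")

    rng = np.random.default_rng(seed)
    e = rng.exponential(size=lp.shape)  # unit-exponential deviates
    scaled = rate * np.exp(lp)
    if family == "exponential":
        t = e / scaled
    elif family == "gompertz":
        b = gompertz_shape
        if b <= 0:
            raise ValueError("gompertz_shape must be > 0")
        # invert H(t) = scaled * (exp(b t) - 1) / b
        t = np.log1p(b * e / scaled) / b
    else:
        raise ValueError(f"unknown hazard family {family!r}")

    event = t <= censor
    time = np.minimum(t, censor)
    return time, event


def _calibrate_rate(
    target: float,
    lp: np.ndarray,
    censor: np.ndarray,
    family: str = "exponential",
    gompertz_shape: float = 0.08,
) -> float:
    """Baseline hazard whose expected events / expected person-years hits
    ``target`` for subjects with the given linear predictors and censoring.

    For an exponential baseline the expected event probability is
    ``p_i = 1 - exp(-lam * m_i * c_i)`` and expected follow-up ``p_i /
    (lam * m_i)``; the marginal rate is monotone in ``lam``, so a scalar
    root-find suffices.  With a homogeneous linear predictor the solution is
    exactly ``target``.  For a Gompertz baseline the same expectation is
    evaluated with the Gompertz survivor function.
    """
    from scipy.optimize import brentq

    m = np.exp(lp - lp.mean())
    scale = float(np.exp(lp.mean()))
    b = gompertz_shape

    def rate(lam: float) -> float:
        r = lam * m * scale
        if family == "exponential":
            p = -np.expm1(-r * censor)
            py = p / r
        else:  # gompertz: H(t) = r (e^{bt} - 1)/b, E[min(T,c)] by quadrature
            p = -np.expm1(-r * (np.expm1(b * censor)) / b)
            ts = np.linspace(0.0, 1.0, 65)[None, :] * censor[:, None]
            surv = np.exp(-r[:, None] * np.expm1(b * ts) / b)
            py = np.trapezoid(surv, ts, axis=1)
        return float(p.sum() / py.sum())

    lo_, hi_ = target * 1e-3, target * 1e3
    return float(brentq(lambda l: rate(l) - target, lo_, hi_, xtol=1e-15, rtol=1e-12))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _draw_marker(rng, spec: MarkerSpec, ba: np.ndarray) -> np.ndarray:
    """Model-scale draw for one marker; exponentiated if log-normal."""
    if spec.monotone:
        mu = spec.intercept_q + spec.slope_k * ba
    else:
        mu = spec.intercept_q + spec.slope_k * (ba - 55.0) ** 2
    noise = rng.normal(0.0, spec.noise_sd_s, size=ba.shape) if spec.noise_sd_s > 0 else 0.0
    x = mu + noise
    return np.exp(x) if spec.log_transform else x


def _draw_diet(rng, n: int, risky_p: float, risky_level: str, safe_level: str) -> np.ndarray:
    out = np.where(rng.random(n) < risky_p, risky_level, safe_level)
    return out.astype(object)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort plus its ground truth.

    Returns ``(cohort, truth)``.  ``cohort`` has one row per participant with
    demographics, raw marker values (blood-pressure columns already reflect
    the treatment-lowering of antihypertensive users; glucose appears as
    random/fasting plasma glucose columns), lifestyle fields, and follow-up.
    ``truth`` carries per-subject latent age acceleration (``true_aa``),
    latent biological age (``true_ba = ca + true_aa``) and the hazard
    multiplier ``exp(lp)``.

    Identical config and seed give identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    groups: list[str] = []
    for g in GROUPS:
        n_g = cfg.n_per_group.get(g, 0)
        groups.extend([g] * n_g)
    n = len(groups)
    if n == 0:
        raise ValueError("empty cohort: all group counts are zero")
    group = np.array(groups, dtype=object)

    lo, hi = cfg.age_range
    ca = rng.uniform(lo, hi, size=n)
    aa_mean = np.array([cfg.group_aa_mean.get(g, 0.0) for g in group])
    delta = rng.normal(aa_mean, cfg.aa_sd) if cfg.aa_sd > 0 else aa_mean.copy()
    ba = ca + delta

    sex = np.where(rng.random(n) < cfg.sex_fraction_female, "female", "male").astype(object)
    area = rng.integers(1, cfg.n_areas + 1, size=n)
    urban = area <= max(1, round(0.3 * cfg.n_areas))
    education = rng.choice(
        ["primary_or_below", "middle_or_high", "college"], size=n, p=[0.617, 0.303, 0.08]
    )

    # smoking: sex-specific current-smoking prevalence
    smoking = np.empty(n, dtype=object)
    male = sex == "male"
    u = rng.random(n)
    smoking[male] = np.select(
        [u[male] < 0.696, u[male] < 0.816], ["current", "former"], default="never"
    )
    smoking[~male] = np.select(
        [u[~male] < 0.04, u[~male] < 0.07], ["current", "former"], default="never"
    )
    quit_for_illness = (smoking == "former") & (rng.random(n) < 0.30)

    alcohol = np.where(
        male,
        rng.lognormal(np.log(10.0), 1.3, size=n),
        rng.lognormal(np.log(0.5), 1.5, size=n),
    )
    past_drinker = rng.random(n) < np.where(male, 0.05, 0.005)

    diet = {
        "diet_vegetables": _draw_diet(rng, n, 0.071, "1_3_per_week", "daily"),
        "diet_fruits": _draw_diet(rng, n, 0.871, "monthly", "daily"),
        "diet_soybean": _draw_diet(rng, n, 0.908, "1_3_per_week", "4_6_per_week"),
        "diet_fish": _draw_diet(rng, n, 0.670, "monthly", "1_3_per_week"),
    }
    # red meat risky either as daily or as less-than-weekly
    u = rng.random(n)
    diet["diet_red_meat"] = np.select(
        [u < 0.25, u < 0.497], ["daily", "monthly"], default="1_3_per_week"
    ).astype(object)

    activity = rng.lognormal(np.log(19.0) - 0.004 * (ca - 57.0), 0.35)
    antihypertensive = rng.random(n) < cfg.antihypertensive_fraction
    fasting_hours = rng.gamma(2.0, 2.35, size=n)

    cohort = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "group": group,
            "sex": sex,
            "ca": ca,
            "area": area,
            "urban": urban,
            "education": education,
            "smoking_status": smoking,
            "quit_for_illness": quit_for_illness,
            "alcohol_g_day": alcohol,
            "past_drinker": past_drinker,
            **diet,
            "total_activity": activity,
            "antihypertensive": antihypertensive,
            "fasting_hours": fasting_hours,
        }
    )

    for spec in cfg.marker_panel:
        if spec.name == "glucose":
            continue  # emitted as rpg / fpg below
        x = _draw_marker(rng, spec, ba)
        if spec.name == "sbp":
            x = np.where(antihypertensive, x - 15.0, x)
        elif spec.name == "dbp":
            x = np.where(antihypertensive, x - 10.0, x)
        cohort[spec.name] = x

    glu = next((m for m in cfg.marker_panel if m.name == "glucose"), None)
    if glu is not None:
        rpg = _draw_marker(rng, glu, ba)
        fpg = _draw_marker(rng, glu, ba)
        has_fpg = (rpg >= 7.8) & (rpg <= 11.0)
        cohort["rpg"] = rpg
        cohort["fpg"] = np.where(has_fpg, fpg, np.nan)

    mid_age = 0.5 * (lo + hi)
    lp = cfg.log_hr_per_year_aa * delta + cfg.age_log_hr * (ca - mid_age)
    for cov, beta in cfg.covariate_effects.items():
        lp = lp + beta * pd.to_numeric(cohort[cov]).to_numpy()
    censor = cfg.admin_censor_years + (
        rng.uniform(-cfg.censor_jitter_years, cfg.censor_jitter_years, size=n)
        if cfg.censor_jitter_years > 0
        else 0.0
    )
    # calibrate each group's baseline so the configured per-year rate is the
    # *marginal* events-per-person-year rate over the heterogeneous linear
    # predictors and censoring times (identity when lp is homogeneous)
    base = np.empty(n)
    for g in GROUPS:
        m = group == g
        if not m.any():
            continue
        base[m] = _calibrate_rate(
            cfg.baseline_hazard[g], lp[m], np.broadcast_to(censor, lp.shape)[m],
            family=cfg.hazard_family, gompertz_shape=cfg.gompertz_shape,
        )
    time, event = simulate_survival(
        lp,
        base,
        censor,
        seed=int(rng.integers(2**31 - 1)),
        family=cfg.hazard_family,
        gompertz_shape=cfg.gompertz_shape,
    )
    cohort["followup_years"] = time
    cohort["died"] = event
    cohort["exclusion_flags"] = ""

    truth = pd.DataFrame(
        {
            "id": cohort["id"],
            "true_aa": delta,
            "true_ba": ba,
            "hazard_multiplier": np.exp(lp),
        }
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# exclusion fixture
# ---------------------------------------------------------------------------

def _apportion(total: int, weights: dict[str, int]) -> dict[str, int]:
    """Largest-remainder split of `total` proportional to `weights`."""
    wsum = sum(weights.values())
    exact = {g: total * w / wsum for g, w in weights.items()}
    base = {g: int(np.floor(v)) for g, v in exact.items()}
    short = total - sum(base.values())
    order = sorted(weights, key=lambda g: exact[g] - base[g], reverse=True)
    for g in order[:short]:
        base[g] += 1
    return base


def generate_exclusion_fixture(
    initial_n: int,
    category_counts: dict[str, int],
    seed: int,
    marker_panel: list[MarkerSpec] | None = None,
) -> pd.DataFrame:
    """Build a cohort of ``initial_n`` records carrying exact exclusion counts.

    Records are drawn from the default generator (group sizes apportioned to
    the sampling-frame proportions), harmonized to the analysis scale, then
    mutually exclusive exclusions are injected so the cascade removes exactly
    the requested number per category:

    - ``sample_quality`` and ``under_lod`` records carry sample-wide flags;
    - ``missing_marker`` records have one marker set to NaN;
    - ``outlier_4sd`` records have one marker displaced far outside the
      pooled 4-SD band, while every clean record's markers are winsorized to
      3.5 pooled SDs so no accidental outliers survive.

    All remaining records pass every filter.
    """
    from .preprocess import analysis_marker_columns, apply_exclusions, harmonize_measurements
    from .config import SimulationConfig, default_marker_panel

    unknown = set(category_counts) - set(EXCLUSION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown exclusion categories: {sorted(unknown)}")
    counts = {c: int(category_counts.get(c, 0)) for c in EXCLUSION_CATEGORIES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("category counts must be >= 0")
    total_flagged = sum(counts.values())
    if total_flagged > initial_n:
        raise ValueError("requested exclusion counts exceed initial_n")

    panel = marker_panel or default_marker_panel()
    cfg = SimulationConfig(
        n_per_group=_apportion(initial_n, FRAME_SIZES), marker_panel=panel, seed=seed
    )
    cohort, _ = generate_cohort(cfg)
    cohort = harmonize_measurements(cohort, panel)
    markers = analysis_marker_columns(panel)

    rng = np.random.default_rng(seed + 1)
    idx = rng.permutation(initial_n)
    pos = 0
    assigned: dict[str, np.ndarray] = {}
    for cat in EXCLUSION_CATEGORIES:
        assigned[cat] = idx[pos : pos + counts[cat]]
        pos += counts[cat]

    flags = np.array([""] * initial_n, dtype=object)
    flags[assigned["sample_quality"]] = "sample_quality"
    flags[assigned["under_lod"]] = "under_lod"
    cohort["exclusion_flags"] = flags

    for i, row in enumerate(assigned["missing_marker"]):
        cohort.loc[cohort.index[row], markers[i % len(markers)]] = np.nan

    # winsorize clean records so the only >4-SD values are the injected ones
    out_marker = markers[0]
    out_rows = cohort.index[assigned["outlier_4sd"]]
    clean = cohort.index.difference(out_rows)
    for m in markers:
        col = cohort[m]
        mu, sd = col.loc[clean].mean(), col.loc[clean].std()
        if sd > 0:
            cohort.loc[clean, m] = col.loc[clean].clip(mu - 3.5 * sd, mu + 3.5 * sd)
    mu, sd = cohort.loc[clean, out_marker].mean(), cohort.loc[clean, out_marker].std()
    cohort.loc[out_rows, out_marker] = mu + 50.0 * sd

    # fail fast if the construction does not realize the requested cascade
    _, log = apply_exclusions(cohort, markers)
    if log.removed != counts:
        raise RuntimeError(
            f"fixture construction failed: wanted {counts}, got {log.removed}"
        )
    return cohort
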