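"""Cohort preprocessing: exclusion cascade, harmonization, lifestyle scoring.

The exclusion cascade removes records in a fixed order — sample-quality
flags, under-limit-of-detection flags, missing marker values, then >4-SD
outliers computed on the records surviving the first three filters — so the
per-category counts are deterministic even when a record would qualify for
more than one category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EXCLUSION_CATEGORIES, MarkerSpec


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

@dataclass
class ExclusionLog:
    """Per-category removal counts; satisfies input = output + sum(removed)."""

    input_n: int
    output_n: int
    removed: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.input_n != self.output_n + sum(self.removed.values()):
            raise ValueError("exclusion log does not conserve record counts")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": c, "removed": self.removed[c]} for c in self.removed]
        rows.append({"category": "retained", "removed": self.output_n})
        return pd.DataFrame(rows)


def _has_flag(flags: pd.Series, category: str) -> pd.Series:
    return flags.fillna("").astype(str).str.split(";").apply(lambda fs: category in fs)


def apply_exclusions(
    cohort: pd.DataFrame,
    marker_columns: list[str],
    outlier_k: float = 4.0,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Run the exclusion cascade and return (survivors, log).

    Outlier means/SDs are computed per marker on the pool surviving the
    sample-quality, under-LOD, and missingness filters, pooled across sexes;
    "outside k SD" is the strict inequality ``|x - mean| / SD > k``.  A
    marker with zero or non-finite SD is skipped by the outlier filter with a
    warning entry rather than an error.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    missing_cols = [m for m in marker_columns if m not in cohort.columns]
    if missing_cols:
        raise KeyError(f"marker columns absent from cohort: {missing_cols}")

    removed: dict[str, int] = {}
    warn: list[str] = []
    pool = cohort

    flags = pool["exclusion_flags"] if "exclusion_flags" in pool.columns else pd.Series(
        "", index=pool.index
    )
    for cat in ("sample_quality", "under_lod"):
        hit = _has_flag(flags.loc[pool.index], cat)
        removed[cat] = int(hit.sum())
        pool = pool.loc[~hit]

    miss = pool[marker_columns].isna().any(axis=1)
    removed["missing_marker"] = int(miss.sum())
    pool = pool.loc[~miss]

    out = pd.Series(False, index=pool.index)
    for m in marker_columns:
        x = pool[m].astype(float)
        mu, sd = x.mean(), x.std()
        if not np.isfinite(sd) or sd == 0:
            warn.append(f"outlier filter skipped for constant marker {m!r}")
            continue
        out |= (x - mu).abs() / sd > outlier_k
    removed["outlier_4sd"] = int(out.sum())
    pool = pool.loc[~out]

    log = ExclusionLog(
        input_n=len(cohort),
        output_n=len(pool),
        removed={c: removed[c] for c in EXCLUSION_CATEGORIES},
        warnings=warn,
    )
    for w in warn:
        warnings.warn(w, stacklevel=2)
    return pool.copy(), log


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def analysis_marker_columns(panel: list[MarkerSpec]) -> list[str]:
    """Marker column names on the analysis scale (after harmonization)."""
    return [m.name for m in panel]


def harmonize_measurements(
    cohort: pd.DataFrame, panel: list[MarkerSpec]
) -> pd.DataFrame:
    """Return a copy of the cohort on the analysis scale.

    - Antihypertensive users' systolic/diastolic pressures are raised by
      15 and 10 mmHg to approximate untreated values.
    - The glucose marker is fasting plasma glucose where measured, otherwise
      random plasma glucose.
    - Biochemical markers flagged ``log_transform`` (all but albumin in the
      default panel) are natural-log transformed; physical measurements stay
      on their raw scale.

    A second application is refused (``cohort.attrs['harmonized']`` guard) so
    the blood-pressure adjustment can never be applied twice.
    """
    if cohort.attrs.get("harmonized"):
        raise ValueError("cohort is already harmonized; refusing to adjust twice")
    out = cohort.copy()

    if "antihypertensive" in out.columns:
        treated = out["antihypertensive"].astype(bool)
        if "sbp" in out.columns:
            out.loc[treated, "sbp"] += 15.0
        if "dbp" in out.columns:
            out.loc[treated, "dbp"] += 10.0

    if any(m.name == "glucose" for m in panel) and "glucose" not in out.columns:
        if not {"rpg", "fpg"} <= set(out.columns):
            raise KeyError("glucose marker requires rpg/fpg columns")
        out["glucose"] = out["fpg"].where(out["fpg"].notna(), out["rpg"])

    for spec in panel:
        if not spec.log_transform:
            continue
        if spec.name not in out.columns:
            raise KeyError(f"marker column {spec.name!r} absent")
        x = out[spec.name].astype(float)
        if (x <= 0).any():
            raise ValueError(f"non-positive value passed to log-transform for {spec.name!r}")
        out[spec.name] = np.log(x)

    out.attrs["harmonized"] = True
    return out


# ---------------------------------------------------------------------------
# lifestyle scoring
# ---------------------------------------------------------------------------

_DIET_FIELDS = ("diet_vegetables", "diet_fruits", "diet_red_meat", "diet_soybean", "diet_fish")
_LT_WEEKLY = ("never_rarely", "monthly")
_LT_4_PER_WEEK = ("never_rarely", "monthly", "1_3_per_week")


def compute_dietary_score(records: pd.DataFrame) -> pd.Series:
    """Risky dietary score, 0-5: one point per risky food habit.

    Points for: vegetables less than daily; fruits less than daily; red meat
    daily or less than weekly; soybean fewer than 4 days/week; fish less than
    weekly.
    """
    missing = [f for f in _DIET_FIELDS if f not in records.columns]
    if missing:
        raise KeyError(f"missing diet frequency fields: {missing}")
    for f in _DIET_FIELDS:
        if records[f].isna().any():
            raise ValueError(f"missing values in diet field {f!r}")
    score = (
        (records["diet_vegetables"] != "daily").astype(int)
        + (records["diet_fruits"] != "daily").astype(int)
        + (
            (records["diet_red_meat"] == "daily")
            | records["diet_red_meat"].isin(_LT_WEEKLY)
        ).astype(int)
        + records["diet_soybean"].isin(_LT_4_PER_WEEK).astype(int)
        + records["diet_fish"].isin(_LT_WEEKLY).astype(int)
    )
    return score.rename("dietary_score")


def activity_age_band(ca: pd.Series) -> pd.Series:
    """Three-level age band used for the activity median split."""
    return pd.cut(
        ca, bins=[-np.inf, 50, 60, np.inf], right=False, labels=["<50", "50-59", ">=60"]
    ).astype(str)


def activity_medians(cohort: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Age-band x sex medians of total physical activity (MET-h/day).

    Computed on the analysis cohort, as the lifestyle score definition
    requires.
    """
    band = activity_age_band(cohort["ca"])
    med = cohort.groupby([band, cohort["sex"]], observed=True)["total_activity"].median()
    return {k: float(v) for k, v in med.items()}


def compute_lifestyle_score(
    records: pd.DataFrame,
    medians: dict[tuple[str, str], float],
) -> tuple[pd.Series, pd.Series]:
    """Risky lifestyle score, 0-4, and the risky-group flag (score 3-4).

    Points for: current smoking (quitting due to illness counts as current);
    daily pure alcohol >= 30 g (men) / >= 15 g (women) or past drinking;
    risky dietary score of 4-5; total activity strictly below the age- and
    sex-specific median (ties go to the non-risky side).
    """
    smoking = (records["smoking_status"] == "current") | (
        (records["smoking_status"] == "former") & records["quit_for_illness"].astype(bool)
    )
    limit = np.where(records["sex"] == "male", 30.0, 15.0)
    alcohol = (records["alcohol_g_day"].to_numpy() >= limit) | records[
        "past_drinker"
    ].astype(bool).to_numpy()
    diet = compute_dietary_score(records) >= 4

    band = activity_age_band(records["ca"])
    keys = list(zip(band, records["sex"]))
    missing = sorted({k for k in keys if k not in medians})
    if missing:
        raise KeyError(f"missing activity median for bands: {missing}")
    med = np.array([medians[k] for k in keys])
    low_activity = records["total_activity"].to_numpy() < med

    score = (
        smoking.astype(int).to_numpy()
        + alcohol.astype(int)
        + diet.astype(int).to_numpy()
        + low_activity.astype(int)
    )
    score = pd.Series(score, index=records.index, name="lifestyle_score")
    risky = (score >= 3).rename("risky_lifestyle")
    return score, risky
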