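"""Configuration objects for the synthetic-cohort generator and pipeline.

The default values emulate the statistical structure of a four-group
cardiovascular-disease-continuum cohort: group sizes and group-specific mean
age acceleration, a marker panel linear in latent biological age, mortality
hazards multiplicative in age acceleration, and administrative censoring.
The marker panel itself is a synthetic stand-in: it mimics the *shape* of a
clinical panel (16 physical + 9 biochemical markers), not any real assay
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: Canonical group labels, in reporting order.
GROUPS = ("control", "MCE", "IS", "ICH_SAH")

#: Exclusion-flag categories, in cascade order.
EXCLUSION_CATEGORIES = ("sample_quality", "under_lod", "missing_marker", "outlier_4sd")


@dataclass
class MarkerSpec:
    """One candidate marker's generating model.

    The marker is linear in latent biological age ``BA = CA + delta`` on its
    model scale: ``x = intercept_q + slope_k * BA + Normal(0, noise_sd_s)``.
    When ``log_transform`` is true the model scale is the natural-log scale
    and the emitted raw value is ``exp(model value)``.  When ``monotone`` is
    false the generator substitutes a U-shaped age response
    ``x = intercept_q + slope_k * (BA - 55)^2 + noise`` so the monotonicity
    filter has something to catch.
    """

    name: str
    klass: str  # "biochemical" | "physical"
    intercept_q: float
    slope_k: float
    noise_sd_s: float
    log_transform: bool = False
    monotone: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd_s < 0:
            raise ValueError(f"noise_sd_s must be >= 0 for marker {self.name!r}")
        if self.klass not in ("biochemical", "physical"):
            raise ValueError(f"unknown marker class {self.klass!r}")


def default_marker_panel() -> list[MarkerSpec]:
    """A synthetic 25-marker panel (16 physical + 9 biochemical analogues).

    Intercepts/slopes/noise are chosen to give plausible adult values and
    marker-age correlations mostly in the 0.15-0.65 band; a few markers are
    deliberately weak (|r| < 0.10) or U-shaped so the screening and
    monotonicity filters are exercised by default.
    """
    P, B = "physical", "biochemical"
    return [
        # physical measurements (raw scale)
        MarkerSpec("sbp", P, 95.0, 0.75, 14.0),
        MarkerSpec("dbp", P, 65.0, 0.25, 9.0),
        MarkerSpec("pulse_pressure", P, 30.0, 0.50, 10.0),
        MarkerSpec("heart_rate", P, 80.0, -0.05, 10.0),  # weak: screened out
        MarkerSpec("fev1", P, 4.2, -0.028, 0.45),
        MarkerSpec("vital_capacity", P, 5.0, -0.030, 0.60),
        MarkerSpec("peak_flow", P, 550.0, -2.8, 80.0),
        MarkerSpec("height", P, 175.0, -0.12, 6.5),
        MarkerSpec("weight", P, 70.0, -0.15, 10.0),
        MarkerSpec("bmi", P, 24.0, -0.002, 3.5, monotone=False),  # inverted-U
        MarkerSpec("waist", P, 65.0, 0.22, 9.0),
        MarkerSpec("hip", P, 90.0, 0.02, 7.0),  # weak: screened out
        MarkerSpec("waist_hip_ratio", P, 0.80, 0.0012, 0.05),
        MarkerSpec("grip_strength", P, 45.0, -0.25, 7.0),
        MarkerSpec("body_fat_pct", P, 20.0, 0.10, 6.0),
        MarkerSpec("lean_mass", P, 55.0, -0.12, 6.0),
        # biochemical markers (log scale except albumin)
        MarkerSpec("albumin", B, 50.0, -0.06, 2.5),
        MarkerSpec("creatinine", B, 4.00, 0.0025, 0.13, log_transform=True),
        MarkerSpec("total_cholesterol", B, 1.35, 0.0035, 0.16, log_transform=True),
        MarkerSpec("ldl_c", B, 0.60, 0.0040, 0.22, log_transform=True),
        MarkerSpec("hdl_c", B, 0.30, 0.0008, 0.18, log_transform=True),  # weak
        MarkerSpec("triglycerides", B, 0.10, 0.0050, 0.40, log_transform=True),
        MarkerSpec("glucose", B, 1.55, 0.0032, 0.12, log_transform=True),
        MarkerSpec("crp", B, -0.50, 0.0120, 0.90, log_transform=True),
        MarkerSpec("cystatin_c", B, -0.35, 0.0060, 0.14, log_transform=True),
    ]


@dataclass
class SimulationConfig:
    """Study-condition parameters for :func:`kdmba.simulate.generate_cohort`.

    Defaults reproduce the analysis-set structure: group sizes
    4197/876/3837/3467, group mean age acceleration -0.3/0.1/0.0/0.3 years
    with SD 1.4 years, a per-year log-hazard of 0.1823 for age acceleration
    (hazard ratio 1.20), group baseline mortality rates of
    13.1/102.7/15.5/84.6 per 1000 person-years, and administrative censoring
    at 12 years.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 4197, "MCE": 876, "IS": 3837, "ICH_SAH": 3467}
    )
    group_aa_mean: dict[str, float] = field(
        default_factory=lambda: {"control": -0.3, "MCE": 0.1, "IS": 0.0, "ICH_SAH": 0.3}
    )
    aa_sd: float = 1.4
    age_range: tuple[float, float] = (30.0, 79.0)
    sex_fraction_female: float = 0.502
    n_areas: int = 10
    marker_panel: list[MarkerSpec] = field(default_factory=default_marker_panel)
    log_hr_per_year_aa: float = 0.1823
    baseline_hazard: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0131, "MCE": 0.1027, "IS": 0.0155, "ICH_SAH": 0.0846}
    )
    hazard_family: str = "exponential"  # or "gompertz"
    gompertz_shape: float = 0.08  # per-year log-hazard slope in t, if gompertz
    age_log_hr: float = 0.085  # log-hazard slope per year of baseline CA
    admin_censor_years: float = 12.0
    censor_jitter_years: float = 2.0  # uniform +/- jitter emulating staggered entry
    covariate_effects: dict[str, float] = field(default_factory=dict)
    antihypertensive_fraction: float = 0.175
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be >= 0")
        if self.aa_sd < 0:
            raise ValueError("aa_sd must be > 0 (0 allowed only for degenerate tests)")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if any(h <= 0 for h in self.baseline_hazard.values()):
            raise ValueError("baseline hazards must be > 0")
        if not self.marker_panel:
            raise ValueError("marker panel must not be empty")
        names = [m.name for m in self.marker_panel]
        if len(names) != len(set(names)):
            raise ValueError("marker names must be unique within the panel")
        if self.hazard_family not in ("exponential", "gompertz"):
            raise ValueError(f"unknown hazard family {self.hazard_family!r}")

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["marker_panel"] = [MarkerSpec(**m) for m in d.get("marker_panel", [])]
        d["age_range"] = tuple(d.get("age_range", (30.0, 79.0)))
        return cls(**d)


def child_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage child seed below 2**31 from a global seed."""
    import zlib

    return (zlib.crc32(f"{stage}:{seed}".encode()) ^ seed) % (2**31 - 1)
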