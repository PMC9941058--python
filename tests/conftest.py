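import numpy as np
import pandas as pd
import pytest

from kdmba.config import GROUPS, SimulationConfig, default_marker_panel
from kdmba.preprocess import analysis_marker_columns, apply_exclusions, harmonize_measurements
from kdmba.simulate import generate_cohort


def small_config(seed: int = 11, n_scale: float = 0.12, **overrides) -> SimulationConfig:
    """Default study conditions at reduced size for fast tests."""
    base = SimulationConfig()
    sizes = {g: max(int(round(n * n_scale)), 40) for g, n in base.n_per_group.items()}
    return SimulationConfig(n_per_group=sizes, seed=seed, **overrides)


def noiseless_config(seed: int = 5, n: int = 700) -> SimulationConfig:
    """Markers exactly linear in CA: no latent AA, no marker noise."""
    panel = [
        type(m)(m.name, m.klass, m.intercept_q, m.slope_k, 0.0, m.log_transform, m.monotone)
        for m in default_marker_panel()
    ]
    return SimulationConfig(
        n_per_group={g: n // 4 for g in GROUPS},
        group_aa_mean={g: 0.0 for g in GROUPS},
        aa_sd=0.0,
        marker_panel=panel,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def analysis_cohort(small_cohort):
    """Harmonized, exclusion-filtered cohort with latent truth attached."""
    cfg, cohort, truth = small_cohort
    harmonized = harmonize_measurements(cohort, cfg.marker_panel)
    markers = analysis_marker_columns(cfg.marker_panel)
    ana, log = apply_exclusions(harmonized, markers)
    tr = truth.set_index("id").loc[ana["id"]]
    ana = ana.assign(true_aa=tr["true_aa"].to_numpy(), true_ba=tr["true_ba"].to_numpy())
    return cfg, ana, markers
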