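"""KDM biological-age core: screening, PCA, estimator, AA, projection."""

import numpy as np
import pandas as pd
import pytest

from kdmba.config import GROUPS, MarkerSpec, SimulationConfig, default_marker_panel
from kdmba.kdm import (
    KDMModel,
    ba_diagnostics,
    compute_aa,
    estimate_ba,
    fit_biological_age,
    fit_kdm,
    fit_pca,
    project_control_model,
    screen_markers,
)
from kdmba.preprocess import analysis_marker_columns, apply_exclusions, harmonize_measurements
from kdmba.simulate import generate_cohort
from tests.conftest import noiseless_config


class TestScreenMarkers:
    def _cohort(self, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        ca = rng.uniform(30, 79, n)
        return pd.DataFrame({
            "ca": ca,
            "weak": 0.004 * ca + rng.normal(0, 1, n),       # r ~ 0.05
            "linear": ca * 1.0,                              # r = 1
            "ushape": (ca - 55.0) ** 2 / 30 + rng.normal(0, 1, n),
            "inverse": -0.05 * ca + rng.normal(0, 1, n),     # r ~ -0.6
            "flat": np.ones(n),
        })

    def test_threshold_and_monotonicity(self):
        df = self._cohort()
        with pytest.warns(UserWarning, match="zero variance"):
            retained, corr = screen_markers(
                df, ["weak", "linear", "ushape", "inverse", "flat"])
        assert "weak" not in retained          # |r| below 0.10
        assert "linear" in retained            # perfectly linear
        assert "ushape" not in retained        # opposite-sign half slopes
        assert "inverse" in retained           # absolute correlation used
        assert corr["linear"] == pytest.approx(1.0)
        assert np.isnan(corr["flat"])

    def test_halfsplit_oracle_agreement(self):
        """The U-shape flag matches a hand-run half-split slope comparison."""
        from scipy import stats

        df = self._cohort(seed=3)
        ca, x = df["ca"].to_numpy(), df["ushape"].to_numpy()
        med = np.median(ca)
        lo = stats.linregress(ca[ca <= med], x[ca <= med])
        hi = stats.linregress(ca[ca > med], x[ca > med])
        assert np.sign(lo.slope) != np.sign(hi.slope)
        assert lo.pvalue < 0.05 and hi.pvalue < 0.05

    def test_needs_two_candidates(self):
        with pytest.raises(ValueError, match="2 candidate"):
            screen_markers(self._cohort(), ["linear"])


class TestFitPca:
    def test_uncorrelated_markers_give_unit_eigenvalues(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
        _, evals, scores, _, _ = fit_pca(df, ["a", "b"])
        assert np.allclose(evals, [1, 1], atol=0.08)

    def test_correlated_pair_closed_form_eigenvalues(self):
        """corr 0.6 => eigenvalues exactly (1.6, 0.4) of the 2x2 matrix."""
        rng = np.random.default_rng(2)
        z = rng.normal(size=(200000, 2))
        a = z[:, 0]
        b = 0.6 * z[:, 0] + np.sqrt(1 - 0.36) * z[:, 1]
        df = pd.DataFrame({"a": a, "b": b})
        _, evals, _, _, _ = fit_pca(df, ["a", "b"])
        assert np.allclose(evals, [1.6, 0.4], atol=0.01)

    def test_reconstruction_of_correlation_matrix(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(500, 2))
        df = pd.DataFrame(
            base @ rng.normal(size=(2, 5)) + 0.3 * rng.normal(size=(500, 5)),
            columns=list("abcde"),
        )
        load, evals, scores, means, sds = fit_pca(df, list("abcde"))
        z = (df.to_numpy() - means) / sds
        corr = (z.T @ z) / (len(df) - 1)
        np.testing.assert_allclose(load @ np.diag(evals) @ load.T, corr, atol=1e-8)
        np.testing.assert_allclose(load.T @ load, np.eye(load.shape[1]), atol=1e-10)
        assert np.all(np.diff(evals) <= 1e-12)

    def test_rank_deficient_components_dropped(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=300)
        df = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=300)})
        load, evals, scores, _, _ = fit_pca(df, ["a", "b", "c"])
        assert load.shape[1] == 2  # duplicated direction collapses

    def test_requires_n_above_p(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)))
        df.columns = list("abcd")
        with pytest.raises(ValueError, match="n > number"):
            fit_pca(df, list("abcd"))


class TestFitKdm:
    def _instance(self, seed=0, n=500, q=(0.0, 10.0, -3.0), k=(1.0, 0.5, -0.8),
                  s=(1.0, 2.0, 1.5)):
        rng = np.random.default_rng(seed)
        ca = rng.uniform(30, 79, n)
        scores = np.column_stack([
            qi + ki * ca + rng.normal(0, si, n) for qi, ki, si in zip(q, k, s)
        ])
        return scores, ca

    def test_parameter_recovery_within_3_se(self):
        q, k, s = (0.0, 10.0, -3.0), (1.0, 0.5, -0.8), (1.0, 2.0, 1.5)
        scores, ca = self._instance()
        model = fit_kdm(scores, ca)
        n = len(ca)
        sd_ca = ca.std()
        for j in range(3):
            se_k = s[j] / (sd_ca * np.sqrt(n))
            assert abs(model.k[j] - k[j]) < 3 * se_k
            se_q = s[j] * np.sqrt(1 / n + ca.mean() ** 2 / (n * sd_ca**2))
            assert abs(model.q[j] - q[j]) < 3 * se_q
            assert model.s[j] == pytest.approx(s[j], rel=0.2)

    def test_ba_e_matches_direct_formula_rowwise(self):
        """Uncorrected BA matches an independently coded closed form."""
        scores, ca = self._instance(seed=5)
        model = fit_kdm(scores, ca)
        w = model.k / model.s**2
        expected = np.array([
            sum((scores[i, j] - model.q[j]) * w[j] for j in range(3))
            / sum(model.k[j] * w[j] for j in range(3))
            for i in range(len(ca))
        ])
        from kdmba.kdm import _ba_uncorrected

        np.testing.assert_allclose(_ba_uncorrected(scores, model.q, model.k, model.s),
                                   expected, atol=1e-10)

    def test_noiseless_component_recovers_exactly(self):
        rng = np.random.default_rng(7)
        ca = rng.uniform(30, 79, 300)
        scores = np.column_stack([2.0 + 0.5 * ca, 1.0 - 0.2 * ca])
        model = fit_kdm(scores, ca)
        assert model.q[0] == pytest.approx(2.0, abs=1e-8)
        assert model.k[0] == pytest.approx(0.5, abs=1e-10)

    def test_rms_r_char_under_homogeneous_correlations(self):
        scores, ca = self._instance(seed=9, q=(0, 0), k=(1.0, -1.0), s=(2.0, 2.0))
        model = fit_kdm(scores, ca, r_char_mode="rms")
        assert model.r_char == pytest.approx(abs(model.r[0]), abs=1e-3)

    def test_degenerate_all_zero_slopes_rejected(self):
        rng = np.random.default_rng(8)
        ca = rng.uniform(30, 79, 200)
        scores = rng.normal(size=(200, 2))  # no age signal
        with pytest.raises(ValueError, match="degenerate|slopes"):
            fit_kdm(np.round(scores - scores.mean(0), 0) * 0.0, ca)


class TestEstimateBa:
    def test_hand_computed_example(self):
        """One subject, two components: BA_EC = 55.75 / 1.0725."""
        model = KDMModel(
            sex="all", retained_markers=["m0", "m1"], candidate_correlations={},
            means=np.zeros(2), sds=np.ones(2), loadings=np.eye(2),
            eigenvalues=np.ones(2),
            q=np.array([0.0, 10.0]), k=np.array([1.0, 0.5]), s=np.array([1.0, 2.0]),
            r=np.array([0.9, 0.7]), r_char=0.8, s_ba2=100.0, ca_range=(30, 79),
        )
        ba = estimate_ba(model, np.array([[52.0, 36.0]]), np.array([50.0]))
        assert ba.iloc[0] == pytest.approx(55.75 / 1.0725, abs=1e-9)

    def test_limits_in_s_ba2(self):
        rng = np.random.default_rng(1)
        ca = rng.uniform(30, 79, 100)
        scores = np.column_stack([0.5 * ca + rng.normal(0, 2, 100)])
        model = fit_kdm(scores, ca)
        from kdmba.kdm import _ba_uncorrected
        ba_e = _ba_uncorrected(scores, model.q, model.k, model.s)

        model.s_ba2 = 1e12
        np.testing.assert_allclose(estimate_ba(model, scores, ca), ba_e, atol=1e-4)
        model.s_ba2 = 1e-9
        np.testing.assert_allclose(estimate_ba(model, scores, ca), ca, atol=1e-3)

    def test_component_rescaling_invariance(self):
        """Rescaling a component (with q,k,s rescaled) leaves BA_EC unchanged."""
        rng = np.random.default_rng(2)
        ca = rng.uniform(30, 79, 200)
        scores = np.column_stack([0.5 * ca + rng.normal(0, 2, 200),
                                  -0.2 * ca + rng.normal(0, 1, 200)])
        m1 = fit_kdm(scores, ca)
        c = 7.3
        scaled = scores.copy()
        scaled[:, 1] *= c
        m2 = fit_kdm(scaled, ca)
        np.testing.assert_allclose(estimate_ba(m1, scores, ca),
                                   estimate_ba(m2, scaled, ca), atol=1e-8)

    def test_component_mismatch_rejected(self):
        scores, ca = np.zeros((5, 3)), np.linspace(40, 60, 5)
        model = fit_kdm(np.column_stack([ca, 2 * ca]), ca)
        with pytest.raises(ValueError, match="components"):
            estimate_ba(model, scores, ca)


class TestComputeAa:
    def test_ba_equals_ca_gives_zero_aa(self):
        ca = pd.Series(np.linspace(30, 79, 50))
        res, model = compute_aa(ca.copy(), ca)
        np.testing.assert_allclose(res.aa, 0.0, atol=1e-10)

    def test_ols_residual_identities(self, analysis_cohort):
        """Sum of AA is 0 and corr(AA, CA) is 0 within the fitting pool."""
        cfg, ana, markers = analysis_cohort
        fit = fit_biological_age(ana, markers)
        aa = fit.result.aa.to_numpy()
        ca = ana["ca"].to_numpy()
        assert abs(aa.mean()) < 1e-10
        assert abs(np.corrcoef(aa, ca)[0, 1]) < 1e-10
        assert fit.result.aa_standardized.std(ddof=1) == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(11)
        ca = rng.uniform(30, 79, 400)
        ba = 5 + 0.9 * ca + rng.normal(0, 2, 400)
        res, model = compute_aa(pd.Series(ba), pd.Series(ca))
        # independent two-parameter least squares via the normal equations
        A = np.column_stack([np.ones_like(ca), ca])
        coef = np.linalg.solve(A.T @ A, A.T @ ba)
        np.testing.assert_allclose(res.aa, ba - A @ coef, atol=1e-8)

    def test_restricted_fit_pool(self):
        rng = np.random.default_rng(12)
        ca = rng.uniform(30, 79, 300)
        ba = ca + rng.normal(0, 1, 300)
        pool = np.arange(300) < 150
        res, model = compute_aa(pd.Series(ba), pd.Series(ca), fit_pool=pool)
        assert abs(res.aa.to_numpy()[pool].mean()) < 1e-10
        # outside the pool the mean is free to differ
        assert res.aa.to_numpy()[~pool].std() > 0

    def test_constant_ca_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_aa(pd.Series([1.0, 2, 3]), pd.Series([50.0, 50, 50]))


class TestBaDiagnostics:
    def test_identity_gives_r1_rmse0(self):
        ca = np.linspace(30, 79, 40)
        r, rmse = ba_diagnostics(pd.Series(ca), pd.Series(ca))
        assert r == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-10)

    def test_matches_regression_oracle_under_noise(self):
        rng = np.random.default_rng(13)
        ca = rng.uniform(30, 79, 10000)
        ba = ca + rng.normal(0, 1.4, 10000)
        r, rmse = ba_diagnostics(pd.Series(ba), pd.Series(ca))
        # brute-force OLS of CA on BA on the same draw
        A = np.column_stack([np.ones_like(ba), ba])
        coef, *_ = np.linalg.lstsq(A, ca, rcond=None)
        expected = float(np.sqrt(np.mean((ca - A @ coef) ** 2)))
        assert rmse == pytest.approx(expected, abs=1e-10)
        assert r == pytest.approx(np.corrcoef(ba, ca)[0, 1], abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ba_diagnostics(pd.Series(np.full(10, 50.0)), pd.Series(np.linspace(30, 79, 10)))


class TestEndToEnd:
    def test_noiseless_identity_through_pca(self):
        """Markers exactly linear in CA force BA_EC = CA to 1e-8."""
        cfg = noiseless_config(seed=2, n=600)
        cohort, _ = generate_cohort(cfg)
        harmonized = harmonize_measurements(cohort, cfg.marker_panel)
        markers = analysis_marker_columns(cfg.marker_panel)
        with pytest.warns(UserWarning):
            ana, _ = apply_exclusions(harmonized, markers)
            fit = fit_biological_age(ana, markers)
        assert np.max(np.abs(fit.result.ba.to_numpy() - ana["ca"].to_numpy())) < 1e-8

    def test_marker_order_invariance(self, analysis_cohort):
        cfg, ana, markers = analysis_cohort
        fit1 = fit_biological_age(ana, markers)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(markers))
        fit2 = fit_biological_age(ana, perm)
        np.testing.assert_allclose(fit1.result.ba, fit2.result.ba, atol=1e-9)

    def test_sex_stratification_equals_independent_fits(self, analysis_cohort):
        cfg, ana, markers = analysis_cohort
        joint = fit_biological_age(ana, markers)
        for sex in ("male", "female"):
            sub = ana[ana["sex"] == sex]
            solo = fit_biological_age(sub, markers, by_sex=False)
            np.testing.assert_allclose(joint.result.ba.loc[sub.index],
                                       solo.result.ba, atol=1e-9)

    def test_recovery_improves_as_marker_noise_shrinks(self):
        cors = []
        for scale in (1.0, 0.3, 0.02):
            panel = [
                MarkerSpec(m.name, m.klass, m.intercept_q, m.slope_k,
                           m.noise_sd_s * scale, m.log_transform, m.monotone)
                for m in default_marker_panel()
            ]
            cfg = SimulationConfig(
                n_per_group={g: 350 for g in GROUPS}, marker_panel=panel, seed=21)
            cohort, truth = generate_cohort(cfg)
            harmonized = harmonize_measurements(cohort, cfg.marker_panel)
            markers = analysis_marker_columns(cfg.marker_panel)
            ana, _ = apply_exclusions(harmonized, markers)
            tr = truth.set_index("id").loc[ana["id"]]
            fit = fit_biological_age(ana, markers)
            cors.append(np.corrcoef(fit.result.aa, tr["true_aa"])[0, 1])
        assert cors[0] > 0
        assert cors[0] < cors[1] < cors[2]
        assert cors[2] > 0.95  # near-noiseless limit: AA tracks latent truth

    def test_model_yaml_roundtrip(self, analysis_cohort, tmp_path):
        cfg, ana, markers = analysis_cohort
        fit = fit_biological_age(ana, markers)
        model = fit.models["female"]
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        back = KDMModel.from_yaml(path)
        np.testing.assert_allclose(back.loadings, model.loadings)
        np.testing.assert_allclose(back.q, model.q)
        assert back.retained_markers == model.retained_markers
        np.testing.assert_allclose(back.transform(ana[ana.sex == "female"]),
                                   model.transform(ana[ana.sex == "female"]))


class TestProjection:
    def test_identity_on_fitting_cohort(self, analysis_cohort):
        cfg, ana, markers = analysis_cohort
        ctrl = ana[ana["group"] == "control"]
        fit = fit_biological_age(ctrl, markers)
        for sex, model in fit.models.items():
            sub = ctrl[ctrl["sex"] == sex]
            proj = project_control_model(model, fit.aa_model, sub)
            np.testing.assert_allclose(proj.ba, fit.result.ba.loc[sub.index], atol=1e-10)
            np.testing.assert_allclose(proj.aa, fit.result.aa.loc[sub.index], atol=1e-10)

    def test_standardized_projection_unit_sd(self, analysis_cohort):
        cfg, ana, markers = analysis_cohort
        ctrl = ana[ana["group"] == "control"]
        fit = fit_biological_age(ctrl, markers)
        sub = ana[ana["sex"] == "female"]
        proj = project_control_model(fit.models["female"], fit.aa_model, sub)
        ratio = proj.aa / proj.aa_standardized
        np.testing.assert_allclose(ratio.dropna(), fit.aa_model.aa_sd, atol=1e-9)
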