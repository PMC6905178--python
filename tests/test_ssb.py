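"""Stable sparse biomarker machinery: screening, age design, elastic net,
stability selection and the classification equation."""

import numpy as np
import pandas as pd
import pytest

from eegssb import ssb
from eegssb.ssb import SsbConfig
from tests.conftest import make_feature_set


class TestIndfeatScreen:
    def test_strong_feature_retained_nulls_decimated(self, rng):
        n, p = 200, 100
        X = rng.standard_normal((n, p))
        y = np.array(["A"] * 100 + ["B"] * 100)
        X[y == "A", 42] += 3.0
        keep = ssb.indfeat_screen(X, y)
        assert 42 in keep
        null_fraction = (len(keep) - 1) / (p - 1)
        assert null_fraction < 0.15

    def test_all_null_retains_percentile_fraction(self, rng):
        X = rng.standard_normal((100, 200))
        y = np.array(["A", "B"] * 50)
        keep = ssb.indfeat_screen(X, y, percentile=90.0)
        assert 15 <= len(keep) <= 25  # ~10% of 200

    def test_small_p_floor_returns_all(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.array(["A", "B"] * 20)
        np.testing.assert_array_equal(ssb.indfeat_screen(X, y), np.arange(5))

    def test_constant_feature_scores_zero(self, rng):
        X = rng.standard_normal((40, 30))
        X[:, 4] = 2.0
        y = np.array(["A", "B"] * 20)
        keep = ssb.indfeat_screen(X, y, percentile=50.0)
        assert 4 not in keep


class TestAgeDesign:
    def test_interaction_is_exact_product(self, rng):
        X = pd.DataFrame({("R0", "b"): rng.standard_normal(20)})
        ages = rng.uniform(5, 11, 20)
        design = ssb.build_age_design(X, ages)
        sc = design.scaler
        raw_inter = ages * X[("R0", "b")].to_numpy()
        expected = (raw_inter - sc.inter_mean[0]) / sc.inter_sd[0]
        np.testing.assert_allclose(design.Z[:, 1], expected, atol=1e-12)
        np.testing.assert_allclose(sc.inter_mean[0], raw_inter.mean())

    def test_training_split_standardisation(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 4)), columns=[("R", f"b{j}") for j in range(4)])
        ages = rng.uniform(5, 11, 50)
        design = ssb.build_age_design(X, ages)
        pen = design.Z[:, design.penalized]
        assert np.abs(pen.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(pen.std(axis=0), 1.0, atol=1e-12)

    def test_held_out_rows_use_training_statistics(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=[("R", f"b{j}") for j in range(3)])
        ages = rng.uniform(5, 11, 60)
        design_tr = ssb.build_age_design(X.iloc[:40], ages[:40])
        design_te = ssb.build_age_design(X.iloc[40:], ages[40:], scaler=design_tr.scaler)
        # held-out columns are NOT mean-zero under the training scaler
        sc = design_tr.scaler
        manual = (X.iloc[40:].to_numpy() - sc.base_mean) / sc.base_sd
        np.testing.assert_allclose(design_te.Z[:, :3], manual, atol=1e-12)

    def test_equal_ages_drop_interaction_block(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=[("R", "a"), ("R", "b")])
        with pytest.warns(UserWarning, match="collinear"):
            design = ssb.build_age_design(X, np.full(20, 8.0))
        terms = {lab[2] for lab in design.column_labels}
        assert "age_interaction" not in terms

    def test_zero_variance_column_dropped(self, rng):
        X = pd.DataFrame(
            {("R", "a"): rng.standard_normal(20), ("R", "b"): np.ones(20)}
        )
        design = ssb.build_age_design(X, rng.uniform(5, 11, 20))
        base_cols = [lab for lab in design.column_labels if lab[2] == "base"]
        assert base_cols == [("R", "a", "base")]


class TestElasticNetFit:
    def test_zero_penalty_is_ols(self, rng):
        n, p = 50, 5
        Z = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        beta, b0, _ = ssb.elastic_net_fit(Z, y, gamma=0.5, lam=0.0)
        ref = np.linalg.lstsq(np.hstack([np.ones((n, 1)), Z]), y, rcond=None)[0]
        np.testing.assert_allclose(np.r_[b0, beta], ref, atol=1e-8)

    def test_single_predictor_soft_threshold(self, rng):
        """Closed-form oracle for the lasso with one standardised predictor."""
        n = 100
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std()
        y = 0.8 * z + 0.5 * rng.standard_normal(n)
        lam = 0.1
        beta, _, _ = ssb.elastic_net_fit(z[:, None], y, gamma=1.0, lam=lam)
        rho = z @ (y - y.mean()) / n
        ref = np.sign(rho) * max(abs(rho) - lam, 0.0) / (z @ z / n)
        assert np.isclose(beta[0], ref, atol=1e-10)

    def test_ridge_matches_linear_solve(self, rng):
        n, p = 40, 8
        Z = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        lam = 0.3
        beta, _, _ = ssb.elastic_net_fit(Z, y, gamma=0.0, lam=lam)
        Zc = Z - Z.mean(axis=0)
        yc = y - y.mean()
        ref = np.linalg.solve(Zc.T @ Zc / n + lam * np.eye(p), Zc.T @ yc / n)
        np.testing.assert_allclose(beta, ref, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_residual_on_wide_problems(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((30, 100))
        y = rng.standard_normal(30)
        gamma, lam = 0.7, 0.05
        beta, _, _ = ssb.elastic_net_fit(Z, y, gamma=gamma, lam=lam)
        Zt, yt, _ = ssb._partial_out(Z, y, np.ones(100, dtype=bool))
        assert ssb.kkt_residual(Zt, yt, beta, gamma, lam) <= 1e-8

    def test_unpenalized_column_never_shrunk(self, rng):
        n = 60
        Z = rng.standard_normal((n, 4))
        penalized = np.array([True, True, True, False])
        y = Z[:, 3] * 2.0 + 0.1 * rng.standard_normal(n)
        beta, b0, unpen = ssb.elastic_net_fit(Z, y, 1.0, lam=10.0, penalized=penalized)
        assert np.all(beta == 0)  # huge penalty kills the penalized block
        assert abs(unpen[0] - 2.0) < 0.1  # but not the unpenalized column

    def test_solution_path_continuity(self, rng):
        """Coefficients vary continuously along a fine lambda grid."""
        Z = rng.standard_normal((50, 10))
        y = Z[:, 0] - Z[:, 3] + rng.standard_normal(50)
        lams = np.geomspace(0.5, 0.005, 40)
        prev = None
        for lam in lams:
            beta, _, _ = ssb.elastic_net_fit(Z, y, 0.9, lam)
            if prev is not None:
                assert np.abs(beta - prev).max() < 0.25
            prev = beta

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ssb.elastic_net_fit(np.array([[np.nan, 1.0]]), np.array([1.0]), 0.5, 0.1)


class TestStabilitySelect:
    def test_two_informative_features_dominate(self, small_effect_features):
        cfg = SsbConfig(n_resamples=100, seed=1)
        res = ssb.stability_select(small_effect_features, cfg)
        comb = np.maximum(res.freq_phi, res.freq_psi)
        true_feats = [("R03", "low_alpha"), ("R17", "low_alpha")]
        for f in true_feats:
            assert comb[f] > 0.5
        assert comb.drop(true_feats).max() < 0.3

    def test_null_cohort_selects_nothing_stable(self, null_features):
        cfg = SsbConfig(n_resamples=100, seed=2)
        res = ssb.stability_select(null_features, cfg)
        assert res.stable_set == []
        assert res.model.phi.empty and res.model.psi.empty

    def test_deterministic_given_seed(self, small_effect_features):
        cfg = SsbConfig(n_resamples=30, seed=9)
        r1 = ssb.stability_select(small_effect_features, cfg)
        r2 = ssb.stability_select(small_effect_features, cfg)
        assert r1.freq_phi.equals(r2.freq_phi)
        assert r1.freq_psi.equals(r2.freq_psi)
        assert r1.stable_set == r2.stable_set

    def test_frequencies_on_exact_grid(self, small_effect_features):
        cfg = SsbConfig(n_resamples=40, seed=3)
        res = ssb.stability_select(small_effect_features, cfg)
        for f in (res.freq_phi, res.freq_psi):
            assert ((f * 40) % 1 == 0).all()
            assert ((f >= 0) & (f <= 1)).all()

    def test_raising_threshold_never_enlarges_stable_set(self, small_effect_features):
        cfg = SsbConfig(n_resamples=40, seed=4)
        res = ssb.stability_select(small_effect_features, cfg)
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8, 1.0):
            current = set(res.stable_at(thr))
            if prev is not None:
                assert current <= prev
            prev = current

    def test_single_class_rejected(self, small_effect_features):
        feats = small_effect_features
        feats.groups[:] = "PEM"
        with pytest.raises(ValueError):
            ssb.stability_select(feats, SsbConfig(seed=0))


class TestClassificationScore:
    def _toy_model(self):
        return ssb.FittedClassifier(
            feature_labels=[("A", "alpha"), ("B", "theta"), ("C", "beta")],
            phi0=0.3,
            phi=pd.Series({("A", "alpha"): 1.0, ("B", "theta"): -1.0}),
            psi=pd.Series({("C", "beta"): 0.05}),
            age_coef=0.0,
            gamma=1.0,
            lam=0.1,
        )

    def test_null_model_returns_intercept(self):
        model = ssb.FittedClassifier(
            feature_labels=[("A", "alpha")], phi0=0.7,
            phi=pd.Series(dtype=float), psi=pd.Series(dtype=float),
            age_coef=0.0, gamma=1.0, lam=0.0,
        )
        x = pd.Series({("A", "alpha"): 3.0})
        assert ssb.classification_score(x, 8.0, model) == 0.7

    def test_alpha_theta_ratio_special_case(self):
        """d_alpha = 1, d_theta = -1 makes exp(score) the classical
        alpha/theta power ratio (up to the intercept)."""
        model = self._toy_model()
        model.psi = pd.Series(dtype=float)
        s_alpha, s_theta = 4.0, 2.5
        x = pd.Series({("A", "alpha"): np.log(s_alpha), ("B", "theta"): np.log(s_theta)})
        t = ssb.classification_score(x, 8.0, model)
        assert np.isclose(np.exp(t - model.phi0), s_alpha / s_theta)

    def test_hand_computed_three_feature_example(self):
        model = self._toy_model()
        x = pd.Series({("A", "alpha"): 0.5, ("B", "theta"): -0.2, ("C", "beta"): 1.5})
        age = 10.0
        expected = 0.3 + 1.0 * 0.5 + (-1.0) * (-0.2) + age * 0.05 * 1.5
        assert np.isclose(ssb.classification_score(x, age, model), expected)

    def test_age_dependent_coefficients(self):
        model = self._toy_model()
        d = model.d(10.0)
        assert d[("A", "alpha")] == 1.0
        assert d[("C", "beta")] == 0.5

    def test_missing_feature_rejected(self):
        model = self._toy_model()
        with pytest.raises(ValueError, match="missing"):
            ssb.classification_score(pd.Series({("A", "alpha"): 1.0}), 8.0, model)

    def test_sign_convention_higher_power_toward_control(self, rng):
        """With Control coded +1, a feature whose power is lower in the PEM
        group gets a positive d_j, so higher power pushes toward Control."""
        feats = make_feature_set(shifted=(3,), shift=-1.5, seed=19)
        cfg = SsbConfig(n_resamples=60, seed=6)
        res = ssb.stability_select(feats, cfg)
        d = res.model.d(8.0)
        assert ("R03", "low_alpha") in d.index
        assert d[("R03", "low_alpha")] > 0
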