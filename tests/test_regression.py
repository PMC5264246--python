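"""Per-balance OLS and mixed-effects modelling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nichebalance as nb
from conftest import random_composition


def gradient_balances(rng, d=6, n=60, slope=1.2, noise=0.3):
    """Balances linear in a gradient with Gaussian noise, plus the design."""
    tree = nb.random_binary_tree([f"f{i}" for i in range(d)], rng)
    basis = nb.build_ilr_basis(tree)
    ph = np.linspace(4, 9, n)
    balances = pd.DataFrame(
        slope * ph[:, None] + rng.normal(0, noise, size=(n, d - 1)),
        index=[f"s{i}" for i in range(n)], columns=basis.index)
    covariates = pd.DataFrame({"ph": ph}, index=balances.index)
    return balances, covariates, basis, tree


class TestBonferroni:
    def test_multiplies_and_flags(self):
        adjusted, significant = nb.bonferroni(np.array([0.01, 0.2, 0.03, 0.9]), 0.05)
        np.testing.assert_allclose(adjusted, [0.04, 0.8, 0.12, 1.0])
        assert list(significant) == [True, False, False, False]

    def test_clipped_at_one(self):
        adjusted, _ = nb.bonferroni(np.array([0.5, 0.5, 0.5, 0.5]))
        np.testing.assert_allclose(adjusted, 1.0)

    def test_single_test_identity(self):
        adjusted, _ = nb.bonferroni(np.array([0.012]))
        assert adjusted[0] == pytest.approx(0.012)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nb.bonferroni(np.array([0.5, 1.5]))

    def test_nan_stays_nan_and_insignificant(self):
        adjusted, significant = nb.bonferroni(np.array([0.001, np.nan]))
        assert np.isnan(adjusted[1]) and not significant[1]
        assert significant[0]


class TestFitOls:
    def test_noiseless_fit_is_exact(self, rng):
        balances, covariates, _, _ = gradient_balances(rng, noise=0.0, slope=0.7)
        result = nb.fit_ols(balances, covariates, "ph")
        slopes = result.coefficients.xs("ph", level="term")["estimate"]
        np.testing.assert_allclose(slopes, 0.7, atol=1e-9)
        assert result.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_balances_give_zero_slope_and_r2(self):
        balances = pd.DataFrame(np.ones((20, 3)), columns=["y0", "y1", "y2"],
                                index=[f"s{i}" for i in range(20)])
        covariates = pd.DataFrame({"ph": np.linspace(0, 1, 20)}, index=balances.index)
        result = nb.fit_ols(balances, covariates, "ph")
        slopes = result.coefficients.xs("ph", level="term")["estimate"]
        np.testing.assert_allclose(slopes, 0.0, atol=1e-9)
        assert result.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_fitted_plus_residual_reconstructs_observed(self, rng):
        balances, covariates, _, _ = gradient_balances(rng)
        result = nb.fit_ols(balances, covariates, "ph")
        np.testing.assert_allclose((result.fitted + result.residual).to_numpy(),
                                   balances.to_numpy(), atol=1e-9)

    def test_slope_recovery_within_three_standard_errors(self, rng):
        n, beta, sigma = 100, 0.8, 0.5
        ph = np.linspace(4, 9, n)
        tree = nb.random_binary_tree([f"f{i}" for i in range(5)], rng)
        basis = nb.build_ilr_basis(tree)
        balances = pd.DataFrame(beta * ph[:, None] + rng.normal(0, sigma, (n, 4)),
                                index=[f"s{i}" for i in range(n)], columns=basis.index)
        covariates = pd.DataFrame({"ph": ph}, index=balances.index)
        result = nb.fit_ols(balances, covariates, "ph")
        analytic_se = sigma / np.sqrt(np.sum((ph - ph.mean()) ** 2))
        slopes = result.coefficients.xs("ph", level="term")["estimate"]
        assert (np.abs(slopes - beta) < 3 * analytic_se).all()

    def test_two_feature_balance_equals_direct_log_ratio_regression(self, rng):
        """With D=2 the single balance is sqrt(1/2) ln(x1/x2); its OLS fit
        must match regressing that quantity directly."""
        n = 40
        x = random_composition(rng, n, 2)
        ph = rng.uniform(4, 9, n)
        table = pd.DataFrame(x, columns=["A", "B"], index=[f"s{i}" for i in range(n)])
        basis = nb.build_ilr_basis(nb.read_newick("(A,B);"))
        balances = nb.ilr_transform(table, basis)
        covariates = pd.DataFrame({"ph": ph}, index=table.index)
        result = nb.fit_ols(balances, covariates, "ph")
        direct = np.sqrt(0.5) * np.log(x[:, 0] / x[:, 1])
        lr = stats.linregress(ph, direct)
        coef = result.coefficients.xs("ph", level="term").iloc[0]
        assert coef["estimate"] == pytest.approx(lr.slope, abs=1e-9)
        assert coef["pvalue"] == pytest.approx(lr.pvalue, rel=1e-6)

    def test_rank_deficient_design_names_terms(self, rng):
        balances, covariates, _, _ = gradient_balances(rng)
        covariates["ph_copy"] = covariates["ph"]
        with pytest.raises(ValueError, match="ph_copy"):
            nb.fit_ols(balances, covariates, "ph + ph_copy")

    def test_missing_sample_rejected(self, rng):
        balances, covariates, _, _ = gradient_balances(rng)
        with pytest.raises(ValueError, match="s0"):
            nb.fit_ols(balances, covariates.drop(index="s0"), "ph")

    def test_r_squared_invariant_to_tree_choice(self, rng):
        """The ILR is an isometry: pooled R^2 does not depend on which
        bifurcating tree defined the balance coordinates."""
        d, n = 10, 50
        x = random_composition(rng, n, d)
        ph = rng.uniform(4, 9, n)
        samples = [f"s{i}" for i in range(n)]
        covariates = pd.DataFrame({"ph": ph}, index=samples)
        features = [f"f{i}" for i in range(d)]
        r2 = []
        for _ in range(20):
            tree = nb.random_binary_tree(features, rng)
            basis = nb.build_ilr_basis(tree, feature_ids=features)
            balances = nb.ilr_transform(
                pd.DataFrame(x, index=samples, columns=features), basis)
            r2.append(nb.fit_ols(balances, covariates, "ph").r_squared)
        np.testing.assert_allclose(r2, r2[0], atol=1e-9)


class TestFitLme:
    def make_grouped(self, rng, n_groups=8, per_group=10, beta=0.6, group_sd=1.0,
                     noise=0.4, d=4):
        tree = nb.random_binary_tree([f"f{i}" for i in range(d)], rng)
        basis = nb.build_ilr_basis(tree)
        rows, meta = [], []
        for g in range(n_groups):
            intercept = rng.normal(0, group_sd)
            ph = np.linspace(5, 8.5, per_group)
            for v in ph:
                rows.append(intercept + beta * v + rng.normal(0, noise, d - 1))
                meta.append((f"g{g}", v))
        samples = [f"s{i}" for i in range(len(rows))]
        balances = pd.DataFrame(rows, index=samples, columns=basis.index)
        covariates = pd.DataFrame(meta, columns=["patient", "ph"], index=samples)
        return balances, covariates

    def test_fixed_effect_recovery(self, rng):
        beta = 0.6
        balances, covariates = self.make_grouped(rng, beta=beta)
        result = nb.fit_lme(balances, covariates, "ph", grouping="patient")
        coef = result.coefficients.xs("ph", level="term")
        assert result.converged.all()
        assert (np.abs(coef["estimate"] - beta) < 3 * coef["stderr"]).all()

    def test_zero_group_variance_matches_ols(self, rng):
        balances, covariates = self.make_grouped(rng, group_sd=0.0, noise=0.3)
        lme = nb.fit_lme(balances, covariates, "ph", grouping="patient")
        ols = nb.fit_ols(balances, covariates, "ph")
        lme_est = lme.coefficients["estimate"]
        ols_est = ols.coefficients["estimate"]
        np.testing.assert_allclose(lme_est, ols_est, atol=1e-6)

    def test_single_group_suggests_ols(self, rng):
        balances, covariates = self.make_grouped(rng, n_groups=1)
        with pytest.raises(ValueError, match="fit_ols"):
            nb.fit_lme(balances, covariates, "ph", grouping="patient")

    def test_adjusted_pvalues_dominate_raw(self, rng):
        balances, covariates = self.make_grouped(rng)
        result = nb.fit_lme(balances, covariates, "ph", grouping="patient")
        coef = result.coefficients.dropna(subset=["pvalue"])
        assert (coef["pvalue_adj"] >= coef["pvalue"] - 1e-15).all()
        assert (coef["pvalue_adj"] <= 1.0).all()


class TestPredictProportions:
    def test_training_prediction_recovers_noiseless_compositions(self, rng):
        d, n = 5, 30
        tree = nb.random_binary_tree([f"f{i}" for i in range(d)], rng)
        basis = nb.build_ilr_basis(tree)
        ph = np.linspace(4, 9, n)
        samples = [f"s{i}" for i in range(n)]
        balances = pd.DataFrame(0.4 * ph[:, None] * np.ones((1, d - 1)) + 0.1,
                                index=samples, columns=basis.index)
        covariates = pd.DataFrame({"ph": ph}, index=samples)
        result = nb.fit_ols(balances, covariates, "ph")
        predicted = nb.predict_proportions(result, covariates, basis)
        observed = nb.inverse_ilr(balances, basis)
        np.testing.assert_allclose(predicted.to_numpy(), observed.to_numpy(),
                                   atol=1e-9)
        np.testing.assert_allclose(predicted.sum(axis=1), 1.0, atol=1e-12)

    def test_intercept_only_predicts_mean_composition(self, rng):
        d, n = 4, 25
        tree = nb.random_binary_tree([f"f{i}" for i in range(d)], rng)
        basis = nb.build_ilr_basis(tree)
        samples = [f"s{i}" for i in range(n)]
        balances = pd.DataFrame(rng.normal(0, 1, (n, d - 1)), index=samples,
                                columns=basis.index)
        covariates = pd.DataFrame({"ph": rng.uniform(4, 9, n)}, index=samples)
        result = nb.fit_ols(balances, covariates, "1")
        predicted = nb.predict_proportions(result, covariates.iloc[:3], basis)
        mean_balance = pd.DataFrame(balances.mean().to_numpy()[None, :],
                                    columns=basis.index)
        expected = nb.inverse_ilr(mean_balance, basis).to_numpy()[0]
        for i in range(3):
            np.testing.assert_allclose(predicted.iloc[i], expected, atol=1e-9)

    def test_missing_covariate_rejected(self, rng):
        balances, covariates, basis, _ = gradient_balances(rng)
        result = nb.fit_ols(balances, covariates, "ph")
        bad = pd.DataFrame({"other": [1.0]}, index=["new"])
        with pytest.raises(ValueError, match="covariate"):
            nb.predict_proportions(result, bad, basis)

    def test_predicted_gradient_community_is_banded(self):
        """An OLS fit on a niche gradient reproduces the diagonal band
        pattern in its predicted proportions."""
        spec = nb.GradientCommunitySpec(n_features=16,
                                        gradient=np.linspace(3.8, 8.2, 40),
                                        widths=0.8, depth=2000, seed=11)
        table, metadata, _ = nb.generate_gradient_community(spec)
        gradient = metadata["gradient"]
        niche = nb.mean_niche_estimator(table, gradient, on_empty="drop")
        tree = nb.upgma_from_niche(niche)
        proportions = nb.closure(nb.add_pseudocount(table[niche.index]))
        basis = nb.build_ilr_basis(tree, feature_ids=proportions.columns)
        balances = nb.ilr_transform(proportions, basis)
        result = nb.fit_ols(balances, metadata, "gradient")
        predicted = nb.predict_proportions(result, metadata, basis)
        sorted_pred = nb.niche_sort(predicted, gradient)
        observed, null, p = nb.band_permutation_test(sorted_pred,
                                                     n_permutations=200, rng=1)
        assert observed < np.quantile(null, 0.01)


class TestFamilyWiseErrorControl:
    def test_permuted_gradient_keeps_familywise_error_at_alpha(self, rng):
        """Under a null covariate (shuffled pH), the chance that any
        balance survives Bonferroni stays at or below alpha."""
        d, n, reps, alpha = 6, 30, 100, 0.05
        tree = nb.random_binary_tree([f"f{i}" for i in range(d)], rng)
        basis = nb.build_ilr_basis(tree)
        samples = [f"s{i}" for i in range(n)]
        x = pd.DataFrame(random_composition(rng, n, d), index=samples,
                         columns=basis.columns)
        balances = nb.ilr_transform(x, basis)
        ph = np.linspace(4, 9, n)
        hits = 0
        for _ in range(reps):
            covariates = pd.DataFrame({"ph": rng.permutation(ph)}, index=samples)
            result = nb.fit_ols(balances, covariates, "ph")
            sig = result.coefficients.xs("ph", level="term")["significant"]
            hits += int(sig.any())
        fwer = hits / reps
        assert fwer <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)
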