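import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from thermovar import pgls, trees
from thermovar.curation import SpeciesTrait
from thermovar.pgls import (
    FULL_MODEL,
    ModelError,
    ModelSpec,
    aic_select,
    build_design,
    glm_fit,
    gls_fit,
    parse_formula,
    profile_lambda,
)
from thermovar.synthetic_data import simulate_species_means

from conftest import random_tree


def make_trait(species, group="temperate", habitat="freshwater",
               hemisphere="northern", **kw):
    defaults = dict(log10_sd_ctmax=0.0, ctmax=32.0, delta_t=12.0,
                    n_individuals=10, heating_rate=0.3)
    defaults.update(kw)
    return SpeciesTrait(species=species, group=group, habitat=habitat,
                        hemisphere=hemisphere, **defaults)


def random_instance(rng, n, p=3):
    """Random GLS problem with a PD covariance from a random tree."""
    t = random_tree(rng, n_tips=n)
    V = trees.vcv_from_tree(t)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = rng.standard_normal(n) + X @ rng.uniform(-1, 1, p)
    return y, X, V


class TestFormula:
    def test_parse_round_trip(self):
        text = ("log10_sd_ctmax ~ group + habitat + delta_t + "
                "group:delta_t")
        spec = parse_formula(text)
        assert spec.terms == ["group", "habitat", "delta_t"]
        assert spec.interactions == [("group", "delta_t")]
        assert parse_formula(spec.formula()) == spec

    @pytest.mark.parametrize(
        "bad",
        ["no tilde", "y ~ ", "y ~ group + ", "y ~ a:b:c",
         "y ~ ctmax:delta_t"],   # last: interaction without main effects
    )
    def test_malformed_formula_rejected(self, bad):
        with pytest.raises(ModelError):
            parse_formula(bad)

    def test_full_model_has_ten_coefficients(self):
        assert FULL_MODEL.n_coefficients == 10


class TestDesign:
    def test_binary_factor_coding_contract(self):
        traits = [
            make_trait("a"), make_trait("b"),
            make_trait("c", group="tropical"),
            make_trait("d", group="tropical"),
        ]
        y, X, names = build_design(traits, ModelSpec(terms=["group"]))
        assert X.shape == (4, 2)
        np.testing.assert_array_equal(X[:, 0], 1.0)
        np.testing.assert_array_equal(X[:, 1], [0, 0, 1, 1])
        assert names == ["(Intercept)", "group[tropical]"]

    def test_full_model_yields_ten_columns(self):
        rng = np.random.default_rng(3)
        traits = [
            make_trait(
                f"s{i}",
                group=rng.choice(["temperate", "tropical"]),
                habitat=rng.choice(["freshwater", "marine"]),
                hemisphere=rng.choice(["northern", "southern"]),
                delta_t=float(rng.uniform(5, 20)),
                ctmax=float(rng.uniform(28, 42)),
                n_individuals=int(rng.integers(5, 40)),
            )
            for i in range(40)
        ]
        y, X, names = build_design(traits, FULL_MODEL)
        assert X.shape == (40, 10)

    def test_interaction_column_is_elementwise_product(self):
        rng = np.random.default_rng(4)
        traits = [
            make_trait(
                f"s{i}",
                group=rng.choice(["temperate", "tropical"]),
                delta_t=float(rng.uniform(5, 20)),
            )
            for i in range(20)
        ]
        spec = ModelSpec(terms=["group", "delta_t"],
                         interactions=[("group", "delta_t")])
        _, X, names = build_design(traits, spec)
        np.testing.assert_array_equal(X[:, 3], X[:, 1] * X[:, 2])

    def test_single_level_factor_rejected(self):
        traits = [make_trait("a"), make_trait("b")]
        with pytest.raises(ModelError, match="single observed level"):
            build_design(traits, ModelSpec(terms=["group"]))

    def test_rank_deficiency_reported(self):
        traits = [
            make_trait("a", delta_t=1.0, ctmax=2.0),
            make_trait("b", delta_t=2.0, ctmax=4.0),
            make_trait("c", delta_t=3.0, ctmax=6.0),
            make_trait("d", delta_t=4.0, ctmax=8.0),
        ]
        with pytest.raises(ModelError, match="rank deficient"):
            build_design(traits, ModelSpec(terms=["delta_t", "ctmax"]))


class TestGLSFit:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(10)
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ [1.0, 2.0, -0.5] + rng.standard_normal(n)
        fit = gls_fit(y, X, np.eye(n))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coefficients, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.standard_errors, ols.bse, atol=1e-10)
        np.testing.assert_allclose(fit.t_values, ols.tvalues, atol=1e-10)
        np.testing.assert_allclose(fit.p_values, ols.pvalues, atol=1e-10)
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-8)

    def test_three_taxon_hand_computed_weighted_mean(self, three_taxon_tree):
        # V^-1-weighted mean of y=(1,2,4) with V=[[2,1,0],[1,2,0],[0,0,2]]
        # works out to 18/7 by direct 3x3 hand inversion
        V = trees.vcv_from_tree(three_taxon_tree)
        y = np.array([1.0, 2.0, 4.0])
        X = np.ones((3, 1))
        fit = gls_fit(y, X, V.matrix)
        assert fit.coefficients[0] == pytest.approx(18 / 7, abs=1e-10)

    def test_matches_explicit_inverse_gls(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(8, 21))
            y, X, V = random_instance(rng, n)
            fit = gls_fit(y, X, V.matrix)
            Vi = np.linalg.inv(V.matrix)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_loglik_is_multivariate_normal_density_at_mle(self):
        rng = np.random.default_rng(12)
        y, X, V = random_instance(rng, 15)
        fit = gls_fit(y, X, V.matrix)
        ll = stats.multivariate_normal.logpdf(
            y, mean=X @ fit.coefficients, cov=fit.sigma2_ml * V.matrix
        )
        assert fit.loglik == pytest.approx(ll, abs=1e-8)

    def test_covariance_scale_invariance(self):
        rng = np.random.default_rng(13)
        y, X, V = random_instance(rng, 18)
        a = gls_fit(y, X, V.matrix)
        b = gls_fit(y, X, 7.5 * V.matrix)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8)
        np.testing.assert_allclose(a.t_values, b.t_values, atol=1e-8)
        np.testing.assert_allclose(a.f_statistic, b.f_statistic, atol=1e-8)
        assert b.sigma2_ml == pytest.approx(a.sigma2_ml / 7.5, rel=1e-8)

    def test_matches_statsmodels_gls(self):
        rng = np.random.default_rng(14)
        y, X, V = random_instance(rng, 25)
        fit = gls_fit(y, X, V.matrix)
        ref = sm.GLS(y, X, sigma=V.matrix).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-8)
        np.testing.assert_allclose(fit.p_values, ref.pvalues, atol=1e-8)

    def test_singular_covariance_is_a_hard_error(self):
        n = 5
        V = np.ones((n, n))  # rank one
        y = np.arange(n, dtype=float)
        X = np.ones((n, 1))
        with pytest.raises(ModelError):
            gls_fit(y, X, V)

    def test_f_statistic_null_distribution_identity_v(self):
        # under an intercept-only truth the overall F follows F(p-1, n-p)
        rng = np.random.default_rng(15)
        n, p = 30, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        fs = []
        for _ in range(2000):
            y = 1.0 + rng.standard_normal(n)
            fs.append(glm_fit(y, X).f_statistic)
        q95 = np.quantile(fs, 0.95)
        analytic = stats.f.ppf(0.95, p - 1, n - p)
        assert abs(q95 - analytic) / analytic < 0.10


class TestProfileLambda:
    def test_refined_loglik_beats_the_grid(self):
        rng = np.random.default_rng(16)
        for _ in range(5):
            n = 40
            t = random_tree(rng, n_tips=n)
            vcv = trees.vcv_from_tree(t)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            y = simulate_species_means(
                t, X, np.array([0.0, 0.5]), 0.6, 0.5,
                int(rng.integers(0, 2**31)), vcv=vcv,
            )
            fit = profile_lambda(y, X, vcv)
            diag = np.diag(np.diag(vcv.matrix))
            off = vcv.matrix - diag
            for lam in np.linspace(0, 1, 101):
                ll = pgls._profile_loglik(lam, y, X, diag, off, n)
                assert fit.loglik >= ll - 1e-9

    def test_transformed_vcv_rejected(self, three_taxon_tree):
        vcv = trees.lambda_transform(
            trees.vcv_from_tree(three_taxon_tree), 0.5
        )
        with pytest.raises(ModelError):
            profile_lambda(np.zeros(3), np.ones((3, 1)), vcv)

    def test_lambda_counted_in_aic_penalty(self):
        rng = np.random.default_rng(17)
        t = random_tree(rng, n_tips=30)
        vcv = trees.vcv_from_tree(t)
        X = np.ones((30, 1))
        y = rng.standard_normal(30)
        fit = profile_lambda(y, X, vcv)
        assert fit.k_parameters == 1 + 1 + 1
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 3, abs=1e-10)


class TestGLM:
    def test_noiseless_line_recovered_exactly(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([np.ones(10), x])
        y = 2 * x + 1
        fit = glm_fit(y, X)
        np.testing.assert_allclose(fit.coefficients, [1.0, 2.0], atol=1e-10)

    def test_equals_gls_with_identity(self):
        rng = np.random.default_rng(18)
        n = 20
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        a = glm_fit(y, X)
        b = gls_fit(y, X, np.eye(n))
        np.testing.assert_allclose(a.coefficients, b.coefficients)
        np.testing.assert_allclose(a.loglik, b.loglik)
        assert a.lambda_hat is None


class TestAICSelect:
    @staticmethod
    def _fit_pair(y, X_small, X_big, Vmat):
        small = gls_fit(y, X_small, Vmat)
        big = gls_fit(y, X_big, Vmat)
        return small, big

    def test_duplicated_specs_tie_broken_by_order(self):
        rng = np.random.default_rng(19)
        n = 20
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        fit = glm_fit(y, X)
        spec = ModelSpec(terms=["delta_t"])
        table = aic_select([(spec, fit), (spec, fit)])
        assert table[0]["delta_aic"] == 0.0
        assert table[1]["delta_aic"] == 0.0
        assert [row["rank"] for row in table] == [1, 2]

    def test_differing_n_rejected(self):
        rng = np.random.default_rng(20)
        f1 = glm_fit(rng.standard_normal(10), np.ones((10, 1)))
        f2 = glm_fit(rng.standard_normal(12), np.ones((12, 1)))
        with pytest.raises(ModelError):
            aic_select([(ModelSpec(), f1), (ModelSpec(), f2)])

    def test_null_extra_term_rarely_helps(self):
        # a spurious extra covariate should lose the AIC race most of the
        # time (AIC keeps it with known ~16% probability per 2*k penalty)
        rng = np.random.default_rng(21)
        n = 200
        t = random_tree(rng, n_tips=n)
        Vm = trees.lambda_transform(trees.vcv_from_tree(t), 0.5)
        L = np.linalg.cholesky(Vm.matrix)
        wins_simple = 0
        reps = 200
        spec_s = ModelSpec(terms=["delta_t"])
        spec_b = ModelSpec(terms=["delta_t", "ctmax"])
        for _ in range(reps):
            x1 = rng.standard_normal(n)
            x2 = rng.standard_normal(n)
            y = 0.5 * x1 + L @ rng.standard_normal(n)
            Xs = np.column_stack([np.ones(n), x1])
            Xb = np.column_stack([np.ones(n), x1, x2])
            small, big = self._fit_pair(y, Xs, Xb, Vm.matrix)
            table = aic_select([(spec_s, small), (spec_b, big)])
            if table[0]["formula"] == spec_s.formula():
                wins_simple += 1
        assert wins_simple / reps >= 0.60

    def test_strong_true_effect_beats_null_model(self):
        rng = np.random.default_rng(22)
        n = 200
        t = random_tree(rng, n_tips=n)
        Vm = trees.lambda_transform(trees.vcv_from_tree(t), 0.5)
        L = np.linalg.cholesky(Vm.matrix)
        scale = np.sqrt(np.mean(np.diag(Vm.matrix)))
        wins_true = 0
        reps = 200
        spec_null = ModelSpec(terms=[])
        spec_true = ModelSpec(terms=["delta_t"])
        for _ in range(reps):
            x = rng.standard_normal(n)
            se_approx = scale / np.sqrt(n)
            beta = 4.0 * se_approx
            y = beta * x + L @ rng.standard_normal(n)
            Xn = np.ones((n, 1))
            Xt = np.column_stack([np.ones(n), x])
            null, true = self._fit_pair(y, Xn, Xt, Vm.matrix)
            table = aic_select([(spec_null, null), (spec_true, true)])
            if table[0]["formula"] == spec_true.formula():
                wins_true += 1
        assert wins_true / reps >= 0.95
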