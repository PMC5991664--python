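"""Covariance algebra, FIML likelihood and model fitting."""

import numpy as np
import pytest

import twinpath as tp
from twinpath.cholesky import _FIMLProblem, _Layout, _smart_start
from conftest import fiml_bruteforce


def _spec_from_paths(a, e, phenotypes, means=None):
    p = len(phenotypes)
    return tp.CholeskyModelSpec(
        phenotypes=tuple(phenotypes),
        family="AE",
        sex_limitation="none",
        a_paths=np.asarray(a, float),
        e_paths=np.asarray(e, float),
        means=means or {"M": np.zeros(p), "F": np.zeros(p)},
    )


class TestExpectedPairCovariance:
    def test_e_only_model_has_zero_cross_twin_block(self):
        spec = _spec_from_paths(np.zeros((2, 2)), np.eye(2), ("x", "y"))
        for zyg in ("MZ", "DZ"):
            sigma, _ = tp.expected_pair_covariance(spec, zyg)
            assert np.allclose(sigma[:2, 2:], 0.0)

    def test_a_only_mz_cross_equals_within(self):
        a = np.array([[0.9, 0.0], [0.2, 0.6]])
        spec = _spec_from_paths(a, 1e-4 * np.eye(2), ("x", "y"))
        sigma, _ = tp.expected_pair_covariance(spec, "MZ")
        assert np.allclose(sigma[:2, :2], sigma[:2, 2:], atol=1e-6)

    def test_hand_worked_two_phenotype_example(self):
        """a = [[0.8, 0], [0.3, 0.5]] gives A = [[0.64, 0.24], [0.24, 0.34]]
        and a DZ cross-twin block of half that."""
        a = np.array([[0.8, 0.0], [0.3, 0.5]])
        spec = _spec_from_paths(a, 0.1 * np.eye(2), ("x", "y"))
        A = spec.a_paths @ spec.a_paths.T
        assert np.allclose(A, [[0.64, 0.24], [0.24, 0.34]])
        sigma, _ = tp.expected_pair_covariance(spec, "DZ")
        assert np.allclose(sigma[:2, 2:], [[0.32, 0.12], [0.12, 0.17]])
        # within-twin blocks identical across zygosity
        mz, _ = tp.expected_pair_covariance(spec, "MZ")
        assert np.allclose(mz[:2, :2], sigma[:2, :2])

    def test_ae_cross_twin_correlations_are_h2_and_half_h2(self, plain_model):
        """For standardized AE models the implied MZ cross-twin correlation
        of each phenotype is h2 and the DZ one is h2/2."""
        dec = tp.standardized_decomposition(plain_model)
        for zyg, factor in (("MZ", 1.0), ("DZ", 0.5)):
            sigma = plain_model.pair_covariance(zyg, "M")
            p = 4
            d = np.sqrt(np.diag(sigma))
            corr = sigma / np.outer(d, d)
            assert np.allclose(np.diag(corr[:p, p:]), factor * dec.h2, atol=1e-12)


class TestFIML:
    def test_single_standard_normal_pair(self):
        """One complete pair, one phenotype, identity covariance, zero means,
        observation (0, 0): -2LL = 2 ln(2 pi)."""
        import pandas as pd

        spec = _spec_from_paths([[np.sqrt(0.5)]], [[np.sqrt(0.5)]], ("x",))
        pairs = pd.DataFrame(
            {"pair_id": ["P1"], "zygosity": ["DZ"], "sex": ["M"],
             "x_t1": [0.0], "x_t2": [0.0]}
        )
        # DZ with A = 0.5 gives off-diagonal 0.25; use E-only for identity
        spec_id = _spec_from_paths([[0.0]], [[1.0]], ("x",))
        ds = tp.TwinDataset(pairs=pairs, phenotypes=("x",))
        val = tp.minus2_loglik_fiml(ds, spec_id)
        assert val == pytest.approx(2 * np.log(2 * np.pi), abs=1e-10)
        pairs2 = pairs.assign(x_t2=[np.nan])
        ds2 = tp.TwinDataset(pairs=pairs2, phenotypes=("x",))
        assert tp.minus2_loglik_fiml(ds2, spec_id) == pytest.approx(
            np.log(2 * np.pi), abs=1e-10
        )

    def test_matches_per_pair_density_oracle(self, plain_model):
        """Grouped sufficient-statistic FIML equals a direct per-pair
        multivariate-normal density evaluation (with missing data)."""
        ds = tp.simulate_twin_pairs(
            plain_model.with_(single_responder_rate=0.2), 40, 40,
            female_fraction=0.5, seed=21,
        )
        spec = tp.CholeskyModelSpec(
            phenotypes=plain_model.phenotypes,
            family="AE",
            sex_limitation="scalar",
            a_paths=plain_model.a_paths,
            e_paths=plain_model.e_paths,
            scalars={"k": np.asarray(plain_model.female_scalars)},
            means={"M": np.zeros(4), "F": np.zeros(4)},
        )
        ours = tp.minus2_loglik_fiml(ds, spec)
        oracle = fiml_bruteforce(ds, spec)
        assert ours == pytest.approx(oracle, abs=1e-8 * max(1, abs(oracle)))

    def test_analytic_gradient_matches_finite_differences(self, plain_model):
        ds = tp.simulate_twin_pairs(
            plain_model.with_(single_responder_rate=0.15), 60, 60,
            female_fraction=0.5, seed=22,
        )
        X, zyg, sex = ds.phenotype_pair_matrix()
        prob = _FIMLProblem(X, zyg, sex, 4)
        rng = np.random.default_rng(23)
        for fam, sl in (("AE", "scalar"), ("ACE", "common_effects"), ("AE", "free")):
            lay = _Layout(4, fam, sl, ("F", "M"))
            th = _smart_start(prob, lay, X, zyg, sex)
            th = th + 0.05 * rng.standard_normal(th.size)
            _, g = prob.neg2ll_and_grad(th, lay)
            for i in rng.choice(lay.n_params, size=8, replace=False):
                e = np.zeros_like(th)
                e[i] = 1e-6
                num = (
                    prob.neg2ll_and_grad(th + e, lay)[0]
                    - prob.neg2ll_and_grad(th - e, lay)[0]
                ) / 2e-6
                assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-4)


class TestModelDf:
    def test_arithmetic(self, plain_model):
        ds = tp.simulate_twin_pairs(plain_model, 5, 5, seed=24)
        assert tp.model_df(ds, 20) == 10 * 4 * 2 - 20
        with pytest.raises(ValueError):
            tp.model_df(ds, 10_000)

    def test_sex_specific_ace_vs_ae_frees_ten_paths_per_sex(self):
        """Dropping all C paths of a 4-variate sex-specific model frees 10
        parameters per sex: delta df = 20."""
        ace = _Layout(4, "ACE", "free", ("F", "M"))
        ae = _Layout(4, "AE", "free", ("F", "M"))
        assert ace.n_params - ae.n_params == 20
        # and the scalar pair differs by the 10 shared C paths
        assert (
            _Layout(4, "ACE", "scalar", ("F", "M")).n_params
            - _Layout(4, "AE", "scalar", ("F", "M")).n_params
            == 10
        )


class TestFitting:
    def test_recovers_generating_model_at_large_n(self, plain_model):
        """At 20,000 pairs per zygosity every standardized share and every
        rg/re entry is recovered to within Monte-Carlo precision."""
        ds = tp.simulate_twin_pairs(
            plain_model, 10_000, 10_000, female_fraction=0.5, seed=30
        )
        fit = tp.fit_model(ds, family="AE", sex_limitation="scalar")
        assert fit.converged
        dec = tp.standardized_decomposition(fit)
        cor = tp.correlation_decomposition(fit)
        truth_dec = tp.standardized_decomposition(plain_model)
        truth_cor = tp.correlation_decomposition(plain_model)
        assert np.allclose(dec.h2, truth_dec.h2, atol=0.03)
        assert np.allclose(dec.shares_a, truth_dec.shares_a, atol=0.03)
        assert np.allclose(cor.rg, truth_cor.rg, atol=0.03)
        assert np.allclose(cor.re, truth_cor.re, atol=0.03)
        assert np.allclose(fit.spec.scalars["k"], plain_model.female_scalars, atol=0.03)

    def test_c_variance_estimates_zero_when_absent(self, bivariate_model):
        ds = tp.simulate_twin_pairs(bivariate_model, 400, 400,
                                    female_fraction=0.0, seed=31)
        ace = tp.fit_model(ds, family="ACE", sex_limitation="none")
        ae = tp.fit_model(ds, family="AE", sex_limitation="none")
        dec = tp.standardized_decomposition(ace)
        assert np.all(dec.c2 < 0.07)
        assert ace.minus2ll <= ae.minus2ll + 1e-6
        assert ae.minus2ll - ace.minus2ll < 4.0  # boundary truth: near-zero gain

    def test_nested_model_likelihood_ordering(self, plain_model):
        """-2LL is monotone along the nesting ladder: free per-sex paths fit
        at least as well as scalar sex limitation, which fits at least as
        well as no sex limitation; ACE at least as well as AE."""
        ds = tp.simulate_twin_pairs(plain_model, 250, 250,
                                    female_fraction=0.5, seed=32)
        fits = {
            (fam, sl): tp.fit_model(ds, family=fam, sex_limitation=sl)
            for fam in ("ACE", "AE")
            for sl in ("free", "scalar", "none")
        }
        slack = 1e-4
        for fam in ("ACE", "AE"):
            assert fits[(fam, "free")].minus2ll <= fits[(fam, "scalar")].minus2ll + slack
            assert fits[(fam, "scalar")].minus2ll <= fits[(fam, "none")].minus2ll + slack
        for sl in ("free", "scalar", "none"):
            assert fits[("ACE", sl)].minus2ll <= fits[("AE", sl)].minus2ll + slack

    def test_scalar_ae_wins_aic_in_majority_of_replicates(self, plain_model):
        """Data generated under the AE model with female SD scalars select
        the AE scalar variant by AIC in most replicates (six-model ladder)."""
        from twinpath.study import DEFAULT_LADDER

        wins = 0
        for r in range(5):
            ds = tp.simulate_twin_pairs(plain_model, 373, 385,
                                        female_fraction=0.646, seed=40 + r)
            fits = {
                name: tp.fit_model(ds, family=fam, sex_limitation=sl)
                for name, fam, sl in DEFAULT_LADDER
            }
            table = tp.compare_models(fits)
            best = table.sort_values(["AIC", "n_params"]).index[0]
            wins += "AE (scalar" in best
        assert wins >= 3

    def test_preconditions(self, plain_model):
        ds = tp.simulate_twin_pairs(plain_model, 50, 0, seed=33)
        with pytest.raises(ValueError, match="MZ and DZ"):
            tp.fit_model(ds, family="AE")
        ds2 = tp.simulate_twin_pairs(plain_model, 50, 50, female_fraction=0.0, seed=34)
        with pytest.raises(ValueError, match="both sexes"):
            tp.fit_model(ds2, family="AE", sex_limitation="scalar")


class TestDecompositions:
    def test_diagonal_paths_give_identity_correlations(self):
        spec = _spec_from_paths(np.diag([0.7, 0.6]), np.diag([0.71, 0.8]), ("x", "y"))
        cor = tp.correlation_decomposition(spec)
        assert np.allclose(cor.rg, np.eye(2))
        dec = tp.standardized_decomposition(spec)
        assert dec.shares_a[0, 1] == 0.0 and dec.shares_a[1, 0] == 0.0

    def test_hand_computed_genetic_correlation(self):
        a = np.array([[0.8, 0.0], [0.3, 0.5]])
        spec = _spec_from_paths(a, 0.3 * np.eye(2), ("x", "y"))
        cor = tp.correlation_decomposition(spec)
        assert cor.rg[0, 1] == pytest.approx(0.24 / np.sqrt(0.64 * 0.34), abs=1e-12)

    def test_shares_sum_to_one(self, plain_model):
        dec = tp.standardized_decomposition(plain_model)
        total = dec.shares_a.sum(axis=1) + dec.shares_e.sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-8)
        assert np.allclose(dec.h2, dec.shares_a.sum(axis=1))

    def test_implied_phenotypic_correlation_identity(self, plain_model):
        """For AE models r_P = sqrt(h2_i h2_j) rg + sqrt(e2_i e2_j) re."""
        dec = tp.standardized_decomposition(plain_model)
        cor = tp.correlation_decomposition(plain_model)
        P = plain_model.phenotypic_cov("M")
        d = np.sqrt(np.diag(P))
        R = P / np.outer(d, d)
        implied = (
            np.sqrt(np.outer(dec.h2, dec.h2)) * cor.rg
            + np.sqrt(np.outer(dec.e2, dec.e2)) * cor.re
        )
        assert np.allclose(R, implied, atol=1e-10)

    def test_zero_variance_component_reported_undefined(self):
        spec = _spec_from_paths(
            [[0.8, 0.0], [0.0, 0.0]], [[0.6, 0.0], [0.1, 0.9]], ("x", "y")
        )
        cor = tp.correlation_decomposition(spec)
        assert np.isnan(cor.rg[0, 1]) and np.isnan(cor.rg[1, 1])


class TestCompareModels:
    def test_mx_aic_identity(self):
        """AIC = -2LL - 2*df reproduces the published bookkeeping."""
        f = tp.FittedBiometricModel(
            spec=None, minus2ll=8571.44, n_params=0, n_obs_values=5960,
            df=5960, converged=True, n_iter=0, grad_norm=0.0,
        )
        assert f.aic == pytest.approx(-3348.56)

    def test_self_comparison_and_validation(self, bivariate_model):
        ds = tp.simulate_twin_pairs(bivariate_model, 150, 150,
                                    female_fraction=0.0, seed=35)
        fit = tp.fit_model(ds, family="AE", sex_limitation="none")
        table = tp.compare_models({"m": fit, "same": fit}, baseline="m")
        assert table.loc["same", "delta_minus2LL"] == 0.0
        assert table.loc["same", "delta_df"] == 0.0
        other = tp.simulate_twin_pairs(bivariate_model, 100, 100,
                                       female_fraction=0.0, seed=36)
        fit2 = tp.fit_model(other, family="AE", sex_limitation="none")
        with pytest.raises(ValueError, match="same dataset"):
            tp.compare_models({"a": fit, "b": fit2})
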