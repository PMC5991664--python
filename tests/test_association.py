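"""Correlations, clustered regression and the extreme-scorer filter."""

import numpy as np
import pandas as pd
import pytest

import twinpath as tp
from conftest import gee_bruteforce


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2, 3, 4])
        assert tp.pearson_corr_ci(x, 2 * x).r == pytest.approx(1.0)
        assert tp.pearson_corr_ci([1, 2, 3, 4], [8, 6, 4, 2]).r == pytest.approx(-1.0)

    def test_hand_computed_fisher_interval(self):
        """r = 0.6 at n = 4: z = artanh(0.6) = 0.6931, SE = 1, so the 95%
        bounds are tanh(0.6931 -/+ 1.96)."""
        cc = tp.pearson_corr_ci([1, 2, 3, 4], [2, 1, 4, 3])
        assert cc.r == pytest.approx(0.6, abs=1e-12)
        assert cc.ci_low == pytest.approx(-0.8529, abs=2e-4)
        assert cc.ci_high == pytest.approx(0.9901, abs=2e-4)
        assert cc.ci_low <= cc.r <= cc.ci_high

    def test_ci_width_decreases_with_n(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(400)
        y = 0.5 * x + rng.standard_normal(400)
        small = tp.pearson_corr_ci(x[:30], y[:30])
        large = tp.pearson_corr_ci(x, y)
        assert (large.ci_high - large.ci_low) < (small.ci_high - small.ci_low)

    def test_errors(self):
        with pytest.raises(ValueError):
            tp.pearson_corr_ci([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="zero variance"):
            tp.pearson_corr_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestGEE:
    def test_singleton_clusters_equal_ols(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(80),
                "x": rng.standard_normal(80),
                "pair_id": np.arange(80),
            }
        )
        res = tp.gee_exchangeable(df, "y", ["x"])
        import statsmodels.api as sm

        ols = sm.OLS(df["y"], sm.add_constant(df[["x"]])).fit()
        assert np.allclose(res.coefficients.to_numpy(), ols.params.to_numpy(), atol=1e-8)

    def test_independence_working_correlation_equals_ols(self):
        rng = np.random.default_rng(2)
        n = 60
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(n),
                "x": rng.standard_normal(n),
                "pair_id": np.repeat(np.arange(n // 2), 2),
            }
        )
        res = tp.gee_exchangeable(df, "y", ["x"], working="independence")
        import statsmodels.api as sm

        ols = sm.OLS(df["y"], sm.add_constant(df[["x"]])).fit()
        assert np.allclose(res.coefficients.to_numpy(), ols.params.to_numpy(), atol=1e-10)

    def test_matches_independent_fixed_point_implementation(self):
        """Exchangeable GEE on balanced clusters agrees with a brute-force
        Liang-Zeger fixed-point iteration written from the estimating
        equations directly."""
        rng = np.random.default_rng(3)
        n_cl = 6
        g = np.repeat(np.arange(n_cl), 2)
        x1 = rng.normal(size=2 * n_cl)
        u = np.repeat(rng.normal(size=n_cl), 2)
        y = 1.0 + 0.5 * x1 + u + 0.5 * rng.normal(size=2 * n_cl)
        df = pd.DataFrame({"y": y, "x1": x1, "pair_id": g})
        res = tp.gee_exchangeable(df, "y", ["x1"])
        beta, alpha = gee_bruteforce(y, np.column_stack([np.ones(2 * n_cl), x1]), g)
        assert np.allclose(res.coefficients.to_numpy(), beta, atol=1e-8)
        assert res.working_corr == pytest.approx(alpha, abs=1e-8)

    def test_recovers_generating_effects_on_fatigue(self, plain_model):
        """Anxiety-depression (0.40) and MS pain (0.31) effects injected into
        a simulated cohort are recovered within 3 robust SEs; sex and
        education with no generating effect stay null."""
        ds = tp.simulate_twin_pairs(plain_model, 375, 375, female_fraction=0.646, seed=13)
        ind = ds.individuals()
        rng = np.random.default_rng(14)
        noise = np.sqrt(0.5) * rng.standard_normal(len(ind))
        ind = ind.assign(
            outcome=0.40 * ind["anxdep"] + 0.31 * ind["mspain"] + noise,
            female=(ind["sex"] == "F").astype(float),
            education=rng.integers(1, 6, size=len(ind)).astype(float),
        )
        res = tp.gee_exchangeable(
            ind, "outcome", ["anxdep", "mspain", "female", "education"]
        )
        co, se = res.coefficients, res.robust_se
        assert abs(co["anxdep"] - 0.40) < 3 * se["anxdep"]
        assert abs(co["mspain"] - 0.31) < 3 * se["mspain"]
        for null in ("female", "education"):
            assert abs(co[null]) < 3 * se[null]
        assert co["anxdep"] > 0 and co["mspain"] > 0
        assert res.converged

    def test_health_index_effect_recovery(self):
        """A +0.24 binary health-index effect on fatigue survives the round
        trip through the generator and the GEE fit."""
        spec = tp.CovariateSpec(
            binary={"impairment": 0.3}, effects={"impairment": {"fatigue": 0.24}}
        )
        model = tp.reference_generating_model(
            items=False, covariates=False, single_responder_rate=0.0
        ).with_(covariate_spec=spec)
        ds = tp.simulate_twin_pairs(model, 1000, 1000, seed=15)
        ind = ds.individuals()
        res = tp.gee_exchangeable(ind, "fatigue", ["impairment"])
        assert abs(res.coefficients["impairment"] - 0.24) < 3 * res.robust_se["impairment"]

    def test_singular_design_names_collinear_columns(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"y": rng.standard_normal(40), "x": rng.standard_normal(40)})
        df["x2"] = 2 * df["x"]
        df["pair_id"] = np.repeat(np.arange(20), 2)
        with pytest.raises(ValueError, match="x2"):
            tp.gee_exchangeable(df, "y", ["x", "x2"])


class TestHierarchicalBlocks:
    def test_overlapping_blocks_rejected(self, reference_cohort):
        with pytest.raises(ValueError, match="overlap"):
            tp.hierarchical_blocks_r2(
                reference_cohort, "fatigue", ["anxdep"], ["anxdep"], subsample="twin1"
            )

    def test_orthogonal_second_block_adds_nothing(self):
        rng = np.random.default_rng(5)
        n = 4000
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(n),
                "x": rng.standard_normal(n),
                "junk": rng.standard_normal(n),
            }
        )
        df["y"] = 0.6 * df["x"] + np.sqrt(1 - 0.36) * df["y"]
        out = tp.hierarchical_blocks_r2(df, "y", ["x"], ["junk"])
        assert out["delta_r2"] < 0.01

    def test_block1_r2_matches_model_implied_value(self, reference_cohort):
        """R2 of fatigue on neuroticism, anxiety-depression and MS pain in a
        twin subsample matches the value implied by the generating
        correlation structure (near the published ~0.5-0.6)."""
        out = tp.hierarchical_blocks_r2(
            reference_cohort,
            "fatigue",
            ["neo_neuro", "anxdep", "mspain"],
            ["medical_condition", "impairment", "reduced_activity"],
            subsample="twin1",
        )
        # implied population R2 from the truth's phenotypic correlations
        P = reference_cohort.truth.phenotypic_cov("M")
        d = np.sqrt(np.diag(P))
        R = P / np.outer(d, d)
        r = R[3, :3]
        implied = float(r @ np.linalg.solve(R[:3, :3], r))
        assert out["r2_block1"] == pytest.approx(implied, abs=0.06)
        assert 0 <= out["delta_r2"] < 0.1
        assert 0.4 < out["r2_block1"] < 0.65


class TestExtremeScorers:
    def test_threshold_above_scale_maximum_is_identity(self, reference_cohort):
        filtered, summary = tp.exclude_extreme_scorers(reference_cohort, "fatigue", 99.0)
        assert summary["n_excluded"] == 0
        assert len(filtered) == len(reference_cohort)

    def test_direct_count(self, plain_model):
        spec = tp.reference_generating_model(items=True, covariates=False,
                                             single_responder_rate=0.0)
        ds = tp.simulate_twin_pairs(spec, 10, 10, seed=16)
        means = pd.concat(
            [
                ds.pairs[[f"fatigue{i}_t{t}" for i in range(1, 7)]].mean(axis=1)
                for t in (1, 2)
            ]
        )
        expected = int((means >= 2.0).sum())
        _, summary = tp.exclude_extreme_scorers(ds, "fatigue", 2.0)
        assert summary["n_excluded"] == expected
        assert summary["n_subjects"] == 40

    def test_about_five_percent_excluded_at_published_threshold(self, reference_cohort):
        """With item marginals calibrated to the published distribution,
        ~5% of subjects score at 'considerable' or above on average."""
        _, summary = tp.exclude_extreme_scorers(reference_cohort, "fatigue", 3.0)
        assert summary["fraction_excluded"] == pytest.approx(0.05, abs=0.03)

    def test_idempotent(self, reference_cohort):
        once, s1 = tp.exclude_extreme_scorers(reference_cohort, "fatigue", 3.0)
        twice, s2 = tp.exclude_extreme_scorers(once, "fatigue", 3.0)
        assert s2["n_excluded"] == 0
        pd.testing.assert_frame_equal(once.pairs, twice.pairs)

    def test_unknown_scale_rejected(self, reference_cohort):
        with pytest.raises(ValueError, match="unknown scale"):
            tp.exclude_extreme_scorers(reference_cohort, "nope", 3.0)
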