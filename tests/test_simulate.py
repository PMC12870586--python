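"""Generator contracts: kinship structure, planted effects, missingness."""

import numpy as np
import pandas as pd
import pytest

import pwaskit as pk
from pwaskit.simulate import DEFAULT_MISSINGNESS


class TestKinship:
    def test_singletons_give_identity(self):
        spec = pk.PedigreeSpec(n_families=25, family_size_weights={1: 1.0}, seed=0)
        K, _ = pk.simulate_kinship(spec)
        np.testing.assert_allclose(K.to_numpy(), np.eye(25))

    def test_sib_pair_block(self):
        spec = pk.PedigreeSpec(n_families=1, family_size_weights={2: 1.0}, seed=0)
        K, _ = pk.simulate_kinship(spec)
        np.testing.assert_allclose(K.to_numpy(), [[1.0, 0.5], [0.5, 1.0]])

    def test_trio_block_eigenvalues(self):
        # 3x3 compound-symmetric block with r=0.5 has eigenvalues {2, 0.5, 0.5}
        spec = pk.PedigreeSpec(n_families=50, family_size_weights={3: 1.0}, seed=3)
        K, _ = pk.simulate_kinship(spec)
        ev = np.linalg.eigvalsh(K.to_numpy())
        assert ev.min() == pytest.approx(0.5, abs=1e-10)
        assert ev.max() == pytest.approx(2.0, abs=1e-10)

    def test_symmetric_unit_diagonal_psd(self):
        spec = pk.PedigreeSpec(n_families=40, seed=5)
        K, _ = pk.simulate_kinship(spec)
        A = K.to_numpy()
        np.testing.assert_allclose(A, A.T)
        np.testing.assert_allclose(np.diag(A), 1.0)
        assert np.linalg.eigvalsh(A).min() >= -1e-10

    def test_relatedness_one_rejected(self):
        with pytest.raises(ValueError, match="relatedness"):
            pk.PedigreeSpec(n_families=5, relatedness_within=1.0)


class TestProteome:
    def test_same_seed_bit_identical(self):
        spec = pk.ProteomeSpec(n_signals=10, seed=7)
        K = np.eye(50)
        a = pk.simulate_proteome(50, spec, K)
        b = pk.simulate_proteome(50, spec, K)
        assert a.equals(b)

    def test_independent_columns_uncorrelated(self):
        spec = pk.ProteomeSpec(
            n_signals=30, n_factors=0, genetic_variance_fraction=0.0,
            noise_sd=1.0, seed=8,
        )
        X = pk.simulate_proteome(2000, spec, np.eye(2000)).to_numpy()
        corr = np.corrcoef(X, rowvar=False)
        off = corr[np.triu_indices_from(corr, 1)]
        assert abs(off.mean()) < 0.01

    def test_sib_pair_signal_correlation(self, sib_pair_kinship):
        # expected within-pair correlation = h2 * relatedness = 0.5 * 0.5
        K, _ = sib_pair_kinship
        n = K.shape[0]
        spec = pk.ProteomeSpec(
            n_signals=60, n_factors=0, genetic_variance_fraction=0.5,
            noise_sd=np.sqrt(0.5), seed=9,
        )
        X = pk.simulate_proteome(n, spec, K).to_numpy()
        r = np.mean(
            [np.corrcoef(X[0::2, j], X[1::2, j])[0, 1] for j in range(X.shape[1])]
        )
        assert r == pytest.approx(0.25, abs=0.03)

    def test_bad_variance_fraction_rejected(self):
        with pytest.raises(ValueError):
            pk.ProteomeSpec(genetic_variance_fraction=1.0)
        with pytest.raises(ValueError, match="exceeds 1"):
            pk.ProteomeSpec(genetic_variance_fraction=0.8, noise_sd=0.9)


class TestOutcomes:
    def test_ols_recovers_planted_coefficients(self):
        n, p, q = 5000, 20, 3
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((n, p)))
        effects = {(2, 0): 0.3, (7, 1): -0.25, (11, 2): 0.2}
        plan = pk.EffectPlan(n_outcomes=q, true_effects=effects)
        Y = pk.simulate_outcomes(X, plan, seed=11).to_numpy()
        B_hat = np.linalg.lstsq(X.to_numpy(), Y, rcond=None)[0]
        # outcomes are standardized after generation: rescale truth per column
        scale = np.ones(q)
        for (j, k), b in effects.items():
            scale[k] = np.sqrt(1.0 + b**2)
        for (j, k), b in effects.items():
            assert B_hat[j, k] == pytest.approx(b / scale[k], abs=0.03)

    def test_null_plan_uncorrelated(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.standard_normal((3000, 5)))
        Y = pk.simulate_outcomes(X, pk.EffectPlan(n_outcomes=2), seed=13)
        corr = np.corrcoef(X.to_numpy().T, Y.to_numpy().T)[:5, 5:]
        assert np.abs(corr).max() < 0.06

    def test_non_psd_residual_correlation_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])
        plan = pk.EffectPlan(n_outcomes=2, residual_outcome_correlation=C)
        with pytest.raises(ValueError, match="positive semi-definite"):
            plan.correlation()


class TestCovariates:
    def test_zero_rates_complete(self):
        rates = {k: 0.0 for k in DEFAULT_MISSINGNESS}
        tab = pk.simulate_covariates(500, rates, seed=14)
        assert not tab.isna().any().any()

    def test_configured_missingness_rate(self):
        tab = pk.simulate_covariates(10000, seed=15)
        frac = tab["alcohol"].isna().mean()
        se = np.sqrt(0.09 * 0.91 / 10000)
        assert abs(frac - 0.09) < 3 * se

    def test_age_and_sex_never_missing(self):
        tab = pk.simulate_covariates(5000, seed=16)
        assert tab["age"].notna().all() and tab["sex"].notna().all()
        with pytest.raises(ValueError, match="age and sex"):
            pk.simulate_covariates(10, {"age": 0.5})

    def test_education_is_eleven_category_ordinal(self):
        tab = pk.simulate_covariates(3000, seed=17)
        vals = tab["education"].dropna().unique()
        assert set(vals).issubset(set(float(v) for v in range(11)))

    def test_rate_of_one_rejected(self):
        with pytest.raises(ValueError):
            pk.simulate_covariates(10, {"bmi": 1.0})


class TestApoe:
    def test_hardy_weinberg_homozygote_fraction(self):
        counts, _ = pk.simulate_apoe(20000, 0.15, seed=18)
        frac2 = (counts == 2).mean()
        se = np.sqrt(0.0225 * (1 - 0.0225) / 20000)
        assert abs(frac2 - 0.0225) < 4 * se

    def test_per_copy_shift_group_means(self, rng):
        n = 20000
        prot = pd.DataFrame({"signal_001": rng.standard_normal(n)})
        counts, shifted = pk.simulate_apoe(
            n, 0.3, {"signal_001": -0.2}, prot, seed=19
        )
        x = shifted["signal_001"]
        diff = x[counts == 2].mean() - x[counts == 0].mean()
        assert diff == pytest.approx(-0.4, abs=0.05)

    def test_empty_shift_map_leaves_proteins_untouched(self, rng):
        prot = pd.DataFrame({"s": rng.standard_normal(100)})
        _, shifted = pk.simulate_apoe(100, 0.2, None, prot, seed=20)
        assert shifted.equals(prot)

    def test_unknown_signal_rejected(self, rng):
        prot = pd.DataFrame({"s": rng.standard_normal(50)})
        with pytest.raises(KeyError, match="unknown signal"):
            pk.simulate_apoe(50, 0.2, {"nope": 0.1}, prot, seed=21)


class TestSurvival:
    def test_full_admin_censoring_gives_zero_events(self, rng):
        prot = pd.DataFrame({"s": rng.standard_normal(200)})
        spec = pk.SurvivalSpec(admin_censor_fraction=1.0, seed=22)
        surv = pk.simulate_survival(200, prot, spec)
        assert surv["event"].sum() == 0

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError, match="baseline_hazard_scale"):
            pk.SurvivalSpec(baseline_hazard_scale=0.0)

    def test_null_loghr_independent_of_signals(self, rng):
        prot = pd.DataFrame(rng.standard_normal((3000, 2)), columns=["a", "b"])
        spec = pk.SurvivalSpec(seed=23)
        surv = pk.simulate_survival(3000, prot, spec)
        ev = surv["event"].to_numpy()
        assert surv["event"].sum() > 50
        r = np.corrcoef(prot["a"], ev)[0, 1]
        assert abs(r) < 0.04

    def test_exit_after_entry_and_event_binary(self, rng):
        prot = pd.DataFrame({"s": rng.standard_normal(500)})
        surv = pk.simulate_survival(500, prot, pk.SurvivalSpec(seed=24))
        assert (surv["exit_age"] > 0).all()
        assert set(surv["event"].unique()).issubset({0, 1})
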