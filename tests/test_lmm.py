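"""Kinship LMM: REML contracts, residualization, APOE factor contrasts."""

import numpy as np
import pandas as pd
import pytest

from pwaskit.lmm import (
    KinshipDecomposition,
    KinshipLMM,
    apoe_association,
    fit_lmm,
    residualize_protein,
)
from pwaskit.simulate import simulate_apoe


def _sim_lmm_data(K, h2, rng, p_fixed=2):
    n = K.shape[0]
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p_fixed - 1))])
    beta = rng.normal(0, 1, p_fixed)
    y = (
        X @ beta
        + L @ rng.standard_normal(n) * np.sqrt(h2)
        + rng.standard_normal(n) * np.sqrt(1 - h2)
    )
    return y, X


class TestReml:
    def test_identity_kinship_matches_ols(self, rng):
        n = 250
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ [0.5, 1.0, -0.8] + rng.standard_normal(n)
        fit = fit_lmm(y, X, np.eye(n))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(fit.params - ols).max() < 1e-6
        # total variance matches the OLS residual variance
        resid = y - X @ ols
        assert fit.sigma2_g + fit.sigma2_e == pytest.approx(
            resid @ resid / (n - 3), rel=1e-3
        )

    def test_reml_optimum_at_least_ols(self, sib_pair_kinship, rng):
        K, _ = sib_pair_kinship
        Kv = K.to_numpy()
        dec = KinshipDecomposition(Kv)
        for _ in range(5):
            y, X = _sim_lmm_data(Kv, 0.5, rng)
            m = KinshipLMM(y, X, dec)
            fit = m.fit()
            assert fit.llf_reml >= m._ols_reml_loglik() - 1e-8

    def test_variance_fraction_recovery_mean(self, sib_pair_kinship, rng):
        # truth 0.4; mean over replicates within +-0.05 (shared decomposition)
        K, _ = sib_pair_kinship
        Kv = K.to_numpy()
        dec = KinshipDecomposition(Kv)
        ests = []
        for _ in range(50):
            y, X = _sim_lmm_data(Kv, 0.4, rng, p_fixed=1)
            ests.append(KinshipLMM(y, X, dec).fit().heritable_fraction)
        assert np.mean(ests) == pytest.approx(0.4, abs=0.05)

    def test_row_permutation_invariance(self, rng):
        n = 120
        K = np.kron(np.eye(n // 2), np.array([[1.0, 0.5], [0.5, 1.0]]))
        y, X = _sim_lmm_data(K, 0.5, rng)
        fit = fit_lmm(y, X, K)
        perm = rng.permutation(n)
        fit_p = fit_lmm(y[perm], X[perm], K[np.ix_(perm, perm)])
        np.testing.assert_allclose(fit.params, fit_p.params, atol=1e-6)

    def test_rank_deficient_design_names_columns(self, rng):
        n = 50
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="aliased.*x2"):
            KinshipLMM(rng.standard_normal(n), X, np.eye(n), exog_names=["i", "x1", "x2"])

    def test_non_psd_kinship_rejected(self, rng):
        K = np.eye(10)
        K[0, 1] = K[1, 0] = 1.5
        with pytest.raises(ValueError, match="PSD"):
            KinshipDecomposition(K)


class TestResidualize:
    def test_identity_kinship_equals_scaled_ols_residuals(self, rng):
        n = 300
        cov = pd.DataFrame(
            {"age": rng.normal(50, 10, n), "sex": rng.binomial(1, 0.5, n).astype(float)}
        )
        y = 0.02 * cov["age"].to_numpy() + rng.standard_normal(n)
        r = residualize_protein(y, cov, np.eye(n))
        X = np.column_stack([np.ones(n), cov["age"], cov["sex"]])
        ols_r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        ols_r = (ols_r - ols_r.mean()) / ols_r.std(ddof=1)
        np.testing.assert_allclose(r, ols_r, atol=1e-6)

    def test_covariate_signal_removed(self, sib_pair_kinship, rng):
        K, _ = sib_pair_kinship
        n = K.shape[0]
        cov = pd.DataFrame(
            {"age": rng.normal(50, 10, n), "sex": rng.binomial(1, 0.5, n).astype(float)},
            index=K.index,
        )
        y = 0.05 * cov["age"].to_numpy() - 0.3 * cov["sex"].to_numpy() + rng.standard_normal(n)
        r = residualize_protein(y, cov, K)
        assert abs(np.corrcoef(r, cov["age"])[0, 1]) < 0.02
        assert abs(np.corrcoef(r, cov["sex"])[0, 1]) < 0.02
        assert r.mean() == pytest.approx(0.0, abs=1e-10)
        assert r.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_exact_linear_response_flagged(self, rng):
        n = 80
        cov = pd.DataFrame(
            {"age": rng.normal(50, 10, n), "sex": rng.binomial(1, 0.5, n).astype(float)}
        )
        y = 1.0 + 0.1 * cov["age"].to_numpy()
        with pytest.raises(ValueError, match="zero variance|degenerate"):
            residualize_protein(y, cov, np.eye(n))


class TestApoeAssociation:
    def _cov(self, n, rng, index=None):
        return pd.DataFrame(
            {"age": rng.normal(50, 10, n), "sex": rng.binomial(1, 0.5, n).astype(float)},
            index=index,
        )

    def test_planted_per_copy_shift_recovered(self, rng):
        n = 4000
        prot = pd.DataFrame({"signal_001": rng.standard_normal(n)})
        counts, shifted = simulate_apoe(n, 0.2, {"signal_001": -0.2}, prot, seed=31)
        tab = apoe_association(
            shifted["signal_001"].to_numpy(), counts, self._cov(n, rng), np.eye(n)
        )
        b1 = tab.loc[tab.contrast == "1 vs 0 copies"].iloc[0]
        b2 = tab.loc[tab.contrast == "2 vs 0 copies"].iloc[0]
        assert b1.beta == pytest.approx(-0.2, abs=3 * b1.se)
        assert b2.beta == pytest.approx(-0.4, abs=3 * b2.se)

    def test_null_type_one_error(self, rng):
        # shared 400-person design, 500 null replicates at alpha = 0.05
        n = 400
        counts = np.repeat([0, 1, 2], [260, 110, 30])
        cov = self._cov(n, rng)
        dec = KinshipDecomposition(np.eye(n))
        hits = total = 0
        for _ in range(500):
            y = rng.standard_normal(n)
            tab = apoe_association(y, counts, cov, dec)
            hits += int((tab["p"] < 0.05).sum())
            total += len(tab)
        rate = hits / total
        assert 0.025 < rate < 0.075

    def test_permuted_genotypes_destroy_association(self, rng):
        n = 2000
        prot = pd.DataFrame({"s": rng.standard_normal(n)})
        counts, shifted = simulate_apoe(n, 0.2, {"s": -0.5}, prot, seed=32)
        perm = rng.permutation(n)
        tab = apoe_association(
            shifted["s"].to_numpy(), counts.to_numpy()[perm], self._cov(n, rng), np.eye(n)
        )
        assert (tab["p"] > 0.001).all()

    def test_missing_genotype_level_rejected(self, rng):
        n = 100
        counts = np.repeat([0, 1], [50, 50])
        with pytest.raises(ValueError, match="allele count"):
            apoe_association(rng.standard_normal(n), counts, self._cov(n, rng), np.eye(n))

    def test_basic_vs_full_estimates_agree_without_confounding(self, rng):
        n = 1500
        cols = ["simd", "bmi", "alcohol", "smoking_score", "depression",
                "education", "high_blood_pressure"]
        cov = self._cov(n, rng)
        for c in cols:
            cov[c] = rng.standard_normal(n)
        b_basic, b_full = [], []
        dec = KinshipDecomposition(np.eye(n))
        for rep in range(12):
            prot = pd.DataFrame({"s": rng.standard_normal(n)})
            counts, shifted = simulate_apoe(n, 0.25, {"s": -0.3}, prot, seed=100 + rep)
            y = shifted["s"].to_numpy()
            b_basic.append(
                apoe_association(y, counts, cov, dec, adjustment="basic")["beta"].values
            )
            b_full.append(
                apoe_association(y, counts, cov, dec, adjustment="full")["beta"].values
            )
        r = np.corrcoef(np.ravel(b_basic), np.ravel(b_full))[0, 1]
        assert r > 0.95
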