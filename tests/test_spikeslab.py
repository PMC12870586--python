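"""Spike-and-slab sampler: oracles, calibration, summaries, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from pwaskit.benchmarks import null_max_pip, single_site_oracle
from pwaskit.preprocess import standardize
from pwaskit.simulate import EffectPlan, simulate_outcomes
from pwaskit.spikeslab import (
    PosteriorDraws,
    SpikeSlabConfig,
    SpikeSlabMultiTrait,
    convergence_diagnostics,
    summarize,
)


def _planted_fit(rng, n=500, p=50, q=3, beta=0.5, n_iter=2000, burn_in=500, seed=5):
    # residual variance 1 - beta^2 so the planted standardized effect is beta
    X = standardize(rng.standard_normal((n, p)))
    B = np.zeros((p, q))
    B[3, 1] = beta
    Y = standardize(X @ B + rng.standard_normal((n, q)) * np.sqrt(1 - beta**2))
    model = SpikeSlabMultiTrait(Y, X)
    return model.fit(config=SpikeSlabConfig(n_iter=n_iter, burn_in=burn_in, seed=seed))


class TestGibbs:
    def test_conjugate_single_site_matches_closed_form(self):
        pip, closed = single_site_oracle(n_draws=20000, seed=3)
        assert pip == pytest.approx(closed, abs=0.02)

    def test_planted_effect_detected_with_interval_coverage(self, rng):
        res = _planted_fit(rng)
        pip = res.pip.to_numpy()
        assert pip[3, 1] > 0.99
        tab = res.summary_frame()
        row = tab[(tab.signal == "x4") & (tab.outcome == "outcome_2")].iloc[0]
        assert row.ci_low <= 0.5 <= row.ci_high
        assert row.significant

    def test_null_data_rarely_crosses_pip_threshold(self):
        maxpips = null_max_pip(n_seeds=20, seed=4)
        assert sum(m < 0.95 for m in maxpips) >= 18

    def test_fixed_seed_reproduces_draws_exactly(self, rng):
        X = standardize(rng.standard_normal((120, 8)))
        Y = standardize(rng.standard_normal((120, 2)))
        cfg = SpikeSlabConfig(n_iter=300, burn_in=100, seed=42)
        a = SpikeSlabMultiTrait(Y, X).fit(config=cfg)
        b = SpikeSlabMultiTrait(Y, X).fit(config=cfg)
        np.testing.assert_array_equal(a.draws.B, b.draws.B)
        np.testing.assert_array_equal(a.draws.Gamma, b.draws.Gamma)

    def test_spike_zero_conservation_in_every_draw(self, rng):
        res = _planted_fit(rng, n=200, p=10, q=2, n_iter=500, burn_in=100)
        d = res.draws
        assert (d.B[d.Gamma == 0] == 0.0).all()
        assert (d.B[d.Gamma == 1] != 0.0).all()

    def test_column_permutation_moves_pip_with_the_signal(self, rng):
        n, p = 400, 20
        X = standardize(rng.standard_normal((n, p)))
        y = standardize(X[:, 7] * 0.5 + rng.standard_normal(n) * 0.8)
        cfg = SpikeSlabConfig(n_iter=1000, burn_in=300, seed=9)
        res = SpikeSlabMultiTrait(y, X).fit(config=cfg)
        perm = np.roll(np.arange(p), 5)
        res_p = SpikeSlabMultiTrait(y, X[:, perm]).fit(config=cfg)
        pip, pip_p = res.pip.to_numpy()[:, 0], res_p.pip.to_numpy()[:, 0]
        assert pip[7] > 0.99 and pip_p[np.flatnonzero(perm == 7)[0]] > 0.99

    def test_unstandardized_input_rejected(self, rng):
        X = rng.standard_normal((50, 3)) + 5.0
        Y = standardize(rng.standard_normal((50, 2)))
        with pytest.raises(ValueError, match="standardized"):
            SpikeSlabMultiTrait(Y, X)

    def test_nan_input_rejected(self, rng):
        X = standardize(rng.standard_normal((50, 3)))
        Y = standardize(rng.standard_normal((50, 2)))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            SpikeSlabMultiTrait(Y, X)

    def test_burn_in_must_be_smaller_than_iterations(self, rng):
        X = standardize(rng.standard_normal((50, 3)))
        with pytest.raises(ValueError, match="burn_in"):
            SpikeSlabMultiTrait(X[:, :1], X).fit(
                config=SpikeSlabConfig(n_iter=100, burn_in=100)
            )

    def test_joint_fit_at_least_as_sensitive_as_single_outcome_fits(self):
        from pwaskit.simulate import ProteomeSpec, simulate_proteome

        n, p, q = 600, 80, 5
        joint_hits = separate_hits = 0
        C = np.full((q, q), 0.6)
        np.fill_diagonal(C, 1.0)
        for seed in (11, 22, 33):
            rng = np.random.default_rng(seed)
            spec = ProteomeSpec(n_signals=p, n_factors=10,
                                genetic_variance_fraction=0.0,
                                noise_sd=np.sqrt(0.66), seed=seed)
            X = simulate_proteome(n, spec, np.eye(n))
            sigs = rng.choice(p, 8, replace=False)
            effects = {(int(j), int(i % q)): 0.12 for i, j in enumerate(sigs)}
            plan = EffectPlan(n_outcomes=q, true_effects=effects,
                              residual_outcome_correlation=C)
            Y = simulate_outcomes(X, plan, seed=seed + 1)
            Xs = standardize(X)
            cfg = SpikeSlabConfig(n_iter=1500, burn_in=500, seed=seed + 2)
            joint = SpikeSlabMultiTrait(Y, Xs).fit(config=cfg).pip.to_numpy()
            sep = np.zeros((p, q))
            for k in range(q):
                r = SpikeSlabMultiTrait(Y.iloc[:, [k]], Xs).fit(config=cfg)
                sep[:, k] = r.pip.to_numpy()[:, 0]
            joint_hits += sum(joint[j, k] >= 0.95 for (j, k) in effects)
            separate_hits += sum(sep[j, k] >= 0.95 for (j, k) in effects)
        assert joint_hits >= separate_hits


def _draws_from_B(B, Gamma=None):
    m, p, q = B.shape
    if Gamma is None:
        Gamma = (B != 0).astype(np.uint8)
    return PosteriorDraws(
        B=B,
        Gamma=Gamma,
        Sigma=np.tile(np.eye(q), (m, 1, 1)),
        tau2=np.ones(m),
        pi=np.full(m, 0.5),
        predictor_names=[f"x{j}" for j in range(p)],
        outcome_names=[f"y{k}" for k in range(q)],
    )


class TestSummarize:
    def test_all_zero_coefficient(self):
        d = _draws_from_B(np.zeros((200, 1, 1)))
        tab = summarize(d)
        row = tab.iloc[0]
        assert row.pip == 0.0 and row.ci_low == 0.0 and row.ci_high == 0.0
        assert not row.significant

    def test_high_pip_with_positive_interval_is_significant(self, rng):
        B = np.zeros((1000, 1, 1))
        inc = rng.random(1000) < 0.96
        B[inc, 0, 0] = 0.2 + 0.05 * rng.random(inc.sum())
        tab = summarize(_draws_from_B(B))
        assert tab.iloc[0].significant

    def test_interval_containing_zero_blocks_significance(self, rng):
        B = np.zeros((1000, 1, 1))
        inc = rng.random(1000) < 0.97
        B[inc, 0, 0] = rng.normal(0.05, 0.1, inc.sum())  # interval straddles 0
        tab = summarize(_draws_from_B(B))
        row = tab.iloc[0]
        assert row.pip >= 0.95 and not row.significant

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            summarize(_draws_from_B(np.zeros((50, 1, 1))))


class TestDiagnostics:
    def test_stationary_chains_have_rhat_near_one(self, rng):
        chains = [
            _draws_from_B(rng.standard_normal((500, 1, 1))) for _ in range(2)
        ]
        for c in chains:
            c.Gamma[:] = 1
        tab = convergence_diagnostics(chains, pip_floor=0.5)
        row = tab[tab.parameter.str.startswith("beta")].iloc[0]
        assert 0.99 <= row.rhat <= 1.05

    def test_constant_chain_flagged_not_crashed(self):
        chains = [_draws_from_B(np.full((300, 1, 1), 0.3)) for _ in range(2)]
        tab = convergence_diagnostics(chains, pip_floor=0.5)
        row = tab[tab.parameter.str.startswith("beta")].iloc[0]
        assert row.flag == "constant" and np.isnan(row.rhat)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            convergence_diagnostics([_draws_from_B(np.zeros((300, 1, 1)))])

    def test_disagreeing_chains_show_large_rhat(self, rng):
        a = _draws_from_B(rng.standard_normal((400, 1, 1)) * 0.1 + 1.0)
        b = _draws_from_B(rng.standard_normal((400, 1, 1)) * 0.1 - 1.0)
        for c in (a, b):
            c.Gamma[:] = 1
        tab = convergence_diagnostics([a, b], pip_floor=0.5)
        assert tab[tab.parameter.str.startswith("beta")].iloc[0].rhat > 1.1
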