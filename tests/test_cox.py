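"""Cox partial likelihood, ties, frailty, age filter, dementia scan."""

import numpy as np
import pandas as pd
import pytest

from pwaskit.benchmarks import cox_brute_force_oracle, frailty_limit_gap
from pwaskit.cox import apply_age_filter, dementia_scan, fit_cox, fit_cox_frailty
from pwaskit.simulate import (
    PedigreeSpec,
    ProteomeSpec,
    SurvivalSpec,
    simulate_kinship,
    simulate_proteome,
    simulate_survival,
)


class TestAgeFilter:
    def _frame(self, exits, events):
        return pd.DataFrame(
            {"exit_age": exits, "event": events, "entry_age": 40.0}
        )

    def test_case_under_65_removed_and_boundary_retained(self):
        data = self._frame([64.9, 65.0, 70.0], [1, 0, 1])
        out = apply_age_filter(data)
        assert list(out["exit_age"]) == [65.0, 70.0]

    def test_all_under_65_rejected(self):
        with pytest.raises(ValueError, match="65"):
            apply_age_filter(self._frame([60.0, 64.0], [1, 1]))


class TestFitCox:
    def test_six_subject_brute_force_oracle(self):
        newton, brute = cox_brute_force_oracle()
        assert newton == pytest.approx(brute, abs=1e-4)

    def test_matches_lifelines(self, small_survival):
        lifelines = pytest.importorskip("lifelines")
        res = fit_cox(small_survival, "x", ["z"])
        cph = lifelines.CoxPHFitter().fit(
            small_survival[["exit_age", "event", "x", "z"]], "exit_age", "event"
        )
        np.testing.assert_allclose(res.params, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(res.bse, cph.standard_errors_.values, atol=1e-5)

    def test_efron_matches_lifelines_with_ties(self, small_survival):
        lifelines = pytest.importorskip("lifelines")
        data = small_survival.copy()
        data["exit_age"] = np.ceil(data["exit_age"] * 4) / 4  # force ties
        res = fit_cox(data, "x", ["z"])
        cph = lifelines.CoxPHFitter().fit(
            data[["exit_age", "event", "x", "z"]], "exit_age", "event"
        )
        np.testing.assert_allclose(res.params, cph.params_.values, atol=1e-5)

    def test_efron_equals_breslow_without_ties(self, small_survival):
        a = fit_cox(small_survival, "x", ["z"], ties="efron")
        b = fit_cox(small_survival, "x", ["z"], ties="breslow")
        assert a.log_hr == pytest.approx(b.log_hr, abs=1e-10)

    def test_scale_equivariance(self, small_survival):
        res = fit_cox(small_survival, "x")
        scaled = small_survival.copy()
        scaled["x"] = scaled["x"] * 4.0
        res4 = fit_cox(scaled, "x")
        assert res4.log_hr == pytest.approx(res.log_hr / 4.0, rel=1e-6)

    def test_row_duplication_halves_variance(self, small_survival):
        # duplication makes every event a tie: exact under Breslow, ~exact
        # under Efron's within-tie correction
        doubled = pd.concat([small_survival, small_survival], ignore_index=True)
        bres = fit_cox(small_survival, "x", ties="breslow")
        bres2 = fit_cox(doubled, "x", ties="breslow")
        assert bres2.log_hr == pytest.approx(bres.log_hr, rel=1e-6)
        assert bres2.se == pytest.approx(bres.se / np.sqrt(2), rel=1e-4)
        efr = fit_cox(small_survival, "x")
        efr2 = fit_cox(doubled, "x")
        assert efr2.log_hr == pytest.approx(efr.log_hr, rel=0.01)
        assert efr2.se == pytest.approx(efr.se / np.sqrt(2), rel=0.01)

    def test_zero_events_rejected(self, small_survival):
        data = small_survival.copy()
        data["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_cox(data, "x")

    def test_separation_flagged_not_crashed(self):
        # perfectly separating binary covariate -> monotone likelihood
        data = pd.DataFrame(
            {
                "exit_age": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 0, 0, 0],
                "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
                "entry_age": 0.0,
            }
        )
        res = fit_cox(data, "x")
        assert not res.converged

    def test_left_truncation_changes_risk_sets(self, small_survival):
        data = small_survival.copy()
        data["entry_age"] = data["exit_age"] * 0.5
        full = fit_cox(data, "x")
        trunc = fit_cox(data, "x", use_entry=True)
        assert trunc.log_hr != pytest.approx(full.log_hr, abs=1e-6)


class TestFrailty:
    def test_zero_variance_limit_reproduces_plain_fit(self):
        assert frailty_limit_gap(seed=2) < 1e-5

    def test_identity_kinship_moderate_variance_runs(self, small_survival):
        res = fit_cox_frailty(
            small_survival, "x", ["z"], K=np.eye(len(small_survival))
        )
        assert res.converged and res.frailty_variance >= 0
        assert res.log_hr == pytest.approx(0.5, abs=0.2)

    def test_singular_kinship_gets_ridge_with_warning(self, rng):
        n = 60
        K = np.kron(np.eye(n // 2), np.ones((2, 2)))  # shared family effect, singular
        x = rng.standard_normal(n)
        T = rng.exponential(np.exp(-0.3 * x))
        data = pd.DataFrame(
            {"exit_age": T, "event": 1, "x": x, "entry_age": 0.0}
        )
        with pytest.warns(UserWarning, match="ridge"):
            res = fit_cox_frailty(data, "x", K=K, fixed_frailty_variance=0.1)
        assert np.isfinite(res.log_hr)

    def test_planted_log_hr_recovered_with_frailty(self):
        spec = PedigreeSpec(n_families=1250, family_size_weights={2: 1.0}, seed=51)
        K, _ = simulate_kinship(spec)
        n = K.shape[0]
        prot = simulate_proteome(
            n,
            ProteomeSpec(n_signals=1, n_factors=0, genetic_variance_fraction=0.0,
                         noise_sd=1.0, seed=52),
            K.to_numpy(),
        )
        sspec = SurvivalSpec(baseline_hazard_scale=125.0, log_hr={0: -0.3},
                             frailty_variance=0.5, seed=53)
        surv = simulate_survival(n, prot, sspec, kinship=K)
        x = prot.iloc[:, 0].to_numpy()
        surv["x"] = (x - x.mean()) / x.std(ddof=1)
        res = fit_cox_frailty(surv, "x", K=K.to_numpy())
        assert res.log_hr == pytest.approx(-0.3, abs=0.1)


class TestDementiaScan:
    def test_scan_flags_planted_signal_and_survives_bad_column(self):
        spec = PedigreeSpec(n_families=260, seed=61)
        K, _ = simulate_kinship(spec)
        n = K.shape[0]
        prot = simulate_proteome(
            n,
            ProteomeSpec(n_signals=4, n_factors=0, genetic_variance_fraction=0.2,
                         noise_sd=np.sqrt(0.8), seed=62),
            K.to_numpy(),
        )
        sspec = SurvivalSpec(baseline_hazard_scale=105.0, log_hr={0: -0.6}, seed=63)
        surv = simulate_survival(n, prot, sspec, kinship=K)
        rng = np.random.default_rng(64)
        data = surv.copy()
        data["age"] = rng.normal(55, 8, n)
        data["sex"] = rng.binomial(1, 0.5, n).astype(float)
        prot["signal_bad"] = 1.0  # constant column cannot be standardized/fit
        tab = dementia_scan(prot, data, K, tier="basic", bonferroni=0.0125)
        assert set(tab["signal"]) == set(prot.columns)
        bad = tab[tab.signal == "signal_bad"].iloc[0]
        assert bad["error"] != "" and np.isnan(bad["log_hr"])
        top = tab.dropna(subset=["p"]).iloc[0]
        assert top.signal == "signal_001" and top.log_hr < 0
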