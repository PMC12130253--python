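"""Both interaction methods: flux adjustment, hard calls, dosage-stratified
fits, Welch ANOVA and the weighted slope."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fluxgei.errors import DegenerateDesignError, ValidationError
from fluxgei.interaction import (
    DosageStratumResult,
    adjust_flux_for_snp,
    dosage_specific_fits,
    hard_call_dosage,
    interaction_effect_test,
    weighted_dosage_slope,
    welch_anova,
)
from fluxgei.interaction import test_pair as run_pair_tests  # avoid collection


class TestAdjustFlux:
    def test_orthogonal_flux_only_centered(self, rng):
        d = rng.integers(0, 3, 200).astype(float)
        raw = rng.standard_normal(200)
        dc = d - d.mean()
        flux = raw - (dc @ raw) / (dc @ dc) * dc  # exactly orthogonal to dosage
        out = adjust_flux_for_snp(flux, d)
        assert np.allclose(out, flux - flux.mean(), atol=1e-12)

    def test_pure_dosage_flux_zeroed(self, rng):
        d = rng.integers(0, 3, 100).astype(float)
        out = adjust_flux_for_snp(2.0 * d, d)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        d = rng.integers(0, 3, 500).astype(float)
        e = rng.standard_normal(500)
        flux = 0.3 * d + e
        X = np.column_stack([np.ones(500), d])
        beta = np.linalg.solve(X.T @ X, X.T @ flux)  # independent solve
        expected = flux - X @ beta
        out = adjust_flux_for_snp(flux, d)
        assert np.allclose(out, expected, atol=1e-10)
        dc = d - d.mean()
        assert abs(np.mean(out * dc)) < 1e-10  # residual uncorrelated with dosage

    def test_constant_dosage_rejected(self):
        with pytest.raises(DegenerateDesignError):
            adjust_flux_for_snp(np.ones(10), np.full(10, 2.0))


class TestHardCall:
    @pytest.mark.parametrize(
        "value,expected", [(0.49, 0), (0.5, 1), (1.5, 2), (0.0, 0), (1.0, 1), (2.0, 2)]
    )
    def test_rounding(self, value, expected):
        assert hard_call_dosage(np.array([value]))[0] == expected

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            hard_call_dosage(np.array([2.1]))

    @given(st.lists(st.floats(0, 2), min_size=1, max_size=50))
    def test_calls_in_range(self, values):
        calls = hard_call_dosage(np.array(values))
        assert set(np.unique(calls)) <= {0, 1, 2}
        assert np.all(np.abs(calls - np.array(values)) <= 0.5 + 1e-12)


def _strata_result(beta, se, n):
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n)
    return DosageStratumResult(
        beta=beta, se=se, n=n,
        events=(n // 5).astype(int), present=np.isfinite(beta),
    )


class TestWelchAnova:
    def test_equal_estimates_give_null(self):
        res = _strata_result([0.2, 0.2, 0.2], [0.05, 0.07, 0.1], [100, 100, 100])
        F, df1, df2, p = welch_anova(res)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_groups_equal_squared_welch_t(self):
        """With k=2 the Welch F is the squared Welch t; cross-checked against
        scipy's independent Welch-t machinery via summary statistics."""
        beta, se, n = [0.1, 0.35], [0.04, 0.09], [4000, 900]
        res = _strata_result(beta + [np.nan], se + [np.nan], n + [0])
        F, df1, df2, p = welch_anova(res)
        t_res = stats.ttest_ind_from_stats(
            beta[0], se[0] * np.sqrt(n[0]), n[0],
            beta[1], se[1] * np.sqrt(n[1]), n[1],
            equal_var=False,
        )
        assert F == pytest.approx(t_res.statistic**2, rel=1e-10)
        assert df1 == 1
        # Welch–Satterthwaite df, written out independently
        v = np.array(se, dtype=float) ** 2
        df_welch = v.sum() ** 2 / (v[0] ** 2 / (n[0] - 1) + v[1] ** 2 / (n[1] - 1))
        assert df2 == pytest.approx(df_welch, rel=1e-10)
        assert p == pytest.approx(t_res.pvalue, rel=1e-9)

    def test_formula_oracle(self):
        """beta=(0,0.2,0.4), SE=0.05 each, n=1e4 each: direct evaluation of
        the Welch formula gives F ~ 15.99947 with df2 ~ 19998."""
        res = _strata_result([0.0, 0.2, 0.4], [0.05] * 3, [10000] * 3)
        F, df1, df2, p = welch_anova(res)
        # independent evaluation of the textbook formula
        w = np.full(3, 1 / 0.05**2)
        xbar = 0.2
        num = (w * (np.array([0.0, 0.2, 0.4]) - xbar) ** 2).sum() / 2
        lam = ((1 - w / w.sum()) ** 2 / 9999).sum()
        F_expected = num / (1 + 2 * 1 / 8 * lam)
        assert F == pytest.approx(F_expected, rel=1e-12)
        assert F == pytest.approx(15.99947, abs=1e-3)
        assert df2 == pytest.approx(8 / (3 * lam), rel=1e-12)

    def test_bad_se_rejected(self):
        res = _strata_result([0.1, 0.2, 0.3], [0.05, 0.0, 0.1], [100] * 3)
        res.present = np.array([True, True, True])
        with pytest.raises(ValidationError):
            welch_anova(res)

    def test_single_group_rejected(self):
        res = _strata_result([0.1, np.nan, np.nan], [0.05, np.nan, np.nan], [90, 0, 0])
        with pytest.raises(ValidationError):
            welch_anova(res)


class TestWeightedSlope:
    def test_arithmetic_progression(self):
        res = _strata_result([0.1, 0.2, 0.3], [0.05] * 3, [100] * 3)
        slope, se = weighted_dosage_slope(res)
        assert slope == pytest.approx(0.1, abs=1e-12)

    def test_constant_betas_zero_slope(self):
        res = _strata_result([0.2, 0.2, 0.2], [0.03, 0.05, 0.08], [100] * 3)
        slope, _ = weighted_dosage_slope(res)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_oracle(self):
        """Unequal SEs: compare with statsmodels WLS on the same 3 points."""
        sm = pytest.importorskip("statsmodels.api")
        beta, se = [0.05, 0.22, 0.61], [0.03, 0.06, 0.15]
        res = _strata_result(beta, se, [1000] * 3)
        slope, slope_se = weighted_dosage_slope(res)
        X = sm.add_constant(np.arange(3.0))
        wls = sm.WLS(beta, X, weights=1 / np.array(se) ** 2).fit()
        assert slope == pytest.approx(wls.params[1], rel=1e-10)
        # statsmodels rescales by the residual variance estimate; undo it to
        # compare the pure inverse-variance normal-equations SE
        unscaled = np.sqrt(wls.cov_params()[1, 1] / wls.scale)
        assert slope_se == pytest.approx(unscaled, rel=1e-10)

    def test_missing_stratum_uses_its_dosage(self):
        res = _strata_result([0.1, np.nan, 0.3], [0.05, np.nan, 0.05], [100, 0, 100])
        slope, _ = weighted_dosage_slope(res)
        assert slope == pytest.approx(0.1, abs=1e-12)  # over dosages 0 and 2


class TestDosageSpecificFits:
    def test_ordered_recovery(self, small_cohort):
        """beta_interaction=0.3 with beta_flux=0.1 generates per-dosage flux
        effects (0.1, 0.4, 0.7): estimates recover the order and values."""
        sim = small_cohort
        calls = hard_call_dosage(sim.genotypes.column("rs1"))
        res = dosage_specific_fits(sim.cohort, calls, sim.fluxes.column("R1"))
        assert res.n_present() == 3
        assert res.n.sum() == len(sim.cohort)
        assert np.all(np.diff(res.beta) > 0)
        for est, truth in zip(res.beta, [0.1, 0.4, 0.7]):
            assert abs(est - truth) < 3 * res.se[np.argmax(res.beta == est)]

    def test_single_stratum_downstream_error(self, small_cohort):
        sim = small_cohort
        calls = np.full(len(sim.cohort), 2)
        res = dosage_specific_fits(sim.cohort, calls, sim.fluxes.column("R1"))
        assert res.n_present() == 1
        with pytest.raises(ValidationError):
            welch_anova(res)

    def test_min_events_flags_stratum_absent(self, small_cohort):
        sim = small_cohort
        calls = hard_call_dosage(sim.genotypes.column("rs1"))
        res = dosage_specific_fits(
            sim.cohort, calls, sim.fluxes.column("R1"), min_events=10**9
        )
        assert res.n_present() == 0


class TestInteractionEffectTest:
    def test_monomorphic_dosage_rejected(self, small_cohort):
        sim = small_cohort
        flux = sim.fluxes.column("R1")
        with pytest.raises(DegenerateDesignError):
            interaction_effect_test(
                sim.cohort, np.zeros(len(sim.cohort)), flux - flux.mean()
            )

    def test_recovers_planted_interaction(self, small_cohort):
        sim = small_cohort
        d = sim.genotypes.column("rs1")
        adj = adjust_flux_for_snp(sim.fluxes.column("R1"), d)
        res = interaction_effect_test(sim.cohort, d, adj)
        assert abs(res.beta_interaction - 0.3) < 3 * res.se
        assert res.p < 1e-6

    def test_pair_isolates_failures(self, small_cohort):
        sim = small_cohort
        res = run_pair_tests(
            sim.cohort, np.zeros(len(sim.cohort)), sim.fluxes.column("R1")
        )
        assert res.error is not None
        assert res.interaction is None


class TestCovariateSensitivity:
    def test_cardio_covariates_leave_estimate_stable(self):
        """Covariates independent of the interaction shift beta_interaction
        by well under half a standard error on average."""
        from fluxgei.simulate import simulate_cohort
        from fluxgei.experiments import single_pair_config

        deltas, ses = [], []
        for seed in range(8):
            cfg = single_pair_config(n=8000, beta_interaction=0.2, seed=seed)
            cfg.cardio_covariates = True
            cfg.cardio_flux_corr = 0.3
            sim = simulate_cohort(cfg)
            d = sim.genotypes.column("rs1")
            adj = adjust_flux_for_snp(sim.fluxes.column("R1"), d)
            plain = interaction_effect_test(sim.cohort, d, adj)
            cardio = interaction_effect_test(
                sim.cohort, d, adj,
                extra_covariates=("bmi", "sbp", "ldl", "hdl", "tg"),
            )
            assert cardio.with_cardio
            deltas.append(abs(cardio.beta_interaction - plain.beta_interaction))
            ses.append(plain.se)
        assert np.mean(deltas) < 0.5 * np.mean(ses)
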