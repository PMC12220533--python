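"""Flux fitting: goodness of fit, mass-balance MTR, CIs, optimizer contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methioflux as mf
from methioflux.fit import DERIVED_FLUXES, chi_square_gof
from methioflux.simulate import generate_observations
from conftest import aux_sizes

# central 95% chi-square quantiles from a standard printed table
CHI2_TABLE = {  # dof: (0.025 quantile, 0.975 quantile)
    1: (0.000982, 5.024),
    5: (0.831, 12.833),
    10: (3.247, 20.483),
    20: (9.591, 34.170),
    30: (16.791, 46.979),
}


class TestChiSquareGof:
    def test_sum_of_squares(self):
        stat, dof, _ = chi_square_gof(np.array([1.0, 2.0]), 0)
        assert stat == 5.0
        assert dof == 2

    def test_zero_residuals_below_region(self):
        stat, _, (lo, _) = chi_square_gof(np.zeros(10), 2)
        assert stat == 0.0
        assert stat < lo

    @pytest.mark.parametrize("dof", sorted(CHI2_TABLE))
    def test_region_matches_printed_quantiles(self, dof):
        _, _, (lo, hi) = chi_square_gof(np.ones(dof + 3), 3, alpha=0.05)
        t_lo, t_hi = CHI2_TABLE[dof]
        assert lo == pytest.approx(t_lo, rel=1e-3, abs=1e-5)
        assert hi == pytest.approx(t_hi, rel=1e-3)

    def test_rejection_case(self):
        # a statistic far above the region is a rejected fit
        stat, _, (lo, hi) = chi_square_gof(np.full(25, 1.35), 2)
        assert stat > hi

    def test_dof_must_be_positive(self):
        with pytest.raises(ValueError):
            chi_square_gof(np.ones(3), 3)


class TestMassBalanceMTR:
    def test_uptake_covers_demand(self):
        assert mf.mtr_flux_by_mass_balance(5.0, 5.0, 10.0).value == 0.0

    def test_shortfall(self):
        r = mf.mtr_flux_by_mass_balance(6.0, 4.0, 4.0)
        assert r.value == pytest.approx(6.0)
        assert not r.floored

    def test_no_uptake_means_full_demand(self):
        assert mf.mtr_flux_by_mass_balance(3.0, 2.0, 0.0).value == 5.0

    def test_negative_balance_floored_and_flagged(self):
        r = mf.mtr_flux_by_mass_balance(1.0, 1.0, 10.0)
        assert r.value == 0.0
        assert r.floored

    @given(a=st.floats(0, 10), b=st.floats(0, 10), c=st.floats(0, 10),
           s=st.floats(0.1, 3))
    @settings(max_examples=50, deadline=None)
    def test_exactly_linear_where_positive(self, a, b, c, s):
        base = a + b - c
        if base <= 0 or s * base <= 0:
            return
        r1 = mf.mtr_flux_by_mass_balance(a, b, c).value
        r2 = mf.mtr_flux_by_mass_balance(s * a, s * b, s * c).value
        assert r2 == pytest.approx(s * r1, rel=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            mf.mtr_flux_by_mass_balance(np.nan, 1.0, 1.0)


class TestFitContract:
    def test_noiseless_data_is_zero_residual_fixed_point(self, truth_met_minus):
        obs = generate_observations(truth_met_minus, seed=0, noise_scale=0.0)
        model = mf.MethionineFluxModel(
            obs, mf.MET_MINUS, truth_met_minus.tracer, multistart=1, seed=0,
            aux_pool_sizes=aux_sizes(truth_met_minus))
        res = model.fit()
        assert res.converged
        assert res.chi_square < 1e-6
        for name, v in truth_met_minus.fluxes.items():
            if v > 1e-6:
                assert res.fluxes[name] == pytest.approx(v, rel=1e-3)

    def test_same_seed_reproduces_fit(self, truth_met_minus):
        obs = generate_observations(truth_met_minus, seed=7)
        kwargs = dict(pool_mode="free", multistart=3, seed=42,
                      aux_pool_sizes=aux_sizes(truth_met_minus))
        r1 = mf.MethionineFluxModel(obs, mf.MET_MINUS, truth_met_minus.tracer,
                                    **kwargs).fit()
        r2 = mf.MethionineFluxModel(obs, mf.MET_MINUS, truth_met_minus.tracer,
                                    **kwargs).fit()
        assert r1.chi_square == r2.chi_square
        assert r1.fluxes == r2.fluxes

    def test_restarts_agree_or_flagged_multimodal(self, fitted_met_minus):
        res = fitted_met_minus
        assert res.converged
        # either all restarts found the same optimum, or it is flagged
        assert isinstance(res.multimodal, bool)

    def test_bounds_respected(self, fitted_met_minus):
        for name, v in fitted_met_minus.fluxes.items():
            assert v >= 0.0
        for name, v in fitted_met_minus.pool_values.items():
            assert v > 0.0

    def test_pool_modes_both_complete(self, truth_met_minus):
        obs = generate_observations(truth_met_minus, seed=5)
        results = {}
        for mode in ("free", "fixed"):
            model = mf.MethionineFluxModel(
                obs, mf.MET_MINUS, truth_met_minus.tracer, pool_mode=mode,
                multistart=1, seed=0,
                aux_pool_sizes=aux_sizes(truth_met_minus))
            results[mode] = model.fit()
        assert all(r.converged for r in results.values())
        # free mode adds one parameter and one observation per measured pool
        n_pools = len(obs.pool_sizes)
        assert (len(results["free"].residuals)
                - len(results["fixed"].residuals)) == n_pools
        assert (len(results["free"].varied_names)
                - len(results["fixed"].varied_names)) == n_pools

    def test_chi_square_reported_with_both_regions(self, fitted_met_minus):
        text = fitted_met_minus.summary()
        assert "acceptance region" in text
        assert "reference acceptance region" in text
        lo, hi = fitted_met_minus.acceptance_region
        assert 0 < lo < hi


class TestConfidenceIntervals:
    def test_cis_contain_estimates(self, fitted_met_minus):
        ci = fitted_met_minus.conf_int(0.95)
        ok = np.isfinite(ci["se"])
        assert (ci.loc[ok, "ci_lower"] <= ci.loc[ok, "estimate"]).all()
        assert (ci.loc[ok, "estimate"] <= ci.loc[ok, "ci_upper"]).all()

    def test_matches_lmfit_linearization(self, fitted_met_minus):
        """Independent route: lmfit's own scaled covariance at the optimum."""
        res = fitted_met_minus
        ours = res.standard_errors()
        lm = res.lmfit_result
        # lmfit's residual vector includes the (identically zero) balance
        # penalty entries, inflating its dof; rescale to our data-only dof
        scale = np.sqrt(lm.nfree / res.dof)
        for name in res.varied_names:
            stderr = lm.params[name].stderr
            if stderr is None or not np.isfinite(stderr) or stderr == 0:
                continue
            if lm.params[name].value < 1e-6:  # boundary-constrained
                continue
            assert ours[name] == pytest.approx(stderr * scale, rel=0.05)

    def test_unscaled_ci_scales_linearly_with_sds(self, truth_met_minus):
        """With trusted SDs (no s^2 scaling), doubling every SD doubles CIs."""
        obs1 = generate_observations(truth_met_minus, seed=9, noise_scale=0.0)
        lab2 = obs1.labeling.copy()
        lab2["sd"] *= 2
        obs2 = mf.ObservationSet(
            labeling=lab2,
            pool_sizes={k: (v, 2 * sd) for k, (v, sd) in
                        obs1.pool_sizes.items()},
            exchange_rates={k: (v, 2 * sd) for k, (v, sd) in
                            obs1.exchange_rates.items()},
            protsyn_rate=(obs1.protsyn_rate[0], 2 * obs1.protsyn_rate[1]),
            labeling_sd_floor=0.0)
        ses = []
        for obs in (obs1, obs2):
            model = mf.MethionineFluxModel(
                obs, mf.MET_MINUS, truth_met_minus.tracer, multistart=1,
                seed=0, aux_pool_sizes=aux_sizes(truth_met_minus))
            ses.append(model.fit().standard_errors(scale_covar=False))
        ratio = (ses[1] / ses[0]).to_numpy()
        assert np.allclose(ratio, 2.0, rtol=1e-2)

    def test_derived_fluxes_have_cis(self, fitted_met_minus):
        ci = fitted_met_minus.conf_int()
        for name in DERIVED_FLUXES:
            assert name in ci.index

    def test_sam_half_life_definition(self, fitted_met_minus):
        res = fitted_met_minus
        expect = np.log(2) * res.pool_values["sam"] / (res.fluxes["MAT"] / 60)
        assert res.sam_half_life_min == pytest.approx(expect)


def test_observation_set_validation():
    lab = pd.DataFrame({"metabolite": ["sam"], "time_min": [5.0],
                        "x1": [0.5], "sd": [0.0]})
    obs = mf.ObservationSet(labeling=lab, pool_sizes={"sam": (0.1, 0.0)},
                            exchange_rates={"met": (-2.0, np.nan)},
                            protsyn_rate=(1.0, 0.0))
    assert obs.labeling["sd"].iloc[0] == 0.02          # floor
    assert obs.pool_sizes["sam"][1] == pytest.approx(0.01)   # 10% default
    assert obs.exchange_rates["met"][1] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        mf.ObservationSet(labeling=pd.DataFrame(), pool_sizes={},
                          exchange_rates={}, protsyn_rate=(1.0, 0.1))
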