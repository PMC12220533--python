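"""Network construction, stoichiometry and labeling dynamics."""

import numpy as np
import pytest
from scipy.linalg import expm

import methioflux as mf
from methioflux.errors import StoichiometryError, UnidentifiableError
from methioflux.network import solve_linear_labeling


def single_pool_model(v=60.0, size=1.0, enrichment=1.0):
    """One pool fed from a boundary at the given enrichment, k = 1/min."""
    pools = {
        "p": mf.Pool("p", size=size),
        "src": mf.Pool("src", is_boundary=True,
                       boundary_enrichment=enrichment),
        "out": mf.Pool("out", is_boundary=True, is_sink=True),
    }
    reactions = [mf.Reaction("in", "src", "p", v),
                 mf.Reaction("out", "p", "out", v)]
    return mf.NetworkModel(pools, reactions, mf.C13_METHIONINE, {"p": 1})


class TestStoichiometry:
    @pytest.mark.parametrize("condition", [mf.MET_PLUS, mf.MET_MINUS])
    def test_default_models_balanced(self, condition):
        truth = mf.default_ground_truth(condition)
        model = truth.network_model()
        model.validate_balance()  # does not raise
        if condition == mf.MET_MINUS:
            # no exogenous methionine: MTR covers methylation + protein
            # synthesis + release
            f = model.fluxes
            assert f["MET_UPTAKE"] == 0.0
            assert f["MTR"] == pytest.approx(
                f["MAT"] + f["PROTSYN"] + f["MET_RELEASE"])

    def test_unbalanced_fluxes_rejected(self, truth_met_plus):
        bad = dict(truth_met_plus.fluxes)
        bad["AHCY_FWD"] += 1.0  # violates SAH balance
        with pytest.raises(StoichiometryError, match="sah"):
            mf.build_model(mf.MET_PLUS, truth_met_plus.tracer,
                           truth_met_plus.pool_sizes, fluxes=bad)

    def test_negative_derived_flux_rejected(self, truth_met_plus):
        free = dict(truth_met_plus.free_fluxes)
        free["HCYS_RELEASE"] = free["MAT"] + 1.0  # MTR would go negative
        with pytest.raises(StoichiometryError):
            mf.build_model(mf.MET_PLUS, truth_met_plus.tracer,
                           truth_met_plus.pool_sizes, free_fluxes=free)

    def test_missing_free_flux(self):
        with pytest.raises(ValueError, match="missing"):
            mf.fluxes_from_free(mf.MET_PLUS, {"MAT": 1.0})


class TestLabelingDynamics:
    def test_frozen_system(self, truth_met_plus):
        model = mf.build_model(
            mf.MET_PLUS, truth_met_plus.tracer, truth_met_plus.pool_sizes,
            fluxes={k: 0.0 for k in truth_met_plus.fluxes})
        x_init = {"met": 0.3, "sam": 0.6}
        sim = mf.simulate_labeling(model, [0, 10, 100], x_init=x_init)
        assert np.allclose(sim["met"], 0.3, atol=1e-9)
        assert np.allclose(sim["sam"], 0.6, atol=1e-9)

    def test_scalar_closed_form(self):
        model = single_pool_model()
        times = np.array([0.0, np.log(2), 1.0, 3.0, 10.0])
        sim = mf.simulate_labeling(model, times)
        assert np.allclose(sim["p"], 1.0 - np.exp(-times), atol=1e-6)
        assert sim.loc[np.log(2), "p"] == pytest.approx(0.5, abs=1e-6)

    def test_integrator_matches_matrix_exponential(self, truth_met_minus):
        model = truth_met_minus.network_model()
        times = np.array([1.0, 5.0, 30.0, 300.0])
        sim = mf.simulate_labeling(model, times, rtol=1e-10, atol=1e-12)
        # independent matrix-exponential route on the augmented system
        A, b, names = model.linear_system()
        n = len(names)
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = A
        M[:n, n] = b
        z0 = np.zeros(n + 1)
        z0[-1] = 1.0
        for i, t in enumerate(times):
            ref = (expm(M * t) @ z0)[:n]
            assert np.allclose(sim.iloc[i].to_numpy(), ref, atol=1e-8)

    def test_eig_fast_path_matches_expm(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 5
            A = -np.diag(rng.uniform(0.1, 2.0, n))
            A += np.triu(rng.uniform(0, 0.3, (n, n)), 1)
            b = rng.uniform(0, 1, n)
            x0 = rng.uniform(0, 1, n)
            times = np.array([0.5, 2.0, 10.0])
            got = solve_linear_labeling(A, b, x0, times)
            M = np.zeros((n + 1, n + 1))
            M[:n, :n] = A
            M[:n, n] = b
            z0 = np.append(x0, 1.0)
            ref = np.array([(expm(M * t) @ z0)[:n] for t in times])
            assert np.allclose(got, ref, atol=1e-9)

    def test_bounded_and_monotone_from_zero(self, truth_met_plus):
        model = truth_met_plus.network_model()
        sim = mf.simulate_labeling(model, np.linspace(0, 1440, 50),
                                   method="expm")
        enrich = truth_met_plus.tracer.purity
        assert (sim.to_numpy() >= -1e-9).all()
        assert (sim.to_numpy() <= enrich + 1e-9).all()
        diffs = np.diff(sim.to_numpy(), axis=0)
        assert (diffs >= -1e-9).all()  # monotone approach to steady state

    def test_sam_half_time_near_fifteen_minutes(self, truth_met_plus):
        model = truth_met_plus.network_model()
        times = np.linspace(0, 120, 481)
        sim = mf.simulate_labeling(model, times)
        ss = mf.steady_state_enrichment(model)["sam"]
        t_half = times[np.searchsorted(sim["sam"].to_numpy(), 0.5 * ss)]
        assert 13.0 < t_half < 19.0  # precursor labels within ~2 min

    def test_unsorted_times_rejected(self, truth_met_plus):
        model = truth_met_plus.network_model()
        with pytest.raises(ValueError):
            mf.simulate_labeling(model, [10.0, 5.0])


class TestSteadyState:
    def test_single_chain_reaches_boundary_enrichment(self):
        model = single_pool_model(enrichment=0.8)
        assert mf.steady_state_enrichment(model)["p"] == pytest.approx(0.8)

    def test_fifty_fifty_mixture(self):
        pools = {
            "p": mf.Pool("p", size=1.0),
            "hot": mf.Pool("hot", is_boundary=True, boundary_enrichment=1.0),
            "cold": mf.Pool("cold", is_boundary=True, boundary_enrichment=0.0),
            "out": mf.Pool("out", is_boundary=True, is_sink=True),
        }
        reactions = [mf.Reaction("a", "hot", "p", 1.0),
                     mf.Reaction("b", "cold", "p", 1.0),
                     mf.Reaction("c", "p", "out", 2.0)]
        model = mf.NetworkModel(pools, reactions, mf.C13_METHIONINE, {})
        assert mf.steady_state_enrichment(model)["p"] == pytest.approx(0.5)

    def test_matches_long_simulation_random_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            free = {"MAT": rng.uniform(0.1, 1), "AHCY_REV": rng.uniform(0, 1),
                    "CYSTS": rng.uniform(0.01, 0.3),
                    "PROTSYN": rng.uniform(0.5, 3),
                    "HCYS_RELEASE": rng.uniform(0.01, 0.05),
                    "MET_RELEASE": rng.uniform(1, 20)}
            sizes = {m: rng.uniform(0.005, 1.0)
                     for m in ("met", "sam", "sah", "hcys", "cyst", "metp",
                               "akb")}
            model = mf.build_model(mf.MET_MINUS, mf.D4_HOMOCYSTEINE, sizes,
                                   free_fluxes=free)
            ss = mf.steady_state_enrichment(model)
            # 50 half-lives of the slowest measured pool
            t_long = 50.0 * 1440.0
            sim = mf.simulate_labeling(model, [t_long], method="expm")
            for name in ("met", "sam", "sah", "hcys", "cyst", "akb"):
                assert sim.iloc[0][name] == pytest.approx(ss[name], abs=1e-6)

    def test_isolated_pool_unidentifiable(self, truth_met_plus):
        fluxes = dict(truth_met_plus.fluxes)
        # cut off cystathionine completely
        fluxes["CYSTS"] = 0.0
        fluxes["CYST_EFFLUX"] = 0.0
        fluxes["MTR"] += 0.0
        model = mf.build_model(mf.MET_PLUS, truth_met_plus.tracer,
                               truth_met_plus.pool_sizes, fluxes=fluxes,
                               validate=False)
        with pytest.raises(UnidentifiableError):
            mf.steady_state_enrichment(model)


class TestProteinSynthesis:
    def test_zero_growth(self):
        assert mf.protein_synthesis_flux(0.0, 2000.0) == 0.0

    def test_stated_product(self):
        mu = np.log(2) / 24.0
        flux = mf.protein_synthesis_flux(mu, 2000.0, 200.0, 0.022, 110.0)
        assert flux == pytest.approx(mu * 200.0 * 2000.0 / 110.0 * 0.022)

    def test_linear_in_growth_rate(self):
        f1 = mf.protein_synthesis_flux(0.01, 2000.0)
        f2 = mf.protein_synthesis_flux(0.02, 2000.0)
        assert f2 == pytest.approx(2 * f1)

    def test_invalid(self):
        with pytest.raises(ValueError):
            mf.protein_synthesis_flux(0.01, -5.0)


def test_c13_single_isotopomer_assumption_holds(truth_met_plus):
    """M+4 methionine production by MTR is small next to tracer influx."""
    ratio = mf.c13_mtr_validity(truth_met_plus.network_model())
    assert 0.0 < ratio < 0.01


def test_ahcy_net_exchange_reporting(truth_met_minus):
    from methioflux.network import ahcy_net_exchange

    f = truth_met_minus.fluxes
    net, exch = ahcy_net_exchange(f)
    assert net == pytest.approx(f["AHCY_FWD"] - f["AHCY_REV"])
    assert exch == pytest.approx(min(f["AHCY_FWD"], f["AHCY_REV"]))
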