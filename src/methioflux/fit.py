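"""Flux estimation for the methionine network.

`MethionineFluxModel` bundles a culture condition, tracer and an
`ObservationSet` (labeling time series, pool sizes, exchange rates, protein
synthesis rate); its :meth:`~MethionineFluxModel.fit` minimizes the weighted
sum of squared residuals over the free fluxes (and, optionally, pool sizes)
by Levenberg--Marquardt and returns a :class:`FluxFitResults` carrying
estimates, linearized confidence intervals, the chi-square goodness-of-fit
statistic with its acceptance region, and per-observation residuals.

Stoichiometric balance is enforced by construction: only a spanning set of
free fluxes is optimized and every dependent flux is derived by steady-state
mass balance (see :func:`methioflux.network.fluxes_from_free`).  MTR flux is
therefore an output of mass balance -- methionine consumed for methylation
and protein synthesis must equal methionine uptake plus MTR synthesis --
rather than of labeling information, which cannot see it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnidentifiableError
from .mid import TracerSpec
from .network import (FREE_FLUXES, MET_MINUS, MET_PLUS, NetworkModel,
                      ahcy_net_exchange, build_model, fluxes_from_free,
                      simulate_labeling, solve_linear_labeling)

#: Chi-square acceptance regions reported for the original fibroblast
#: datasets (BJ-TERT / BJ-RAS), kept for side-by-side comparison in reports;
#: their degrees of freedom and significance level were not stated.
REFERENCE_ACCEPTANCE_REGIONS = {"C13": (12.0, 21.0), "H2": (18.0, 28.8)}

DERIVED_FLUXES = ("METHYLATION", "AHCY_FWD", "MTR", "MET_UPTAKE",
                  "HCYS_UPTAKE", "CYST_EFFLUX")

_PENALTY = 1e3


@dataclass
class ObservationSet:
    """Measurements entering the flux fit, each with a strictly positive SD.

    ``labeling``: DataFrame with columns metabolite, time_min, x1, sd.
    ``pool_sizes``: metabolite -> (fmol/cell, sd).
    ``exchange_rates``: metabolite ('met'/'hcys') -> (net release fmol/cell/h,
    sd); negative values are net uptake.
    ``protsyn_rate``: (fmol/cell/h, sd).

    Default weighting, overridable per observation by supplying sds: heavy
    fractions get an absolute SD floor of 0.02; pool sizes and rates with no
    measured SD (missing or zero) default to 10% relative (with a small
    absolute floor on rates near zero).  A supplied positive SD is used
    as-is.  Chi-square values are only meaningful relative to this
    weighting.
    """

    labeling: pd.DataFrame
    pool_sizes: dict[str, tuple[float, float]]
    exchange_rates: dict[str, tuple[float, float]]
    protsyn_rate: tuple[float, float]
    labeling_sd_floor: float = 0.02
    default_relative_sd: float = 0.10
    rate_sd_abs_floor: float = 0.01

    def __post_init__(self):
        need = {"metabolite", "time_min", "x1", "sd"}
        if not need.issubset(self.labeling.columns):
            raise ValueError(f"labeling table needs columns {sorted(need)}")
        if len(self.labeling) == 0:
            raise ValueError("empty labeling table")
        lab = self.labeling.copy()
        lab["sd"] = np.maximum(lab["sd"].fillna(0.0), self.labeling_sd_floor)
        self.labeling = lab.sort_values(["metabolite", "time_min"]).reset_index(
            drop=True)

        def default_sd(value, sd, abs_floor=1e-9):
            if sd is None or not np.isfinite(sd) or sd <= 0:
                sd = self.default_relative_sd * abs(value)
            return max(sd, abs_floor)

        self.pool_sizes = {
            k: (v, default_sd(v, sd))
            for k, (v, sd) in self.pool_sizes.items()
        }
        self.exchange_rates = {
            k: (v, default_sd(v, sd, self.rate_sd_abs_floor))
            for k, (v, sd) in self.exchange_rates.items()
        }
        v, sd = self.protsyn_rate
        self.protsyn_rate = (v, default_sd(v, sd, self.rate_sd_abs_floor))
        for name, (_, sd) in {**self.pool_sizes, **self.exchange_rates}.items():
            if sd <= 0:
                raise ValueError(f"nonpositive sd for {name}")

    @property
    def n_obs(self) -> int:
        return (len(self.labeling) + len(self.pool_sizes)
                + len(self.exchange_rates) + 1)

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.labeling["time_min"].to_numpy(dtype=float))


def chi_square_gof(residuals: np.ndarray, n_params: int, alpha: float = 0.05
                   ) -> tuple[float, int, tuple[float, float]]:
    """Chi-square statistic, degrees of freedom and central acceptance region.

    The statistic is the sum of squared weighted residuals; the acceptance
    region is the central (1 - alpha) interval of the chi-square distribution
    with ``len(residuals) - n_params`` degrees of freedom.
    """
    residuals = np.asarray(residuals, dtype=float)
    dof = len(residuals) - n_params
    if dof <= 0:
        raise ValueError("need more residuals than parameters")
    stat = float(residuals @ residuals)
    region = tuple(stats.chi2.ppf([alpha / 2.0, 1.0 - alpha / 2.0], dof))
    return stat, dof, region


@dataclass(frozen=True)
class MassBalanceMTR:
    """MTR flux inferred by mass balance; ``floored`` marks a negative raw value."""

    value: float
    floored: bool = False


def mtr_flux_by_mass_balance(methylation_net: float, protsyn: float,
                             met_uptake: float) -> MassBalanceMTR:
    """MTR = net methylation + protein synthesis - methionine uptake.

    Methionine consumed for methylation and protein synthesis must equal
    methionine uptake plus synthesis via MTR; a negative balance is floored
    at zero and flagged.
    """
    for v in (methylation_net, protsyn, met_uptake):
        if not np.isfinite(v):
            raise ValueError("non-finite input")
    raw = methylation_net + protsyn - met_uptake
    if raw < 0:
        return MassBalanceMTR(0.0, floored=True)
    return MassBalanceMTR(float(raw))


class MethionineFluxModel:
    """Weighted least-squares flux model for one tracing experiment.

    Parameters
    ----------
    observations : ObservationSet
    condition : str
        ``"met_plus"`` or ``"met_minus_hcys_plus"``.
    tracer : TracerSpec
    pool_mode : str
        ``"free"`` fits the measured pool sizes as parameters (with their
        measurements as observations); ``"fixed"`` pins them to the measured
        values.
    aux_pool_sizes : dict
        Sizes of unmeasured pools (protein-bound met, alpha-ketobutyrate)
        that are simulated but never fitted.
    boundary_enrichment : float, optional
        Enrichment of the medium tracer pool; defaults to the tracer purity.
    multistart : int
        Number of perturbed restarts around the initial guess (seeded).
    """

    def __init__(self, observations: ObservationSet, condition: str,
                 tracer: TracerSpec, pool_mode: str = "free",
                 aux_pool_sizes: dict | None = None,
                 boundary_enrichment: float | None = None,
                 multistart: int = 10, seed: int = 0):
        if condition not in (MET_PLUS, MET_MINUS):
            raise ValueError(f"unknown condition {condition!r}")
        if pool_mode not in ("free", "fixed"):
            raise ValueError("pool_mode must be 'free' or 'fixed'")
        self.observations = observations
        self.condition = condition
        self.tracer = tracer
        self.pool_mode = pool_mode
        self.boundary_enrichment = boundary_enrichment
        self.multistart = multistart
        self.seed = seed
        self.aux_pool_sizes = {"metp": 80.0, "akb": 0.01}
        if aux_pool_sizes:
            self.aux_pool_sizes.update(aux_pool_sizes)
        self._measured_pools = sorted(observations.pool_sizes)
        self._times = observations.times
        self._lab_idx = None

    # -- parameterization -------------------------------------------------
    def _all_pool_sizes(self, pool_values: dict[str, float]) -> dict[str, float]:
        sizes = dict(self.aux_pool_sizes)
        sizes.update(pool_values)
        for name in ("met", "sam", "sah", "hcys", "cyst"):
            if name not in sizes:
                # unmeasured interior pool: fall back to a small nominal size
                sizes[name] = 0.01
        return sizes

    def default_init(self) -> dict[str, float]:
        """Demand-balanced starting values seeded from the measurements."""
        obs = self.observations
        pools = {k: v for k, (v, _) in obs.pool_sizes.items()}
        protsyn = max(obs.protsyn_rate[0], 1e-3)

        def turnover_flux(met, default):
            # crude rate-constant estimate from the earliest labeling point
            sub = obs.labeling[obs.labeling["metabolite"] == met]
            if len(sub) < 2 or met not in pools:
                return default
            x = sub["x1"].to_numpy()
            t = sub["time_min"].to_numpy()
            xss = min(max(x.max(), 1e-3) * 1.05, 1.0)
            frac = np.clip(x[0] / xss, 1e-3, 0.95)
            k = -np.log(1.0 - frac) / max(t[0], 1e-6)  # per minute
            return max(k * pools[met] * 60.0, 1e-4)

        mat = turnover_flux("sam", 0.1)
        cysts = min(turnover_flux("cyst", 1e-3), 0.3 * mat)
        init = {
            "MAT": mat,
            "AHCY_REV": 0.2 * mat,
            "CYSTS": max(cysts, 1e-4),
            "PROTSYN": protsyn,
        }
        net_hcys = obs.exchange_rates.get("hcys", (0.0, 1.0))[0]
        net_met = obs.exchange_rates.get("met", (0.0, 1.0))[0]
        if self.condition == MET_PLUS:
            # keep derived MTR = MAT - HCYS_RELEASE - CYSTS nonnegative
            init["HCYS_RELEASE"] = float(
                np.clip(net_hcys, 1e-4, 0.6 * mat))
            init["MET_RELEASE"] = max(-net_met, 1.0)
            init["CYSTS"] = min(init["CYSTS"], 0.2 * mat)
        else:
            init["HCYS_RELEASE"] = max(0.1 * abs(net_hcys), 1e-3)
            init["MET_RELEASE"] = max(net_met, 1e-3)
        return init

    def _residuals(self, free: dict[str, float], pool_values: dict[str, float],
                   with_penalty: bool = True) -> np.ndarray:
        obs = self.observations
        derived = fluxes_from_free(self.condition, free)
        penalties = [
            _PENALTY * min(0.0, derived[name]) for name in DERIVED_FLUXES
        ] if with_penalty else []
        fluxes = {k: max(v, 0.0) for k, v in derived.items()}

        sizes = self._all_pool_sizes(pool_values)
        model = build_model(
            self.condition, self.tracer, sizes, fluxes=fluxes,
            boundary_enrichment=self.boundary_enrichment, validate=False,
        )
        A, b, names = model.linear_system()
        X = np.clip(
            solve_linear_labeling(A, b, np.zeros(len(names)), self._times),
            0.0, 1.0)
        if self._lab_idx is None:
            time_pos = {t: i for i, t in enumerate(self._times)}
            col_pos = {n: i for i, n in enumerate(names)}
            self._lab_idx = (
                np.array([time_pos[t] for t in obs.labeling["time_min"]]),
                np.array([col_pos[m] for m in obs.labeling["metabolite"]]),
                obs.labeling["x1"].to_numpy(),
                obs.labeling["sd"].to_numpy(),
            )
        ti, ci, x_obs, sd_obs = self._lab_idx
        res = list((X[ti, ci] - x_obs) / sd_obs)
        if self.pool_mode == "free":
            for name in self._measured_pools:
                v, sd = obs.pool_sizes[name]
                res.append((pool_values[name] - v) / sd)
        pred_rates = {
            "met": fluxes["MET_RELEASE"] - fluxes["MET_UPTAKE"],
            "hcys": fluxes["HCYS_RELEASE"] - fluxes["HCYS_UPTAKE"],
        }
        for name in sorted(obs.exchange_rates):
            v, sd = obs.exchange_rates[name]
            res.append((pred_rates[name] - v) / sd)
        v, sd = obs.protsyn_rate
        res.append((fluxes["PROTSYN"] - v) / sd)
        return np.array(res + penalties)

    def _split(self, values: dict[str, float]):
        free = {k: values[f"f_{k}"] for k in FREE_FLUXES}
        if self.pool_mode == "free":
            pools = {k: values[f"c_{k}"] for k in self._measured_pools}
        else:
            pools = {k: v for k, (v, _) in self.observations.pool_sizes.items()}
        return free, pools

    def _make_params(self, init: dict[str, float]) -> lmfit.Parameters:
        params = lmfit.Parameters()
        for k in FREE_FLUXES:
            params.add(f"f_{k}", value=max(init[k], 1e-6), min=1e-9)
        for name in self._measured_pools:
            v, _ = self.observations.pool_sizes[name]
            params.add(f"c_{name}", value=max(v, 1e-9), min=1e-12,
                       vary=self.pool_mode == "free")
        return params

    # -- fitting -----------------------------------------------------------
    def fit(self, init: dict[str, float] | None = None,
            alpha: float = 0.05) -> "FluxFitResults":
        """Levenberg--Marquardt fit with seeded multi-start; returns results."""
        obs = self.observations
        init = dict(init or self.default_init())
        rng = np.random.default_rng(self.seed)

        def run(start_values):
            params = self._make_params(start_values)

            def fcn(p):
                return self._residuals(*self._split(p.valuesdict()))

            # trust-region least squares: handles the nonnegativity bounds
            # natively (MINPACK's bound transform stalls on zero fluxes)
            return lmfit.minimize(fcn, params, method="least_squares",
                                  xtol=1e-10, ftol=1e-10, gtol=1e-10)

        attempts = [run(init)]
        for _ in range(max(self.multistart - 1, 0)):
            perturbed = {k: v * float(rng.lognormal(0.0, 0.5))
                         for k, v in init.items()}
            attempts.append(run(perturbed))

        def data_chisq(result):
            free, pools = self._split(result.params.valuesdict())
            r = self._residuals(free, pools, with_penalty=False)
            return float(r @ r)

        chisqs = [data_chisq(a) for a in attempts]
        best_i = int(np.argmin(chisqs))
        best = attempts[best_i]
        converged_chis = [c for a, c in zip(attempts, chisqs) if a.success]
        multimodal = bool(
            converged_chis
            and max(converged_chis) - min(converged_chis)
            > 1e-4 * max(1.0, min(converged_chis))
        )

        free, pools = self._split(best.params.valuesdict())
        varied = [p for p in best.params if best.params[p].vary]
        theta = np.array([best.params[p].value for p in varied])
        resid = self._residuals(free, pools, with_penalty=False)
        stat, dof, region = chi_square_gof(resid, len(varied), alpha=alpha)

        jac = self._jacobian(varied, theta)
        derived = fluxes_from_free(self.condition, free)
        boundary_warning = any(derived[k] < -1e-9 for k in DERIVED_FLUXES)
        if boundary_warning:
            warnings.warn("dependent flux negative at optimum (boundary)")

        return FluxFitResults(
            model=self, free_fluxes=free, pool_values=pools,
            fluxes={k: max(v, 0.0) for k, v in derived.items()},
            varied_names=varied, theta=theta, jacobian=jac,
            residuals=resid, chi_square=stat, dof=dof,
            acceptance_region=region, alpha=alpha,
            converged=bool(best.success), multimodal=multimodal,
            boundary_warning=boundary_warning, seed=self.seed,
            n_restarts=len(attempts), lmfit_result=best,
        )

    def _jacobian(self, varied, theta) -> np.ndarray:
        """Central-difference Jacobian of the weighted data residuals."""
        def residual_at(vec):
            values = {}
            for name, v in zip(varied, vec):
                values[name] = v
            # non-varied params keep their fixed values
            all_values = dict(values)
            if self.pool_mode == "fixed":
                for k, (v, _) in self.observations.pool_sizes.items():
                    all_values.setdefault(f"c_{k}", v)
            free = {k: all_values[f"f_{k}"] for k in FREE_FLUXES}
            if self.pool_mode == "free":
                pools = {k: all_values[f"c_{k}"] for k in self._measured_pools}
            else:
                pools = {k: v for k, (v, _)
                         in self.observations.pool_sizes.items()}
            return self._residuals(free, pools, with_penalty=False)

        r0 = residual_at(theta)
        J = np.empty((len(r0), len(theta)))
        for k in range(len(theta)):
            h = 1e-6 * max(abs(theta[k]), 1e-6)
            up, dn = theta.copy(), theta.copy()
            up[k] += h
            dn[k] = max(dn[k] - h, 1e-12)
            J[:, k] = (residual_at(up) - residual_at(dn)) / (up[k] - dn[k])
        return J


@dataclass
class FluxFitResults:
    """Estimates, uncertainties and diagnostics from a flux fit."""

    model: MethionineFluxModel
    free_fluxes: dict[str, float]
    pool_values: dict[str, float]
    fluxes: dict[str, float]
    varied_names: list[str]
    theta: np.ndarray
    jacobian: np.ndarray
    residuals: np.ndarray
    chi_square: float
    dof: int
    acceptance_region: tuple[float, float]
    alpha: float
    converged: bool
    multimodal: bool
    boundary_warning: bool
    seed: int
    n_restarts: int
    lmfit_result: object = None

    # -- uncertainty -------------------------------------------------------
    def covariance(self, scale_covar: bool = True
                   ) -> tuple[np.ndarray, np.ndarray]:
        """Linearized covariance s^2 (J^T J)^-1 and identifiability flags.

        ``scale_covar=True`` (default) scales by the reduced chi-square
        s^2 = chi2/dof, the usual convention when the absolute noise scale is
        uncertain; with ``scale_covar=False`` the covariance is (J^T J)^-1,
        trusting the stated observation SDs (then CI half-widths scale
        exactly linearly with the SDs).  A rank-deficient normal matrix is
        pseudo-inverted; parameters with a significant null-space component
        are flagged unidentifiable (their CIs are infinite), never a crash.
        """
        J = self.jacobian
        JtJ = J.T @ J
        s2 = self.chi_square / self.dof if scale_covar else 1.0
        U, s, Vt = np.linalg.svd(JtJ)
        tol = max(JtJ.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)
        rank = int(np.sum(s > tol))
        cov = s2 * np.linalg.pinv(JtJ, rcond=1e-12)
        unident = np.zeros(len(self.theta), dtype=bool)
        if rank < len(s):
            null = Vt[rank:]
            unident = np.any(np.abs(null) > 1e-6, axis=0)
        return cov, unident

    def standard_errors(self, scale_covar: bool = True) -> pd.Series:
        cov, unident = self.covariance(scale_covar)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se[unident] = np.inf
        return pd.Series(se, index=self.varied_names)

    def conf_int(self, level: float = 0.95,
                 scale_covar: bool = True) -> pd.DataFrame:
        """Linear-approximation CIs for fitted parameters and derived fluxes."""
        if not self.converged:
            warnings.warn("confidence intervals from a non-converged fit")
        z = stats.norm.ppf(0.5 * (1.0 + level))
        cov, unident = self.covariance(scale_covar)
        rows = []
        for i, name in enumerate(self.varied_names):
            est = self.theta[i]
            se = np.inf if unident[i] else np.sqrt(max(cov[i, i], 0.0))
            rows.append((name, est, se, est - z * se, est + z * se,
                         not unident[i]))
        # derived fluxes: delta method with numerical gradients of the
        # balance map (linear, so exact)
        for name in DERIVED_FLUXES:
            grad = np.zeros(len(self.theta))
            base = fluxes_from_free(self.model.condition, self.free_fluxes)[name]
            for i, pname in enumerate(self.varied_names):
                if not pname.startswith("f_"):
                    continue
                fkey = pname[2:]
                h = 1e-6 * max(abs(self.free_fluxes[fkey]), 1e-6)
                bumped = dict(self.free_fluxes)
                bumped[fkey] += h
                grad[i] = (fluxes_from_free(self.model.condition, bumped)[name]
                           - base) / h
            var = float(grad @ cov @ grad)
            se = np.inf if np.any(unident & (grad != 0)) else np.sqrt(max(var, 0.0))
            rows.append((name, base, se, base - z * se, base + z * se,
                         np.isfinite(se)))
        return pd.DataFrame(
            rows, columns=["name", "estimate", "se", "ci_lower", "ci_upper",
                           "identifiable"],
        ).set_index("name")

    # -- derived biology ---------------------------------------------------
    @property
    def sam_half_life_min(self) -> float:
        """SAM turnover half-time ln2 * C_sam / v_MAT, in minutes."""
        c_sam = self.pool_values["sam"]
        return float(np.log(2) * c_sam / (self.fluxes["MAT"] / 60.0))

    @property
    def ahcy_net_exchange(self) -> tuple[float, float]:
        return ahcy_net_exchange(self.fluxes)

    @property
    def mtr_mass_balance(self) -> MassBalanceMTR:
        return mtr_flux_by_mass_balance(
            self.fluxes["METHYLATION"], self.fluxes["PROTSYN"],
            self.fluxes["MET_UPTAKE"])

    def network_model(self) -> NetworkModel:
        sizes = self.model._all_pool_sizes(self.pool_values)
        return build_model(self.model.condition, self.model.tracer, sizes,
                           fluxes=self.fluxes,
                           boundary_enrichment=self.model.boundary_enrichment)

    def residual_table(self) -> pd.DataFrame:
        obs = self.model.observations
        kinds = (["labeling"] * len(obs.labeling))
        labels = [f"{m}@{t:g}min" for m, t in
                  zip(obs.labeling["metabolite"], obs.labeling["time_min"])]
        if self.model.pool_mode == "free":
            kinds += ["pool_size"] * len(self.model._measured_pools)
            labels += list(self.model._measured_pools)
        kinds += ["exchange_rate"] * len(obs.exchange_rates) + ["protsyn"]
        labels += sorted(obs.exchange_rates) + ["PROTSYN"]
        return pd.DataFrame({"kind": kinds, "observation": labels,
                             "weighted_residual": self.residuals})

    def summary(self, level: float = 0.95) -> str:
        ci = self.conf_int(level)
        lo, hi = self.acceptance_region
        ref = REFERENCE_ACCEPTANCE_REGIONS.get(self.model.tracer.element)
        lines = [
            "Methionine-cycle flux fit",
            "=" * 60,
            f"condition: {self.model.condition}   tracer: "
            f"{self.model.tracer.element} ({self.model.tracer.n_atoms} atoms, "
            f"purity {self.model.tracer.purity})",
            f"converged: {self.converged}   restarts: {self.n_restarts}   "
            f"seed: {self.seed}   multimodal: {self.multimodal}",
            f"chi-square: {self.chi_square:.2f}  (dof {self.dof}; central "
            f"{100 * (1 - self.alpha):.0f}% acceptance region "
            f"[{lo:.1f}, {hi:.1f}])",
        ]
        if ref:
            lines.append(
                f"reference acceptance region (original study): "
                f"[{ref[0]:.1f}, {ref[1]:.1f}]")
        lines.append(f"SAM half-life: {self.sam_half_life_min:.1f} min")
        net, exch = self.ahcy_net_exchange
        lines.append(f"AHCY net {net:.3g}, exchange {exch:.3g} fmol/cell/h")
        lines.append("-" * 60)
        lines.append(f"{'parameter':<16}{'estimate':>12}{'se':>12}"
                     f"{'ci_lower':>12}{'ci_upper':>12}")
        for name, row in ci.iterrows():
            lines.append(
                f"{name:<16}{row.estimate:>12.4g}{row.se:>12.4g}"
                f"{row.ci_lower:>12.4g}{row.ci_upper:>12.4g}")
        if self.boundary_warning:
            lines.append("warning: a dependent flux hit the zero boundary")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Measured vs fitted labeling time courses (one panel)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = self.model.observations
        sim_times = np.linspace(0.0, obs.times.max(), 200)
        model = self.network_model()
        sim = simulate_labeling(model, sim_times, method="expm")
        for met, sub in obs.labeling.groupby("metabolite"):
            line, = ax.plot(sim_times, sim[met], label=met)
            ax.errorbar(sub["time_min"], sub["x1"], yerr=sub["sd"],
                        fmt="o", color=line.get_color(), ms=4)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("heavy fraction")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=8)
        return ax


def confidence_intervals(fit: FluxFitResults, level: float = 0.95
                         ) -> pd.DataFrame:
    """Module-level alias for :meth:`FluxFitResults.conf_int`."""
    return fit.conf_int(level)
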