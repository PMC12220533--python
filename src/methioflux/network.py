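"""Methionine-cycle reaction network and compartmental labeling dynamics.

The network covers the methionine cycle and its immediate neighbors:
medium methionine/homocysteine exchange, MAT (met -> SAM), methylation
(SAM -> SAH), the reversible AHCY reaction (SAH <-> hcys), MTR remethylation
(hcys -> met), transsulfuration entry CYSTS (hcys -> cystathionine, with
alpha-ketobutyrate downstream in the d4 model), and protein synthesis
(met -> protein-bound met, an accumulating sink).

Each pool carries a single state variable: the heavy fraction x_i of the
labeled moiety.  With steady-state fluxes v_j and pool sizes C_i the
dynamics are linear,

    dx_i/dt = sum_over_inbound_j (v_j / C_i) * (s_j - x_i)

where s_j is the enrichment delivered by reaction j: the boundary
enrichment for uptake reactions, the substrate pool's x for reactions that
preserve the labeled moiety, and 0 for reactions that do not (MTR in the
uniformly-13C experiment makes M+4 methionine, which is not the tracked
M+5 isotopomer).

Units: pool sizes in fmol/cell, fluxes in fmol/cell/h, time in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import IntegrationFailureError, StoichiometryError, UnidentifiableError
from .mid import (MOIETY_MAP_C13_MET, MOIETY_MAP_D4_HCYS, TracerSpec)

MET_PLUS = "met_plus"
MET_MINUS = "met_minus_hcys_plus"

#: Free fluxes spanning the stoichiometric solution space; every other flux
#: follows from steady-state balance (see :func:`fluxes_from_free`).
FREE_FLUXES = ("MAT", "AHCY_REV", "CYSTS", "PROTSYN", "HCYS_RELEASE", "MET_RELEASE")

BALANCE_TOL = 1e-6


@dataclass
class Pool:
    """A metabolite pool.

    Interior pools have a positive size (fmol/cell).  Boundary pools (medium
    metabolites, the export sink) hold a fixed enrichment and no size.  Sink
    pools (protein-bound met, export) receive flux but have no outflow and
    are exempt from the balance check.
    """

    name: str
    size: float = 0.0
    is_boundary: bool = False
    boundary_enrichment: float = 0.0
    is_sink: bool = False

    def __post_init__(self):
        if self.is_boundary:
            if not (0.0 <= self.boundary_enrichment <= 1.0):
                raise ValueError(
                    f"{self.name}: boundary enrichment outside [0, 1]"
                )
        elif self.size <= 0:
            raise ValueError(f"interior pool {self.name} needs a positive size")


@dataclass
class Reaction:
    """A one-way reaction with a nonnegative flux.

    Reversible steps (AHCY, transport) are represented as paired forward and
    reverse reactions.  ``transmits_label`` is False when the product's
    tracked isotopomer cannot be formed from the substrate's labeled moiety.
    """

    name: str
    substrate: str
    product: str
    flux: float
    transmits_label: bool = True

    def __post_init__(self):
        if self.flux < -1e-12:
            raise ValueError(f"{self.name}: negative flux {self.flux}")
        self.flux = max(self.flux, 0.0)


@dataclass
class NetworkModel:
    """Pools, reactions, tracer and moiety map defining the labeling ODE."""

    pools: dict[str, Pool]
    reactions: list[Reaction]
    tracer: TracerSpec
    moiety_map: dict[str, int]
    condition: str = MET_PLUS
    validate: bool = True

    def __post_init__(self):
        for r in self.reactions:
            for p in (r.substrate, r.product):
                if p not in self.pools:
                    raise ValueError(f"reaction {r.name}: unknown pool {p!r}")
        if self.validate:
            self.validate_balance()

    # -- stoichiometry ---------------------------------------------------
    def validate_balance(self, tol: float = BALANCE_TOL) -> None:
        """Check inflow == outflow on every interior, non-sink pool."""
        for name, pool in self.pools.items():
            if pool.is_boundary or pool.is_sink:
                continue
            inflow = sum(r.flux for r in self.reactions if r.product == name)
            outflow = sum(r.flux for r in self.reactions if r.substrate == name)
            if abs(inflow - outflow) > tol * max(1.0, inflow, outflow):
                raise StoichiometryError(
                    f"pool {name!r} unbalanced: inflow {inflow:.6g} != "
                    f"outflow {outflow:.6g} fmol/cell/h"
                )

    def flux(self, name: str) -> float:
        for r in self.reactions:
            if r.name == name:
                return r.flux
        raise KeyError(f"no reaction named {name!r}")

    @property
    def fluxes(self) -> dict[str, float]:
        return {r.name: r.flux for r in self.reactions}

    @property
    def interior_pools(self) -> list[str]:
        return [n for n, p in self.pools.items() if not p.is_boundary]

    # -- linear system ----------------------------------------------------
    def linear_system(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (A, b, names) with dx/dt = A x + b, time in minutes."""
        names = self.interior_pools
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        A = np.zeros((n, n))
        b = np.zeros(n)
        for r in self.reactions:
            if r.product not in idx or r.flux == 0.0:
                continue
            i = idx[r.product]
            k = r.flux / self.pools[r.product].size / 60.0  # per minute
            A[i, i] -= k
            src = self.pools[r.substrate]
            if src.is_boundary:
                b[i] += k * (src.boundary_enrichment if r.transmits_label else 0.0)
            elif r.transmits_label:
                A[i, idx[r.substrate]] += k
            # non-transmitting interior source contributes unlabeled inflow
        return A, b, names


def ahcy_net_exchange(fluxes: dict[str, float]) -> tuple[float, float]:
    """Net and exchange components of the reversible AHCY reaction."""
    fwd, rev = fluxes["AHCY_FWD"], fluxes["AHCY_REV"]
    return fwd - rev, min(fwd, rev)


def fluxes_from_free(condition: str, free: dict[str, float]) -> dict[str, float]:
    """Derive the full steady-state flux vector from the free fluxes.

    Balance on SAM gives METHYLATION = MAT; on SAH, AHCY_FWD = MAT +
    AHCY_REV.  In met+ medium there is no homocysteine to take up, so
    homocysteine balance pins MTR = MAT - HCYS_RELEASE - CYSTS and
    methionine balance pins the uptake.  In met-/hcys+ medium methionine
    uptake is zero, so methionine balance pins MTR = MET_RELEASE + MAT +
    PROTSYN (methylation plus protein synthesis demand must be met by MTR)
    and homocysteine balance pins the homocysteine uptake.
    """
    missing = set(FREE_FLUXES) - set(free)
    if missing:
        raise ValueError(f"missing free fluxes: {sorted(missing)}")
    f = dict(free)
    f["METHYLATION"] = f["MAT"]
    f["AHCY_FWD"] = f["MAT"] + f["AHCY_REV"]
    if condition == MET_PLUS:
        f["HCYS_UPTAKE"] = 0.0
        f["MTR"] = f["MAT"] - f["HCYS_RELEASE"] - f["CYSTS"]
        f["MET_UPTAKE"] = f["MET_RELEASE"] + f["MAT"] + f["PROTSYN"] - f["MTR"]
    elif condition == MET_MINUS:
        f["MET_UPTAKE"] = 0.0
        f["MTR"] = f["MET_RELEASE"] + f["MAT"] + f["PROTSYN"]
        f["HCYS_UPTAKE"] = f["HCYS_RELEASE"] + f["MTR"] + f["CYSTS"] - f["MAT"]
    else:
        raise ValueError(f"unknown condition {condition!r}")
    f["CYST_EFFLUX"] = f["CYSTS"]
    return f


def build_model(
    condition: str,
    tracer: TracerSpec,
    pool_sizes: dict[str, float],
    free_fluxes: dict[str, float] | None = None,
    fluxes: dict[str, float] | None = None,
    boundary_enrichment: float | None = None,
    validate: bool = True,
) -> NetworkModel:
    """Assemble the balanced network model for one culture condition.

    Either ``free_fluxes`` (the spanning set, dependent fluxes derived by
    balance) or a complete ``fluxes`` dict (validated against balance) must
    be given.  The medium tracer pool is a boundary at ``boundary_enrichment``
    (default: the tracer atom purity); in met+ medium homocysteine influx is
    absent, in met-/hcys+ methionine uptake is zero.
    """
    if (free_fluxes is None) == (fluxes is None):
        raise ValueError("give exactly one of free_fluxes or fluxes")
    if free_fluxes is not None:
        fluxes = fluxes_from_free(condition, free_fluxes)
        negative = {k: v for k, v in fluxes.items() if v < -BALANCE_TOL}
        if negative:
            raise StoichiometryError(
                f"derived fluxes negative under balance: {negative}"
            )
        fluxes = {k: max(v, 0.0) for k, v in fluxes.items()}

    c13 = tracer.element == "C13"
    enrich = tracer.purity if boundary_enrichment is None else boundary_enrichment
    moiety = dict(MOIETY_MAP_C13_MET if c13 else MOIETY_MAP_D4_HCYS)

    pools: dict[str, Pool] = {}
    interior = ["met", "sam", "sah", "hcys", "cyst", "metp"]
    if not c13:
        interior.append("akb")
    for name in interior:
        if name not in pool_sizes:
            raise ValueError(f"missing pool size for {name!r}")
        pools[name] = Pool(name, size=pool_sizes[name],
                           is_sink=(name in ("metp",)))
    med_met_x = enrich if condition == MET_PLUS else 0.0
    med_hcys_x = enrich if condition == MET_MINUS else 0.0
    pools["medium_met"] = Pool("medium_met", is_boundary=True,
                               boundary_enrichment=med_met_x)
    pools["medium_hcys"] = Pool("medium_hcys", is_boundary=True,
                                boundary_enrichment=med_hcys_x)
    pools["sink"] = Pool("sink", is_boundary=True, is_sink=True)

    def rx(name, sub, prod, transmits=True):
        return Reaction(name, sub, prod, fluxes[name], transmits)

    reactions = [
        rx("MET_UPTAKE", "medium_met", "met"),
        rx("MET_RELEASE", "met", "medium_met"),
        rx("HCYS_UPTAKE", "medium_hcys", "hcys"),
        rx("HCYS_RELEASE", "hcys", "medium_hcys"),
        rx("MAT", "met", "sam"),
        rx("METHYLATION", "sam", "sah"),
        rx("AHCY_FWD", "sah", "hcys"),
        rx("AHCY_REV", "hcys", "sah"),
        # In the 13C experiment MTR adds an unlabeled methyl to the 4-carbon
        # homocysteine backbone: the product is M+4 methionine, not the
        # tracked M+5 isotopomer, so the label is not transmitted.
        rx("MTR", "hcys", "met", transmits=not c13),
        rx("CYSTS", "hcys", "cyst"),
        rx("PROTSYN", "met", "metp"),
    ]
    if c13:
        reactions.append(rx("CYST_EFFLUX", "cyst", "sink"))
    else:
        reactions.append(Reaction("CYST_LYASE", "cyst", "akb",
                                  fluxes["CYST_EFFLUX"]))
        reactions.append(Reaction("AKB_EFFLUX", "akb", "sink",
                                  fluxes["CYST_EFFLUX"]))
    return NetworkModel(pools, reactions, tracer, moiety, condition,
                        validate=validate)


def solve_linear_labeling(A: np.ndarray, b: np.ndarray, x0: np.ndarray,
                          times: np.ndarray) -> np.ndarray:
    """Exact solution of dx/dt = A x + b at the given times.

    Uses the eigendecomposition of the augmented system [[A, b], [0, 0]]
    (which handles a singular A uniformly) with a matrix-exponential
    fallback for defective or ill-conditioned eigenvector bases.
    """
    n = len(x0)
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = b
    z0 = np.append(x0, 1.0)
    try:
        w, V = np.linalg.eig(M)
        c = np.linalg.solve(V, z0)
        if np.linalg.cond(V) < 1e10:
            Z = (V[None, :, :] * np.exp(np.outer(times, w))[:, None, :]) @ c
            return np.real(Z[:, :n])
    except np.linalg.LinAlgError:
        pass
    out = np.empty((len(times), n))
    for i, t in enumerate(times):
        out[i] = (expm(M * t) @ z0)[:n]
    return out


def simulate_labeling(
    model: NetworkModel,
    times: np.ndarray,
    x_init: dict[str, float] | None = None,
    method: str = "lsoda",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Integrate the labeling ODE; rows are time points (min), columns pools.

    ``method="lsoda"`` (default) uses a stiff-capable ODE integrator;
    ``method="expm"`` evaluates the exact matrix-exponential solution of the
    linear system (fast path used inside the fitting loop).  The unlabeled
    4-hour preculture corresponds to the default ``x_init = 0``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValueError("times must be sorted and nonnegative")
    A, b, names = model.linear_system()
    x0 = np.zeros(len(names))
    if x_init:
        for k, v in x_init.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"initial enrichment for {k} outside [0, 1]")
            x0[names.index(k)] = v

    if method == "expm":
        X = solve_linear_labeling(A, b, x0, times)
    else:
        def rhs(_t, x):
            return A @ x + b

        t_end = times[-1] if len(times) else 0.0
        sol = solve_ivp(
            rhs, (0.0, max(t_end, 1e-9)), x0, t_eval=times, method="LSODA",
            rtol=rtol, atol=atol, jac=lambda _t, _x: A,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationFailureError(
                f"labeling ODE integration failed: {sol.message}"
            )
        X = sol.y.T
    if not np.all(np.isfinite(X)):
        raise IntegrationFailureError("non-finite labeling state")
    return pd.DataFrame(np.clip(X, 0.0, 1.0), index=times, columns=names)


def steady_state_enrichment(model: NetworkModel) -> dict[str, float]:
    """t -> infinity limit of the labeling dynamics (solves A x = -b)."""
    A, b, names = model.linear_system()
    try:
        x = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError:
        raise UnidentifiableError(
            "singular labeling system: some pool has no inflow"
        )
    if np.max(np.abs(A @ x + b)) > 1e-8:
        raise UnidentifiableError("ill-conditioned labeling steady state")
    return dict(zip(names, x))


def protein_synthesis_flux(
    growth_rate: float,
    cell_volume: float,
    protein_density: float = 200.0,
    met_residue_fraction: float = 0.022,
    mean_residue_mass: float = 110.0,
) -> float:
    """Methionine demand of protein synthesis (fmol/cell/h).

    µ (1/h) times the cell's protein amino-acid content (protein density in
    g/L of cell volume in fL over the mean residue mass in g/mol) times the
    methionine residue mol fraction.  The defaults are typical mammalian-cell
    constants and are configurable.
    """
    if growth_rate < 0:
        raise ValueError("growth rate must be nonnegative")
    if min(cell_volume, protein_density, met_residue_fraction,
           mean_residue_mass) <= 0:
        raise ValueError("all parameters must be positive")
    residues_fmol = protein_density * cell_volume / mean_residue_mass
    return growth_rate * residues_fmol * met_residue_fraction


def c13_mtr_validity(model: NetworkModel) -> float:
    """M+4 methionine production by MTR relative to methionine influx.

    In the uniformly-13C experiment MTR converts labeled homocysteine into
    M+4 methionine; the single-isotopomer assumption holds when this rate is
    negligible compared to tracer influx.  Returns
    ``MTR * x_hcys(ss) / MET_UPTAKE``.
    """
    ss = steady_state_enrichment(model)
    uptake = model.flux("MET_UPTAKE")
    if uptake <= 0:
        return np.inf
    return model.flux("MTR") * ss["hcys"] / uptake
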