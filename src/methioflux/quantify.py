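"""Isotope-dilution quantification, intracellular concentrations and rates.

Concentrations are measured by spiking a known amount ``n_std`` of an
unlabeled internal standard (heavy fraction ``x_std``, essentially natural
abundance) into an unknown amount ``n`` of the labeled analyte (heavy
fraction ``x``) and measuring the heavy fraction ``x_mix`` of the mixture.
Conservation of the heavy species on mixing gives

    (n + n_std) * x_mix = n * x + n_std * x_std

which is solved for ``n``.  A variant with a factor 1/2 on the right-hand
side (``dilution_equation="as_printed"``) reproduces a published form of the
equation verbatim; it is not the default because it breaks conservation
(with it, equal amounts no longer put ``x_mix`` at the midpoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InconsistentMeasurementError, UnidentifiableError


@dataclass(frozen=True)
class StandardSpike:
    """Internal unlabeled standard added to a sample.

    ``n_std`` is an amount (nmol: standard concentration in the spike
    solvent times the spiked volume); ``x_std`` its heavy fraction, which for
    an unlabeled standard is natural abundance, i.e. close to zero under the
    two-ensemble convention.
    """

    metabolite: str
    n_std: float
    x_std: float = 0.0

    def __post_init__(self):
        if self.n_std <= 0:
            raise ValueError("standard amount must be positive")
        if not (0.0 <= self.x_std < 0.5):
            raise ValueError("standard heavy fraction must be in [0, 0.5)")


@dataclass(frozen=True)
class CultureMeasurements:
    """Cell counts, sizes and medium bookkeeping for one culture."""

    cell_count_t0: float
    cell_count_t: float
    mean_diameter: float  # µm
    duration: float  # h
    medium_volume: float  # mL

    def __post_init__(self):
        if min(self.cell_count_t0, self.cell_count_t) <= 0:
            raise ValueError("cell counts must be positive")
        if self.duration <= 0 or self.mean_diameter <= 0:
            raise ValueError("duration and diameter must be positive")
        if self.medium_volume <= 0:
            raise ValueError("medium volume must be positive")


def isotope_dilution_amount(
    x_mix: float,
    x: float,
    spike: StandardSpike,
    dilution_equation: str = "mass_balance",
) -> float:
    """Solve the isotope-dilution mixing equation for the analyte amount.

    Returns ``n = n_std * (x_std - x_mix) / (x_mix - x)`` (mass-balance
    form).  ``x_mix == x_std`` returns 0 (no analyte); ``x_mix`` outside the
    closed interval spanned by ``x`` and ``x_std`` is physically impossible
    and raises :class:`InconsistentMeasurementError`.
    """
    x_std = spike.x_std
    if abs(x - x_std) < 1e-12:
        raise UnidentifiableError(
            f"{spike.metabolite}: sample and standard have equal heavy "
            "fraction; amount is not identifiable"
        )
    lo, hi = min(x, x_std), max(x, x_std)
    if not (lo <= x_mix <= hi):
        raise InconsistentMeasurementError(
            f"{spike.metabolite}: x_mix={x_mix:.6g} outside the interval "
            f"[{lo:.6g}, {hi:.6g}] spanned by sample and standard"
        )
    if dilution_equation == "mass_balance":
        if abs(x_mix - x) < 1e-12:
            raise InconsistentMeasurementError(
                f"{spike.metabolite}: x_mix equals the sample heavy fraction; "
                "the implied amount is unbounded"
            )
        return spike.n_std * (x_std - x_mix) / (x_mix - x)
    elif dilution_equation == "as_printed":
        # (n + n_std) x_mix = (n x + n_std x_std) / 2
        denom = x_mix - 0.5 * x
        if abs(denom) < 1e-12:
            raise InconsistentMeasurementError(
                f"{spike.metabolite}: degenerate printed-form denominator"
            )
        return spike.n_std * (0.5 * x_std - x_mix) / denom
    raise ValueError(f"unknown dilution_equation {dilution_equation!r}")


def isotope_dilution_sd(
    x_mix: float, x: float, spike: StandardSpike,
    sd_x_mix: float = 0.0, sd_x: float = 0.0,
) -> float:
    """Linearized SD of the mass-balance amount estimate."""
    dn_dxmix = spike.n_std * (x - spike.x_std) / (x_mix - x) ** 2
    n = spike.n_std * (spike.x_std - x_mix) / (x_mix - x)
    dn_dx = n / (x_mix - x)
    return float(np.hypot(dn_dxmix * sd_x_mix, dn_dx * sd_x))


def cell_volume_fL(mean_diameter: float) -> float:
    """Spherical cell volume (fL) from the mean diameter (µm)."""
    if mean_diameter <= 0:
        raise ValueError("diameter must be positive")
    return np.pi / 6.0 * mean_diameter ** 3


def intracellular_concentration(
    n: float,
    cell_count: float,
    mean_diameter: float,
    cytosol_fraction: float = 1.0,
) -> float:
    """Convert an extract amount (nmol) to intracellular concentration (µM).

    Total cytosol volume is ``cell_count`` spheres of the measured mean
    diameter, scaled by ``cytosol_fraction`` (default 1: whole-cell volume
    as proxy for cytosol).
    """
    if cell_count <= 0 or mean_diameter <= 0 or cytosol_fraction <= 0:
        raise ValueError("cell count, diameter and cytosol fraction must be positive")
    if n < 0:
        raise ValueError("amount must be nonnegative")
    vol_L = cell_count * cell_volume_fL(mean_diameter) * cytosol_fraction * 1e-15
    return n * 1e-3 / vol_L  # nmol -> µmol gives µmol/L = µM


def growth_rate(n0: float, n1: float, elapsed: float) -> float:
    """Exponential growth rate µ = ln(n1/n0)/elapsed (1/h)."""
    if n0 <= 0 or n1 <= 0:
        raise ValueError("cell counts must be positive")
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    return float(np.log(n1 / n0) / elapsed)


def doubling_time(n0: float, n1: float, elapsed: float) -> float:
    """Doubling time (h) assuming exponential growth between two counts.

    Equal counts return +inf with a warning; a shrinking culture returns a
    negative doubling time (flagged by a warning), matching the sign of µ.
    """
    mu = growth_rate(n0, n1, elapsed)
    if mu == 0.0:
        warnings.warn("no net growth between counts; doubling time is infinite")
        return np.inf
    if mu < 0:
        warnings.warn("shrinking culture: negative doubling time")
    return float(np.log(2) / mu)


def cell_hours(n0: float, n1: float, elapsed: float,
               method: str = "integral") -> float:
    """Time-integral of cell number between two counts (cell·h).

    ``integral`` (default) integrates the exponential trajectory,
    ``(n1 - n0)/µ``; ``endpoint`` uses ``n1 * elapsed``; ``mean`` uses the
    arithmetic-mean count.
    """
    if method == "integral":
        mu = growth_rate(n0, n1, elapsed)
        if mu == 0.0:
            return n0 * elapsed
        return (n1 - n0) / mu
    if method == "endpoint":
        return n1 * elapsed
    if method == "mean":
        return 0.5 * (n0 + n1) * elapsed
    raise ValueError(f"unknown cell-hours method {method!r}")


def uptake_release_rate(
    baseline_conc: float,
    spent_conc: float,
    medium_volume: float,
    cell_hours: float,
) -> float:
    """Net exchange rate in fmol/cell/h; positive means release.

    ``(spent - baseline)`` µM times the medium volume (mL) is the net amount
    released (nmol) over the culture window, normalized by the cell·h
    integral.
    """
    if cell_hours <= 0:
        raise ValueError("cell_hours must be positive")
    if medium_volume <= 0:
        raise ValueError("medium volume must be positive")
    delta_nmol = (spent_conc - baseline_conc) * medium_volume
    return delta_nmol * 1e6 / cell_hours  # nmol -> fmol
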