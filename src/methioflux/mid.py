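"""Mass isotopomer distributions (MIDs) and heavy-fraction estimation.

An MID is the vector of fractional abundances of a metabolite's mass shifts
(M0, M+1, ..., M+n) for the tracer element.  Under the two-ensemble labeling
model every metabolite pool is a mixture of an unlabeled ensemble with MID
``y0`` (natural isotope abundance) and a fully labeled ensemble with MID
``y1`` (tracer atom purity), both binomial over the atoms of the labeled
moiety.  The mixture weight ``x1`` -- the heavy fraction -- is the single
state variable per pool used for flux analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UnidentifiableError

# Heavy-isotope natural abundance of the supported tracer elements
# (atom fraction): 13C and deuterium.
NATURAL_ABUNDANCE = {"C13": 0.0107, "H2": 0.000115}


@dataclass(frozen=True)
class TracerSpec:
    """Identity and isotopic quality of the tracer molecule.

    Parameters
    ----------
    element : str
        Tracer element, ``"C13"`` or ``"H2"``.
    n_atoms : int
        Number of labeled atoms in the tracer molecule (5 for uniformly
        labeled methionine, 4 for 3,3,4,4-d4 homocyst(e)ine).
    purity : float
        Atom fraction of heavy isotope at the labeled positions, in (0, 1].
    natural_abundance : float
        Heavy-isotope atom fraction of the element at natural abundance.
    """

    element: str
    n_atoms: int
    purity: float
    natural_abundance: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.natural_abundance is None:
            try:
                object.__setattr__(
                    self, "natural_abundance", NATURAL_ABUNDANCE[self.element]
                )
            except KeyError:
                raise ValueError(f"unknown tracer element {self.element!r}")
        if not (0.9 < self.purity <= 1.0):
            raise ValueError(f"atom purity {self.purity} outside (0.9, 1.0]")
        if self.purity <= self.natural_abundance:
            raise ValueError("purity must exceed natural abundance")
        if self.n_atoms < 1:
            raise ValueError("tracer must label at least one atom")


#: Tracers used in the two tracing experiments: uniformly 13C-labeled
#: methionine at 99% atom purity, and 3,3,4,4-d4 homocyst(e)ine at 99.6%.
C13_METHIONINE = TracerSpec("C13", 5, 0.99)
D4_HOMOCYSTEINE = TracerSpec("H2", 4, 0.996)


@dataclass
class MassIsotopomerDistribution:
    """Nonnegative fractions over mass shifts 0..n_atoms, summing to 1."""

    metabolite: str
    n_atoms: int
    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (self.n_atoms + 1,):
            raise ValueError(
                f"{self.metabolite}: expected {self.n_atoms + 1} fractions, "
                f"got {self.fractions.shape}"
            )
        if np.any(self.fractions < -1e-12):
            raise ValueError(f"{self.metabolite}: negative MID fraction")
        total = self.fractions.sum()
        if total <= 0:
            raise ValueError(f"{self.metabolite}: MID sums to zero")
        self.fractions = np.clip(self.fractions, 0.0, None) / total

    @classmethod
    def from_peak_areas(cls, metabolite, areas):
        """Normalize raw peak areas to an MID.

        Raises ``ValueError`` for all-zero areas (missing data must be
        flagged upstream, never silently treated as unlabeled).
        """
        areas = np.asarray(areas, dtype=float)
        if areas.sum() <= 0:
            raise ValueError(f"{metabolite}: total peak area is zero (missing data)")
        return cls(metabolite, len(areas) - 1, areas)


@dataclass(frozen=True)
class HeavyFraction:
    """Estimated heavy (labeled) fraction x1 of a pool, with its SD."""

    x1: float
    sd: float

    def __post_init__(self):
        if not (0.0 <= self.x1 <= 1.0):
            raise ValueError(f"x1={self.x1} outside [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    @property
    def x0(self) -> float:
        return 1.0 - self.x1


def natural_abundance_mid(n_atoms: int, abundance: float,
                          metabolite: str = "") -> MassIsotopomerDistribution:
    """Binomial MID of an unlabeled molecule at natural isotope abundance."""
    if n_atoms < 0:
        raise ValueError("n_atoms must be nonnegative")
    if not (0.0 <= abundance < 1.0):
        raise ValueError("abundance must be in [0, 1)")
    k = np.arange(n_atoms + 1)
    return MassIsotopomerDistribution(
        metabolite, n_atoms, stats.binom.pmf(k, n_atoms, abundance)
    )


def tracer_mid(n_atoms: int, purity: float,
               metabolite: str = "") -> MassIsotopomerDistribution:
    """Binomial MID of the fully labeled ensemble at the tracer atom purity."""
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    if n_atoms < 0:
        raise ValueError("n_atoms must be nonnegative")
    k = np.arange(n_atoms + 1)
    return MassIsotopomerDistribution(
        metabolite, n_atoms, stats.binom.pmf(k, n_atoms, purity)
    )


def fit_heavy_fraction(
    measured: MassIsotopomerDistribution,
    y0: MassIsotopomerDistribution,
    y1: MassIsotopomerDistribution,
    sd_floor: float = 0.01,
) -> HeavyFraction:
    """Least-squares fit of the two-component mixture y = (1-x1) y0 + x1 y1.

    The 1-D problem has the closed-form solution
    ``x1 = <y - y0, y1 - y0> / ||y1 - y0||^2``, clipped to [0, 1].  The SD is
    the linearized residual-based estimate ``s / ||y1 - y0||`` with
    ``s^2 = RSS / (m - 1)``, floored at ``sd_floor`` so downstream weights
    never blow up on a perfect fit.
    """
    y = measured.fractions
    a = y0.fractions
    b = y1.fractions
    if not (len(y) == len(a) == len(b)):
        raise ValueError("MID length mismatch between measured, y0 and y1")
    d = b - a
    dd = float(d @ d)
    if dd < 1e-20:
        raise UnidentifiableError(
            "y0 and y1 coincide; heavy fraction is not identifiable"
        )
    x1 = float((y - a) @ d) / dd
    x1 = float(np.clip(x1, 0.0, 1.0))
    resid = y - a - x1 * d
    m = len(y)
    s2 = float(resid @ resid) / max(m - 1, 1)
    sd = max(np.sqrt(s2 / dd), sd_floor)
    return HeavyFraction(x1, sd)


# Labeled-moiety atom counts per metabolite.  For uniformly 13C-labeled
# methionine the methyl carbon is lost at methylation, so SAH, homocysteine
# and cystathionine carry 4 labeled carbons; methionine and SAM carry 5.
# The d4 label sits on carbons 3 and 4 of the homocysteine backbone and is
# untouched by every reaction in the network, so all pools carry 4.
MOIETY_MAP_C13_MET = {
    "met": 5, "sam": 5, "sah": 4, "hcys": 4, "cyst": 4, "metp": 5,
}
MOIETY_MAP_D4_HCYS = {
    "met": 4, "sam": 4, "sah": 4, "hcys": 4, "cyst": 4, "akb": 4, "metp": 4,
}


def labeled_moiety_atoms(metabolite: str, tracer: TracerSpec,
                         moiety_map: dict | None = None) -> int:
    """Mass shift of the single labeled isotopomer of ``metabolite``.

    ``moiety_map`` defaults to the bundled map for the given tracer.
    """
    if moiety_map is None:
        moiety_map = (MOIETY_MAP_C13_MET if tracer.element == "C13"
                      else MOIETY_MAP_D4_HCYS)
    try:
        return moiety_map[metabolite]
    except KeyError:
        raise KeyError(
            f"metabolite {metabolite!r} not in the labeled-moiety map "
            f"({sorted(moiety_map)})"
        )


def mixture_mid(metabolite: str, n_atoms: int, x1: float, tracer: TracerSpec
                ) -> MassIsotopomerDistribution:
    """Forward model: MID of a pool with heavy fraction ``x1``."""
    y0 = natural_abundance_mid(n_atoms, tracer.natural_abundance, metabolite)
    y1 = tracer_mid(n_atoms, tracer.purity, metabolite)
    return MassIsotopomerDistribution(
        metabolite, n_atoms, (1.0 - x1) * y0.fractions + x1 * y1.fractions
    )
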