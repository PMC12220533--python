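"""Synthetic tracing experiments with known ground truth.

The generator emulates the full measurement chain of a methionine-cycle
tracing experiment: labeling time courses produced by the compartmental
ODE model at known fluxes, conversion of heavy fractions to full MIDs
(binomial natural-abundance and tracer-purity components), isotope-dilution
mixtures with internal unlabeled standards for cell extracts and spent
medium, exponential cell growth, and seeded Gaussian measurement noise.
Every stage of the analysis pipeline can therefore be tested against known
fluxes without any external data.

The bundled ground truths mimic the qualitative regimes of the two culture
conditions: in methionine medium (met+), transport exchange is fast enough
that intracellular methionine labels within minutes and SAM turns over with
a ~15 min half-time; in homocysteine medium (met-/hcys+), MAT flux and the
SAM pool are reduced, AHCY reverse flux is elevated, and the SAM:SAH ratio
collapses from >30 to <5.  The "bj_like" cell line is methionine-independent
(high MTR when methionine is withdrawn); "ras_like" is methionine-dependent
(low MTR, minimal growth in met-/hcys+).  These are fixture choices that
reproduce the dynamical features of interest, not measured values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mid import (C13_METHIONINE, D4_HOMOCYSTEINE, TracerSpec,
                  labeled_moiety_atoms, mixture_mid)
from .network import (MET_MINUS, MET_PLUS, build_model, fluxes_from_free,
                      simulate_labeling)
from .quantify import cell_hours, cell_volume_fL

#: Sampling grid of the tracing experiments: 5, 15, 30 min and 1, 5, 24 h.
SAMPLING_TIMES_MIN = (5.0, 15.0, 30.0, 60.0, 300.0, 1440.0)

MEASURED_METABOLITES = ("met", "sam", "sah", "hcys", "cyst")

# Internal-standard concentrations (µM in the 1 mL extraction methanol /
# added to spent medium), per condition.
EXTRACT_STANDARDS_UM = {
    MET_PLUS: {"hcys": 5.0, "met": 200.0, "sam": 5.0, "sah": 5.0, "cyst": 50.0},
    MET_MINUS: {"hcys": 50.0, "met": 5.0, "sam": 5.0, "sah": 5.0, "cyst": 50.0},
}
MEDIUM_STANDARDS_UM = {
    MET_PLUS: {"hcys": 10.0, "met": 100.0},
    MET_MINUS: {"hcys": 100.0, "met": 100.0},
}

PROTEIN_DENSITY_G_L = 200.0
MET_RESIDUE_FRACTION = 0.022
MEAN_RESIDUE_MASS = 110.0


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise magnitudes; all Gaussian, all seeded.

    ``labeling_sd``: absolute SD on time-course heavy fractions (matches the
    default fitting weight so chi-square is calibrated on synthetic data).
    ``quant_rel_sd``: relative SD on isotope-dilution heavy fractions
    (ion-counting noise scales with the signal).
    ``area_rel_sd``: SD on MID peak areas relative to the total area.
    """

    labeling_sd: float = 0.02
    quant_rel_sd: float = 0.03
    area_rel_sd: float = 0.005

    def __post_init__(self):
        for v in (self.labeling_sd, self.quant_rel_sd, self.area_rel_sd):
            if v < 0:
                raise ValueError("noise SDs must be nonnegative")


@dataclass
class GroundTruth:
    """Complete specification of one synthetic tracing experiment."""

    condition: str
    cell_line: str
    tracer: TracerSpec
    free_fluxes: dict[str, float]  # fmol/cell/h
    pool_conc_uM: dict[str, float]
    mean_diameter_um: float
    growth_rate: float  # 1/h
    cell_count_24h: float
    medium_volume_mL: float = 1.0
    extract_volume_mL: float = 1.0
    medium_conc_uM: float = 100.0  # tracer metabolite in the feed
    akb_conc_uM: float = 5.0
    noise: NoiseModel = field(default_factory=NoiseModel)

    @property
    def cell_volume_fL(self) -> float:
        return cell_volume_fL(self.mean_diameter_um)

    @property
    def pool_sizes(self) -> dict[str, float]:
        """Interior pool sizes in fmol/cell, including unmeasured pools."""
        v = self.cell_volume_fL
        sizes = {m: c * v * 1e-6 for m, c in self.pool_conc_uM.items()}
        sizes["metp"] = (PROTEIN_DENSITY_G_L * v / MEAN_RESIDUE_MASS
                         * MET_RESIDUE_FRACTION)
        sizes["akb"] = self.akb_conc_uM * v * 1e-6
        return sizes

    @property
    def fluxes(self) -> dict[str, float]:
        return fluxes_from_free(self.condition, self.free_fluxes)

    @property
    def cell_count_t0(self) -> float:
        return self.cell_count_24h * np.exp(-self.growth_rate * 24.0)

    def network_model(self):
        return build_model(self.condition, self.tracer, self.pool_sizes,
                           free_fluxes=self.free_fluxes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tracer"] = {"element": self.tracer.element,
                       "n_atoms": self.tracer.n_atoms,
                       "purity": self.tracer.purity}
        d["fluxes"] = self.fluxes
        d["pool_sizes_fmol"] = self.pool_sizes
        return d


def default_ground_truth(condition: str, cell_line: str = "bj_like",
                         noise: NoiseModel | None = None) -> GroundTruth:
    """Bundled study-condition ground truths (synthetic; see module docs)."""
    noise = noise if noise is not None else NoiseModel()
    diameter = 15.6  # µm -> ~1990 fL
    vol = cell_volume_fL(diameter)
    residues = PROTEIN_DENSITY_G_L * vol / MEAN_RESIDUE_MASS

    def mat_for(sam_uM, half_life_min=15.0):
        c_sam = sam_uM * vol * 1e-6
        return np.log(2) * c_sam / half_life_min * 60.0

    if condition == MET_PLUS:
        mu = np.log(2) / 24.0
        protsyn = mu * residues * MET_RESIDUE_FRACTION
        if cell_line == "bj_like":
            conc = {"met": 500.0, "sam": 50.0, "sah": 1.5, "hcys": 1.0,
                    "cyst": 5.0}
            free = {"MAT": mat_for(50.0), "AHCY_REV": 0.05, "CYSTS": 0.02,
                    "PROTSYN": protsyn, "HCYS_RELEASE": 0.10,
                    "MET_RELEASE": 20.0}
            n24 = 3.17e5
        elif cell_line == "ras_like":
            conc = {"met": 500.0, "sam": 100.0, "sah": 3.0, "hcys": 1.0,
                    "cyst": 5.0}
            free = {"MAT": mat_for(100.0), "AHCY_REV": 0.08, "CYSTS": 0.03,
                    "PROTSYN": protsyn, "HCYS_RELEASE": 0.15,
                    "MET_RELEASE": 20.0}
            n24 = 2.52e5
        else:
            raise ValueError(f"unknown cell line {cell_line!r}")
        tracer = C13_METHIONINE
    elif condition == MET_MINUS:
        if cell_line == "bj_like":
            mu = np.log(2) / 36.0
            conc = {"met": 5.0, "sam": 10.0, "sah": 4.0, "hcys": 100.0,
                    "cyst": 5.0}
            free = {"MAT": mat_for(10.0), "AHCY_REV": 0.5, "CYSTS": 0.02,
                    "PROTSYN": mu * residues * MET_RESIDUE_FRACTION,
                    "HCYS_RELEASE": 2.0, "MET_RELEASE": 0.05}
            n24 = 3.80e5
        elif cell_line == "ras_like":
            mu = 0.003  # barely growing: methionine-dependent
            conc = {"met": 4.0, "sam": 8.0, "sah": 3.5, "hcys": 100.0,
                    "cyst": 5.0}
            free = {"MAT": mat_for(8.0), "AHCY_REV": 0.6, "CYSTS": 0.02,
                    "PROTSYN": mu * residues * MET_RESIDUE_FRACTION,
                    "HCYS_RELEASE": 1.2, "MET_RELEASE": 0.02}
            n24 = 3.14e5
        else:
            raise ValueError(f"unknown cell line {cell_line!r}")
        tracer = D4_HOMOCYSTEINE
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return GroundTruth(
        condition=condition, cell_line=cell_line, tracer=tracer,
        free_fluxes=free, pool_conc_uM=conc, mean_diameter_um=diameter,
        growth_rate=mu, cell_count_24h=n24, noise=noise,
    )


@dataclass
class ExperimentBundle:
    """Generated tables plus the ground truth that produced them."""

    mid: pd.DataFrame
    abundance: pd.DataFrame
    cells: pd.DataFrame
    truth: GroundTruth
    seed: int

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tag = f"{self.truth.condition}_{self.truth.cell_line}"
        paths = {}
        for name, df in (("mid", self.mid), ("abundance", self.abundance),
                         ("cells", self.cells)):
            p = directory / f"{tag}_{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        p = directory / f"{tag}_truth.json"
        p.write_text(json.dumps(self.truth.to_dict(), indent=2, default=float))
        paths["truth"] = p
        return paths


def generate_experiment(truth: GroundTruth, seed: int = 0) -> ExperimentBundle:
    """Simulate one tracing experiment end to end.

    Returns tables in the dialects the readers consume: a long MID peak-area
    table (labeling time courses), an abundance table with the measured
    heavy fractions of standard-spiked extract and medium samples, and a
    cell sheet.  The same seed yields byte-identical tables.
    """
    rng = np.random.default_rng(seed)
    noise = truth.noise
    model = truth.network_model()
    times = np.array(SAMPLING_TIMES_MIN)
    sim = simulate_labeling(model, times)
    fluxes = truth.fluxes

    # ---- MID peak-area table -------------------------------------------
    total_area = 1e6
    mid_rows = []
    for met in MEASURED_METABOLITES:
        n_atoms = labeled_moiety_atoms(met, truth.tracer)
        for t in times:
            x = float(sim.at[t, met])
            x_noisy = float(np.clip(x + rng.normal(0.0, noise.labeling_sd),
                                    0.0, 1.0))
            frac = mixture_mid(met, n_atoms, x_noisy, truth.tracer).fractions
            areas = total_area * frac + rng.normal(
                0.0, noise.area_rel_sd * total_area, size=n_atoms + 1)
            areas = np.clip(areas, 0.0, None)
            for shift, area in enumerate(areas):
                mid_rows.append((truth.condition, truth.cell_line, met,
                                 t, shift, area))
    mid_df = pd.DataFrame(mid_rows, columns=[
        "condition", "cell_line", "metabolite", "time", "mass_shift",
        "peak_area"])

    # ---- abundance table (isotope-dilution mixtures) --------------------
    def rel_noise(value, rel_sd):
        return value * (1.0 + rng.normal(0.0, rel_sd)) if rel_sd > 0 else value

    pool_sizes = truth.pool_sizes
    n24 = truth.cell_count_24h
    boundary_x = truth.tracer.purity
    ab_rows = []

    def add_row(sample_type, metabolite, n_true, x_sample, n_std, volume):
        if n_true > 0:
            x_mix = n_true * x_sample / (n_true + n_std)
        else:
            x_mix = 0.0
        x_mix_meas = float(np.clip(rel_noise(x_mix, noise.quant_rel_sd), 0, 1))
        if np.isnan(x_sample):
            x_sample_meas, x_sample_sd = np.nan, np.nan
        else:
            x_sample_meas = float(np.clip(
                rel_noise(x_sample, noise.quant_rel_sd), 0, 1))
            x_sample_sd = noise.quant_rel_sd * max(x_sample, 1e-12)
        ab_rows.append((
            sample_type, truth.condition, truth.cell_line, metabolite,
            x_mix_meas, noise.quant_rel_sd * max(x_mix, 1e-12),
            x_sample_meas, x_sample_sd, n_std, 0.0, volume,
        ))

    for met in MEASURED_METABOLITES:
        n_true = pool_sizes[met] * n24 * 1e-6  # fmol/cell * cells -> nmol
        n_std = (EXTRACT_STANDARDS_UM[truth.condition][met]
                 * truth.extract_volume_mL) if met in \
            EXTRACT_STANDARDS_UM[truth.condition] else None
        if n_std is None:
            continue
        x_sample = float(sim.at[times[-1], met])
        add_row("extract", met, n_true, x_sample, n_std,
                truth.extract_volume_mL)

    ch = cell_hours(truth.cell_count_t0, n24, 24.0)
    vol = truth.medium_volume_mL
    tracer_met = "met" if truth.condition == MET_PLUS else "hcys"
    other_met = "hcys" if truth.condition == MET_PLUS else "met"
    net_uptake = (fluxes[f"{tracer_met.upper()}_UPTAKE"]
                  - fluxes[f"{tracer_met.upper()}_RELEASE"])
    released = fluxes[f"{other_met.upper()}_RELEASE"] * ch * 1e-6  # nmol
    baseline = {tracer_met: truth.medium_conc_uM * vol, other_met: 0.0}
    spent = {
        tracer_met: truth.medium_conc_uM * vol - net_uptake * ch * 1e-6,
        other_met: released,
    }
    x_medium = {
        tracer_met: boundary_x,
        other_met: float(sim.at[times[-1], other_met]),
    }
    for met in (tracer_met, other_met):
        n_std = MEDIUM_STANDARDS_UM[truth.condition][met] * vol
        add_row("baseline_medium", met, baseline[met],
                x_medium[met] if baseline[met] > 0 else np.nan, n_std, vol)
        add_row("medium", met, max(spent[met], 0.0),
                x_medium[met] if spent[met] > 0 else np.nan, n_std, vol)

    abundance_df = pd.DataFrame(ab_rows, columns=[
        "sample_type", "condition", "cell_line", "metabolite",
        "mixture_heavy_fraction", "mixture_heavy_fraction_sd",
        "sample_heavy_fraction", "sample_heavy_fraction_sd",
        "standard_amount_nmol", "standard_heavy_fraction", "volume_mL"])

    cells_df = pd.DataFrame([{
        "condition": truth.condition, "cell_line": truth.cell_line,
        "cell_count_t0": truth.cell_count_t0, "cell_count_24h": n24,
        "mean_diameter_um": truth.mean_diameter_um, "duration_h": 24.0,
        "medium_volume_mL": vol, "extract_volume_mL": truth.extract_volume_mL,
    }])

    return ExperimentBundle(mid_df, abundance_df, cells_df, truth, seed)


def generate_observations(truth: GroundTruth, seed: int = 0,
                          labeling_sd: float = 0.02,
                          rel_sd: float = 0.05,
                          rate_sd_abs_floor: float = 0.01,
                          noise_scale: float = 1.0):
    """Synthetic fit inputs with exactly the stated Gaussian noise.

    Unlike :func:`generate_experiment`, which emulates the full measurement
    chain (MIDs, isotope-dilution mixtures) including its physical [0, 1]
    truncation of heavy fractions, this generator perturbs the model's
    predicted observables directly with untruncated Gaussian noise whose SDs
    equal the fitting weights.  Use it for calibration studies (chi-square
    distribution, CI coverage, parameter recovery); use
    :func:`generate_experiment` to exercise the reading/quantification
    pipeline.  ``noise_scale=0`` yields exact observations with unchanged
    SDs (weights), the zero-residual fixed point of the fit.
    """
    from .fit import ObservationSet

    rng = np.random.default_rng(seed)

    def draw(sd):
        return noise_scale * rng.normal(0.0, sd)

    model = truth.network_model()
    times = np.array(SAMPLING_TIMES_MIN)
    sim = simulate_labeling(model, times)
    fluxes = truth.fluxes
    pool_sizes = truth.pool_sizes

    rows = []
    for met in MEASURED_METABOLITES:
        for t in times:
            x = float(sim.at[t, met]) + draw(labeling_sd)
            rows.append((met, t, x, labeling_sd))
    labeling = pd.DataFrame(rows, columns=["metabolite", "time_min", "x1",
                                           "sd"])
    pools = {}
    for met in MEASURED_METABOLITES:
        v = pool_sizes[met]
        sd = rel_sd * v
        pools[met] = (v + draw(sd), sd)
    rates = {}
    for met in ("met", "hcys"):
        v = (fluxes[f"{met.upper()}_RELEASE"] - fluxes[f"{met.upper()}_UPTAKE"])
        sd = max(rel_sd * abs(v), rate_sd_abs_floor)
        rates[met] = (v + draw(sd), sd)
    v = fluxes["PROTSYN"]
    sd = max(rel_sd * v, rate_sd_abs_floor)
    protsyn = (v + draw(sd), sd)
    return ObservationSet(labeling=labeling, pool_sizes=pools,
                          exchange_rates=rates, protsyn_rate=protsyn)


def generate_growth_curves(n0: float, doubling_time: float, days: int,
                           noise_cv: float = 0.0, seed: int = 0
                           ) -> pd.DataFrame:
    """Daily cell counts from exponential growth with lognormal noise.

    The noise multiplier is ``exp(sigma * N(0,1))`` with ``sigma =
    ln(1 + noise_cv)``: median-unbiased, so doubling times inferred from
    log counts are unbiased.
    """
    if min(n0, doubling_time) <= 0 or days < 1:
        raise ValueError("n0, doubling_time and days must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    day = np.arange(0, days + 1)
    counts = n0 * 2.0 ** (day * 24.0 / doubling_time)
    if noise_cv > 0:
        sigma = np.log1p(noise_cv)
        factors = np.exp(sigma * rng.standard_normal(len(day)))
        factors[0] = 1.0  # seeding count is known exactly
        counts = counts * factors
    return pd.DataFrame({"day": day, "count": counts})
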