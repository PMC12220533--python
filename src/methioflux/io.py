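"""Table readers/writers and the stage-to-stage pipeline plumbing.

All tables are comma-separated UTF-8 text with a mandatory header row; time
is in minutes, concentrations in µM, amounts in nmol, rates in fmol/cell/h.
Readers validate required columns and value ranges and report offending
rows by line number; malformed rows are never silently dropped.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableFormatError
from .fit import ObservationSet
from .mid import (MassIsotopomerDistribution, TracerSpec, fit_heavy_fraction,
                  labeled_moiety_atoms, natural_abundance_mid, tracer_mid)
from .network import MET_PLUS, protein_synthesis_flux
from .quantify import (StandardSpike, cell_hours, cell_volume_fL,
                       growth_rate, intracellular_concentration,
                       isotope_dilution_amount, isotope_dilution_sd,
                       uptake_release_rate)

MID_COLUMNS = ["condition", "cell_line", "metabolite", "time", "mass_shift",
               "peak_area"]
ABUNDANCE_COLUMNS = ["sample_type", "condition", "cell_line", "metabolite",
                     "mixture_heavy_fraction", "standard_amount_nmol",
                     "standard_heavy_fraction", "volume_mL"]
CELLS_COLUMNS = ["condition", "cell_line", "cell_count_t0", "cell_count_24h",
                 "mean_diameter_um", "duration_h", "medium_volume_mL"]


def _read_table(path, required, numeric):
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: file is empty")
    if len(df) == 0:
        raise TableFormatError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            lines = [int(i) + 2 for i in bad[:5]]
            raise TableFormatError(
                f"{path}: non-numeric {col!r} at line(s) {lines}")
        df[col] = vals
    return df


def read_mid_table(path) -> pd.DataFrame:
    df = _read_table(path, MID_COLUMNS, ["time", "mass_shift", "peak_area"])
    bad = df.index[(df["peak_area"] < 0) | (df["time"] < 0)]
    if len(bad):
        raise TableFormatError(
            f"{path}: negative time or peak area at line(s) "
            f"{[int(i) + 2 for i in bad[:5]]}")
    return df


def read_abundance_table(path) -> pd.DataFrame:
    df = _read_table(path, ABUNDANCE_COLUMNS,
                     ["mixture_heavy_fraction", "standard_amount_nmol",
                      "standard_heavy_fraction", "volume_mL"])
    bad = df.index[(df["mixture_heavy_fraction"] < 0)
                   | (df["mixture_heavy_fraction"] > 1)
                   | (df["standard_amount_nmol"] <= 0)]
    if len(bad):
        raise TableFormatError(
            f"{path}: invalid heavy fraction or standard amount at line(s) "
            f"{[int(i) + 2 for i in bad[:5]]}")
    return df


def read_cells_table(path) -> pd.DataFrame:
    return _read_table(path, CELLS_COLUMNS,
                       ["cell_count_t0", "cell_count_24h", "mean_diameter_um",
                        "duration_h", "medium_volume_mL"])


# ---------------------------------------------------------------------------


def estimate_heavy_fractions(mid_df: pd.DataFrame, tracer: TracerSpec,
                             sd_floor: float = 0.01) -> pd.DataFrame:
    """Fit the two-component mixture to every (metabolite, time) MID.

    Returns a long table with columns condition, cell_line, metabolite,
    time_min, x1, sd.  Groups with zero total area are reported as missing
    (skipped with a warning), never treated as unlabeled.
    """
    rows = []
    keys = ["condition", "cell_line", "metabolite", "time"]
    for (cond, line, met, t), grp in mid_df.groupby(keys, sort=True):
        grp = grp.sort_values("mass_shift")
        n_atoms = labeled_moiety_atoms(met, tracer)
        shifts = grp["mass_shift"].to_numpy(dtype=int)
        if not np.array_equal(shifts, np.arange(n_atoms + 1)):
            raise TableFormatError(
                f"{met} at t={t}: expected mass shifts 0..{n_atoms}, "
                f"got {shifts.tolist()}")
        areas = grp["peak_area"].to_numpy(dtype=float)
        if areas.sum() <= 0:
            warnings.warn(f"{met} at t={t}: zero total area, flagged missing")
            continue
        measured = MassIsotopomerDistribution.from_peak_areas(met, areas)
        y0 = natural_abundance_mid(n_atoms, tracer.natural_abundance, met)
        y1 = tracer_mid(n_atoms, tracer.purity, met)
        hf = fit_heavy_fraction(measured, y0, y1, sd_floor=sd_floor)
        rows.append((cond, line, met, float(t), hf.x1, hf.sd))
    return pd.DataFrame(rows, columns=["condition", "cell_line", "metabolite",
                                       "time_min", "x1", "sd"])


def quantify_abundance(abundance_df: pd.DataFrame, cells: pd.Series,
                       dilution_equation: str = "mass_balance"
                       ) -> pd.DataFrame:
    """Isotope-dilution amounts and concentrations for every sample row.

    Extract rows are converted to intracellular concentrations using the
    cell count and mean diameter; medium rows to medium concentrations using
    the sample volume.  Rows whose mixture composition matches the bare
    standard are reported as zero amount.
    """
    rows = []
    for idx, row in abundance_df.iterrows():
        spike = StandardSpike(row["metabolite"], row["standard_amount_nmol"],
                              row["standard_heavy_fraction"])
        x_mix = row["mixture_heavy_fraction"]
        x = row.get("sample_heavy_fraction", np.nan)
        sd_mix = row.get("mixture_heavy_fraction_sd", 0.0) or 0.0
        sd_x = row.get("sample_heavy_fraction_sd", 0.0) or 0.0
        if np.isnan(x):
            if abs(x_mix - spike.x_std) > 0.01:
                raise TableFormatError(
                    f"line {int(idx) + 2}: sample heavy fraction missing but "
                    f"mixture differs from the standard")
            n, sd_n = 0.0, 0.0
        else:
            n = isotope_dilution_amount(x_mix, x, spike, dilution_equation)
            sd_n = isotope_dilution_sd(x_mix, x, spike, sd_mix, sd_x)
        if row["sample_type"] == "extract":
            conc = intracellular_concentration(
                n, cells["cell_count_24h"], cells["mean_diameter_um"])
            sd_conc = (conc * sd_n / n) if n > 0 else 0.0
        else:
            conc = n / row["volume_mL"]  # nmol / mL = µM
            sd_conc = sd_n / row["volume_mL"]
        rows.append((row["sample_type"], row["condition"], row["cell_line"],
                     row["metabolite"], n, sd_n, conc, sd_conc))
    return pd.DataFrame(rows, columns=[
        "sample_type", "condition", "cell_line", "metabolite", "amount_nmol",
        "amount_sd", "concentration_uM", "concentration_sd"])


def exchange_rates(conc_df: pd.DataFrame, cells: pd.Series) -> pd.DataFrame:
    """Net uptake/release rates from baseline vs spent medium (fmol/cell/h)."""
    ch = cell_hours(cells["cell_count_t0"], cells["cell_count_24h"],
                    cells["duration_h"])
    vol = cells["medium_volume_mL"]
    rows = []
    medium = conc_df[conc_df["sample_type"] == "medium"]
    baseline = conc_df[conc_df["sample_type"] == "baseline_medium"]
    for met in sorted(medium["metabolite"].unique()):
        spent_row = medium[medium["metabolite"] == met].iloc[0]
        base = baseline[baseline["metabolite"] == met]
        base_conc = base["concentration_uM"].iloc[0] if len(base) else 0.0
        base_sd = base["concentration_sd"].iloc[0] if len(base) else 0.0
        rate = uptake_release_rate(base_conc, spent_row["concentration_uM"],
                                   vol, ch)
        sd = (np.hypot(base_sd, spent_row["concentration_sd"])
              * vol * 1e6 / ch)
        rows.append((met, rate, sd))
    return pd.DataFrame(rows, columns=["metabolite", "net_release_rate",
                                       "rate_sd"])


def build_observations(labeling_df: pd.DataFrame, conc_df: pd.DataFrame,
                       rates_df: pd.DataFrame, cells: pd.Series,
                       protein_density: float = 200.0,
                       met_residue_fraction: float = 0.022,
                       mean_residue_mass: float = 110.0) -> ObservationSet:
    """Assemble the fit inputs from the quantified pipeline stages.

    Pool sizes (fmol/cell) come from intracellular concentrations and the
    spherical cell volume; the protein-synthesis rate from the growth rate
    and cell size (these constants are configurable, not measured).
    """
    v_fL = cell_volume_fL(cells["mean_diameter_um"])
    extracts = conc_df[conc_df["sample_type"] == "extract"]
    pool_sizes = {}
    for _, row in extracts.iterrows():
        size = row["concentration_uM"] * v_fL * 1e-6
        sd = row["concentration_sd"] * v_fL * 1e-6
        pool_sizes[row["metabolite"]] = (size, sd)
    rates = {row["metabolite"]: (row["net_release_rate"], row["rate_sd"])
             for _, row in rates_df.iterrows()}
    mu = growth_rate(cells["cell_count_t0"], cells["cell_count_24h"],
                     cells["duration_h"])
    protsyn = protein_synthesis_flux(max(mu, 0.0), v_fL, protein_density,
                                     met_residue_fraction, mean_residue_mass)
    labeling = labeling_df[["metabolite", "time_min", "x1", "sd"]].copy()
    return ObservationSet(labeling=labeling, pool_sizes=pool_sizes,
                          exchange_rates=rates, protsyn_rate=(protsyn, 0.0))
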