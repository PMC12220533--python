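# Methods

## The compartmental labeling model

The methionine network is modeled as a single compartmental system: pools
met, sam, sah, hcys, cyst (plus alpha-ketobutyrate downstream of
cystathionine in the deuterium model), an accumulating protein-bound
methionine sink (metp), and medium methionine/homocysteine as boundary
pools.  Reactions are MET/HCYS uptake and release, MAT, methylation,
AHCY forward/reverse, MTR, CYSTS and protein synthesis; cystathionine
leaves by efflux (¹³C model) or via the lyase to alpha-ketobutyrate
(²H₄ model).  Every reversible step is carried as a pair of one-way fluxes,
both ≥ 0; net and exchange components are derived for reporting.

Each pool's state is the heavy fraction of its labeled moiety.  This
one-variable-per-pool reduction requires each metabolite to have a single
labeled isotopomer.  It is exact for the ²H₄ tracer, whose labeled moiety
(deuteriums on carbons 3 and 4 of the homocysteine backbone) is untouched
by every reaction in the network.  For uniformly ¹³C-labeled methionine the
moiety shrinks from five carbons (met, SAM) to four (SAH, hcys,
cystathionine) when the methyl group leaves at methylation; remethylation
of labeled homocysteine by MTR would create M+4 methionine, which is not
the tracked M+5 species, so MTR's inflow to the methionine pool carries
zero enrichment in the ¹³C model.  The validity ratio
MTR·x_hcys(ss)/MET_UPTAKE is computable (`c13_mtr_validity`); for the
bundled conditions it is below 1%.

With steady-state fluxes v and constant pool sizes C, the dynamics
dx/dt = A x + b are linear.  `simulate_labeling` integrates with LSODA
(stiff-capable; default rtol 1e-6, atol 1e-9, configurable) or evaluates
the exact solution via the eigendecomposition of the augmented system
[[A, b], [0, 0]] with a matrix-exponential fallback for defective cases
("expm" method, used inside the fitting loop for speed).  The two routes
agree to better than 1e-8, which the test suite verifies against an
independent `scipy.linalg.expm` evaluation.  The 4 h unlabeled preculture
maps to x(0) = 0 at the medium switch.

Units are fmol/cell for pool sizes, fmol/cell/h for fluxes, and minutes
internally for time, matching the sampling grid (5, 15, 30 min, 1, 5,
24 h).

## Heavy-fraction estimation

A measured MID is fit as y = (1 − x₁)·y⁰ + x₁·y¹ with y⁰ the binomial at
the tracer element's natural abundance (0.0107 for ¹³C, 1.15e-4 for ²H) and
y¹ the binomial at the tracer atom purity (0.99 for ¹³C₅-met, 0.996 for
²H₄-hcys).  Only the tracer element's atoms in the labeled moiety enter
these binomials; isotopes of other elements are ignored.  The 1-D least
squares has the closed form x₁ = ⟨y − y⁰, y¹ − y⁰⟩/‖y¹ − y⁰‖², clipped to
[0, 1] (identical to the box-constrained optimum for this 1-D problem).
The SD is the residual-based linearization with a floor (default 0.01) so a
perfect fit never produces a zero weight.  Peak areas are normalized to
fractions before fitting; an all-zero group is flagged as missing data,
never treated as unlabeled.

## Quantification

Isotope dilution: an amount n_std of unlabeled standard (heavy fraction
x_std ≈ 0) is mixed into the unknown amount n (heavy fraction x), and the
mixture fraction x_mix is measured; conservation gives
n = n_std(x_std − x_mix)/(x_mix − x).  A published variant of this
equation carries a factor ½ on the labeled-species side; that form breaks
conservation (with equal amounts the mixture is no longer the midpoint, and
it is degenerate whenever x_mix = x/2), but it can be selected with
`dilution_equation="as_printed"` for comparison.  Whether the ½ was a
typesetting artifact or a DL-racemate bookkeeping device is undecidable
from the equation alone; the mass-balance form is the default.  SDs of
estimated amounts are propagated linearly from the heavy-fraction SDs and
carried through to the fit weights.

Intracellular concentrations divide the extract amount by the total cell
volume — cell count × sphere volume of the measured mean diameter — scaled
by a configurable cytosol fraction (default 1, whole-cell volume as proxy).
Uptake/release rates are (spent − baseline) medium concentration × volume
over the cell·hour integral of exponential growth between the two counts
(alternatives: endpoint or arithmetic-mean normalization).  Doubling times
assume exponential growth; equal counts give +inf with a warning, a
shrinking culture a negative value with a warning.

For the DL-homocystine feed, 200 µM racemate is treated as 100 µM
L-homocysteine at the vendor purity; the D-enantiomer is assumed
metabolically inert and invisible.

## Flux fitting

Free parameters are a spanning set of six fluxes — MAT, AHCY_REV, CYSTS,
PROTSYN, HCYS_RELEASE, MET_RELEASE — plus, in the default `pools: free`
mode, the five measured pool sizes.  All dependent fluxes follow from
steady-state balance: METHYLATION = MAT; AHCY_FWD = MAT + AHCY_REV; in
methionine medium (no homocysteine influx) MTR = MAT − HCYS_RELEASE −
CYSTS and methionine uptake closes the methionine balance; in
homocysteine medium (no methionine uptake) MTR = MET_RELEASE + MAT +
PROTSYN and homocysteine uptake closes the homocysteine balance.  The
optimizer therefore can never leave the stoichiometric manifold; derived
fluxes that would go negative incur a smooth penalty and raise a boundary
warning if negative at the optimum.  The spanning set is recorded in the
fit report for dof accounting.

Observations are the labeling time series (SD floor 0.02 absolute), pool
sizes and net exchange rates (propagated SDs where available, 10% relative
default otherwise), and the protein-synthesis rate
µ·(protein density × cell volume / mean residue mass)·methionine residue
fraction, with defaults 200 g/L, 110 g/mol and 0.022 — typical
mammalian-cell constants, all configurable.  Because measurement SDs are
partly assumed, χ² values are only meaningful relative to this weighting;
the report prints the recomputed central 95% acceptance region next to the
reference regions of the original fibroblast study, whose dof and
significance level were not stated.

Minimization uses lmfit with the trust-region `least_squares` backend:
it is a Levenberg–Marquardt-type damped least-squares method whose native
box handling is robust when a flux sits on the zero boundary, where
MINPACK's parameter transform stalls.  Multi-start (default 10 seeded
log-normal perturbations of the demand-balanced initial guess) guards
against local minima; disagreeing restarts set a `multimodal` flag.
Initial values seed PROTSYN from the measured rate and MAT/CYSTS from
crude single-exponential turnover estimates of the earliest labeling
points.

Confidence intervals are the linear approximation around the optimum:
cov = s²(JᵀJ)⁻¹ with s² = χ²/dof and J the central-difference Jacobian of
the weighted residuals (data residuals only, penalties excluded).  With
`scale_covar=False` the stated SDs are trusted instead (cov = (JᵀJ)⁻¹), in
which case CI half-widths scale exactly linearly with the SDs.  Derived
fluxes get delta-method intervals through the (linear) balance map.  A
rank-deficient normal matrix is pseudo-inverted and the affected parameters
flagged unidentifiable with infinite CIs.  In practice MAT, CYSTS, PROTSYN,
the dominant transport fluxes and mass-balance MTR are well identified at
the bundled noise levels (linearized relative SE below 15%), while
AHCY_REV in methionine medium and MET_RELEASE in homocysteine medium are
weakly identified — their information comes only from fast early labeling
dynamics sampled no earlier than 5 min.

## Synthetic data

The generator emulates the full measurement chain: ODE labeling time
courses at known fluxes, mixture MIDs with peak-area noise,
isotope-dilution mixtures for extracts (standards at the study's
concentrations in 1 mL extraction solvent) and for baseline/spent medium,
exponential growth between seeded and 24 h counts, and seeded Gaussian
noise.  The bundled ground truths reproduce the qualitative regimes of the
two culture conditions and two cell phenotypes — methionine medium:
intracellular methionine ~5× medium, SAM:SAH > 30, fast transport exchange
(methionine labels within minutes), SAM half-time 15 min; homocysteine
medium: methionine 100-fold down, homocysteine at medium level, SAM:SAH
< 5, elevated AHCY reverse flux, and MTR either high (methionine-
independent "bj_like") or low (methionine-dependent "ras_like", minimal
growth).  Pool sizes use a 15.6 µm diameter (~2000 fL); 24 h cell counts
are 3.17e5/2.52e5 (met⁺) and 3.80e5/3.14e5 (met⁻hcys⁺) for the two
phenotypes.  These are fixture choices reproducing the dynamical features
of interest, not measured values.

Noise defaults mirror the fitting weights (0.02 absolute on labeling heavy
fractions; 3% relative on isotope-dilution heavy fractions, whose
propagated concentration SDs land near the 10% default) so that χ² is
calibrated on synthetic data.  One deliberate mismatch remains: measured
heavy fractions are physically confined to [0, 1], so near-fully-labeled
time points have truncated noise and the pipeline χ² runs slightly low.
`generate_observations` therefore provides an observation-level generator
with exact untruncated Gaussian noise for calibration studies (χ²
distribution, CI coverage, parameter recovery), while
`generate_experiment` exercises the full table-reading pipeline.

What passing tests show — and what they do not: the pipeline inverts its
own forward model at realistic noise; real chromatographic artifacts,
missing isotopologue peaks, batch effects, multi-element natural-abundance
overlap and model misspecification (e.g., SAM consumption by polyamine
synthesis, protein turnover returning methionine) are outside the
generator and therefore untested.

## Numerical choices and limitations

- Integration tolerances 1e-9 absolute / 1e-6 relative (configurable);
  fitting uses the exact linear-system solution, so optimizer precision is
  not integrator-limited.
- Medium pools are fixed-enrichment boundaries at the tracer atom purity
  (rapid exchange with a much larger reservoir); finite-medium depletion is
  not simulated.  Holding the boundary at the purity treats unlabeled
  tracer-element atoms as diluting the heavy ensemble; the alternative
  convention (boundary at 1.0 with purity absorbed entirely into y¹) is
  available via `boundary_enrichment`.
- Protein-bound methionine accumulates without turnover; its growth
  dilution is not modeled (pool size fixed at the protein methionine
  content, ~80 fmol/cell at the default geometry).
- Cystathionine has efflux only; no medium exchange.
- The mixture constraint is x₀ + x₁ = 1 (the complementary fraction of the
  unlabeled ensemble).
- Problem sizes: fits use 30 labeling observations (5 metabolites × 6 time
  points), 5 pool sizes, 2 exchange rates and the protein-synthesis rate —
  38 observations against 11 parameters (dof 27) in the default free-pool
  mode; recovery and coverage studies use 20 replicate experiments.
- Positional isotopomer (EMU/cumomer) modeling, folate-cycle carbon
  sourcing, polyamine SAM consumption, profile-likelihood or bootstrap
  CIs, and model selection across topologies are out of scope.
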