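# Methods

## Scope

`dryanfis` analyses thin-layer convective drying of a small spherical
fruit (miracle berry, *Synsepalum dulcificum*) under warm-water blanching
pretreatments, and models the resulting moisture-ratio surface with an
adaptive neuro-fuzzy inference system (ANFIS).  The package covers four
stages: drying-curve kinetics, ANFIS training with structure search,
ANFIS-based factor sensitivity, and a synthetic-data generator that
emulates the study design end to end.

## Drying kinetics

**Moisture bookkeeping.** Dry-basis moisture content is
`Mc = 100 (Ww − Dw)/Dw`; the moisture ratio is
`MR = (Mt − Me)/(Mo − Me)`, decaying from 1 toward 0.  The equilibrium
moisture `Me` defaults to 0 (the standard thin-layer simplification when
`Me` is not measured) and is configurable.

**Diffusivity.** The falling-rate curve of a sphere obeys Fick's second
law; its series solution is

    MR(t) = (6/π²) Σ_{n≥1} (1/n²) exp(−n² π² D_eff t / r²).

At long times the n = 1 term dominates and ln MR is linear in t with
slope `K_L = −π² D_eff / r²`, so `D_eff = |K_L| r² / π²` (the slope
method).  The characteristic radius defaults to r = 0.02 m, the length
scale of the whole fruit; it is the only radius consistent with the
reference diffusivity tables this package reproduces (the slope/Deff
ratio of every table row equals r²/π² with r = 0.0200 m).

*Units.* Two conventions are provided.  `mode="table"` applies the
per-minute regression slope with no time conversion — the convention
under which the reference tables are internally consistent —
and `mode="si"` divides by 60 to give m²/s.  The active convention is
logged; `si = table/60` exactly.

*Fit window.* The one-term form cannot exceed its amplitude 6/π² ≈ 0.608,
and near that amplitude the higher series terms still contribute, so the
dataset pipeline fits ln MR only over points with
`MR < (6/π²) e⁻¹ ≈ 0.224` — one diffusive time constant into the decay,
where the second term is below (1/4)e⁻³ ≈ 1.2 % of the first.  On
noiseless generated curves this window recovers every cell's diffusivity
to 0.32 % and every activation energy to 0.18 %; fitting all positive
points instead (available via `max_mr=None`, with `min_mr = 0.01` as the
lower cutoff) leaves a several-percent early-time bias.  Non-positive
moisture ratios are excluded with a log entry; a non-negative slope is
non-physical and yields `D_eff = 0` with a warning.

**Activation energy.** `ln D_eff` is regressed on `1/T` (kelvin,
offset 273.15) and `Ea = −slope · R` with R = 8.314 J/(mol K), reported
in kJ/mol.  `Ea` is invariant to any constant rescaling of the
diffusivities, so both unit conventions give the same value.  Duplicate
temperatures are averaged with a warning.

**Energy accounting.** Total drying energy follows
`Et = A v ρa ca ΔT Dt` (tray area m², air velocity m/s, air density
kg/m³, air specific heat kJ/(kg °C), temperature rise °C, drying time h).
The raw product is treated as kJ and converted once to kWh by 1/3600.
Specific energy is `Es = Et / W0` with `W0` the initial load in kg.

## ANFIS

A first-order Takagi–Sugeno system with grid partitioning: each input
carries m membership functions, the rule base is the full Cartesian
product (mᵏ rules for k inputs), firing strengths are products of
membership degrees, and each rule has a linear consequent
`f = p·x + r`.  The output is the normalized-firing-weighted sum of the
consequents.  Membership families are the four canonical ones:
triangular, Gaussian, generalized bell, and the spline-based Π curve.

**Initialization.** Uniform grid partition: centers equally spaced over
the observed input range, widths chosen so adjacent functions cross at
degree 0.5 (σ = h/(2√(2 ln 2)) for Gaussians; half-width a = h/2, b = 2
for bells; feet at ±h for triangles and Π curves).  Initialization is
deterministic given the data and the membership count.

**Input normalization.** Models built from data map every input affinely
onto [0, 1] internally (the map is stored with the model and applied on
entry).  Drying time spans hundreds of minutes while blanching time
spans single digits; without normalization both the gradient direction
and the minimum-norm consequent solution are dominated by the
largest-unit factor, and premise refinement effectively stalls.

**Hybrid learning.** Per epoch: (1) the consequents are solved by linear
least squares with the premise frozen, on the column-equilibrated design
whose entries are normalized firing strength × augmented input; (2) the
premise parameters take one full-batch normalized-gradient step (the
step size is a length along the unit gradient), with the classic
adaptation heuristic — ×1.1 after four consecutive error decreases,
×0.9 after two up-down oscillations.  Gradients are analytic for all
four families, with subgradient 0 at the kinks of the piecewise
families; parameter validity (σ > 0, ordering) is restored by projection
after each step.

Two numerical safeguards matter in practice:

- *Consequent ridge.* A full Cartesian rule base on a factorial design
  has strongly collinear columns (temperature takes three discrete
  values, so within a rule the strength×temperature column is nearly
  proportional to the strength column), and the exact minimum-norm
  interpolant swings wildly between training points.  Training therefore
  adds a small Tikhonov penalty (default `ridge = 1e-3` in the
  equilibrated basis), solved exactly in the primal or dual form
  depending on which is smaller.  `lse_consequents` itself defaults to
  the pure unpenalized solve (SVD minimum-norm with a warning under rank
  deficiency).
- *Coverage guard.* Compact-support families (triangular, Π) can drift
  during premise training until some observed input fires no rule.  A
  premise step that breaks rule coverage of the dataset is reverted and
  the step length shrunk.  At prediction time, firing-strength sums are
  floored at `min_firing = 1e-12` before normalization to avoid 0/0 at
  extreme extrapolation; an input whose strengths are all exactly zero
  raises a degenerate-input error naming the offending row.

**Epoch selection.** The data are shuffled once with the configured seed
and cut into contiguous 60/15/25 % train/check/test slices (not
stratified).  Each epoch's checking RMSE is recorded after the
consequent solve; the returned model is the snapshot at the epoch with
minimum checking RMSE (first occurrence on ties), which guards against
over-fitting.  Test RMSE and R² (1 − SSE/SST; the squared Pearson
correlation is logged alongside) are computed only on the held-out test
slice with that snapshot.  The same seed reproduces the split,
initialization and trajectories bit-identically.

## Structure search

All 12 combinations of family {trimf, gbellmf, gaussmf, pimf} ×
membership count {2, 3, 5} are trained on identical partitions (8, 27 or
125 rules for the 3-factor problem), so performance differences reflect
structure only.  The winner maximizes test R², with ties broken toward
fewer rules and then the lower best epoch.  A failure in one cell is
recorded on its row and the grid continues.  The epoch cap defaults to
500; the bundled pipeline and acceptance runs use 300, which the error
trajectories show is past the checking-selected optimum for every
structure on the synthetic design.

## Sensitivity analysis

A factor subset is more *sensitive* the lower the prediction RMSE of an
ANFIS retrained on that subset alone.  The three singletons and three
pairs of {drying time, temperature, pretreatment} are retrained with the
winning structure's family and count (the rule base shrinks to
m^|subset|), under the same split seed.  The ranking metric is the
full-dataset prediction RMSE of each best-epoch model (per-partition
RMSEs are reported alongside); singletons and pairs are ranked
separately.  A constant input column makes a subset degenerate — it is
flagged and excluded from the ranking rather than failing the run.

## Synthetic-data generator

The experimental curves behind this analysis were published only as
figures, so the generator reconstructs the study *design* from the
published parameter tables: 4 blanching pretreatments (0/3/5/10 min at
60 °C) × 3 drying temperatures (50/60/70 °C), weights sampled at 10-min
intervals to 120 min and 30-min intervals after, through the first
reading below MR = 0.01 (the observation that the weight went constant).

Per cell, `D_eff(T) = D0 exp(−Ea/RT)` with the published activation
energies (28.86/36.59/37.48/36.91 kJ/mol by pretreatment) and `D0`
anchored so that `D_eff` at 50 °C equals each pretreatment's published
50 °C diffusivity in m²/s.  This reproduces the published drying-time
scale (≈540 min generated vs 530 reported for the unblanched sample at
50 °C; ≈100–130 min for the fastest cell) and spans the full published
diffusivity range.  MR follows the Fick sphere series with 50 terms
(truncation error < 1e−12 at every scheduled t > 0; at t = 0 the series
is evaluated as its analytic value 1).  Noise is multiplicative Gaussian
on MR (default sd 0.01 — weighing error scales with mass), except at
t = 0 where MR ≡ 1 by definition; the sampling schedule is determined by
the noiseless physics, so the record count (233 at defaults, against the
reference design's 255 — the reference time grid itself is not
recoverable from the publication) is seed-independent.

**What the generator does not emulate:** blanching physics, case
hardening, constant-rate drying periods (the reference curves show none),
shrinkage, or replicate-to-replicate systematic error.  Its curves are
exactly Arrhenius–Fickian, whereas real Table rows deviate a few percent
from their own Arrhenius fit; passing tests therefore demonstrate
correct recovery under the stated physics, not robustness to real-fruit
model misfit.

## Numerical choices and degenerate inputs

- Regression lines via ordinary least squares (`scipy.stats.linregress`);
  R² is clipped to [0, 1] and set to 1 for exactly collinear input.
- Consequent solves: SVD least squares (pure) or
  Cholesky-factorized primal/dual ridge (training); columns equilibrated
  to unit norm first.
- A premise gradient whose norm is below 1e−10 is treated as
  floating-point noise and no step is taken (a normalized step along a
  noise direction would undo a converged fit).  Non-finite gradient
  components are zeroed and logged.
- Split sizes are floors of the fractions; training requires at least
  2 points in each partition.
- Descriptive statistics use the bias-corrected sample formulas
  (spreadsheet convention); kurtosis is excess; both are NA for constant
  columns.  The mode is the smallest most-frequent value.
- CSV output uses 10 significant digits; write→read round-trips
  bit-identically after one cycle.

## Problem sizes

Default runs train 12 structures × 300 epochs on 233 records (≈12 s on
one CPU) plus 6 subset models for sensitivity (≈3 s); the kinetics stage
is instantaneous.  The test suite runs in well under a minute.

## Known limitations

- The reference tables' two internally inconsistent rows (unblanched and
  10-min-blanched at 50 °C, whose printed diffusivities disagree with
  their own printed slopes by ~5–6 %) are reproduced from their slopes,
  not their diffusivities.
- Sensitivity RMSE magnitudes depend on the dataset; only the procedure
  and the induced ordering are comparable across datasets.
- The ANFIS is batch-only (no online/recursive consequent estimation),
  grid-partition-only (no subtractive clustering), and all inputs share
  one membership count.
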