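# Methods

## Scope and state

The simulator represents one *Brassica napus* seedling from transfer into
a climate chamber (one visible leaf) through roughly its first two months.
The plant is an ordered list of phytomers — here, one leaf blade with its
petiole — on a single unbranched stem. Internodes, roots, flowering and
vernalization are outside scope; assimilate partitioning is reduced to a
single whole-plant carbon pool. There is no feedback from carbon status to
extension: leaf growth is strictly thermal-time driven, and the carbon
budget is a parallel, clearly labeled mechanistic readout.

## Thermal time

Chamber regimes are square waves: day temperature during the photoperiod
(14 h by default), night temperature otherwise. The daily increment is the
time-weighted mean temperature minus a 5 °C base, clamped at zero — young
rapeseed stops extension growth below 5 °C while photosynthesis continues
at lower temperatures. Internal arithmetic keeps unrounded increments
(23⅓, 15⅓, 7⅓ °Cd d⁻¹ for the H/M/L presets); the integers 23/15/7 are a
reporting convention exposed by `reported_increment`. One step per day; no
sub-daily resolution, since every growth curve is a function of
accumulated temperature only. Rounding-vs-flooring of the reported rates
is observationally neutral here (both give the same integers).

## Growth-curve families

* **Blade extension** (per rank × treatment): `y = y_m/(1+(ts/ts_0)^b)`,
  with `ts` the *plant-level* accumulated temperature since transfer, not
  per-leaf age — each rank's `ts_0` already encodes its delay. The power
  is undefined at `ts = 0` for `b < 0`, so evaluation requires `ts > 0`;
  the simulator uses ε = 10⁻⁶ °Cd on day 0.
* The low-treatment rows of the extension table carry *positive* fitted
  slopes (b up to 63), making the raw curve a decreasing step — an
  artifact of leaves that were already extended when measurement began.
  The raw evaluator stays faithful to the table; the simulator reads
  lengths through a running-maximum wrapper so no blade ever shrinks.
* **Normalized dry mass**: `y′ = y_m/(1+exp(a ts′² + b ts′ + c))` on
  normalized time `ts′ = ts/ts_max`, optionally piecewise with separate
  branches below/above a transition `ts_tr` ("double logistic"). Branches
  are evaluated exactly as parameterized, with no continuity constraint;
  the jump at `ts_tr` is measured (`branch_discontinuity`) and reported,
  never smoothed (0.014 for the H plant-level curve, 0.091 for M).
  Both branches carry a `y_m` factor: the per-rank tables include an
  upper-branch maximum of 15.31 for one curve, so the plant-level upper
  branches (all 1.00) are the special case, not the rule.
* **Denormalization** anchors (`y_max` mg, `ts_max` °Cd) are run-config
  inputs, defaulting to `y_max = 1` (output stays normalized) and
  `ts_max` = the treatment's 30-day accumulated temperature. Published
  treatment-mean dry weights are means across sampling dates, not
  endpoint values, and are unsuitable as anchors.
* **Whole-plant leaf area**: adopted as
  `LA = LA_0 + LA_max/(1+exp(−b(ts−TS_m)))`. The source prints the
  denominator as `(ts−TS_m)^(−b)`, which is undefined for `ts ≤ TS_m` at
  non-integer `b` and cannot produce a sigmoid with `b ≈ 0.02`; the
  exponential-argument reading matches the stated exponential/linear/
  maturation phases and makes `b` (per °Cd) dimensionally sensible. The
  raw printed form remains available (`leaf_area_raw_power_form`, NaN
  where undefined) for comparison.

Exponent arguments are clipped at ±700 before `exp` so extreme shape
parameters saturate instead of overflowing.

## Allometry

WLR (blade width/length) and PBR (petiole/blade length) are linear in
rank per treatment; LMA is exponential in rank for H and M and the
constant 0.01639 kg m⁻² for L, where no significant rank trend exists.
The H-treatment WLR intercept is transcribed as 0.8921 — the printed
0.08921 is inconsistent with the treatment's mean WLR (0.849) and with
the other intercepts, and is treated as a dropped digit (noted in the
parameter CSV). Blade area is `k·length·width` with a leaf-ellipse shape
factor `k = 0.7`, a typical dicot value; the true outline was never
published, and `k` is config-exposed. Dry mass is `area·LMA` with the
unit bridge 1 kg m⁻² = 100 mg cm⁻². Regressions are trusted over ranks
1–8; beyond that they extrapolate and the functions warn rather than
fail, and a PBR extrapolated below zero is clamped to a small positive
value with a warning.

## Organogenesis and the daily loop

Leaf count is exactly `initial + ⌊ts/phyllochron⌋` with a 75 °Cd
phyllochron; one phytomer is appended per multiple crossed, at azimuth
steps of 137.5° (golden-angle spiral — visualization plumbing with no
physiological claim, as is the petiole elevation schedule of 60° − 5° per
rank). Ranks beyond the parameterized extension table (the H regime
initiates ~10 leaves but five ranks are parameterized) reuse the highest
parameterized rank's curve shifted by the difference in initiation
thermal time; every such fallback is logged. Geometric totals sum
per-leaf allometric areas and masses; empirical mode reports the directly
fitted whole-plant curves alongside. The two are not reconciled — they
are independent fits to the same experiment and their ratio is a
diagnostic, not an error.

## Curve fitting

Trust-region-reflective least squares throughout (the source names no
algorithm). Initialization is deterministic: plain heuristics (y_m
slightly above the observed maximum, the half-maximum time, unit slope of
either sign) plus linearized estimates — each family log- or
logit-transforms into a linear/quadratic regression at a grid of candidate
y_m values — with the best final rss winning; there is no random restart,
so fits are reproducible given data. All starts are first run with capped
iterations, and the winner is polished at ftol = xtol = 10⁻¹⁵. The double
logistic treats `ts_tr` as a grid-searched hyperparameter (step 0.01 on
normalized time, scanned coarse-to-fine) because the printed piecewise
form defines no joint objective; each branch is fitted independently on
its own side — consistent with the published parameters, which are
discontinuous at the transition — seeded with the full-series single fit,
which guarantees the piecewise fit never has a larger rss than the single
fit (model nesting). Non-convergence and degenerate inputs (constant
series) return a flagged result, never an exception.

On noise-free dense grids every packaged parameter set refits to within
0.1% (transition within one grid step). Under measurement noise the
*curves* remain recoverable everywhere (median refit RMSE well below the
noise sd), but some printed *parameters* are intrinsically unidentifiable:
sets with y_m ≫ 1 never saturate on [0, 1], leaving y_m and c exactly
degenerate (`y′ ≈ y_m e^{−c} e^{−at′²−bt′}`), and the near-flat extension
rows (|b| ≈ 0.1) carry no usable timing information — the source's own
fits acknowledge as much for ranks 1–2. Parameter-level recovery claims
in the test suite are scoped accordingly.

## Synthetic measurement series

`generate_synthetic_series` emulates the destructive-sampling design
(three plants harvested every 3 days over a month): curve values on a
time grid plus additive Gaussian noise truncated at zero, deterministic
per seed. It does *not* emulate between-plant variability structure,
sampling without replacement, rank-correlated errors, or measurement
digitization — so passing recovery tests demonstrate estimator
correctness under idealized i.i.d. noise, not field robustness.

## Chamber light model

The real cabinet (39 wall-mounted fluorescent tubes) is reduced to three
cosine-emitting luminous walls — two lateral, one back — in a
1.0 × 0.6 × 1.5 m box, total source output 330 μmol m⁻² s⁻¹ split
equally, with two upward-facing virtual sensors above the shelves
(z = 0.40 and 1.10 m on the chamber axis). Sensor PPFD is a Monte-Carlo
view-factor estimate (uniform panel sampling, standard errors reported)
plus a uniform diffuse ambient term for light recycled by the reflective
interior, in the integrating-sphere approximation
`E_amb = ρ/(1−ρ)·Φ/A_interior`. The wall reflectance ρ = 0.63 is the
single calibrated constant, fixed once so the two default sensors average
150 μmol m⁻² s⁻¹ — the measured value the original chamber
reconstruction was also calibrated to. Direct readings alone are ~63 and
~33 μmol m⁻² s⁻¹; the chamber interior dimensions were never published,
so the whole scene is config-exposed. Per-leaf absorption is forward ray
casting from the panels onto blade ellipses with single-interaction
absorption (absorptance 0.85, no scattering — seedling canopies are
sparse) plus the ambient term on the upper face; total absorption cannot
exceed emission.

## Leaf photosynthesis and carbon budget

A standard C3 biochemical model: `A = min(Wc, Wj) − Rd` with
Rubisco-limited `Wc = Vcmax(Ci−Γ*)/(Ci+Kc(1+O/Ko))`, electron-transport
limited `Wj = J(Ci−Γ*)/(4Ci+8Γ*)`, J from the non-rectangular hyperbola
(curvature 0.9, quantum yield 0.3 e⁻ per absorbed photon), Arrhenius
temperature responses with standard kinetic constants, fixed
Ci/Ca = 0.7 at Ca = 400 μmol mol⁻¹, and leaf temperature equal to air
temperature. Stomatal conductance and leaf energy balance are deliberately
replaced by the fixed Ci ratio: the original parameterization was never
published, and the module's purpose here is a structurally complete
carbon budget, not gas-exchange accuracy. Defaults Vcmax25 = 60,
Jmax25 = 120, Rd25 = 1 μmol m⁻² s⁻¹ are generic literature values for
well-fertilized young C3 dicot leaves; all are config inputs.

The daily budget: gross assimilation integrates each blade's rate over
the photoperiod at the day temperature (the light model already applied
absorption, so the leaf model runs at absorptance 1); maintenance
respiration is 0.5 μmol CO₂ per mg dry mass per day at 25 °C with
Q10 = 2 on the daily mean temperature; of a positive net pool a fraction
Y_g = 0.75 becomes structure and the rest is growth respiration; a
negative pool draws down mass. Conversion is 30 μg CH₂O per μmol CO₂.
The identity gross = increment·conversion + growth respiration +
maintenance holds to machine precision by construction and is verified on
randomized inputs.

## Problem sizes and numerical choices

Default simulations run 30–60 days (the experiment lasted one month).
Recovery tests use grids of ~70–140 points per series with 50 noise
replicates; sensor estimates use 10⁵ rays (standard error ≈ 0.2 μmol m⁻²
s⁻¹), per-leaf absorption 2–6 × 10⁴ rays per day. Ties at phyllochron
multiples count the crossing (a leaf appears exactly at 75 °Cd); a 10⁻¹²
relative guard absorbs float drift in the crossing count. All random
streams are `numpy` `default_rng` with explicit seeds.

## Known limitations

* The extension curves for low-temperature ranks 1, 2 and 4 are
  decreasing steps as printed; the monotone wrapper makes them usable but
  their timing is not meaningful.
* Geometric and empirical whole-plant totals differ (by ~25% at M day
  30); no reconciliation is attempted, mirroring the two independent
  descriptions in the source data.
* The chamber geometry is a calibrated reconstruction, not a measured
  one; absolute per-leaf fluxes inherit that uncertainty even though the
  sensor calibration is matched.
* The carbon-mode dry-mass increment is not validated against measured
  dry mass and is not fed back into growth.
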