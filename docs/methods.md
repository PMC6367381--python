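# Methods

## Model

The package treats one folding or unfolding reaction as barrier crossing
with a temperature-independent activation heat capacity ΔC‡ₚ. Writing
T_H for the temperature at which the activation enthalpy vanishes, the
Eyring plot is

    ln(k/T) = C₂ − (ΔC‡ₚ/RT)·[T − T_H − T·ln(T/T_H)]

with C₂ a temperature-independent constant (it absorbs the transmission
prefactor and the activation entropy at T_H; the two are never needed
separately and are not represented separately). Folding has ΔC‡ₚ < 0 and
a convex plot with a maximum at T_H; unfolding has ΔC‡ₚ > 0 and a
concave plot with a minimum. Differencing the curve between a
measurement temperature T_x and the standard T₀ = 298.15 K gives the
correction

    ln k(T₀) = ln k(T_x) + [1 + ΔC‡ₚ/R]·ln(T₀/T_x) + (ΔC‡ₚ/R)·(1/T₀ − 1/T_x)·T_H

`correct_rate` computes this grouped form as the canonical path; the
algebraically equivalent difference form is kept in the tests as an
independent oracle, and the two agree within 1e−9 over a randomized
sweep (T ∈ [270, 360] K, ΔC‡ₚ ∈ [−10, 10] kJ/mol/K, T_H ∈ [100, 350] K).
The grouping makes the T_x = T₀ case exactly zero term by term, so
records already at the target temperature pass through bit-identically.

Assumptions worth keeping in mind: ΔC‡ₚ constant in temperature; rate
constants extrapolated to zero denaturant before correction (the package
does not model denaturant dependence); no pH or pressure corrections;
panel parameters calibrated on mesophilic proteins (thermophilic records
are corrected but flagged with a warning).

## Parameters

- **R** is fixed at 8.314462618×10⁻³ kJ/mol/K so that ΔCₚ/R is
  dimensionless with heat capacities in kJ/mol/K.
- **ΔCₚ(L)**: the equilibrium unfolding heat capacity is taken from
  chain length as 0.062·L_PDB − 0.53 kJ/mol/K by default, with the
  zero-intercept variant 0.058·L_PDB available; for L ≥ 34 the two
  differ by exactly 0.004·L − 0.53 (< 0.15 kJ/mol/K at L = 98) and give
  essentially identical corrections. L_PDB (the PDB-structure length) is
  always used, not the experimental construct length, because the
  regression is stated in L_PDB. Lengths below 34 residues are rejected:
  the regression was never applied there.
- **(T_H, β) policy**: the default policy ships the rounded headline
  pairs (315 K, −0.62), (305 K, −0.75), (224 K, 0.38), (119 K, 0.21) for
  folding-2S, folding-N2S, unfolding-2S, unfolding-N2S respectively;
  `default_policy(precision="panel")` substitutes the unrounded folding
  panel means recomputed from the packaged panels (314.70 K, −0.6226 for
  two-state). Both precisions circulate in practice, so both are
  offered; the rounded pair is the default because it is the quoted one.
- **Parameter choice per record**: protein-specific (ΔH‡, ΔC‡ₚ) data, when
  present on a record, beat the panel values (provenance
  `protein_specific`); a record's own Tanford β can replace the panel β
  via β = −β_T (folding, two-state only) or β = 1 − β_T (unfolding),
  provenance `tanford_beta`; otherwise the class/direction panel pair is
  used (`panel_default`). 2S* (hidden-intermediate two-state) records
  use two-state parameters throughout. Intermediate-formation rates
  (ln k_I) are never corrected — no correction is defined for them.
- **Per-record target override**: a record may carry its own standard
  temperature (one published validation entry was observed at 26 °C);
  an explicit function argument beats the override.

## Calibration procedures

**Eyring fitting.** `fit_eyring` fits (C₂, ΔC‡ₚ, T_H) directly by
nonlinear least squares on ln(k/T) vs T (scipy `curve_fit`), with
analytic initial guesses: C₂ and T_H from the extremal point, ΔC‡ₚ from
a quadratic pre-fit using the identity that the curvature at the
extremum is ΔC‡ₚ/(R·T_H²). T_H is bounded to [1, 2000] K. Noiseless
model data are recovered to ≲1e−8 relative error; under Gaussian noise
of sd 0.05 on ln k the mean recovered T_H stays within 1 K of truth over
seeded replicates. Fewer than 3 points, duplicate temperatures, or a
flat series over a sub-Kelvin span are rejected rather than fitted.

**Panel averaging.** `calibrate_folding_panel` converts each protein's
literature triple (T_a, ΔH‡, ΔC‡ₚ) to T_H = T_a − ΔH‡/ΔC‡ₚ (or takes a
fitted `EyringParams` directly; the triple wins when both exist, since
it reflects directly reported activation data), computes β against
ΔCₚ(L), and averages with `panel_mean_se` (mean, and sample-sd/√n with
the n−1 denominator). Screening of anomalous proteins whose |ΔC‡ₚ|
exceeds the equilibrium ΔCₚ is deliberately the caller's step
(`screen_overlarge_activation`), so the averaging function has no hidden
exclusions.

**Unfolding T_H placement.** The unfolding Eyring minimum lies far below
observable temperatures, so `optimize_t_hu` instead minimizes the RMSD
between observed and corrected 25 °C rates over proteins measured at two
temperatures: a dense grid (default [50, 298] K at 0.1 K; ties toward
the lower T_H for determinism) followed by bounded scalar refinement.
The returned minimum is verified in tests against an independent
brute-force scan. Proteins contributing several measurement temperatures
count per-row, not per-protein. With a single observation the problem is
underdetermined — the residual is linear in T_H, so a whole curve of
solutions exists; the optimizer returns the in-range zero and the
single-observation case is documented as non-unique.

## Curation rules

Records are excluded, in a fixed precedence, for: length < 34 residues,
disulfide bonds, covalently bound prosthetic groups, irrelevant rate
constants (intermediate-formation instead of folding rates), rates
measured in the presence of denaturant, missing PDB coordinates, missing
experimental reference. The precedence is a package decision (the
sources list exclusions categorically without ordering); each excluded
record carries exactly the first triggered reason, filters classify
rather than fail, and the report satisfies the accounting identity
input = kept + excluded + dropped-duplicates on every input (fuzzed in
tests). Flags are curator-supplied annotations; structure parsing is out
of scope. Record identity is the PDB code plus an optional range/chain
suffix, so fragments and terminal domains of one entry stay distinct.
Duplicate pairs keep the first-listed record unless its flags force
exclusion. Dataset merging is a key-union in which the first dataset
wins collisions. The off-pathway-intermediate flag exists for β_T
averaging only and does not affect membership; denaturant-activity
extrapolation is recorded as a flag with no activity-to-molarity
conversion attempted.

## Synthetic data

`SyntheticSpec` defaults emulate the folding calibration design: a dozen
proteins of 40–160 residues, measurements every 5 K from 280 to 320 K,
the two-state panel truth (T_H = 315 K, β = −0.62), i.i.d. Gaussian
noise on ln k (log-space normality, i.e. multiplicative noise on k, is
the standard convention for rate constants). The generator
forward-simulates the same model the estimators invert, so passing
recovery tests demonstrates correct inversion and calibration machinery
— not that real proteins obey a constant-ΔC‡ₚ model, that real noise is
log-Gaussian, or that real panels are as homogeneous as simulated ones.
Real data also carry denaturant-extrapolation error and inter-laboratory
variation that the generator does not model.

## Numerical choices and degenerate inputs

Temperatures live in Kelvin internally (°C only at I/O boundaries; CLI
temperatures require explicit unit suffixes). Displayed temperatures and
heat capacities are rounded to 2 decimals; full precision is kept
internally. Parallel-pathway amplitude sums within 0.01 of 1 are
renormalized with a warning, outside that they are errors. The dataset
CSV writer emits shortest round-trippable float representations, so
read → write → read is lossless; the Kelvin↔Celsius offset round-trips
exactly in double precision over the physiological range. Grid-search
ties break toward lower T_H. All simulation-based tests run under fixed
seeds.

## Known limitations

- One calibration-panel row (2CRO) is internally inconsistent in its
  source: T_a − ΔH‡/ΔC‡ₚ gives 306.49 K while the transcribed cell reads
  310.50 K. The package reproduces the formula and keeps the transcribed
  cell in the fixture; consumers of the fixture should treat that cell,
  not the formula, as suspect.
- The published optimized unfolding T_H values (224 K and 119 K) depend
  on per-protein chain lengths that are not part of the printed panels;
  `fixtures.validation_pairs` supports rerunning that placement when
  lengths are supplied externally, but the package does not assert those
  endpoints, and the shipped policy carries them as calibrated constants.
- Source-roster reductions (126 → 102, 107 → 99) are not exactly
  recoverable from the published exclusion lists (one protein appears
  both as an exclusion and as a duplicate-pair member); the packaged
  lists encode them as given and only the downstream arithmetic
  (102 + 6 = 108, + 33 = 141 = 89 + 52) is asserted, on synthetic
  stand-in rosters generated to the published composition margins.
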