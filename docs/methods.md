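# Methods

This note documents the models behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Aggregation kinetics (ThT)

**Model.** A normalized fluorescence time course F(t) is described by the
four-parameter logistic

    F(t) = F_inf + (F0 - F_inf) / (1 + exp(k (t - t50)))

with baseline F0, plateau F_inf, apparent rate k (min⁻¹) and midpoint
t50 (min). The lag time is the tangent construction at the midpoint:
the tangent to F at t50 has slope (F_inf − F0)·k/4 and meets the F = F0
baseline at

    t_lag = t50 - 2/k .

This is an empirical descriptor of sigmoidal amyloid kinetics, not a
mechanistic nucleation–elongation model; fold changes in t_lag between
conditions are its intended use.

**Normalization and censoring.** Traces are background-corrected and
min-max normalized per well. Whether to normalize per well or per plate
is a genuine choice; per-well was picked (and recorded in the output
metadata) because conditions on one plate can differ in plateau
fluorescence for reasons unrelated to kinetics. Censoring, however, is
necessarily a plate-level decision: a well that never fibrillates has no
dynamic range of its own, so its smoothed rise is compared against the
largest smoothed rise on the plate (the de-facto positive control). A
well below 10% of that reference — or, at fit time, below 5× its own
baseline read noise (MAD of first differences) — is censored: no fit,
lag reported as a lower bound equal to the run length. The smoothing
(15-point moving average) matters: over 721 points the *extreme spread*
of pure read noise is ~7σ and would otherwise masquerade as a rise.

**Fitting.** Least squares via lmfit/Levenberg–Marquardt with
deterministic data-driven starts (F0/F_inf from the 5th/95th
percentiles, t50 from the half-range crossing, k from 4·max-slope/range)
and bounds F0, F_inf ∈ [−0.2, 1.2], k ∈ (0, 10] min⁻¹, t50 within one
run-span of the observed window. Noiseless synthetic curves are
recovered to ~1e-14 relative; at read noise σ = 0.02 the median relative
t50 error over 100 replicates is ~0.1% and the lag-time bias ~0.1%.

**Replicates and fold change.** Per condition: mean ± sd over replicate
lag times (censored wells excluded and counted separately). Fold change
is the ratio of mean lag times against the untreated control matched on
buffer (pH) and temperature; whether to use means-of-lags or the lag of
the mean curve was open — means-of-lags was chosen so each replicate
contributes an independent estimate. A fully censored condition reports
the bound `> run_length / mean(control)`.

## Secondary chemical shifts

**Secondary shifts.** Δδ(n) = δ_obs(n) − δ_rc(n) per nucleus
n ∈ {Cα, Cβ}, with random-coil references shipped as a versioned data
file (`wishart95`; no neighbor-residue corrections by default — the
provenance of the table used is recorded in every output). The
difference ΔδCα − ΔδCβ is the primary structure indicator: ≈ +3 ppm in
formed helix, ≈ −3 ppm in formed strand, near 0 in coil. Glycine has no
Cβ; its profile carries ΔδCα alone, flagged, and no code path ever
references a Gly Cβ.

**Propensity score.** Per residue, each available nucleus is normalized
against full-structure reference offsets (second versioned data file:
helix/strand offsets per nucleus, +2.8/−1.5 ppm for Cα, −0.5/+2.3 ppm
for Cβ) so that a residue sitting at the full-helix reference scores +1
and at the full-strand reference −1 (Cβ contributions enter with
inverted sign). Residue scores are averaged over a ±2 window (default
window 5, odd, ≥3) restricted to assigned residues and clipped to
[−1, 1]. Both Cα-only and Cα+Cβ modes are supported and recorded.

**Segment calling.** Runs of ≥3 residues with ΔδCαβ ≤ −0.7 ppm become
strands; runs of ≥4 with ≥ +0.7 ppm become helices (thresholds exposed
in config; the minimum strand length 3 reflects that real strands of
interest span 4–5 residues). A single unassigned residue between two
qualifying runs is bridged by default, since missing assignments should
not fragment a real strand. Segment edges are then guarded: a terminal
residue whose |signal| is below half the run's median |signal| is
trimmed. The rationale is the noise model — at coil noise σ = 0.3 ppm
per nucleus, sd(ΔδCαβ) ≈ 0.42 ppm, so a coil residue adjacent to a
strand crosses the −0.7 threshold with ~5% probability and segment
boundaries would smear outward; a genuine edge residue carries close to
the full strand offset (~8σ away) and is never trimmed. The guard costs
sensitivity only for strands that taper gradually, which the
full-offset generator does not produce and which real propensity data
would anyway place near the threshold.

## Probe topology

**Reduction statistic.** r_i = 1 − I_probe,i / I_ref,i per residue, with
residues present in only one table excluded (warned) and zero-reference
residues dropped. Following the sample-average convention, residues with
r_i above the mean over compared residues are "affected". Because a few
fully broadened residues inflate the mean and can hide modest
broadening, a robust alternative (median + 1 MAD) is available behind
`threshold_rule="median_mad"`; the default remains the mean.

**Consensus rule.** Membrane evidence = above-average reduction on
nanodisc binding OR 5-DSA quenching; solvent evidence = above-average
Gd(III) PRE. Membrane if membrane-and-not-solvent, solvent if
solvent-and-not-membrane, ambiguous if both, unclassified if neither;
residues observed by no probe (and prolines, which have no amide) are
unassigned. This operationalization of "which probe speaks for which
environment" is a repo-defined rule and is recorded in the output JSON.

**Known data quirk.** The default solvent residue set used by the
generator retains residue 19 as printed in the source intensity tables
even though residue 19 of the sequence is Ser rather than Phe; the
inconsistency is reproduced deliberately rather than silently corrected.

## SASA and membrane orientation

**Quadrature.** Shrake–Rupley-style: each atom's accessible sphere
(radius r_i = vdW + radius_augment, plus the probe radius) is sampled
with a golden-spiral point set — deterministic, seedless, defined for
any n (default 960; <32 rejected as too coarse). A point is buried if it
falls inside any other atom's accessible sphere; the area is the exposed
fraction times 4π(r_i + probe)². Occlusion is tested against *all* atoms
of the model while areas are reported only for the selected group, so
the peptide's area inside a peptide+membrane system correctly feels the
membrane. Isolated spheres are exact at any n; two-sphere overlaps agree
with the spherical-cap closed form to ~0.3% at n = 960; rigid motions
change totals by ≲0.1%; a 10⁵-points-per-atom rejection-sampling oracle
agrees to ~0.2% on 50-atom clusters.

**Coarse-grained radii.** For Martini-style bead models the bead radius
convention is half the LJ σ (0.235 nm), and the published analysis
enlarges the van der Waals distance by 0.21 nm. Whether that 0.21 nm
replaced or augmented radii or the probe is not stated; here it is
implemented as `radius_augment = 0.21` nm added to every bead radius
with `probe_radius = 0`, both independently overridable and recorded in
the output parameters.

**Lipid split.** For identical peptide conformations,
lipid_area_i = SASA_alone,i − SASA_complex,i (clamped at 0; clamps
beyond 0.02 nm² warn, since they indicate mismatched conformations) and
solvent_area_i = SASA_complex,i. Preference: buried if both < 0.10 nm²
(roughly one bead-contact patch, configurable); mixed if both areas are
within 25% of each other; otherwise lipid or solvent by the larger area.
Multi-model PDBs are averaged per residue after per-snapshot profiles
(uniform frame weighting).

**Agreement.** The NMR membrane set and the SASA lipid-preferring set
are compared as a 2×2 contingency over the shared residues; the overlap
coefficient is |both| / min(|NMR|, |SASA|), undefined (flagged) for an
empty NMR set.

## Synthetic data

One seed drives everything; per-stage seeds are derived by hashing
(seed, stage-name), so stages are independently reproducible and the
whole pipeline is a pure function of the config.

* **ThT plates**: logistic truth curves plus i.i.d. Gaussian read noise
  (σ = 0.02 of the normalized range), three replicates per condition on
  a 4-min grid over 48 h (721 points). Default conditions: an untreated
  control (t50 = 300 min, k = 0.02), a slowed nanodisc condition
  (t50 = 900, k = 0.008) and a flat, fully inhibited condition.
* **Shift tables**: δ = random-coil + full secondary-structure offset
  (strand −1.8/+1.5 ppm for Cα/Cβ, helix +2.6/−0.4) + N(0, 0.3 ppm)
  per nucleus; the default fixture places strands at 8–12, 15–18, 26–29
  and leaves residues 1–5 and 35–37 unassigned (29 of 37 rows). Noise is
  drawn for every residue whether or not it is written out, so the
  unassigned set does not perturb the stream for the rest.
* **Probe tables**: the reference spectrum carries multiplicative noise
  (σ = 5%); each probe table is that same realization scaled by the
  broadening factor (0.3) on its affected residues. Sharing the
  realization models the reduction as a within-session ratio; a fresh
  independent-noise mode exists behind `independent_noise=True` for
  stress-testing the threshold rule.
* **Geometry**: one bead per residue (radius 0.23 nm) in a straight
  chain at 0.55 nm spacing over a two-layer hexagonal bead slab
  (radius 0.26 nm, pitch 0.5 nm). Contact residues (default 11–19) sit
  half-sunk in the head-group plane — bead center 0.25 nm above the top
  bead-center plane — so their membrane-facing hemisphere is genuinely
  occluded; the rest of the chain is lifted 1.6 nm, beyond augmented
  interaction range. A per-bond height-change limit (2 nm) guards
  against contact patterns a connected chain could not realize.

**What the generator does not emulate**: secondary-structure-dependent
line widths, exchange broadening, scalar-coupling or neighbor-residue
shift corrections, realistic lipid chemistry, chain flexibility or
conformational ensembles, and heteroscedastic plate noise. Passing the
recovery suites therefore shows the estimators are correct under the
stated statistical model, not that real spectra or trajectories would
behave as cleanly.

## Problem sizes

The test and acceptance workloads use the study-scale grids directly
(721-point kinetics, 37-residue tables, ~700-bead complexes) and
Monte-Carlo suites of 100–200 draws, which keep full runs in the
seconds-to-minutes range on one CPU while leaving every recovery margin
well clear of its threshold.

## Known limitations

* The logistic fit reports `converged` from the optimizer; pathological
  traces (double sigmoids, strong drift) are not detected beyond RMSE.
* NMR-STAR support is the `Atom_chem_shift` loop only.
* The SASA module is quadrature-based by design; no analytic
  (power-diagram) areas, no binary trajectory formats (multi-model PDB
  only).
* The consensus topology rule treats the three probes as binary votes;
  it does not weight by reduction magnitude or probe concentration.
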