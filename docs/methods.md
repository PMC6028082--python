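# Methods

## Chemical model

The assay buffer holds `total_carbon` (default 25 mM) of dissolved carbon at
chemical equilibrium, partitioned between CO₂(aq) (lumped with H₂CO₃) and
HCO₃⁻ by Henderson–Hasselbalch with a single apparent constant
`pK1_apparent`. The default pK1 is 6.35 at 16 °C, a conventional value for
the apparent first dissociation in dilute buffer; it is configurable
everywhere because the pH 7.4→6.8 fold-change prediction depends on it
(scanned in `analysis/05_ph_fold_change.py`: the fold moves from 2.5 to 3.1
as pK1 moves from 6.10 to 6.60). Carbonate ion is neglected — below ~1.5%
of species at the highest pH used (7.9) — which keeps the isotopologue state
small; this is a documented limitation, not an approximation toggle.

The uncatalyzed background hydration constant is `k_h = 1.2×10⁻³ s⁻¹` at
16 °C with Q10 = 2 temperature scaling (configurable). Its exact value is
unimportant — it matters only so that fully inhibited preparations still
show a slow background decay — but it must exist, and the dehydration
constant is always tied to it by flux balance `k_d = k_h·[CO₂]/[HCO₃⁻]` so
the chemical system never drifts.

## Isotope-exchange dynamics

State: per compartment, CO₂ isotopologues with 0–2 ¹⁸O and HCO₃⁻ with 0–3,
plus one absorbing sink (¹⁸O released to water, tracked in moles so the
budget closes across compartments of different volume). The generator is
assembled from per-molecule rates `kc = F/[CO₂]`, `kb = F/[HCO₃⁻]` where
`F = R1_catalyzed + k_h·[CO₂]` is the total interconversion flux. Hydration
preserves a molecule's labels and adds an unlabeled oxygen; dehydration
discards one of the three oxygens uniformly at random (probability j/3 of
losing a label from a j-labeled molecule). No separate proton-transfer-
limited H₂¹⁸O release channel is modeled: the fitted quantity is R1 only,
and the uniform-loss rule applies to catalyzed and uncatalyzed events alike.
A known consequence is that the single-compartment slow decay rate has the
closed form `λ = (tr − √(tr² − (4/3)·kc·kb))/2`, `tr = kc + kb`, which the
code exposes as an independent oracle for the matrix eigenvalue.

Initial condition: each oxygen site is labeled independently with
probability `label_enrichment` (binomial over 2 or 3 sites). The default
enrichment 0.2 is a fixture parameter chosen arbitrarily; the dynamics are
linear in label, so every fitted rate constant is independent of it.

Integration is exact (matrix exponential, cached per step size); a stiff
`solve_ivp` route is retained purely as an independent cross-check, and the
two agree pointwise to <10⁻⁸ on α in the tests. All randomness lives in the
noise generators; the simulator is deterministic.

## Whole-cell (two-compartment) model

Cells are a second compartment of total volume
`cell_density × per-cell volume` (default 2 pL/cell → volume fraction 10⁻³
at 5×10⁵ cells/mL). CO₂ isotopologues exchange across the membrane with a
first-order constant expressed on the extracellular concentration
(`co2_exchange_rate`); the intracellular-side constant is scaled by the
volume ratio so total CO₂ is conserved. HCO₃⁻ does not cross. Intracellular
speciation is taken identical to extracellular (no pH gradient is modeled).
Cell or ghost addition is an event at `t_add` (default 120 s): enzymes
switch on and, for whole cells, an unlabeled intracellular compartment is
spliced in.

None of the cell-geometry parameters are published for these lines; they are
placeholders that shape only the early phase. Defaults: cytosolic CAII at
20 µM with efficiency maximum 1.2×10⁸ M⁻¹s⁻¹ and pKa 6.9 (typical for the
enzyme), and `co2_exchange_rate = 0.15 s⁻¹`. The exchange constant was set
by a structural requirement, not by fitting: the post-addition transient
(the cell-uptake modes, rates ≈ 0.1–0.2 s⁻¹ at this setting) must be fully
decayed before the late window opens at 250 s, so that the late-window
regression agrees with the slow eigenvalue to better than 0.1%. At slower
exchange (≲0.08 s⁻¹) a near-degenerate mode survives into the window and
biases the fitted constant by up to ~1%. The resulting curves are strongly
biphasic (early slope 15–40× the late slope), qualitatively matching
whole-cell measurements; no quantitative claim is made about the early
phase.

A genuine physical effect follows from the same analysis: for very
low-activity layouts the CO₂-pool scrambling mode (rate ≈ kc + kb) is
itself slow, and at the weakest fixture (normoxic HBL-100,
k = 0.43×10⁻³ s⁻¹) it has not fully decayed by 250 s, leaving a −2.8%
bias in the default-window fit. The bias vanishes (<0.1%) when the window
is opened after ~5 scrambling time constants (e.g. 800–1200 s on a longer
run), which the tests demonstrate. Fits of such slow preparations should
use `segment_phases(mode="auto")` or a later window.

## Calibration and inversion

`calibrate_activity_to_kobs` finds, by bracketed root solve, the exofacial
enzyme concentration whose slow eigenvalue equals a target rate constant
(tolerance 10⁻⁸ relative); this is how cell-line fixtures expressed as
published rate constants become simulatable layouts. The inverse direction,
`efficiency_from_kobs`, finds the catalyzed flux R1 reproducing a fitted
k_obs on top of the uncatalyzed background — the subtraction happens in
flux space, where contributions are exactly additive, not on fitted slopes —
and converts to efficiency by `(R1/E)/[CO₂]`, valid in the sub-saturation
regime (`K_eff ≫ [CO₂]`) the exchange assay reports. A finite `K_eff_CO2`
switches the forward model to the saturating Michaelis form, but no fixture
uses it.

## Fitting stages

- **First-order constants**: OLS of ln α on time. Chosen over a nonlinear
  exponential fit because the published constants are defined operationally
  as log-linear slopes; `fit_exponential` is kept as a cross-check.
  Windows default to 130–180 s (early) and 250–450 s (late); auto
  segmentation scans a two-segment piecewise-linear fit on a 5 s breakpoint
  grid and trims 10 s each side.
- **pH titration**: nonlinear least squares of `A/(1 + 10^(pKa−pH))`,
  initialized at the half-maximum crossing, bounded pKa within the sampled
  span ±1, tolerances 10⁻¹²; flat curves (range <10% of max) are rejected.
  A single ionization is assumed — the conventional model when one apparent
  pKa is reported per enzyme — and the assumption is flagged here because
  the published fits do not state their model. The dehydration curve is
  never fitted independently: one equilibrium flux underlies both
  directions, so it follows from the hydration fit by
  `eff_dehyd = eff_hyd·10^(pK1−pH)`.
- **Tight binding**: Morrison quadratic fitted in log-parameter space (both
  parameters are positive scale parameters and the (E, Kd) surface is badly
  conditioned in linear coordinates), initialized by extrapolating the steep
  titration region to zero activity. Data in the classical regime
  (E ≪ Kd), where E_total is a flat likelihood direction, raise
  `UnidentifiableError` (detected by the covariance of the fit). The series
  must span activities from >0.9 down to <0.2.
- **Classical Ki**: `1/(1 + I/Ki)` least squares.

## Synthetic data

Generators are pure functions of (entry, parameters, seed). Noise is
multiplicative log-normal (instrument noise scales with signal) with default
relative sd 0.5% on trace atom fractions and 5% on titration efficiencies;
no noise figures were published, and these defaults were chosen once so that
seeded recovery studies land at the published ± precision (the 5% titration
noise gives a replicate pKa sd of ~0.03–0.04, consistent with the quoted
±0.1). Replicate counts honor the published n (4 for CAIX, 3 for CAXII).
T47D, MCF7 and HBL-100 use the CAII-free single-compartment layout (their
blots show no CAII and their curves are log-linear); UFH-001 uses the
two-compartment layout. The ethoxzolamide Kd (1 nM) is a configurable
default — only stoichiometric titratability matters for enzyme
quantification — while the N-3500 Ki (12.6 µM, classical, impermeant) is a
published value.

What the generators do not emulate: instrument drift, inlet memory and CO₂
consumption, temperature ramps, ¹³C bookkeeping (the ¹³C label only isolates
the species in the mass spectrum), intracellular pH regulation, and mixed
exofacial isoforms (each line expresses a single exofacial CA, which is the
premise of the comparison). Passing round trips therefore demonstrate
internal consistency of simulator and fitters under the published
conditions, not robustness to these real-data effects.

## Degenerate inputs and numerical conventions

pH outside [5, 9] is rejected at construction. Zero bicarbonate makes the
dehydration constant undefined (rejected); zero CO₂ simply gives `k_d = 0`.
Non-equilibrium speciations are rejected with a diagnostic before matrix
assembly (tolerance 10⁻⁹ on the Henderson–Hasselbalch ratio). The slow
eigenvalue filters numerically zero modes at 10⁻¹⁰ of the largest matrix
entry; a zero generator returns 0. Saturating inhibitor concentration
(I = ∞) is accepted and yields zero fractional activity, which is the limit
in which the impermeant-blockade background test is exact. Two zero-variance
groups with equal means return t = 0, p = 1 in the group comparison
(equal-variance Student's t by default; Welch behind a flag).

## Problem sizes

Default runs simulate 0–500 s at 1 Hz (8- or 15-dimensional generator, one
matrix exponential per constant-step segment). The seeded recovery studies
use 200 replicates for traces and binding series and 100 for titrations;
the whole suite completes in well under a minute on one core.
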