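# Methods

`fibwave` is a desk-scale in-silico laboratory for genotype-specific atrial
fibrillation (AF): a biophysical atrial myocyte model embedded in a 2D
anisotropic monodomain sheet, seeded synthetic substrates standing in for
patient electroanatomical maps, clinical-style induction and intervention
protocols (catheter ablation, antiarrhythmic drugs), and the wave-dynamics
metrics used to compare them.

## Ionic model

Cellular electrophysiology is the Courtemanche–Ramirez–Nattel (CRN) human
atrial model: 12 ionic currents, a two-compartment sarcoplasmic reticulum,
and Ca²⁺ buffering by troponin, calmodulin and calsequestrin (21 state
variables).  The implementation is verified against an independently coded
brute-force forward-Euler transliteration of the model equations (`dt` =
0.005 ms): membrane-potential traces agree to < 0.05 mV RMS over a paced
beat, and the quiescent model reproduces the published resting state
(−81.2 mV) and CL-1000 ms APD90 (≈ 297 ms).

Every experimental condition is a **multiplicative scaling preset**: a map
from current identifier to a non-negative factor applied to the maximal
conductance (or, for `I_Caup`, the maximal SR uptake flux).  Presets
compose by element-wise multiplication (commutative, associative, identity
= all-ones).  Shipped presets:

| preset | factors (≠ 1) |
|---|---|
| `wt_sr` | — (unmodified CRN) |
| `wt_af` | I_Na 0.90, I_to 0.30, I_CaL 0.30, I_Kur 0.50, I_Caup 0.80, I_K1 2.10 |
| `pitx2_modifier` | I_K1 0.75, I_Kr 2.0 |
| `pitx2_af` | = `wt_af` × `pitx2_modifier` (I_K1 1.575, I_Kr 2.0) |
| `fibrotic_modifier` | I_K1 0.50, I_CaL 0.50, I_Na 0.60 |
| drugs | per-dose YAML tables (see below) |

Drug presets (amiodarone 5/10 µM, dronedarone 3/10 µM, flecainide
5/15 µM) are **data**: `data/drug_presets.yaml` maps each (drug, dose) to
a factor table with a provenance field.  The shipped factors are synthetic
placeholders shaped by the drugs' known block profiles (amiodarone
multi-channel; dronedarone predominantly I_Kr with I_CaL/I_Na; flecainide
predominantly I_Na); they demonstrate the mechanism and should be replaced
by measured block fractions for quantitative drug studies.  Doses are
independent tables, not points on a fitted dose–response curve.

## Numerics

Gates use the Rush–Larsen exponential update; membrane potential and
concentrations use forward Euler.  Default `dt`: 0.02 ms for single
cells, 0.1 ms in tissue, 0.2 ms for the scaled test episodes (planar CV
shifts < 0.3% between dt 0.05 and 0.2 at the episode lattice, and the CV
calibration is performed at the episode's own dt anyway); an explicit
stability check refuses unstable `dx`/`dt`/diffusion combinations and
reports the admissible limit.  Voltage-dependent gate kinetics and
current rectification factors are tabulated on a 0.1 mV grid (float32,
linear interpolation, L2-cache-resident) with the per-step decay factors
baked in; the sharp SR-release-gate sigmoids are tabulated likewise, and
reversal potentials are refreshed every 8 steps (concentrations drift on
second scales).  These approximations sit orders of magnitude below
model error — the oracle-equivalence test bounds their combined effect.
A quiescent sheet with no pending stimulus exits early: the model has no
spontaneous activity, so the remaining trajectory is identically resting.

Stimuli are 2 ms rectangular pulses at ≈ 2× diastolic threshold
(20 pA/pF single cell, 40 pA/pF in tissue over a 3 mm pacing disc).
Quiescent states are equilibrated per preset until the membrane potential
drifts < 10⁻⁴ mV/ms.

**APD90 convention.** The upstroke time is the instant of maximum dV/dt;
the take-off potential is the diastolic minimum immediately preceding the
upstroke; APD90 is the time until V first recovers to
`peak − 0.9 (peak − takeoff)`.  (Referencing the take-off potential *at*
the max-dV/dt instant was rejected: on CRN action potentials that
potential is ≈ −2 mV, which puts the 90% level just below the spike peak
and collapses APD90 to a few milliseconds.)  "Steady state" during fixed-
rate pacing means beat-to-beat APD90 change < 1 ms (cap 50 beats).

## Tissue solver

The monodomain reaction–diffusion equation is solved on a regular lattice
with an anisotropic tensor `D = D_T I + (D_L − D_T) f fᵀ` built from the
local fiber angle, discretized in divergence form as a 9-point stencil
with face-averaged coefficients and no-flux boundaries.  The stencil is
constructed so that it annihilates constant fields exactly (machine-
precision zero-flux conservation).  Anisotropy is fixed at
`D_L : D_T = 5 : 1`.

Fibrotic nodes carry the fibrotic ionic modifier **and** a ×0.5 coupling
reduction.  Ablated nodes are clamped at 0 mV and removed from the
coupling graph entirely — a permanent conduction block.

**CV calibration.** Because lattice discretization slows numerical
conduction, the global diffusion scale is calibrated per grid and preset:
planar-wave CV is measured on a homogeneous fiber-aligned reference strip
at the same spacing, time step and anisotropy, and bisected (≤ 12
iterations, log-scale, using CV ∝ √D) until it matches the target —
0.6 m/s along fibers by default.  Calibration uses the episode's own
ionic preset: AF-remodeled tissue (doubled I_K1) has a larger excitation
sink and would otherwise fail to propagate on coarse lattices.
Measuring on a strip rather than the fibrotic sheet keeps the reference
substrate-independent; the self-consistency test confirms a recalibrated
grid reproduces its target within 5%.

Activation events are detected in-kernel on the upward crossing of
−40 mV (50 ms refractory blanking, sub-step interpolation); 90%-
repolarization events use the same take-off convention as above.

## Synthetic substrate

The generator emulates the features of a patient left-atrial map that the
protocols interact with, on a 60 × 60 mm monolayer sheet (default
`dx` 0.25 mm; 0.2351 mm at the full-resolution setting, matching the
235.1 µm mean inter-node distance of clinical meshes):

* **Zones** — four pulmonary-vein ostia (non-conducting vein lumen inside
  a conducting labeled sleeve), a high-septum pacing zone, an appendage
  zone.  The lumen holes act as the anatomical anchors that veins provide
  in a real atrium.
* **Voltage surrogate** — a Gaussian random field (configurable
  correlation length, default 8 mm) mapped through a lognormal transform
  into the clinical 0.05–5 mV bipolar-voltage envelope, sampled at 500
  pseudo-electrode nodes and interpolated back by inverse distance
  weighting (exact at electrode locations), mimicking electroanatomical
  map interpolation.
* **Fibrosis** — per-node Bernoulli draw with logistic probability
  `P(v) = 1/(1+exp((v−v0)/k))` (defaults v0 = 0.5 mV, k = 0.15 mV); when
  a burden target is set (default 0.20, moderate remodeling typical of AF
  ablation cohorts) the midpoint is tuned by bisection so the expected
  fraction matches it.  Fibrosis therefore clusters in low-voltage
  patches, as clinically observed.
* **Fibers** — a smooth random orientation field (±25° deviation,
  10 mm smoothness) with circumferential wrap blended in around each PV
  ostium.

What the generator does **not** emulate: real chamber geometry and wall
thickness, the right atrium, LAT-map-derived fiber fitting, spatially
registered clinical voltage data.  Passing the property suite therefore
demonstrates the mechanisms (re-entry, isolation, genotype effect
directions), not patient-specific rates.

## Protocols

* **Induction** — ramp pacing from the septum: cycle length 200 → 120 ms
  in 10 ms stages, 8 beats per stage (72 stimuli, exactly 11,520 ms).
* **Episode** — induction + 20,480 ms observation = 32 s; DF/Smax/AFCL
  analyzed over 17,000–23,000 ms; APD90/CV measured separately at CL
  600 ms with sinus-rhythm currents.
* **Desk scale** — the tests and examples run a proportionally scaled
  episode (4 beats per stage → 5,760 ms induction, 10,240 ms observation,
  16 s total, window 8,000–14,000 ms) at `dx` 0.5 mm and `dt` 0.2 ms so a
  full matched-genotype suite fits in minutes; the full 32-s layout is
  the default for experiments.  Lattices coarser than 0.5 mm
  over-organize the re-entry (most episodes self-terminate), so the
  spacing is the one parameter desk scale does not relax.
* **CPVI** — two closed stadium-shaped contours (default 2 nodes wide,
  3 mm outside the ostia) around the ipsilateral PV pairs; closure is
  verified by flood fill.
* **High-DF ablation (DFA)** — connected components of the baseline DF
  map at/above the 90th percentile contribute their peak node (ties →
  lowest index), non-maximum-suppressed at twice the disc radius, up to 3
  discs of 5 mm radius.  In the pipeline DFA is a conditional second
  pass applied only to episodes not defragmented by CPVI alone.
* **Drugs** — the drug preset composes over the genotype AF baseline from
  episode start; ablations modify the grid before induction and re-induce.

## Wave-dynamics analysis

* **DF** — Welch spectra (2 s hann segments, 50% overlap, mean
  detrending, zero-padded to ≤ 0.05 Hz bins) of per-node membrane
  potential; search band 2.5–20 Hz; a node is undefined without in-band
  power or without any activation in the window.  The map mean is the
  arithmetic mean over defined, non-ablated nodes.
* **Smax** — per node, (DI, APD90) pairs collected from the episode's own
  activity (`DI_n = act_n − rep90_{n−1}`, `APD_n = rep90_n − act_n`,
  ≥ 5 pairs); mono-exponential fit `APD = A − B e^{−DI/τ}` whose
  derivative at the smallest observed DI is Smax; when the family
  degenerates (τ or B at bound, flat data, non-convergence) the maximum
  finite-difference slope is used, which is exact on linear data.
* **AFCL** — mean inter-activation interval pooled over non-ablated nodes.
* **Outcome** — `terminated` if no activation in the final second; `AT`
  if ≥ 90% of active nodes have interval coefficient of variation < 0.10
  and the spatial SD of node DF is < 0.5 Hz; otherwise `AF`.
  Defragmentation = AT or terminated.  The thresholds operationalize an
  electrogram-based judgment; they are configurable module constants.

## Pipeline

`run_matrix` executes genotype × {baseline, CPVI, CPVI±DFA, 3 drugs × 2
doses} over seeded substrates (default 25 seeds; one episode per cell),
calibrates CV per genotype preset, carries the baseline DF map into DFA
targeting, flags baseline induction failures and excludes them from
intervention denominators, persists each episode row as JSON for
resumability, and never drops a failed episode silently.  `summarize`
reports defragmentation/termination rates with numerators/denominators
and median [IQR] wave dynamics; `compare_groups` provides two-sided
Mann–Whitney U for continuous metrics and Fisher's exact test for rates,
with no multiplicity correction (reporting layer only).

## Numerical accuracy and known limitations

* Planar CV converges under lattice refinement (0.125 → 0.0625 mm changes
  CV < 5%); at the coarse desk-scale lattices discretization slows
  conduction substantially, which the per-grid CV calibration absorbs —
  the same strategy the clinical modeling platforms use.  Re-entry
  survival is resolution-limited: at 0.5 mm the wild-type-AF substrate
  sustains the scaled observation in 3/5 seeds (mean DF 6.0–6.4 Hz); at
  0.6–0.75 mm most episodes self-terminate.
* Desk-scale episode outcomes are often classified AT rather than AF: a
  60 × 60 mm sheet supports one or two anchored macro-re-entries whose
  activation is regular, unlike the multi-wavelet activity of a full
  atrium.  The defragmentation bookkeeping is unchanged; baseline
  "defragmentation" at desk scale simply reflects this organization.
* Episode-derived Smax at desk scale measures the diastolic-interval
  range an episode actually visits as much as the restitution curve
  itself: the PITX2-deficient preset, with longer APD and hence shorter
  visited DIs, fits a *steeper* apparent slope than wild type even though
  its cellular restitution is genuinely shallower (single-cell dynamic
  restitution: wt_af Smax 0.30 vs pitx2_af 0.20).  The genotype ordering
  of episode Smax reported by the clinical platform is therefore not
  reproduced at this scale; the cellular route is exposed via
  ``dynamic_restitution`` and the ``smax_window`` parameter.
* Single-cell APD90 at CL 600 ms is 288 ms (wild type) and 255 ms
  (PITX2-deficient) — the correct direction and the faithful CRN values,
  but longer than the 233/179 ms reported by the proprietary clinical
  platform, whose integrator and settings are unpublished.  The
  acceptance test records this discrepancy rather than hiding it.
* 2D monolayer only (no wall thickness, no endo/epi dissociation, no
  bidomain electrics, no mechanics); drug action is pore-block scaling
  (no state-dependent binding kinetics); outcomes at desk scale are
  mechanism demonstrations, not patient-rate predictions.
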