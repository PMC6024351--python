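# Methods

## Cell model

The myocyte is the ten Tusscher–Panfilov 2006 human left-ventricular model,
epicardial parameter set: 12 Hodgkin–Huxley gates, a ryanodine-release
variable, subspace/SR calcium handling and five intracellular
concentrations. All currents are in pA/pF; the published resting point is the
initial condition and every run first relaxes it for 1000 ms at the chosen
[ATP]ᵢ (the hypoxic currents shift rest by well under a millivolt, but the
relaxation makes "rest" an honest fixed point of the integrated system —
the unstimulated drift over a further second is below 1 mV at every
supported ATP level).

**Hypoxia.** Graded hypoxia is a single scalar, [ATP]ᵢ ∈ [2, 6] mM, acting in
two places:

* an ATP-sensitive potassium current
  `I_K(ATP) = g_katp_max · f_ATP · (K_o/5.4)^0.24 · (V − E_K)` with
  `f_ATP = 1/(1 + ([ATP]ᵢ/K_½)^h)`;
* a metabolic scale on the L-type Ca²⁺ conductance,
  `f_CaL = 1/(1 + (K_CaL/[ATP]ᵢ)^h_CaL)`, monotone in ATP and → 1 at
  saturating ATP.

**Calibration.** The five free constants were fitted (Nelder–Mead, single
cell paced 5 beats at CL 1000 ms) so the APD₉₀-vs-ATP profile reproduces the
characterized hypoxic remodeling (21 / 48 / 140 / 260 / 330 ms at
2…6 mM). Defaults:

| parameter | value | unit |
|---|---|---|
| `g_katp_max` | 0.06286 | nS/pF |
| `katp_atp_half` | 3.7726 | mM |
| `katp_hill` | 10.774 | – |
| `ical_atp_half` | 2.3519 | mM |
| `ical_atp_hill` | 7.771 | – |

yielding APD₉₀ = 21.0 / 48.1 / 139.1 / 282.8 / 300.9 ms (max |error| 8.8 %,
strictly monotone). Two honest caveats: (i) the base model's intrinsic
normoxic APD₉₀ at CL 1000 ms is ≈ 304 ms, which bounds the 6 mM point ~9 %
below the 330 ms reference — no admissible parameter choice can exceed the
baseline; (ii) the fitted ATP Hill coefficients are much steeper than
single-channel K_ATP inhibition measurements (h ≈ 2). They are
phenomenological constants that reproduce the *tissue-level* APD profile
under the APD₉₀ convention, not channel biophysics; all are exposed in the
`[cell]` config section.

**Integration.** Operator order per Δt = 0.02 ms step: currents from the
current state → forward-Euler concentrations → Rush–Larsen gates (exact
exponential relaxation toward V-dependent targets; the release variable and
the subspace-Ca gate relax toward Ca-dependent targets under the same form)
→ forward-Euler V. A readable reference integrator (`ionic.step_cell`)
defines the semantics; the production numba kernels tabulate every purely
V-dependent factor on a 0.05 mV grid (float32, linear interpolation) and
reproduce the reference trace to ~10⁻⁴ mV over an action potential. The
kernel refreshes Nernst potentials every 25 steps (0.5 ms; the underlying
concentrations move by ~0.1 % per beat) and replaces the two remaining
exponentials by cubic expansions valid to 10⁻⁹ at their small arguments.
Divergence (|V| > 500 mV) raises a numerical-instability error naming the
first offending cell.

**Stimulus convention.** Depolarizing stimulus current is positive, in
pA/pF. Single-cell pacing uses 2 ms pulses at twice the diastolic threshold
(found by bisection per ATP level); tissue stimuli default to 120 pA/pF ×
2 ms applied to a one-cell-thick boundary layer — strong enough to capture
against the electrotonic load at the stiffest conductivities used.

## Tissue model

Monodomain, isotropic, on a regular grid of h = 100 µm cubes:
β C_m ∂V/∂t + β I_ion = ∇·(σ∇V) + I_stim, no-flux boundaries. The 7-point
face-flux finite-volume operator assigns conductance σ/h² to a face iff both
adjacent cells are conductive; fibrotic cells are completely disconnected
and hold no state. The operator is symmetric with zero row sums
(conservation), verified against a dense edge-by-edge assembly.

β = 1400 cm⁻¹ and C_m = 1 µF/cm² are fixed; only D = σ/(βC_m) enters the
dynamics. σ is calibrated by bisection so a planar wave at 6 mM on a
homogeneous strip travels at 34.2 cm/s, giving σ = 0.448 mS/cm
(D ≈ 3.2·10⁻⁴ cm²/ms). The explicit stability bound Δt ≤ βC_m h²/(6σ)
(= 0.0417 ms at the calibrated σ) is checked at construction.

With this calibration the model's velocities at 3/4/5 mM (33.6 / 34.0 /
34.2 cm/s) show the expected near-constancy, but the 2 mM velocity drops
only ~2 % (33.5 cm/s) rather than the characterized ~8 % (31.4 cm/s). The
drop is controlled by the K_ATP leak during the wave foot, and the leak
magnitude is pinned by the 21 ms APD constraint: across the whole admissible
K_ATP/I_CaL calibration frontier, CV(2 mM) spans only 32.9–33.5 cm/s. We
report the discrepancy rather than distort the APD calibration; hypoxic CV
slowing in real ischemia is driven largely by hyperkalemia, which this model
deliberately excludes.

**Quiescent-cell gating.** Cells start frozen at their equilibrated resting
state and are integrated only after diffusion moves their potential by
> 0.05 mV; diffusion rows are evaluated only for cells in or adjacent to the
active set. Both sets grow monotonically (no re-freezing: the slow Na⁺
inactivation gate keeps recovering for hundreds of ms after an AP, and
freezing it would bias re-excitability), so the scheme is deterministic and
exact ahead of the wavefront up to the sub-microvolt frozen-rest
approximation. Runs end early once no cell exceeds −70 mV for 20 ms after
the last stimulus, or (in Monte-Carlo mode) at the first confirmed
re-activation.

**Activation bookkeeping.** An activation is an upward crossing of −40 mV by
a cell that has re-armed below −70 mV since its last event, with ≥ 10 ms
between events. This guards against counting electrotonic wobble near
threshold as re-excitation.

## Fibrosis generator (the synthetic data)

Per-cell i.i.d. Bernoulli(φ) removal restricted to the injured region:
one uniform variate per grid cell in fixed C order from a seeded PCG64
generator. Consequences used by the tests: realized fractions follow the
binomial law; fields are reproducible from (geometry, φ, seed); for a common
seed the removal sets are nested across φ (common random numbers), which
makes the percolation monotone-coupling property exact. What it does *not*
emulate: compact/interstitial/patchy fibrosis textures, spatial correlation,
myofibroblast coupling — so passing tests say nothing about textured
fibrosis in real tissue.

Geometries: rectangular slabs (width × height × layers, optionally with a
full-thickness injured disc by cell-center inclusion) and cubes. [ATP]ᵢ is
uniform inside the injured region and 6 mM outside.

## Percolation analysis

The primary crossing test is 6-connected (face-adjacency, matching the
finite-volume coupling) component labeling of the conductive mask
(`scipy.ndimage.label`); a path must join the two opposite faces of the
chosen axis. Crossing probabilities use 100 independent fields per (N, φ) by
default; φ_th interpolates the crossing curve linearly at probability ½.
A wave-based mode propagates an actual action potential through each mask
and reports both verdicts, since connectivity is necessary but not
sufficient for propagation (source–sink mismatch). Reference values
recovered by the suite: single-layer 4 × 4 cm slab φ_th ≈ 0.407
(= 1 − 0.5927, the 2-D site-occupation limit), rising with thickness toward
the 3-D limit ≈ 0.69; the 1 × 1 × N chain obeys φ_th = 1 − 0.5^{1/N}
exactly.

## Reentry detection and Monte Carlo

The quiescence horizon is computed, not guessed: stimulus end + domain
diagonal at the slowest characterized CV + longest characterized APD +
100 ms margin (the characterization table ships in
`reentry.REFERENCE_AP_TABLE`, regenerated by the acceptance script's
protocol). A trial is *reentrant* if (a) any activity outlives the horizon,
or (b) any cell records a second, re-armed activation outside every stimulus
window; both sub-criteria are logged separately in the verdict's rationale.
An *ectopic beat* additionally requires a healthy-region cell to re-fire
more than 50 ms after its first activation. Truncated records yield an
indeterminate flag rather than a verdict.

Monte-Carlo sweeps draw per-trial seeds from a master `SeedSequence`; every
trial cross-checks (i) far-face propagation ⇒ graph percolation of its mask
and (ii) reentry ⇒ at least one injured-region activation. Numerically
failed trials are excluded from numerator and denominator and reported.
Error bars are binomial ±1 standard error (normal approximation), matching
how the study conditions are summarized.

**Problem sizes.** The shipped sweep runs the single-layer 2 × 2 cm injured
slab (40 000 cells) at 2 mM with 20 trials per φ ∈ {0.10, 0.35, 0.38, 0.40,
0.70} — the package's desk-scale study conditions. The histogram-shaped
claims are checked as monotonicity properties at reduced scale: the
hypoxia effect (probability non-increasing in [ATP]ᵢ) on a 0.8 × 0.8 cm
slab with 8 trials per level, and the stimulus-synchronization effect
(reentry count non-increasing from 1 → 4 → 6 stimulated cube faces) on a
0.24 cm cube with 5 trials per protocol, both asserted within combined
binomial error. Full-scale 400 × 400 × 10 histograms and the minimum-size
searches use the same code paths (`probability_histogram`,
`minimum_size_search`, the CLI `mc-reentry`/`min-size`) and simply scale
the geometry, trial counts and size schedules in config.

## Known limitations

* Hypoxia only: no hyperkalemia or acidosis, hence realistic APD shortening
  but understated conduction slowing at 2 mM (see above); no
  oxidative-stress or fibroblast-coupling effects.
* Epicardial cell type only; no transmural heterogeneity, no fiber
  anisotropy, no bidomain effects.
* Diffuse fibrosis only, uncorrelated; σ is binary (0 or σ).
* Explicit fixed-step integration; the stability bound caps σ at ~1.17
  mS/cm for Δt = 0.02 ms at h = 100 µm.
* Reentry classification is event-based; rotor-vs-figure-of-eight typing,
  dominant frequencies and ECGs are out of scope.
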