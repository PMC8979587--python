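# Methods

This note documents the models and procedures implemented in `branchfield`,
the defaults they use, and what the synthetic-data tests do and do not show
about real recordings.

## Branch complexity

A recording site on a dendrite sees two directions of membrane; β(x) counts
the distinct dendritic points at on-path (geodesic) distance x from the site.
β starts at 2, gains one per bifurcation passed and loses one per terminal
reached, so it is piecewise constant with breakpoints at branch points and
tips. Branch complexity is the exponentially discounted integral

Ω(λ) = ∫₀^∞ β(x) e^(−x/λ) dx = Σᵢ βᵢ λ (e^(−xᵢ/λ) − e^(−xᵢ₊₁/λ)),

with units of length (reported in µm and mm). The integral truncates
naturally at the farthest tip — no tail extrapolation. The default
λ = 145 µm is the spatial extent of membrane depolarized simultaneously by a
propagating bAP: conduction velocity (154.9 µm/ms) × somatic AP full-width
half-maximum (0.94 ms) ≈ 145.6 µm. Ω rises with nearby membrane and is
inversely related to the local input resistance; the Ω–Rin regression across
a synthetic ensemble peaks in explanatory power for λ of roughly
50–200 µm, with an interior maximum (R² ≈ 0.8–0.85 around λ ≈ 100–145 µm).

Traversal conventions: by default β crosses the soma into all reachable
neurites but never enters AIS or axon, and soma-region segments carry path
length without being counted as dendritic branch; both are configurable
(`cross_soma`, `include_axon`). A site exactly on a bifurcation node is
represented on the parent edge at offset 1, preserving β(0) = 2. Distances
are 3-D path lengths; a planar mode (`site_metrics(..., planar=True)`)
reproduces the ≤10 % underestimate of distances measured on maximum-intensity
projections.

## Compartmental model

Geometry: cylindrical soma 12 µm × 12 µm, AIS 30 µm × 2 µm, axon
300 µm × 1 µm, dendrites uniformly 1 µm in diameter. Passive constants:
Cm = 1 µF/cm², Rm = 7000 Ω·cm², Ri = 100 Ω·cm; leak reversal −75 mV
(configurable; with the resting potassium conductances the model settles
near −79 mV, close to measured resting potentials). Each edge is split into
segments no longer than `max_compartment_length` (default 10 µm); membrane
area is conserved exactly under refinement.

Integration is backward Euler on the voltage with a Hines-ordered O(N)
elimination over the compartment tree (compartments are numbered
parent-first, so one backward sweep eliminates all branches); gate variables
advance by exponential integration against the previous step's voltage
(staggered update). Default dt = 0.01 ms for calibration-grade runs; the
ensemble experiments use 0.02 ms, where halving dt changes bAP peaks by well
under 0.5 mV. Simulations pre-equilibrate for 30 ms at coarse dt so active
models start from their true resting state. A voltage excursion beyond
±200 mV raises a diagnostic naming dt.

Channel densities (pS/µm²) follow the L2/3 pyramidal-cell table: Na — axon
170, AIS 2550, soma 85, dendrites 85; delayed-rectifier K — axon 33, AIS
100, soma 100, dendrites 3; M-type K — soma 2.2, dendrites 1; HVA Ca — soma
0.5, dendrites 0.5; LVA Ca — soma 3, dendrites 1.5; plus an A-type K channel
on soma and dendrites whose uniform density is calibrated per cell. Only the
HVA calcium kinetics are fully specified by published rate functions (shared
with the point gating module); the others are standard Hodgkin–Huxley-style
forms behind a pluggable gate interface (`GateSpec` accepts α/β or
steady-state/τ definitions):

* Na: classic squid-axon m³h kinetics with the activation rates scaled 2.5×
  and shifted 6.5 mV hyperpolarized — a conventional adjustment for
  mammalian channels near physiological temperature. This parameterization
  was chosen so that the model reproduces the qualitative backpropagation
  regime reported for these cells: bAPs that reach about −10 mV at
  100–160 µm for low-to-moderate A-type density, a smooth monotone
  dependence of dendritic peak on A-type density (required for simplex
  calibration), and abrupt branch-dependent propagation failure.
* Delayed rectifier: classic n⁴ kinetics.
* A-type K: product of a fast activation gate (V½ = −30 mV, slope 15 mV,
  τ = 1 ms) and a slow inactivation gate (V½ = −60 mV, slope 8 mV,
  τ = 15 ms).
* LVA Ca: m²h with low-threshold activation (V½ = −50 mV, τ = 3 ms) and slow
  inactivation (V½ = −78 mV, τ = 40 ms).
* M-type K: single slow gate (V½ = −35 mV, τ = 30 ms).

Calcium-activated potassium channels are not included: they require an
intracellular calcium pool, and calcium dynamics (buffering, diffusion,
extrusion) are outside the model's scope. For the same reason the calcium
readout is a conductance, g_Ca(t) = density × open probability at the
recorded compartment (HVA reported separately from HVA+LVA totals), not an
intracellular concentration. `reduced_channels()` (Na + delayed rectifier +
A-type + HVA Ca) is the default experimental model; `standard_channels()`
adds M-type and LVA.

Reversal potentials: E_Na = +60 mV, E_K = −90 mV, and E_Ca = +131 mV (the
Nernst potential for 75 nM internal / 1.5 mM external calcium at 34 °C).

### Derived experiments

* **Input resistance** — solved directly from the passive steady-state
  system (the limit of a small hyperpolarizing injection); linear, hence
  exactly independent of injection amplitude. Agreement with the sealed-end
  finite-cable closed form R∞·coth(ℓ/λ_c) is within 1 % at 2 µm resolution.
* **bAP stimulus** — a 1.5 ms somatic pulse at the smallest multiple of
  0.5 nA (within 0.5–3.5 nA) that drives the soma above 0 mV.
* **A-type calibration** — Nelder-Mead simplex on the uniform
  somato-dendritic density, objective |bAP peak at the reference site −
  target| with target −10 mV, verified by re-simulation (tolerance 0.1 mV
  for headline runs, 0.25 mV inside ensemble loops). An unattainable target
  raises an error reporting the attainable peak bracket.
* **Synapse injection** — biexponential conductance (rise 0.3 ms, decay
  3 ms, 0.5 nS, reversal 0 mV, all configurable); reports local and somatic
  peak depolarization and flags triggered spikes.
* **Simulated dendrotomy** — branches near the high-complexity site are
  removed until the pair's input resistances agree within 2 %: first the
  subtrees immediately adjacent to the site (closest first, skipping cuts
  that would overshoot the partner's Rin), then a greedy pass over a 150 µm
  neighbourhood choosing the removal that best narrows the gap. The
  calibrated A-type density is retained for the cut morphology.

### The ensemble experiment and a known limitation

`pipeline.run_insilico` generates cells with an inclusion criterion
mirroring experimental pair selection (the reference, low-complexity site
must support a bAP above the −10 mV calibration target with A-type removed;
roughly 1 in 20 synthetic cells fails this), calibrates each cell, and
compares the two members of each distance-matched pair. Across 20 pairs the
higher-complexity member has lower input resistance, lower bAP peak and
lower peak calcium conductance in every pair.

Cutting, however, only partially nullifies the pair differences here: the
mean per-pair reduction is ≈ 0.73 for bAP-peak deltas and ≈ 0.48 for
peak-g_Ca deltas, short of a full (≥ 80 %) nullification. The reason is
instructive: in the steeply nonlinear propagation regime, a scalar passive
input resistance does not determine the active waveform. We observed matched
pairs whose post-cut Rin agreed to 1 % and Ω to 4 % yet whose bAP peaks
still differed by tens of mV, and pairs with equal post-cut peaks whose
local AP widths differed nearly three-fold — and the HVA activation gate
(τ ≈ 1–5 ms near threshold) integrates width as much as peak, so calcium
conductance deltas persist even when peaks match. Statistical
(population-level) equalization of cut pairs is a weaker statement than
per-pair delta nullification, and only the former should be expected from
Rin-matched cutting in this model family.

## Point gating model

A single voltage-clamped compartment carries a VGCC (activation m, squared;
inactivation h) and an NMDAR (unblocked fraction n under Mg²⁺ block):

* α_m = 0.055(−27−V)/(e^((−27−V)/3.8) − 1), β_m = 0.94 e^((−75−V)/17)
* α_h = 0.000457 e^((−13−V)/50), β_h = 0.0065/(e^((−V−15)/28) + 1)
* k_off = e^(0.017V + 0.96), k_on = [Mg²⁺]·e^(−0.045V − 6.97) (ms⁻¹, Mg in µM)

The removable singularity in α_m at −27 mV is evaluated by its analytic
limit (0.209 ms⁻¹). Gates integrate by forward Euler at dt = 0.01 ms from
their analytic steady state at the −70 mV holding potential. The inactivation
time constant exceeds ~170 ms everywhere in −80…+40 mV, so h is nearly
constant during millisecond stimuli (it is integrated anyway). Integrated
influx converges first-order in dt; at the standard dt the residual
discretization error is ≲ 0.2 % for NMDAR and reaches ~1 % for VGCC under
the strongest commands.

Calcium influx through an open channel uses the GHK current form with
[Ca]ᵢ = 75 nM and [Ca]ₒ = 1.5 mM; the V = 0 singularity is replaced by its
analytic limit (RT/2F)([Ca]ᵢ − [Ca]ₒ). Temperature defaults to 307.15 K
(34 °C bath), giving RT/2F ≈ 13.2 mV. Influx units are arbitrary (channel
permeability is absorbed into the open-probability scaling); sweep tables
also report influx normalized to each channel's maximum for cross-channel
comparison. Integrated influx is baseline-subtracted because NMDARs are
partially open at the holding potential.

The Mg²⁺ concentration is exposed in `GatingParams`; the default follows the
stated 1 µM, and the differential VGCC-vs-NMDAR drop-off below a −10 mV peak
holds at both 1 µM and 1 mM (the half-block voltage differs materially
between the two, so both are exercised in the tests).

Command waveforms are quadratic depolarizations step(t) = V_amp − (a·t)² with
a = 2√V_amp/V_dur, peaking at baseline + V_amp and returning to baseline at
±V_dur/2; default durations 1.0 and 0.5 ms.

## Trial quantification

* **ΔG/R** — trial-averaged change in the calcium-sensitive channel over its
  pre-stimulus baseline, divided by the structural-channel baseline.
  Baseline window: 50 ms before the stimulus (or all pre-stimulus samples if
  shorter). Amplitude: mean over a 10 ms window centered on the site's
  average peak time (taken from the recording's own trial average when no
  external peak time is supplied).
* **Amplification** — ΔCa_amp = ΔCa_pairing − (ΔCa_AP + ΔCa_uEPSP); exactly
  linear, negative values permitted.
* **Classification** — high if 0.1 < ΔCa_AP < 0.3, low if ΔCa_AP < 0.04
  (two-photon scale); one-photon amplitudes run smaller, so the bands are
  rescaled by the 1.75 sensitivity factor between modalities.
* **uEPSP** — trial average → baseline subtraction → 1 ms median filter
  (reflect padding) → maximum on (0, 25] ms after uncaging. A flat trace
  reports amplitude 0 with the peak time flagged as unreliable (NaN) rather
  than raising.
* **Loose patch** — per-trial mean over a ±0.1 ms window centered on the
  peak; trials ranked by SNR (|peak| / baseline SD) and the top half
  averaged; reported as sealed minus pre-seal estimate.
* **Conduction velocity** — per-site latency from the maximum of the
  derivative of the trial-averaged ΔG/R (central differences, no smoothing
  at 8 kHz sampling); velocity is the inverse slope of the latency-distance
  regression, with R², F and p reported and non-positive slopes flagged as
  unphysical.
* **STA ΔF/F₀** — spike-triggered-average movie → initial waveform from the
  brightest 5 % of pixels, normalized to unit peak above baseline →
  per-pixel regression against the waveform with a pixel-dependent offset
  (slope = ΔF map, offset = F map) → watershed segmentation of the ΔF map
  (basins of the inverted map, restricted to pixels above 10 % of the ΔF
  peak) → within the basin containing the ΔF peak, regress F on ΔF; ΔF/F₀
  is the inverse slope. A movie with no spike-locked structure (ΔF peak
  under 5× the median |ΔF|) raises rather than returning noise.
* **Statistics** — Mann–Whitney U (exact p for groups of ≤ 8, otherwise the
  tie-corrected normal approximation, with z reported), rank-sum, Welch-free
  two-sample t, Cohen's d with pooled SD, and regression records
  (slope/intercept/R²/F/p). No multiple-testing correction is applied; raw p
  values are reported.

## Synthetic data

The generators define the study conditions and emit their ground truth
alongside the data; all recovery tests read truth only from that channel.
Everything is bit-reproducible per seed (sub-seeds are spawned with
`numpy.random.SeedSequence`).

* **Morphologies** — a 12 µm soma cylinder with AIS and axon, a 50 µm apical
  trunk, then two daughter subtrees grown with exponential inter-branch
  segment lengths (base rate 1/80 µm⁻¹, orders capped at 8, depth ≈ 330 µm,
  1 µm dendrites, 3-D direction jitter). One subtree carries a branching
  hotspot (rate × 6 for 90 µm) starting just distal to a target site
  distance drawn from 100–160 µm — emulating recording sites immediately
  proximal to dendritic branch elaboration. Each cell emits one
  distance-matched site pair (≤ 10 µm soma-distance mismatch, well inside
  the 20 µm matching threshold) whose Ω values differ by ≥ 30 %; generation
  retries bounded times and fails loudly otherwise (a symmetric tree,
  elaboration 1, fails by construction). Across a 20-cell ensemble the Ω
  values span more than six-fold.
* **Fluorescence trials** — G(t) = baseline + amplitude × double-exponential
  kernel (rise 4 ms, decay 90 ms) × R-baseline, plus Gaussian noise and a
  signal-scaled term approximating shot noise; R(t) = constant + noise.
  500 Hz sampling (2 ms line-scan), 20 trials, stimulus at 150 ms. The noise
  scale is a stylistic match to single-trial line-scan data, not a
  quantitative one. Voltage trials carry a 0.5 mV EPSP (rise 2 ms, decay
  15 ms) and an AP command artifact 5 ms after the uncaging event for
  pairing protocols, at 20 kHz.
* **STA movies** — a dendrite-shaped mask with lognormal per-pixel
  brightness and spike-locked ΔF proportional to F (truth ΔF/F₀), a bright
  background blob with no spike-locked signal, and photon-like noise
  (SD ∝ √intensity).
* **Latency data** — distances uniform on 75–300 µm, latency = onset delay +
  distance/154.9 µm/ms + Gaussian jitter (SD 0.05 ms); the regression CI
  covers the true velocity in ≥ 90 % of seeds.

What passing these tests shows: the estimators are unbiased and within
stated tolerances under the generator's noise model, and the morphometric
and biophysical orderings hold under the generator's geometry. What they do
not show: robustness to motion, bleaching, dye saturation, non-Gaussian
noise, reconstruction errors, or morphologies outside the binary-branching
apical regime the generator produces.

## Problem sizes and numerical defaults

Ensemble runs use 20 cells, 10 µm compartments and dt = 0.02 ms
(≈ 600–900 compartments, ≈ 4 minutes for the full in-silico experiment on
one CPU); calibration-grade single-cell runs use dt = 0.01–0.02 ms.
The headline calibration reproduces its −10 mV target within 0.1 mV across
seeds. Gating sweeps use dt = 0.01 ms over V_amp = 0–110 mV in 5 mV steps
for durations 1.0 and 0.5 ms.
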