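# branchfield

Branch-specific back-propagating action potentials (bAPs) carry calcium into
some dendritic branches of cortical layer-2/3 pyramidal cells and not others.
`branchfield` is a Python package for studying how local dendritic branch
structure produces that compartmentalization. It provides:

* **Branch complexity Ω** — a distance-discounted morphometric of nearby
  dendritic length. With β(x) the number of dendritic branches at on-path
  distance x from a recording site (β starts at 2, +1 per branch point,
  −1 per terminal),

  Ω(λ) = ∫₀^∞ β(x) e^(−x/λ) dx

  evaluated in closed form per piecewise-constant interval. The default
  length constant λ = 145 µm is the spatial extent of a propagating bAP
  (conduction velocity 154.9 µm/ms × somatic AP width 0.94 ms ≈ 145.6 µm).
  Ω is inversely related to the local electrotonic input resistance.

* **A multicompartment cable simulator** — tree-structured backward-Euler
  integration with an O(N) Hines solve, Hodgkin–Huxley-style pluggable
  channels (Na, delayed-rectifier K, A-type K, M-type K, and high/low-voltage-
  activated Ca), the standard L2/3 passive parameters
  (Cm = 1 µF/cm², Rm = 7000 Ω·cm², Ri = 100 Ω·cm) and per-region channel
  density table, dendritic input resistance, Nelder-Mead calibration of the
  A-type density so the bAP peaks at −10 mV at a reference site, synaptic
  conductance injection, and simulated dendrotomy (cutting branches until the
  input resistances of a site pair match).

* **A single-compartment gating simulator** — voltage-gated calcium channel
  (open probability m²h) and NMDA receptor (Mg²⁺ block, open fraction n)
  kinetics under quadratic AP-like voltage commands, with
  Goldman–Hodgkin–Katz calcium influx ([Ca]ᵢ = 75 nM, [Ca]ₒ = 1.5 mM).

* **Trial quantification** — ΔG/R calcium-transient amplitudes, supralinear
  pairing amplification ΔCa_amp = ΔCa_pairing − (ΔCa_AP + ΔCa_uEPSP),
  high/low site classification, uncaging-EPSP metrics, loose-patch spike
  amplitudes, conduction-velocity regression, spike-triggered-average ΔF/F₀
  mapping (pixelwise regression + watershed), and the group statistics used
  to compare site populations (Mann–Whitney U with z, rank-sum, Cohen's d,
  regression diagnostics).

* **Synthetic data generators** — apical-tree morphologies with
  distance-matched site pairs of contrasting Ω, two-channel fluorescence and
  voltage trials, voltage-imaging movies, and latency datasets, all with
  ground truth emitted alongside the data and bit-reproducible per seed.

## Worked example

```python
from branchfield import cable, morphology, synth

cell = synth.gen_morphology(seed=0)          # synthetic apical tree + site pair
print(f"high-complexity site: {cell.omega_high:.0f} um "
      f"({cell.omega_high/1000:.2f} mm), "
      f"low: {cell.omega_low:.0f} um at lambda = 145 um")

model = cable.build_model(cell.morphology, channels=cable.reduced_channels())
for label, site in (("high", cell.site_high), ("low", cell.site_low)):
    rin = cable.input_resistance(model, site)
    print(f"{label}-complexity site: Rin = {rin:.1f} MOhm")

stim = cable.find_bap_stimulus(model)        # smallest suprathreshold pulse
hi = cable.replace_site_label(cell.site_high, "hi")
lo = cable.replace_site_label(cell.site_low, "lo")
density, peak, fitted = cable.fit_ka_density(model, lo, target_peak=-10.0,
                                             stim=stim, dt=0.02)
tr = cable.simulate_bap(fitted, [hi, lo], stim=stim, dt=0.02)
print(f"A-type density {density:.1f} pS/um^2 -> reference peak {peak:.2f} mV")
print(f"bAP peak  high-omega: {tr.v['hi'].max():.1f} mV, "
      f"low-omega: {tr.v['lo'].max():.1f} mV")
print(f"peak gCa  high-omega: {tr.g_ca['hi'].max():.3f}, "
      f"low-omega: {tr.g_ca['lo'].max():.3f} pS/um^2")
```

Output:

```
high-complexity site: 4002 um (4.00 mm), low: 2617 um at lambda = 145 um
high-complexity site: Rin = 60.3 MOhm
low-complexity site: Rin = 80.8 MOhm
A-type density 13.5 pS/um^2 -> reference peak -10.02 mV
bAP peak  high-omega: -18.3 mV, low-omega: -10.0 mV
peak gCa  high-omega: 0.045, low-omega: 0.278 pS/um^2
```

The higher-complexity site sits next to more dendritic membrane, so it has a
lower input resistance and the bAP attenuates more strongly on the way to it;
because the voltage-gated calcium channels activate steeply in this range, an
8 mV difference in bAP peak translates into a six-fold difference in peak
calcium conductance between two sites at the same distance from the soma.

The same experiments run from the shell:

```bash
branchfield synth --what morphology --seed 0 --out cell.swc
branchfield complexity --swc cell.swc --site 42:0.5 --lam 145 --sweep 5:400:8
branchfield gating-sweep --vamp 0:110:5 --vdur 1,0.5 --mg 1 --out sweep.csv
branchfield run pairs --seed 0 --n-cells 20 --out results/
```

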