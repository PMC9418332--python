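# porewave

Kinetics of the perforin-2 (PFN2/MPEG1) pre-pore → pore transition.

PFN2 assembles 16-subunit pre-pore rings on bacterial membranes that, upon
acidification, convert into membrane-piercing pores by a clockwise
hand-over-hand mechanism: rings break transiently (~1.8 s⁻¹), a breakage
occasionally (~0.2 s⁻¹ per ring) nucleates a conformational wave in which
each subunit first rises ~1.6 nm to a short-lived (~75 ms) intermediate
(pre-pore-II, the MACPF-domain flip) and then a further ~2.2 nm into the
pore state (TMH unfurling through the bilayer), both waves propagating
clockwise at ~13 s⁻¹ and ~15 s⁻¹ so a full ring completes in ~1.3 s.
Observed pore arcs peak at 12 of 16 subunits.

`porewave` implements, as a tested library + CLI, the quantitative
machinery behind those numbers, for single-molecule biophysicists who want
to simulate, re-analyze, or benchmark this class of HS-AFM experiments:

* **Run-length model** (`porewave.runlength`) — a Zimm–Bragg-style
  nucleation–propagation law for pore-arc lengths on a ring,

  $$Z = 1 + \sum_{n=1}^{N} \frac{N\,\sigma\, s^{n}}{1 + e^{\,n-n_0}},\qquad
    p(n) = \frac{N\,\sigma\,s^{n}}{(1+e^{\,n-n_0})\,Z},\qquad p(0)=\tfrac1Z,$$

  with nucleation probability σ, propagation Boltzmann factor
  $s = e^{-\Delta E/kT}$ (per-step coupling probability $p_c = s/(1+s)$),
  and a logistic long-run penalty of characteristic length $n_0$.
  Evaluation, sampling, and maximum-likelihood fitting (σ cancels in the
  conditional arc-length law).
* **Ring kinetic Monte Carlo** (`porewave.kmc`) — exact stochastic
  simulation of breakage/re-closure, nucleation, the clockwise
  Exp($k_{12}$) pre-pore-I→II wave and Exp($k_{23}$) II→pore conversions
  (optionally neighbour-gated), producing event trajectories.
* **Synthetic HS-AFM data** (`porewave.synthetic`) — renders trajectories
  into topography movies (hexagonally packed rings, 200 ms frames,
  one-frame breakage openings, Gaussian height noise) and 2 ms line-scan
  kymographs (plateaus joined by finite-speed ramps), always with ground
  truth.
* **Movie analysis** (`porewave.movie`) — ring unbending into 16 angular
  sectors, three-state height thresholding (0.8 / 2.7 nm above the
  pre-pore-I baseline), breakage-opening counting, clockwise
  directionality scoring, interval-censored (frame-quantized) exponential
  rate estimation, arc lengths, transition times, height distributions.
* **Kymograph analysis** (`porewave.kymo`) — plateau/ramp segmentation of
  single-subunit traces, step heights and ramp speeds, and left-truncated
  exponential fitting of the pre-pore-II dwell.

## Worked example

Simulate 300 rings for 30 s at the measured kinetic preset, quantize to
200 ms frames, and recover the kinetics with the analysis estimators:

```python
import numpy as np
import porewave as pw

rates = pw.measured_rates()          # k_open 1.8/s, initiation 0.2/s,
trajs = pw.simulate_ensemble(rates, 300, 30.0, seed=11)   # k12 13, k23 15

surv = pw.initiation_survival(trajs)
print(f"initiation lifetime: {surv.tau:.2f} s  (n = {surv.n_events} rings)")

arcs = pw.arc_length_distribution(trajs)
fit = pw.fit_run_lengths(arcs)
print(f"arc-length fit: s = {fit.params.s:.2f}  n0 = {fit.params.n0:.1f}  "
      f"mode = {pw.pmf_mode(fit.params)} subunits")

states = [pw.trajectory_to_state_matrix(t, 150, 0.2) for t in trajs]
k12, k23 = pw.estimate_propagation_rates(states)
print(f"propagation rates: k12 = {k12.rate:.1f} /s   k23 = {k23.rate:.1f} /s")
```

prints

```
initiation lifetime: 5.27 s  (n = 300 rings)
arc-length fit: s = 1.82  n0 = 11.9  mode = 12 subunits
propagation rates: k12 = 12.7 /s   k23 = 14.8 /s
```

i.e. the censored survival fit recovers the ~5 s pre-pore lifetime, the
fitted run-length model peaks at 12 subunits (coupling
$p_c = s/(1+s) \approx 0.64$), and the frame-quantized MLE recovers the
two propagation rates from 200 ms sampling even though the true ~77 ms
and ~67 ms waits are mostly censored inside a single frame.

The CLI exposes the same steps: `porewave simulate`, `porewave
synth-movie`, `porewave synth-kymo`, `porewave analyze-movie`, `porewave
analyze-kymo`, `porewave fit-runlength`, and `porewave run` (end-to-end
seeded pipeline emitting a JSON report).

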