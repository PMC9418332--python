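# Methods

This note documents the models implemented in `porewave`, the defaults and
why they were chosen, the estimator designs, and what the synthetic-data
round trips do and do not demonstrate.

## The kinetic scheme

A 16-subunit pre-pore ring under acidic conditions is modelled as:

1. **Breakage/re-closure.** Inter-subunit breakages arrive as a Poisson
   process at `k_open` (default 1.8 s⁻¹, the measured opening rate) on a
   uniformly random bond, and re-close after an Exp(`k_close`) dwell.
   Only a lower bound (≫5 s⁻¹) on re-closure is observable — openings
   never persist beyond one 200 ms frame — so `k_close` defaults to
   10 s⁻¹; it affects only detectability, not kinetics.
2. **Nucleation.** Each breakage independently initiates the transition
   with probability `q_nucleate`. The default 0.2/1.8 ≈ 0.111 makes
   `k_open · q` reproduce the measured 0.2 s⁻¹ per-ring initiation rate;
   the data constrain the two rates but not their mechanistic coupling,
   so the Bernoulli-per-breakage form is the simplest consistent choice.
3. **Clockwise wave.** The subunit clockwise of the broken bond starts a
   run of n\* consecutive pre-pore-I → pre-pore-II conversions with i.i.d.
   Exp(`k12`) waiting times (`k12` = 13 s⁻¹). Each subunit then converts
   II → pore after an Exp(`k23`) dwell (`k23` = 15 s⁻¹), by default
   independently of its neighbours ("ungated"). The gated variant (pore
   conversion additionally waits for the counter-clockwise neighbour's
   pore state) is provided; it provably inflates full-ring completion
   beyond the observed ~1.3 s at these rates, which is why ungated is the
   default — the observed completion time is consistent with the additive
   16/k₁₂ + 1/k₂₃ picture.
4. **Run length.** n\* is drawn up front from the run-length model
   (below) conditioned on a run occurring. This reproduces the observed
   arc-length law by construction; a step-wise Bernoulli alternative
   would entangle the arc-length and timing laws without observational
   support.

All post-nucleation steps are irreversible (pores never revert), and the
simulator stops the breakage process at nucleation: the ring is no longer
an intact pre-pore. Completion time is measured from nucleation to the
last pore conversion, i.e. it includes all 16 Exp(k₁₂) stages of a
full-ring run; its mean is ≈ 16/13 + 1/15 ≈ 1.3 s.

Subunit indices 0–15 increase clockwise viewed from above the membrane;
bond *b* joins subunits *b* and *b+1* (mod 16), and the first
transitioning subunit of a run is *b+1*.

## Run-length model

The probability of a pore run of length n on an N-ring is
`p(n) = N σ sⁿ / ((1+e^(n−n0)) Z)` with `Z = 1 + Σ w(n)` and `p(0) = 1/Z`:
σ is the (small) nucleation probability, `s = exp(−ΔE/kT)` the
propagation factor, and the logistic term an agnostic penalty for long
runs (strain, membrane mechanics) with characteristic length `n0`. ΔE is
represented only through s. With `n0 = 11.9` and per-step coupling
probability 0.64 the discrete mode of p(n) is 12 subunits.

Two deliberately separated quantities: `pmf_mode` is the discrete argmax
of p(n) (ties → smaller n); `continuous_argmax` is the real-n maximizer
of the weight function. The fitted `n0` is a third number; the three are
reported separately and never conflated.

**Coupling ↔ s mapping.** The reported per-step coupling ~0.64 cannot be
s itself (s > 1 since ΔE < 0). We use the unique monotone two-state
Boltzmann (odds) mapping `s = p_c/(1−p_c)`, so 0.64 ↔ s ≈ 1.78, which is
consistent with both statements.

**Fitting.** σ cancels in the conditional law p(n | n ≥ 1) — arcs are only
observed when a run occurred — so the MLE fits (s, n0) on the conditional
pmf (Nelder–Mead on (log s, log n0), three starts, convergence flagged).
σ is estimated separately from the fraction f of rings with a run via
`1 − 1/Z = f` when total ring counts are supplied, otherwise reported as
undetermined. Numerics: sⁿ and the penalty are evaluated in log space
(`logaddexp`), and "no penalty" is `n0 = None` handled analytically, so
no overflow at large n0 or s. Parameter recovery from 5000 draws:
s within ±10%, n0 within ±0.8 subunits in ≥19/20 seeded replicates.

## Synthetic HS-AFM data

The generator's defaults are the study conditions: pre-pore-I top height
8.1 nm above a 0 nm membrane baseline, steps of 1.6 nm (I→II) and 2.2 nm
(II→pore) — total rise 3.8 nm — ramp speeds 47.3 and 48 nm/s, 200 ms
frames, 2 ms kymograph lines, additive i.i.d. Gaussian height noise of
0.3 nm per pixel. Ring radius (10 nm), annulus width (4 nm) and pixel
size (1 nm) are geometry choices — the recordings print heights, not
lateral ring dimensions — and are exposed in the configuration.

Movies: each ring is an annulus of 16 equal 22.5° sectors whose height is
its subunit's state level sampled at the frame midpoint. A breakage drops
the two sectors flanking the broken bond to the membrane level in exactly
the frame containing the opening (breakage dwells are sub-frame). Sector
indexing is clockwise with the image displayed row-0-at-top; renderer and
analyzer share one convention (and one sector-geometry routine — the
round-trip tests therefore validate state logic and noise robustness, not
an independent geometric registration). Ramps are not visible at 200 ms
framing and are rendered as instantaneous level changes in movies.

Kymographs: a single-subunit trace holds plateaus at the three state
levels joined by linear ramps of duration Δh/v (≈34 ms and ≈46 ms); the
pre-pore-II *dwell* is the flat plateau duration between ramp end and
next ramp start. Ensemble generation jitters per-trace step heights and
speeds at the observed spreads (±0.4, ±0.2 nm; ±5, ±7 nm/s) and draws
dwells from Exp(75 ms).

Not emulated: tip convolution (an optional spherical-cap dilation exists
but is off — no tip radius is available), scanner/feedback artifacts,
drift, parachuting, inter-ring interactions, merging of two breakage
waves, and mica (non-membrane) scenes. Passing round trips therefore
demonstrate estimator correctness under the stated noise model, not
robustness to instrument artifacts.

## Movie analysis

**Unbending and baseline.** Annulus pixels are partitioned into the 16
sectors and averaged per frame (~20 px/sector, so sector noise is
~0.07 nm at σ = 0.3). The pre-pore-I baseline is the median sector height
of the first frame(s); recordings are assumed to start pre-transition.

**State assignment.** Relative to baseline: < −4 nm → OPEN (the "visual
discontinuity" depth is not numerically defined in the source data; 4 nm
is unambiguous at the stated noise), < 0.8 nm → pre-pore-I, < 2.7 nm →
pre-pore-II, ≥ 2.7 nm → pore. The thresholds sit at the ramp midpoints
of the two steps (0.8 = 1.6/2; 2.7 = 1.6 + 2.2/2). An optional temporal
median filter exists but is off by default: it would erase one-frame
breakage openings and sub-frame pre-pore-II passages, and sector
averaging already suppresses pixel noise far below the thresholds.

**Opening rate.** Openings are counted per pre-transition ring-frame as
visible discontinuities: an OPEN run of L contiguous sectors counts as
L−1 broken bonds (one bond drops two sectors; this makes same-frame
adjacent-bond coincidences count correctly, and residual distance-2
overcounts cancel same-bond repeats in expectation). A ring whose
transition initiates during the recording contributes one further
opening — initiations occur at breakage sites, so the nucleating opening
belongs to the same breakage process even though it never re-closes.
Counting stops at the first pre-pore-II frame; the denominator is total
pre-transition ring-time. The estimate carries a small (−2%) downward
bias from the initiation lag (nucleation to first visible pre-pore-II)
included in the denominator.

**Propagation rates (interval censoring).** At 200 ms framing the ~77 ms
I→II waits and ~67 ms II→pore dwells are usually censored inside a single
frame. Waits are therefore reduced to frame-index differences d (I→II of
subunit i measured from subunit i−1's entry — wave-relative, so the
initiation delay does not enter; II→pore from the subunit's own entry)
and fitted with the exact MLE of the quantization model: with
q = e^(−λΔ) and the reference event's phase uniform in the frame,
P(d=0) = 1 − (1−q)/(λΔ) and P(d=k) = (1−q)² q^(k−1)/(λΔ). This estimator
converges to the naive 1/mean estimator as Δ → 0, and errors explicitly
when every wait is censored into one frame (rate unresolvable at that
framing). Waves initiating within a guard window (3 s) of the movie end
are skipped to avoid edge censoring. Recovery at the defaults is within
a few percent with ≥500 pooled events (tolerance ±20%).

**Directionality.** Each circular neighbour pair (i, i+1) in which both
subunits transitioned contributes sign(entry(i+1) − entry(i)); same-frame
ties are skipped (within-frame order is unobservable at this framing),
and for full-ring runs the single wave seam (largest entry gap) is
excluded. A clockwise wave scores exactly +1, its mirror −1, and shuffled
entry orders concentrate near 0.

**Heights.** Per-assembly top height is the mean of the 16 sector means
lying within 0.5 nm of the highest sector. Sector averaging makes this
noise-averaging; a raw upper-decile pixel statistic would carry an
order-statistic bias of ≈ +0.5 nm at σ = 0.3.

**Transition/survival times** use the frame-midpoint convention; survival
fits use the closed-form right-censored exponential MLE
(τ̂ = total time / events, exact χ² CI).

## Kymograph segmentation

Two passes over each trace (≥50 lines required):

1. **Coarse banding.** 5-line median filter; baseline = median of the
   first 25 filtered lines (traces must start in pre-pore-I, which the
   generator guarantees with a ≥120 ms initial plateau); hysteretic
   (±0.2 nm) classification into the three bands; runs shorter than
   3 lines absorbed (noise chatter); non-monotone band sequences are
   flagged, not repaired.
2. **Refinement.** For each band boundary, the transition midpoint is the
   crossing of the mean of the two adjacent plateau levels, and the ramp
   is fit by least squares to a clipped-linear profile (plateau levels
   fixed, midpoint and slope free) on the raw samples around the
   boundary. The ramp extent is Δh/v centred on the midpoint, and plateau
   levels are re-estimated from the raw samples strictly between ramps
   (second iteration), so in-band ramp samples cannot contaminate short
   plateaus. Because the band thresholds are ramp midpoints, the
   inter-ramp plateau duration equals the true flat dwell with no
   half-ramp offset.

Segments tile [0, duration] exactly. The minimum resolvable plateau is
10 ms (5 lines). Step heights are adjacent plateau-level differences and
speeds the fitted slopes, grouped I→II vs II→pore.

**Pre-pore-II lifetime.** Dwells are plateau durations; edge-truncated
plateaus are excluded. Detection near the 10 ms floor is soft (on 2000
synthetic traces, acceptance rises from ~0.64 just above the floor to a
~0.96 plateau by ~20 ms), so the left-truncated exponential fit
truncates at twice the plateau floor, where acceptance has levelled off:
τ̂ = mean(d − 20 ms | d ≥ 20 ms), unbiased within ~0.5% on the same
synthetic set, with exponential memorylessness supplying the truncation
correction. Constant injected dwells are reported as their mean with the
MLE flagged degenerate.

Per-trace step-height jitter at the observed spreads induces a small
selection bias in recovered mean steps (traces whose first step falls
below the 0.8 nm band threshold are unresolvable), ≈ +0.05 nm on the
I→II step; noise-free traces recover all generator values exactly.

## Problem sizes and reproducibility

The shipped analyses use desk-scale ensembles — 2000–3000 replicates for
completion times, 500 rings for survival, ~50 ring-minutes of rendered
movie for opening rates, 150–300 rings for propagation rates, 500
kymograph traces for dwell and step statistics — sizes at which every
estimator's sampling error is comfortably inside its stated tolerance.
Every stochastic routine takes a seed (or NumPy `SeedSequence`); the
pipeline expands one global seed into per-stage substreams, and reruns
with the same configuration are bit-identical.

## Known limitations

* Arc lengths are capped at 16; arcs longer than one ring (observable
  when two waves merge) are out of scope.
* The σ estimate requires total ring counts and assumes every run is
  detected.
* The opening-rate estimator assumes breakage dwells shorter than one
  frame (as observed); longer dwells would double-count.
* Kymograph segmentation assumes a monotone I→II→pore trace with ≥120 ms
  of initial pre-pore-I; other schedules are segmented but flagged.
* The ring-center detector for layout-free input is intentionally simple;
  synthetic work supplies centers from the layout.
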