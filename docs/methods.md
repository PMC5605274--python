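# Methods

## The dynamical network model

Two V4 units (each preferring one of the two shapes used in a session) and
two vlPFC units are coupled by delayed feedforward and feedback connections.
Rates obey

    tau_V4  dr_V4,i /dt = -r_V4,i  + F(U_V4,i  - r_thr,V4)  + eta
    tau_PFC dr_PFC,i/dt = -r_PFC,i + fbar(c) * F(U_PFC,i - r_thr,PFC) + eta

with the Naka–Rushton nonlinearity `F(x) = f_max x^N / (sigma^N + x^N)` for
`x >= 0` (0 otherwise). Fixed parameters: `tau_V4 = 50 ms`,
`tau_PFC = 20 ms`, `r_thr,V4 = 20`, `r_thr,PFC = 0`, `sigma = 90`, `N = 2`,
`f_max = 100`, feedback threshold `r_thr1 = 30 sp/s`, adaptation trigger
`r_thr2 = 10 sp/s`, adaptation time constant `tau_a = 30 ms`. Connection
parameters (reference values): delays `tau_d,ff = tau_d,fb = 40 ms`, weights
`w_sff = 0.5`, `w_wff = 0.2`, `w_sfb = 1.3`, and
`w_wfb = w_sfb * w_wff / w_sff` unless overridden, so feedback mirrors the
feedforward asymmetry.

**Feedforward drive.** `uFF_i = [(k * R_i)^3 / max(k * R_i)^2]_+` where
`R_1(c,t) = (2.5c + 20) - 0.05t` (preferred shape) and
`R_2(c,t) = (12 c^(1/3) + 120) - 0.05t` (nonpreferred) on a 30–530 ms
support, and `k` is a difference of Gaussians
(`15 exp(-(t-30)^2/800) - 10 exp(-(t-50)^2/800)`) sampled causally on
[0, 120] ms. The cube-and-renormalize step sharpens the transient while
keeping the drive's peak equal to the peak of the convolution.

**Kernel normalization.** The kernel is normalized to **unit integral** by
default. This choice is load-bearing: the drive's absolute scale passes
through the fixed semi-saturation `sigma = 90`, and a unit-area kernel keeps
`max(k * R)` on the ramp's own scale (~440 input units at c = 100 vs ~270
at c = 59), which yields graded, occlusion-dependent V4 responses. A
unit-peak kernel would scale the drive by the kernel's ~28 ms-unit area and
saturate `F` at every occlusion level, flattening the first transient's
occlusion tuning. `kernel_norm` also accepts `"peak"` and `"none"` for
sensitivity analyses.

**Feedback and adaptation.** Feedback is thresholded and rectified:
`u_PFC(j)i = w_fb(j,i) [r_PFC,j(t - tau_d,fb) - r_thr1]_+`; the threshold
keeps the non-preferred V4 unit's second peak small. Feedforward input to
vlPFC passes through weights obeying `dw/dt = (w_inf - w)/tau_a`, with
`w_inf` latched to 0 for the rest of the trial as soon as the receiving
unit's rate reaches `r_thr2` (both incoming weights of that unit adapt).
The latch is what terminates the loop: without it, positive feedback
reverberates and the rates blow up (this is the expected phenotype of the
`no_adaptation` ablation, flagged by the `diverged` attribute when any rate
exceeds `10 * f_max`).

**Gain.** `fbar(c) = -0.0017 c^3 + 0.39 c^2 - 29.6 c + 806`. Its value at
c = 100 (unoccluded), 46.0, is the global minimum on (0, 100]; occluded
stimuli receive larger gain, which is the mechanism behind the vlPFC
preference for occlusion. Note the cubic is *not* globally monotone — its
derivative is positive on roughly c in (70, 83) (e.g. fbar(72) = 62.1 <
fbar(82) = 63.9). Nothing in the model depends on strict monotonicity, only
on the unoccluded minimum. `gain_delay` applies the occlusion-dependent
value from a configurable time (unoccluded baseline gain before it),
supporting robustness checks of delayed gain arrival; verdicts are stable
for delays up to at least 50 ms.

**Integration.** Forward Euler at `dt = 0.01 ms` (configurable; a guard
rejects `dt > min(tau)/10`). Rates start at 0 with zero delay history,
weights at their steady-state values; rates are clamped at 0 after each
step. Halving dt changes the reference trajectories by < 0.1 sp/s, and with
constant input each uncoupled unit converges to the closed-form fixed point
`F(U0 - r_thr)`. The noise term `eta` is Gaussian with sd `300 * dt` added
to the right-hand side of the rate equations as printed above (i.e. inside
the `1/tau` factor); it is off by default and in all tests, since
trial-to-trial variability is modeled downstream by Poisson sampling.

## Synthetic sessions

The generator emulates the trial structure of the occluded-shape
discrimination experiments: per neuron, 2 shapes x 4–9 occlusion levels
drawn from {100, 99, 95, 90, 82, 72, 59, 45, 27}% visible area (100% always
included; 6 levels for V4 and 5 for vlPFC by default), >= 7 repeats per
condition (15 by default), spike times on a -300 to +700 ms window around
test-stimulus onset, with alternating match/nonmatch labels.

Three rate-profile classes: `v4_single` (early transient + decaying
sustained response, all of it shrinking with occlusion), `v4_double` (adds
a second transient whose amplitude follows an inverted U in % visible area,
centered at 78% with 16% width), and `vlpfc_occlusion` (single broad
transient growing with occlusion, near-baseline when unoccluded). Defaults
place the V4 first/second transients at 84/214 ms and the vlPFC peak at
157 ms; populations jitter peak times (sd 4/8 ms) and amplitudes (±15%)
across neurons. A separate `pref_ratio_second` lets shape preference
concentrate in the second transient, reproducing late-emerging shape
selectivity under occlusion.

Trials are independent inhomogeneous Poisson processes sampled by thinning.
This is an assumption, not a measured property: real spike trains carry
refractoriness, burstiness and slow excitability drifts that Poisson
sampling omits, so passing tests certify the *pipeline* (estimators,
screens, classifier) under known ground truth, not the trial-noise model of
real recordings. The pre-stimulus window runs at the template baseline and
stands in for the pre-reference fixation epoch, giving the responsiveness
screen a proper null epoch. `rates_from_model` / `session_from_model`
bridge the simulator to the sampler, flooring rates at 2 sp/s so sampling
is non-degenerate.

## Analysis conventions

All times are ms relative to test-stimulus onset; every count window is
closed on the left, open on the right. PSTHs use 1 ms bins smoothed with a
Gaussian of sigma = 10 ms with zero padding, so the integral of the
smoothed rate preserves the mean spike count.

- **Responsiveness screen:** paired t-test (two-sample optional) of
  per-trial rates, 150 ms window starting 80 ms after test onset vs the
  fixation epoch; significance at p < 0.01. Degenerate zero-variance input
  reports p = 1.
- **Factorial screen:** two-way fixed-effects ANOVA with interaction on
  response-window counts (shape x occlusion, or shape x match/nonmatch),
  via statsmodels; empty cells raise an error naming the cell.
- **Preferred shape:** largest mean response across all levels (V4) or
  across occluded levels only (vlPFC, whose neurons often ignore unoccluded
  stimuli); exact ties break to shape 1 with a warning.
- **Shape selectivity:** sliding-window ROC area between preferred and
  nonpreferred spike-count distributions at 1 ms steps, centered windows of
  75 ms (V4) or 150 ms (vlPFC), per level or pooled across occluded levels.
  The ROC area equals the Mann–Whitney statistic P(X>Y) + 0.5 P(X=Y) and is
  reported as-is (no folding around 0.5, which would bias null timecourses
  upward).
- **Peak latency:** argmax of the across-level average smoothed PSTH
  restricted to 50–600 ms (excludes reference-stimulus and saccade-related
  activity); flat profiles return the earliest time with a warning.
- **Occlusion slope:** OLS of per-level mean responses (normalized to the
  maximum level) on % visible area; a per-trial variant is available.
- **Windowed measures:** 30 ms peak-centered responses relative to a
  -115 to -85 ms baseline, and the late-minus-early (199–229 vs 69–99 ms)
  difference of PSTHs normalized by each neuron's maximum over time and
  levels.

## Two-peak classification

1. **Inclusion:** average the preferred-shape smoothed PSTHs over occlusion
   levels whose response reaches >= 33% of the unoccluded maximum (none →
   the neuron is unclassifiable, reported as an explicit error).
2. **Candidates:** local maxima of the averaged PSTH within 300 ms of
   onset, found by sign changes of the first difference on the 1 ms grid
   (plateaus break to the earliest sample); each is paired with the PSTH
   minimum between the previous peak (or onset) and itself.
3. **Rejection:** the *first transient* is the earliest candidate reaching
   >= 50% of the tallest candidate — anchoring on the literally earliest
   zero crossing would let pre-response baseline ripples anchor the height
   rule and inflate false positives. Later candidates are rejected if
   below 50% of the first transient's height or below a 15% trough-to-peak
   modulation ratio ((peak - trough)/peak, computed against the local
   peak).
4. **Significance:** surviving candidates beyond the first transient need a
   paired t-test of single-trial spike counts (30 ms windows at peak vs
   preceding trough, trials pooled over included levels) with p below 0.05
   Bonferroni-corrected across the tested candidates, and a positive mean
   count increase. If several qualify, the largest is reported as the
   second peak.

All thresholds live in `PeakFinderConfig`. Operating characteristics under
the default synthetic conditions (15 trials/condition): false-positive rate
3% on 100 single-transient neurons; detection 98% on two-peak templates
whose inclusion-average second peak is >= 60% of the first with >= 30%
modulation; median peak-time error < 3 ms.

## Population summaries

Per-neuron responses are normalized to each neuron's maximum across levels
(or across time x levels for the fixed-window difference) before averaging.
Occlusion curves report contributing-n and drop levels sampled by fewer
than 5 neurons (the cutoff is configurable; sessions sample level subsets,
so rare levels otherwise produce unstable averages). The proportion test is
the exact two-sided binomial test with the point-probability convention
(sum of outcomes no more likely than the observed one), which is what
`scipy.stats.binomtest` computes.

## Problem sizes and calibration

The test suite exercises the pipeline at 100-neuron populations with 15
trials per condition (the classifier's operating point), 60-neuron
detection panels, and 1000–2000-replicate null simulations for screen
calibration; the responsiveness and ANOVA screens hold their nominal
type-I error within a factor of two at alpha = 0.01 and 0.05 respectively.
Model-level checks run at the reference dt = 0.01 ms; most unit tests use
dt = 0.05 ms, which matches the reference trajectories to < 0.1 sp/s.

## Known limitations

- Rate-based model only; no spiking dynamics, and no fitting of model
  parameters to recorded data.
- The Poisson trial-noise assumption (above) is the main gap between
  synthetic and recorded sessions.
- The gain cubic's local non-monotonicity (c in ~(70, 83)) is a property of
  the printed coefficients; analyses relying on a strictly monotone gain
  should supply their own `gain_coeffs`.
- The model-based (linear-scaling) alternative to the two-peak algorithm
  and choice-probability analyses are out of scope.
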