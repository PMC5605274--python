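# v4pfc

Primate recognition of partially occluded shapes engages a loop between
mid-level visual cortex (area V4) and ventrolateral prefrontal cortex
(vlPFC). Under occlusion, many V4 neurons respond with **two transient
peaks**: an early, stimulus-driven peak whose amplitude falls as occlusion
increases, and a later peak — attributed to vlPFC feedback — that is largest
at intermediate occlusion levels. vlPFC neurons show the complementary
profile: weak responses to unoccluded shapes, stronger responses under
occlusion.

`v4pfc` packages, for computational and systems neuroscientists:

1. a **two-layer dynamical firing-rate model** of this circuit (2 V4 units +
   2 vlPFC units with delayed feedforward/feedback coupling, synaptic
   adaptation, feedback rectification, and occlusion-dependent gain), with
   mechanism ablations and parameter sweeps;
2. a **synthetic spike-train generator** producing trial-structured sessions
   with V4-like and vlPFC-like response statistics (inhomogeneous Poisson);
3. the **spike-train analysis pipeline** used on such data: Gaussian-smoothed
   PSTHs, responsiveness and two-factor ANOVA screens, sliding-window ROC
   shape selectivity, occlusion-slope regression, peak latency, the
   two-transient-peak classification algorithm, and population summaries.

## The model

Each unit's rate follows a thresholded Naka–Rushton firing-rate equation,
integrated by forward Euler (dt = 0.01 ms):

    tau_V4  dr_V4,i /dt = -r_V4,i  + F(U_V4,i  - r_thr,V4)  + eta
    tau_PFC dr_PFC,i/dt = -r_PFC,i + fbar_PFC(c) * F(U_PFC,i - r_thr,PFC) + eta

    F(x) = f_max * x^N / (sigma^N + x^N)  for x >= 0, else 0

V4 unit *i* receives a transient feedforward drive `uFF_i` — an occlusion-
scaled ramp convolved with a difference-of-Gaussians kernel, cubed,
renormalized and rectified — plus delayed, thresholded feedback
`w_fb * [r_PFC,j(t - tau_d,fb) - r_thr1]_+`. vlPFC unit *i* receives delayed
feedforward input `w_ff * r_V4,j(t - tau_d,ff)` through weights that adapt
to zero (time constant `tau_a`) once the unit's own rate crosses `r_thr2`,
preventing runaway reverberation. The multiplicative gain `fbar_PFC(c)`, a
cubic in % visible area `c`, is smallest for the unoccluded stimulus and
confers the vlPFC preference for occluded shapes.

The reference parameter set ships as a packaged YAML config
(`v4pfc/_config/defaults.yaml`).

## Worked example

```python
import numpy as np
import v4pfc as v

params = v.default_params()
traj = v.simulate_trial(params, v.StimulusCondition(shape_id=1, c=82.0))

peaks = v.rate_profile_peaks(traj.time, traj.r_v4[0],
                             v.PeakFinderConfig(smoothing_sigma=0.0))
print([f"{p.peak_time:.0f} ms ({p.peak_height:.1f} sp/s)" for p in peaks])
print(f"vlPFC peak: {traj.time[np.argmax(traj.r_pfc[0])]:.0f} ms")

# Poisson-sample a spiking session from the model and classify it
session = v.session_from_model(params, [100.0, 90.0, 82.0, 72.0, 59.0],
                               n_trials=15, seed=5)
cls = v.classify_two_peak(session)
print(cls.verdict, cls.first_peak_time, cls.second_peak_time)
```

prints

```
['110 ms (53.5 sp/s)', '203 ms (61.9 sp/s)']
vlPFC peak: 138 ms
two_peak 111.5 208.5
```

i.e. the preferred-shape V4 unit at 82% visible area produces two transient
peaks that straddle the vlPFC peak, and 15 Poisson trials per condition
suffice for the classifier to recover the two-peak verdict with both peak
times. Ablating the feedback (`v.ablate(params, "no_feedback")`) leaves a
single peak.

On synthetic populations the full pipeline recovers the generating mixture:

```python
spec = v.PopulationSpec(n_neurons=100, seed=11)   # 35% two-peak profiles
k = sum(v.classify_two_peak(v.generate_session(spec, i)).is_two_peak
        for i in range(100))
```

gives 33/100 two-peak verdicts (true mixture 35%), with median detected
first/second peak times 86.5 / 216.5 ms against generator defaults of
84 / 214 ms, and an exact binomial test against a fair-coin proportion of
p = 8.7e-4.

The same workflows are scriptable from the shell:

```
v4pfc generate --neurons 100 --seed 11 --out sessions/
v4pfc analyze  --sessions sessions/ --out analysis/
v4pfc report   --sessions sessions/ --analysis analysis/ --out report/
v4pfc simulate --out traj/ --levels 100,82 --ablate no_feedback
v4pfc sweep    --out sweep/ --tau-d-fb 20,40,80
```

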