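"""Synthetic spike-train sessions with V4- and vlPFC-like response structure.

Three parametric rate-profile classes emulate the response types seen in the
occluded-shape discrimination experiments:

``v4_single``
    one early transient riding on a decaying sustained response; the whole
    evoked response shrinks with occlusion.
``v4_double``
    adds a second, later transient whose amplitude is largest at
    intermediate occlusion levels (the feedback signature).
``vlpfc_occlusion``
    a single broad transient that is near-absent for the unoccluded
    stimulus and grows with occlusion.

Trial-to-trial variability is inhomogeneous Poisson (sampled by thinning);
the pre-stimulus window runs at the template baseline so responsiveness
screens have a proper null epoch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .model import simulate_trial
from .params import OCCLUSION_LEVELS, NetworkParams, StimulusCondition
from .session import DEFAULT_WINDOW, SessionData, SpikeTrainSet, Trial

PROFILE_CLASSES = ("v4_single", "v4_double", "vlpfc_occlusion")


@dataclass
class RateTemplate:
    """Parametric firing-rate profile for one synthetic neuron.

    Times in ms relative to test-stimulus onset, rates in spikes/s, widths
    are Gaussian sigmas.  Occlusion tuning is controlled per response
    component: the first transient scales with ``(c/100)**first_pow``
    (floored), the second transient follows a Gaussian in % visible area
    centered at ``second_center``, and the vlPFC profile scales with a power
    of the occluded fraction.
    """

    profile: str = "v4_double"
    baseline: float = 10.0
    peak1_time: float = 84.0
    peak1_amp: float = 70.0
    peak1_width: float = 12.0
    peak2_time: float | None = 214.0
    peak2_amp: float = 50.0
    peak2_width: float = 14.0
    sustained_frac: float = 0.30   # sustained plateau, fraction of peak1_amp
    sustained_tau: float = 500.0   # plateau decay time constant
    pref_ratio: float = 2.0        # preferred / nonpreferred amplitude ratio
    # separate preference ratio for the second transient (None: use
    # pref_ratio); > pref_ratio concentrates shape selectivity late
    pref_ratio_second: float | None = None
    # occlusion-tuning parameters
    first_floor: float = 0.35
    first_pow: float = 1.5
    second_center: float = 78.0
    second_width: float = 16.0
    vlpfc_pow: float = 0.4
    match_gain: float = 1.0        # rate multiplier on match trials

    def __post_init__(self) -> None:
        if self.profile not in PROFILE_CLASSES:
            raise ValueError(f"unknown profile {self.profile!r}")
        for name in ("baseline", "peak1_amp", "peak2_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.profile == "v4_double":
            if self.peak2_time is None or self.peak2_time <= self.peak1_time:
                raise ValueError("v4_double requires peak2_time > peak1_time")

    # -- occlusion tuning rules -----------------------------------------
    def first_tuning(self, c: float) -> float:
        return self.first_floor + (1.0 - self.first_floor) * (c / 100.0) ** self.first_pow

    def second_tuning(self, c: float) -> float:
        return float(
            np.exp(-((c - self.second_center) ** 2) / (2.0 * self.second_width**2))
        )

    def vlpfc_tuning(self, c: float) -> float:
        occluded = max(100.0 - c, 0.0) / (100.0 - min(OCCLUSION_LEVELS))
        return occluded**self.vlpfc_pow


def _bump(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    return np.exp(-((t - t0) ** 2) / (2.0 * width**2))


def _plateau(t: np.ndarray, tau: float) -> np.ndarray:
    """Sustained response: ramps on over 60-90 ms, decays, off by 560 ms."""
    on = np.clip((t - 60.0) / 30.0, 0.0, 1.0)
    off = np.clip((560.0 - t) / 30.0, 0.0, 1.0)
    decay = np.exp(-np.maximum(t - 90.0, 0.0) / tau)
    return on * off * decay


def template_rate(
    template: RateTemplate,
    shape_id: int,
    c: float,
    t_grid: np.ndarray,
    preferred_shape: int = 1,
) -> np.ndarray:
    """Evaluate the template's firing rate (spikes/s) on ``t_grid``."""
    if shape_id not in (1, 2):
        raise ValueError(f"shape_id must be 1 or 2, got {shape_id}")
    if not (0.0 < c <= 100.0):
        raise ValueError(f"% visible area must be in (0, 100], got {c}")
    t = np.asarray(t_grid, dtype=float)
    pref = 1.0 if shape_id == preferred_shape else 1.0 / template.pref_ratio

    if template.profile == "vlpfc_occlusion":
        evoked = (
            template.peak1_amp
            * template.vlpfc_tuning(c)
            * _bump(t, template.peak1_time, template.peak1_width)
        )
    else:
        f1 = template.first_tuning(c)
        evoked = template.peak1_amp * f1 * _bump(
            t, template.peak1_time, template.peak1_width
        )
        evoked = evoked + template.sustained_frac * template.peak1_amp * f1 * _plateau(
            t, template.sustained_tau
        )
        if template.profile == "v4_double":
            ratio2 = (
                template.pref_ratio
                if template.pref_ratio_second is None
                else template.pref_ratio_second
            )
            pref2 = 1.0 if shape_id == preferred_shape else 1.0 / ratio2
            second = template.peak2_amp * template.second_tuning(c) * _bump(
                t, template.peak2_time, template.peak2_width
            )
            return template.baseline + pref * evoked + pref2 * second
    return template.baseline + pref * evoked


def sample_spike_trains(
    t_grid: np.ndarray,
    rate: np.ndarray,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
    window: tuple[float, float] | None = None,
) -> list[np.ndarray]:
    """Draw independent inhomogeneous-Poisson spike trains by thinning.

    ``rate`` (spikes/s) is interpolated linearly on ``t_grid`` (ms).
    Returns one sorted spike-time array per trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rate = np.asarray(rate, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if not np.all(np.isfinite(rate)):
        raise ValueError("rate must be finite everywhere")
    if np.any(rate < 0):
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(rng)
    if window is None:
        window = (float(t[0]), float(t[-1]))
    t0, t1 = window
    lam_max = float(rate.max())
    duration_s = (t1 - t0) / 1000.0
    trials = []
    for _ in range(n_trials):
        if lam_max == 0.0:
            trials.append(np.empty(0))
            continue
        n_cand = rng.poisson(lam_max * duration_s)
        times = rng.uniform(t0, t1, size=n_cand)
        accept = rng.uniform(0.0, lam_max, size=n_cand) < np.interp(times, t, rate)
        trials.append(np.sort(times[accept]))
    return trials


# ---------------------------------------------------------------------------
# Population specification and session generation
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Recipe for a synthetic population of recording sessions."""

    n_neurons: int = 100
    area: str = "V4"
    mixture: dict = field(
        default_factory=lambda: {"v4_single": 0.65, "v4_double": 0.35}
    )
    n_trials: int = 15
    n_levels: int | None = None  # default: 6 for V4, 5 for vlPFC
    templates: dict = field(default_factory=dict)  # per-class RateTemplate overrides
    # across-neuron jitter of template parameters
    peak1_time_sd: float = 4.0
    peak2_time_sd: float = 8.0
    amp_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.area not in ("V4", "vlPFC"):
            raise ValueError(f"area must be 'V4' or 'vlPFC', got {self.area!r}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions must sum to 1, got {total}")
        for cls in self.mixture:
            if cls not in PROFILE_CLASSES:
                raise ValueError(f"unknown profile class {cls!r}")
        if self.n_trials < 7:
            raise ValueError("n_trials must be >= 7 (minimum repeats per condition)")
        if self.n_levels is None:
            self.n_levels = 6 if self.area == "V4" else 5
        lo, hi = (4, 9) if self.area == "V4" else (5, 6)
        if not (lo <= self.n_levels <= hi):
            raise ValueError(
                f"n_levels={self.n_levels} outside the {self.area} range {lo}-{hi}"
            )

    def class_assignment(self) -> list[str]:
        """Deterministic per-neuron class labels hitting the mixture exactly."""
        classes = sorted(self.mixture)
        counts = {cls: int(round(self.mixture[cls] * self.n_neurons)) for cls in classes}
        # fix rounding drift on the largest class
        drift = self.n_neurons - sum(counts.values())
        counts[max(classes, key=lambda cl: self.mixture[cl])] += drift
        labels = [cls for cls in classes for _ in range(counts[cls])]
        rng = np.random.default_rng((self.seed, 0xC1A55))
        return [labels[i] for i in rng.permutation(self.n_neurons)]

    def base_template(self, cls: str) -> RateTemplate:
        if cls in self.templates:
            tmpl = self.templates[cls]
            return tmpl if isinstance(tmpl, RateTemplate) else RateTemplate(**tmpl)
        if cls == "vlpfc_occlusion":
            return RateTemplate(
                profile=cls,
                baseline=5.0,
                peak1_time=157.0,
                peak1_amp=35.0,
                peak1_width=40.0,
                peak2_time=None,
            )
        return RateTemplate(profile=cls, peak2_time=214.0 if cls == "v4_double" else None)


def generate_session(spec: PopulationSpec, neuron_index: int) -> SessionData:
    """Build one neuron's session (deterministic given ``spec.seed``)."""
    if not (0 <= neuron_index < spec.n_neurons):
        raise ValueError(f"neuron_index {neuron_index} outside [0, {spec.n_neurons})")
    cls = spec.class_assignment()[neuron_index]
    rng = np.random.default_rng((spec.seed, neuron_index))

    base = spec.base_template(cls)
    jit = {
        "peak1_time": base.peak1_time + rng.normal(0.0, spec.peak1_time_sd),
        "peak1_amp": base.peak1_amp * (1.0 + rng.uniform(-spec.amp_jitter, spec.amp_jitter)),
    }
    if cls == "v4_double":
        jit["peak2_time"] = base.peak2_time + rng.normal(0.0, spec.peak2_time_sd)
        jit["peak2_amp"] = base.peak2_amp * (
            1.0 + rng.uniform(-spec.amp_jitter, spec.amp_jitter)
        )
    template = replace(base, **jit)

    others = [c for c in OCCLUSION_LEVELS if c != 100.0]
    levels = [100.0] + sorted(
        rng.choice(others, size=spec.n_levels - 1, replace=False).tolist(), reverse=True
    )
    preferred = int(rng.integers(1, 3))

    t_grid = np.arange(DEFAULT_WINDOW[0], DEFAULT_WINDOW[1] + 1.0, 1.0)
    conditions: dict[tuple[int, float], SpikeTrainSet] = {}
    for shape in (1, 2):
        for c in levels:
            rate = template_rate(template, shape, c, t_grid, preferred_shape=preferred)
            trials = []
            for k in range(spec.n_trials):
                is_match = k % 2 == 0
                trial_rate = rate * (template.match_gain if is_match else 1.0)
                spikes = sample_spike_trains(t_grid, trial_rate, 1, rng)[0]
                trials.append(
                    Trial(spikes, shape=shape, pct_visible=c, match=is_match)
                )
            conditions[(shape, c)] = SpikeTrainSet(
                trials, shape=shape, pct_visible=c
            )

    session = SessionData(
        area=spec.area,
        neuron_id=f"{spec.area.lower()}-{neuron_index:04d}",
        conditions=conditions,
        ground_truth={
            "profile": cls,
            "preferred_shape": preferred,
            "peak1_time": template.peak1_time,
            "peak2_time": template.peak2_time if cls == "v4_double" else None,
            "levels": levels,
        },
    )
    session.validate()
    return session


def generate_population(spec: PopulationSpec) -> list[SessionData]:
    return [generate_session(spec, i) for i in range(spec.n_neurons)]


# ---------------------------------------------------------------------------
# Bridging simulator output to the Poisson sampler
# ---------------------------------------------------------------------------

def rates_from_model(
    params: NetworkParams,
    conditions: list[StimulusCondition],
    unit: int = 1,
    layer: str = "v4",
    floor: float = 2.0,
) -> dict[tuple[int, float], tuple[np.ndarray, np.ndarray]]:
    """Noise-free network rate trajectories as sampler-ready rate functions.

    Simulates each condition with noise off and returns, per condition, a
    ``(time, rate)`` pair on the full session window, floored at ``floor``
    spikes/s so Poisson sampling is non-degenerate.  ``unit`` selects V4 or
    vlPFC unit 1 or 2 via ``layer``.
    """
    if layer not in ("v4", "pfc"):
        raise ValueError("layer must be 'v4' or 'pfc'")
    quiet = params.replace(noise_on=False)
    out = {}
    for cond in conditions:
        traj = simulate_trial(quiet, cond)
        if traj.diverged:
            raise RuntimeError(
                f"integration failure (divergence) for condition {cond}"
            )
        rate_model = (traj.r_v4 if layer == "v4" else traj.r_pfc)[unit - 1]
        t_grid = np.arange(DEFAULT_WINDOW[0], DEFAULT_WINDOW[1] + 1.0, 1.0)
        rate = np.interp(t_grid, traj.time, rate_model, left=0.0, right=0.0)
        out[(cond.shape_id, cond.c)] = (t_grid, np.maximum(rate, floor))
    return out


def session_from_model(
    params: NetworkParams,
    levels: list[float],
    n_trials: int = 15,
    seed: int | None = 0,
    unit: int = 1,
    layer: str = "v4",
    floor: float = 2.0,
    area: str = "V4",
    neuron_id: str = "model-unit",
) -> SessionData:
    """Poisson-sample a full session from noise-free network trajectories."""
    conds = [
        StimulusCondition(shape_id=s, c=c) for s in (1, 2) for c in levels
    ]
    rates = rates_from_model(params, conds, unit=unit, layer=layer, floor=floor)
    rng = np.random.default_rng(seed)
    conditions = {}
    for (shape, c), (t_grid, rate) in rates.items():
        spikes = sample_spike_trains(t_grid, rate, n_trials, rng)
        trials = [
            Trial(st, shape=shape, pct_visible=c, match=(k % 2 == 0))
            for k, st in enumerate(spikes)
        ]
        conditions[(shape, c)] = SpikeTrainSet(trials, shape=shape, pct_visible=c)
    return SessionData(
        area=area, neuron_id=neuron_id, conditions=conditions, ground_truth=None
    )
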