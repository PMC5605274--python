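"""Two-layer V4-vlPFC firing-rate network with delayed feedback.

The model has two shape-selective V4 units driven by a transient feedforward
input whose strength grows with % visible area, and two vlPFC units that
receive delayed feedforward input from V4, are gain-modulated by occlusion
level, and send delayed, thresholded feedback to V4.  Rates follow

    tau_V4  * dr/dt = -r + F(U_V4  - r_thr_V4)  + eta
    tau_PFC * dr/dt = -r + g(c) * F(U_PFC - r_thr_PFC) + eta

with F a Naka-Rushton nonlinearity, integrated by forward Euler.  Runaway
positive feedback is prevented by activity-triggered adaptation of the
feedforward weights: once a vlPFC unit's rate crosses ``r_thr2`` its incoming
weights decay to zero with time constant ``tau_a`` for the rest of the trial.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .params import Ablations, NetworkParams, StimulusCondition

__all__ = [
    "Kernel",
    "DriveSignal",
    "RateTrajectory",
    "dog_kernel",
    "ramp_drive",
    "feedforward_drive",
    "naka_rushton",
    "pfc_gain",
    "simulate_trial",
    "relax_uncoupled",
    "sweep",
]

DIVERGENCE_FACTOR = 10.0  # rates above DIVERGENCE_FACTOR * f_max flag failure


@dataclass
class Kernel:
    """Sampled difference-of-Gaussians filter on a causal support."""

    time: np.ndarray  # ms, starting at 0
    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if len(self.time) != len(self.values):
            raise ValueError("time and values must have equal length")


@dataclass
class DriveSignal:
    """A named input time course on a uniform time grid."""

    time: np.ndarray  # ms
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if len(self.time) != len(self.values):
            raise ValueError("time and values must have equal length")


@dataclass
class RateTrajectory:
    """Simulated rates, adapting weights and inputs for one trial.

    ``r_v4``/``r_pfc`` have shape (2, n); ``w_sff``/``w_wff`` are the
    adapting incoming weights of each vlPFC unit.  Delayed/derived drive
    signals are reconstructed on demand from the stored rate histories.
    """

    time: np.ndarray
    r_v4: np.ndarray
    r_pfc: np.ndarray
    w_sff: np.ndarray
    w_wff: np.ndarray
    u_ff: np.ndarray  # (2, n) feedforward drive to the V4 units
    gain: np.ndarray  # (n,) occlusion gain applied to the vlPFC units
    condition: StimulusCondition
    params: NetworkParams
    diverged: bool = False

    @property
    def n_steps(self) -> int:
        return self.time.size

    def _delayed(self, rates: np.ndarray, delay_ms: float) -> np.ndarray:
        lag = int(round(delay_ms / self.params.dt))
        out = np.zeros_like(rates)
        if lag < rates.shape[-1]:
            out[..., lag:] = rates[..., : rates.shape[-1] - lag]
        return out

    def feedback_drive(self, j: int, i: int) -> DriveSignal:
        """u_PFC(j)->i: thresholded, rectified, delayed vlPFC feedback."""
        p = self.params
        thr = 0.0 if p.ablations.no_rectification else p.r_thr1
        w = p.w_inf_sfb if i == j else p.w_inf_wfb
        delayed = self._delayed(self.r_pfc[j - 1], p.tau_d_fb)
        vals = w * np.maximum(delayed - thr, 0.0)
        return DriveSignal(self.time, vals, f"uPFC({j}){i}")

    def feedforward_pfc_drive(self, j: int, i: int) -> DriveSignal:
        """u_V4(j)->i: delayed V4 input through the adapting weight."""
        p = self.params
        w = (self.w_sff if i == j else self.w_wff)[i - 1]
        delayed = self._delayed(self.r_v4[j - 1], p.tau_d_ff)
        return DriveSignal(self.time, w * delayed, f"uV4({j}){i}")

    def to_frame(self, include_drives: bool = False) -> pd.DataFrame:
        """Tidy long-format table (columns: time_ms, unit, rate)."""
        units = ["V4_1", "V4_2", "PFC_1", "PFC_2"]
        traces = [self.r_v4[0], self.r_v4[1], self.r_pfc[0], self.r_pfc[1]]
        if include_drives:
            units += ["uFF_1", "uFF_2", "gain"]
            traces += [self.u_ff[0], self.u_ff[1], self.gain]
        frames = [
            pd.DataFrame({"time_ms": self.time, "unit": u, "rate": v})
            for u, v in zip(units, traces)
        ]
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Drive construction
# ---------------------------------------------------------------------------

def dog_kernel(params: NetworkParams) -> Kernel:
    """Difference-of-Gaussians temporal filter shaping the feedforward drive.

    g1(t) = 15 exp(-(t-30)^2/800) and g2(t) = 10 exp(-(t-50)^2/800) on a
    causal support [0, kernel_support] ms.  ``kernel_norm`` selects the
    normalization of g1 - g2: "area" (unit integral, the default; keeps the
    convolved drive on the same scale as the ramp so the fixed Naka-Rushton
    semi-saturation is meaningful), "peak" (unit peak absolute value) or
    "none".
    """
    dt = params.dt
    n_k = int(round(params.kernel_support / dt)) + 1
    t = np.arange(n_k) * dt
    diff = 15.0 * np.exp(-((t - 30.0) ** 2) / 800.0) - 10.0 * np.exp(
        -((t - 50.0) ** 2) / 800.0
    )
    if params.kernel_norm == "area":
        area = diff.sum() * dt
        values = diff / area
    elif params.kernel_norm == "peak":
        values = diff / np.max(np.abs(diff))
    else:
        values = diff
    return Kernel(time=t, values=values, dt=dt)


def ramp_drive(shape_id: int, c: float, t_grid: np.ndarray) -> DriveSignal:
    """Occlusion-scaled input ramp feeding the difference-of-Gaussians filter.

    ``shape_id`` indexes the role of the driven unit relative to the shown
    stimulus: 1 = the unit preferring the shape, 2 = the other unit.  The
    ramp is supported on 30 <= t <= 530 ms and declines at 0.05 per ms:

        R1 = (2.5 c + 20)        - 0.05 t   (preferred)
        R2 = (12 c^(1/3) + 120)  - 0.05 t   (nonpreferred)
    """
    if shape_id not in (1, 2):
        raise ValueError(f"shape_id must be 1 or 2, got {shape_id}")
    if not (0.0 < c <= 100.0):
        raise ValueError(f"% visible area must be in (0, 100], got {c}")
    t = np.asarray(t_grid, dtype=float)
    if shape_id == 1:
        base = 2.5 * c + 20.0
    else:
        base = 12.0 * c ** (1.0 / 3.0) + 120.0
    vals = np.where((t >= 30.0) & (t <= 530.0), base - 0.05 * t, 0.0)
    return DriveSignal(t, vals, f"ramp_{shape_id}")


def feedforward_drive(
    shape_id: int, c: float, t_grid: np.ndarray, kernel: Kernel
) -> DriveSignal:
    """Feedforward input to one V4 unit.

    The ramp is convolved with the difference-of-Gaussians kernel, cubed,
    renormalized by the squared maximum (so the peak value equals the peak of
    the convolution) and half-wave rectified:

        uFF = [ (k * R)^3 / max(k * R)^2 ]_+
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size > 1:
        dt_grid = t[1] - t[0]
        if not math.isclose(dt_grid, kernel.dt, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"kernel sampled at dt={kernel.dt} but grid spacing is {dt_grid}"
            )
    ramp = ramp_drive(shape_id, c, t).values
    conv = fftconvolve(ramp, kernel.values)[: t.size] * kernel.dt
    peak = conv.max()
    if peak <= 0.0:
        return DriveSignal(t, np.zeros_like(t), f"uFF_{shape_id}")
    vals = np.maximum(conv**3 / peak**2, 0.0)
    return DriveSignal(t, vals, f"uFF_{shape_id}")


def naka_rushton(x, params: NetworkParams):
    """Saturating rate nonlinearity F(x) = f_max x^N / (sigma^N + x^N), 0 for x < 0."""
    x = np.asarray(x, dtype=float)
    pos = np.maximum(x, 0.0)
    xn = pos**params.n_nr
    out = params.f_max * xn / (params.sigma_nr**params.n_nr + xn)
    if out.ndim == 0:
        return float(out)
    return out


def pfc_gain(c: float, params: NetworkParams | None = None) -> float:
    """Occlusion-dependent multiplicative gain on the vlPFC response.

    A cubic in % visible area, lowest for the unoccluded stimulus and larger
    under occlusion; this is what confers the vlPFC preference for occluded
    shapes.
    """
    if not (0.0 < c <= 100.0):
        raise ValueError(f"% visible area must be in (0, 100], got {c}")
    a3, a2, a1, a0 = params.gain_coeffs if params is not None else (
        -0.0017,
        0.39,
        -29.6,
        806.0,
    )
    return a3 * c**3 + a2 * c**2 + a1 * c + a0


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def simulate_trial(
    params: NetworkParams, condition: StimulusCondition
) -> RateTrajectory:
    """Integrate one trial of the full network by forward Euler.

    Units start silent (rates 0, zero delay history) with weights at their
    steady-state values.  Rates are clamped at zero after each step.  A
    trajectory whose rates exceed ``10 * f_max`` is flagged ``diverged``
    (integration continues so the failure mode can be inspected).
    """
    p = params
    abl = p.ablations
    dt = p.dt
    n = int(round(p.t_total / dt))
    t = np.arange(n) * dt

    kern = dog_kernel(p)
    u_ff = np.empty((2, n))
    for unit in (0, 1):
        role = 1 if (unit + 1) == condition.shape_id else 2
        u_ff[unit] = feedforward_drive(role, condition.c, t, kern).values

    g_full = pfc_gain(100.0, p) if abl.no_gain else pfc_gain(condition.c, p)
    g_before = pfc_gain(100.0, p)  # baseline gain before the modulation arrives
    g_step = int(round(p.gain_delay / dt))
    gain = np.full(n, g_full)
    gain[: min(g_step, n)] = g_before

    if p.noise_on:
        rng = np.random.default_rng(p.seed)
        eta = rng.normal(0.0, p.noise_std_coeff * dt, size=(4, n))
    else:
        eta = None

    lag_ff = int(round(p.tau_d_ff / dt))
    lag_fb = int(round(p.tau_d_fb / dt))
    thr_fb = 0.0 if abl.no_rectification else p.r_thr1
    w_sfb, w_wfb = p.w_inf_sfb, p.w_inf_wfb
    adapt = not abl.no_adaptation

    # histories as plain lists: scalar indexing dominates the inner loop
    hv1 = [0.0] * n
    hv2 = [0.0] * n
    hp1 = [0.0] * n
    hp2 = [0.0] * n
    ws1_tr = [p.w_inf_sff] * n
    ws2_tr = [p.w_inf_sff] * n
    ww1_tr = [p.w_inf_wff] * n
    ww2_tr = [p.w_inf_wff] * n
    uff1 = u_ff[0].tolist()
    uff2 = u_ff[1].tolist()
    gain_l = gain.tolist()

    f_max, sig_n, n_nr = p.f_max, p.sigma_nr**p.n_nr, p.n_nr
    rthr_v4, rthr_pfc, rthr2 = p.r_thr_v4, p.r_thr_pfc, p.r_thr2
    kv = dt / p.tau_v4
    kp = dt / p.tau_pfc
    ka = dt / p.tau_a

    def F(x: float) -> float:
        if x <= 0.0:
            return 0.0
        xn = x**n_nr
        return f_max * xn / (sig_n + xn)

    ws1, ws2 = p.w_inf_sff, p.w_inf_sff
    ww1, ww2 = p.w_inf_wff, p.w_inf_wff
    winf_s1, winf_s2 = p.w_inf_sff, p.w_inf_sff
    winf_w1, winf_w2 = p.w_inf_wff, p.w_inf_wff
    rv1 = rv2 = rp1 = rp2 = 0.0

    if eta is not None:
        e1, e2, e3, e4 = (eta[i].tolist() for i in range(4))

    for m in range(n - 1):
        mf = m - lag_ff
        mb = m - lag_fb
        rpd1 = hp1[mb] if mb >= 0 else 0.0
        rpd2 = hp2[mb] if mb >= 0 else 0.0
        rvd1 = hv1[mf] if mf >= 0 else 0.0
        rvd2 = hv2[mf] if mf >= 0 else 0.0

        fb1 = rpd1 - thr_fb
        fb1 = fb1 if fb1 > 0.0 else 0.0
        fb2 = rpd2 - thr_fb
        fb2 = fb2 if fb2 > 0.0 else 0.0

        uv1 = uff1[m] + w_sfb * fb1 + w_wfb * fb2
        uv2 = uff2[m] + w_wfb * fb1 + w_sfb * fb2
        up1 = ws1 * rvd1 + ww1 * rvd2
        up2 = ws2 * rvd2 + ww2 * rvd1
        g = gain_l[m]

        dv1 = -rv1 + F(uv1 - rthr_v4)
        dv2 = -rv2 + F(uv2 - rthr_v4)
        dp1 = -rp1 + g * F(up1 - rthr_pfc)
        dp2 = -rp2 + g * F(up2 - rthr_pfc)
        if eta is not None:
            dv1 += e1[m]
            dv2 += e2[m]
            dp1 += e3[m]
            dp2 += e4[m]

        rv1 += kv * dv1
        rv2 += kv * dv2
        rp1 += kp * dp1
        rp2 += kp * dp2
        if rv1 < 0.0:
            rv1 = 0.0
        if rv2 < 0.0:
            rv2 = 0.0
        if rp1 < 0.0:
            rp1 = 0.0
        if rp2 < 0.0:
            rp2 = 0.0

        if adapt:
            if rp1 >= rthr2:
                winf_s1 = 0.0
                winf_w1 = 0.0
            if rp2 >= rthr2:
                winf_s2 = 0.0
                winf_w2 = 0.0
            ws1 += ka * (winf_s1 - ws1)
            ww1 += ka * (winf_w1 - ww1)
            ws2 += ka * (winf_s2 - ws2)
            ww2 += ka * (winf_w2 - ww2)

        mm = m + 1
        hv1[mm] = rv1
        hv2[mm] = rv2
        hp1[mm] = rp1
        hp2[mm] = rp2
        ws1_tr[mm] = ws1
        ws2_tr[mm] = ws2
        ww1_tr[mm] = ww1
        ww2_tr[mm] = ww2

    r_v4 = np.array([hv1, hv2])
    r_pfc = np.array([hp1, hp2])
    diverged = bool(max(r_v4.max(), r_pfc.max()) > DIVERGENCE_FACTOR * p.f_max)
    return RateTrajectory(
        time=t,
        r_v4=r_v4,
        r_pfc=r_pfc,
        w_sff=np.array([ws1_tr, ws2_tr]),
        w_wff=np.array([ww1_tr, ww2_tr]),
        u_ff=u_ff,
        gain=gain,
        condition=condition,
        params=p,
        diverged=diverged,
    )


def relax_uncoupled(
    params: NetworkParams,
    u0: float,
    unit: str = "v4",
    gain: float = 1.0,
    t_total: float | None = None,
) -> DriveSignal:
    """Integrate a single, uncoupled unit under constant input ``u0``.

    Uses the same Euler update as :func:`simulate_trial` (noise off); with
    constant input the rate converges to ``gain * F(u0 - r_thr)``, which
    serves as a closed-form check on the integrator.
    """
    if unit not in ("v4", "pfc"):
        raise ValueError("unit must be 'v4' or 'pfc'")
    tau = params.tau_v4 if unit == "v4" else params.tau_pfc
    rthr = params.r_thr_v4 if unit == "v4" else params.r_thr_pfc
    dt = params.dt
    n = int(round((t_total if t_total is not None else params.t_total) / dt))
    target = gain * naka_rushton(u0 - rthr, params)
    k = dt / tau
    r = 0.0
    out = np.empty(n)
    out[0] = 0.0
    for m in range(1, n):
        r += k * (-r + target)
        out[m] = r
    return DriveSignal(np.arange(n) * dt, out, f"relax_{unit}")


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

def _trajectory_summary(traj: RateTrajectory) -> dict:
    from .peaks import PeakFinderConfig, rate_profile_peaks

    cfg = PeakFinderConfig(smoothing_sigma=0.0)  # model traces are already smooth
    i_pref = traj.condition.shape_id - 1
    i_non = 1 - i_pref
    kept = rate_profile_peaks(traj.time, traj.r_v4[i_pref], cfg)
    second_time = second_amp = math.nan
    if len(kept) >= 2:
        second = max(kept[1:], key=lambda cand: cand.peak_height)
        second_time, second_amp = second.peak_time, second.peak_height
    pfc_pref = traj.r_pfc[i_pref].max()
    pfc_non = traj.r_pfc[i_non].max()
    denom = pfc_pref + pfc_non
    return {
        "n_peaks": len(kept),
        "first_peak_time": kept[0].peak_time if kept else math.nan,
        "first_peak_amp": kept[0].peak_height if kept else math.nan,
        "second_peak_time": second_time,
        "second_peak_amp": second_amp,
        "pfc_peak_time": float(traj.time[np.argmax(traj.r_pfc[i_pref])]),
        "pfc_selectivity": (pfc_pref - pfc_non) / denom if denom > 0 else math.nan,
        "diverged": traj.diverged,
    }


def sweep(
    params: NetworkParams,
    grid: dict[str, Sequence],
    condition: StimulusCondition | None = None,
) -> pd.DataFrame:
    """Simulate every cell of a parameter grid and summarize each trajectory.

    ``grid`` maps NetworkParams field names (e.g. ``tau_d_fb``, ``w_inf_sfb``)
    to value lists; the Cartesian product is simulated under ``condition``
    (default: preferred shape at 82% visible area).  Failed cells are
    reported in the ``error`` column rather than aborting the sweep.
    """
    if condition is None:
        condition = StimulusCondition(shape_id=1, c=82.0)
    names = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in names)):
        cell = dict(zip(names, values))
        row = dict(cell)
        try:
            cell_params = params.replace(**cell)
            if "w_inf_wfb" not in cell and (
                "w_inf_sfb" in cell or "w_inf_wff" in cell or "w_inf_sff" in cell
            ):
                # re-derive the weak feedback weight from the Table rule
                cell_params = cell_params.replace(w_inf_wfb=None)
            traj = simulate_trial(cell_params, condition)
            row.update(_trajectory_summary(traj))
            row["error"] = ""
        except Exception as exc:  # propagate per-cell without aborting
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
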