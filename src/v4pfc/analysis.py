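"""Per-neuron spike-train analyses.

PSTH construction, responsiveness and factorial screens, sliding-window ROC
shape selectivity, peak latency, occlusion-slope regression and windowed
response measures.  All times are in ms relative to test-stimulus onset;
count windows are closed on the left and open on the right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .session import SessionData, SpikeTrainSet, Trial

DEFAULT_SIGMA = 10.0  # ms, PSTH smoothing
TEST_EPOCH = (0.0, 600.0)
RESPONSE_WINDOW = (80.0, 230.0)
FIXATION_WINDOW = (-300.0, 0.0)

#: sliding-ROC window length (ms) per cortical area
ROC_WINDOW = {"V4": 75.0, "vlPFC": 150.0}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Psth:
    """Trial-averaged, Gaussian-smoothed firing rate (spikes/s)."""

    time: np.ndarray
    rate: np.ndarray
    sigma: float
    n_trials: int
    label: str = ""


@dataclass
class SelectivityTimecourse:
    """Sliding-window ROC area between preferred/nonpreferred spike counts."""

    time: np.ndarray
    auc: np.ndarray
    window: float
    selector: str  # "c=<level>" or "pooled_occluded"


@dataclass
class TestResult:
    statistic: float
    p_value: float
    significant: bool


@dataclass
class AnovaResult:
    factors: tuple[str, str]
    f_values: dict
    p_values: dict
    table: pd.DataFrame


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_value: float
    n_levels: int


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def psth(
    spike_trains: list[np.ndarray],
    sigma: float = DEFAULT_SIGMA,
    window: tuple[float, float] = (-300.0, 700.0),
    bin_ms: float = 1.0,
    label: str = "",
) -> Psth:
    """Trial-averaged rate histogram smoothed with a Gaussian of sd ``sigma``.

    Smoothing uses zero padding so that the integral of the smoothed rate
    equals the mean spike count over the window (mass preservation).
    """
    if len(spike_trains) == 0:
        raise ValueError("psth requires at least one trial")
    t0, t1 = window
    edges = np.arange(t0, t1 + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    for st in spike_trains:
        counts += np.histogram(st, bins=edges)[0]
    rate = counts / len(spike_trains) / (bin_ms / 1000.0)
    if sigma > 0:
        rate = gaussian_filter1d(rate, sigma / bin_ms, mode="constant")
    centers = edges[:-1] + bin_ms / 2.0
    return Psth(time=centers, rate=rate, sigma=sigma, n_trials=len(spike_trains), label=label)


def condition_psth(
    session: SessionData,
    shape: int,
    pct_visible: float,
    sigma: float = DEFAULT_SIGMA,
) -> Psth:
    sts = session.trains(shape, pct_visible)
    return psth(
        sts.spike_arrays(),
        sigma=sigma,
        window=session.window,
        label=f"shape={shape}, c={pct_visible}",
    )


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def visual_responsiveness(
    session: SessionData,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    fixation_window: tuple[float, float] = FIXATION_WINDOW,
    alpha: float = 0.01,
    paired: bool = True,
) -> TestResult:
    """t-test of per-trial firing rate, response window vs fixation epoch.

    The default response window is 150 ms starting 80 ms after test onset
    (transient responses; the offset absorbs response latency).  Paired by
    trial by default; set ``paired=False`` for a two-sample test.
    """
    trials = session.trials()
    if not trials:
        raise ValueError("session has no trials")
    w0, w1 = fixation_window
    if w0 < session.window[0] or w1 > session.window[1]:
        raise ValueError("fixation epoch not covered by the session window")
    fix = np.array([tr.rate(*fixation_window) for tr in trials])
    resp = np.array([tr.rate(*response_window) for tr in trials])
    if paired:
        diffs = resp - fix
        if np.allclose(diffs.std(), 0.0):
            # degenerate: identical samples carry no evidence either way
            return TestResult(0.0, 1.0, False)
        t, p = stats.ttest_rel(resp, fix)
    else:
        if np.allclose(resp.std(), 0.0) and np.allclose(fix.std(), 0.0):
            return TestResult(0.0, 1.0, False)
        t, p = stats.ttest_ind(resp, fix)
    return TestResult(float(t), float(p), bool(p < alpha))


def two_factor_anova(
    counts: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    names: tuple[str, str] = ("shape", "occlusion"),
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on per-trial counts."""
    counts = np.asarray(counts, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (counts.size == fa.size == fb.size):
        raise ValueError("counts and factor labels must have equal length")
    if np.unique(fa).size < 2 or np.unique(fb).size < 2:
        raise ValueError("each factor needs at least 2 levels")
    for a in np.unique(fa):
        for b in np.unique(fb):
            n_cell = int(np.sum((fa == a) & (fb == b)))
            if n_cell < 2:
                raise ValueError(
                    f"cell ({names[0]}={a}, {names[1]}={b}) has {n_cell} "
                    "replicates; at least 2 required"
                )
    df = pd.DataFrame({"count": counts, "A": fa.astype(str), "B": fb.astype(str)})
    fit = smf.ols("count ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    key_a, key_b, key_ab = "C(A)", "C(B)", "C(A):C(B)"
    f_values = {
        names[0]: float(table.loc[key_a, "F"]),
        names[1]: float(table.loc[key_b, "F"]),
        "interaction": float(table.loc[key_ab, "F"]),
    }
    p_values = {
        names[0]: float(table.loc[key_a, "PR(>F)"]),
        names[1]: float(table.loc[key_b, "PR(>F)"]),
        "interaction": float(table.loc[key_ab, "PR(>F)"]),
    }
    return AnovaResult(factors=names, f_values=f_values, p_values=p_values, table=table)


def anova_from_session(
    session: SessionData,
    factors: tuple[str, str] = ("shape", "occlusion"),
    response_window: tuple[float, float] = RESPONSE_WINDOW,
) -> AnovaResult:
    """Factorial screen on response-window counts.

    ``factors`` may combine "shape", "occlusion" and "match".
    """
    getters = {
        "shape": lambda tr: tr.shape,
        "occlusion": lambda tr: tr.pct_visible,
        "match": lambda tr: tr.match,
    }
    for f in factors:
        if f not in getters:
            raise ValueError(f"unknown factor {f!r}")
    trials = session.trials()
    counts = np.array([tr.count(*response_window) for tr in trials])
    fa = np.array([getters[factors[0]](tr) for tr in trials])
    fb = np.array([getters[factors[1]](tr) for tr in trials])
    return two_factor_anova(counts, fa, fb, names=factors)


# ---------------------------------------------------------------------------
# Shape preference and ROC selectivity
# ---------------------------------------------------------------------------

def preferred_shape(
    session: SessionData, epoch: tuple[float, float] = TEST_EPOCH
) -> int:
    """Shape evoking the largest average response.

    V4 sessions average across all occlusion levels including 100%; vlPFC
    sessions average across occluded levels only (many vlPFC neurons barely
    respond to unoccluded stimuli).  Exact ties break to shape 1 with a
    warning.
    """
    if set(session.shapes) != {1, 2}:
        raise ValueError("both shapes must be present to define a preference")
    if session.area == "vlPFC":
        levels = [c for c in session.levels if c < 100.0]
        if not levels:
            raise ValueError("vlPFC preference rule needs occluded conditions")
    else:
        levels = session.levels
    means = {}
    for shape in (1, 2):
        rates = [tr.rate(*epoch) for tr in session.trials(shape=shape, levels=levels)]
        means[shape] = float(np.mean(rates))
    if means[1] == means[2]:
        warnings.warn("tied average responses; preferring shape 1", stacklevel=2)
        return 1
    return 1 if means[1] > means[2] else 2


def roc_area(counts_pref, counts_nonpref) -> float:
    """Area under the ROC curve from two spike-count samples.

    Equals the Mann-Whitney statistic P(X > Y) + 0.5 P(X = Y) over all
    cross-pairs: 0.5 = indistinguishable, 1.0 = complete separation.
    """
    x = np.asarray(counts_pref, dtype=float)
    y = np.asarray(counts_nonpref, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both count samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def _window_counts(spike_trains: list[np.ndarray], centers: np.ndarray, width: float) -> np.ndarray:
    """(n_centers, n_trials) spike counts in centered windows [c-w/2, c+w/2)."""
    lo = centers - width / 2.0
    hi = centers + width / 2.0
    out = np.empty((centers.size, len(spike_trains)))
    for j, st in enumerate(spike_trains):
        out[:, j] = np.searchsorted(st, hi) - np.searchsorted(st, lo)
    return out


def _roc_rows(counts_x: np.ndarray, counts_y: np.ndarray) -> np.ndarray:
    """Row-wise ROC area for matrices of shape (n_steps, n_trials)."""
    n1 = counts_x.shape[1]
    n2 = counts_y.shape[1]
    both = np.concatenate([counts_x, counts_y], axis=1)
    ranks = stats.rankdata(both, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def roc_selectivity_timecourse(
    session: SessionData,
    preferred: int,
    window: float | None = None,
    step: float = 1.0,
    occlusion: float | str = "pooled_occluded",
    t_range: tuple[float, float] = TEST_EPOCH,
) -> SelectivityTimecourse:
    """Sliding-window ROC shape selectivity at 1 ms resolution.

    ``occlusion`` selects a single % visible area, or ``"pooled_occluded"``
    to concatenate every occluded (c < 100) condition.  The window defaults
    to 75 ms for V4 sessions and 150 ms for vlPFC sessions and is truncated
    (with a warning) where it would exceed the recorded range.
    """
    if window is None:
        window = ROC_WINDOW[session.area]
    if occlusion == "pooled_occluded":
        levels = [c for c in session.levels if c < 100.0]
        selector = "pooled_occluded"
    else:
        levels = [float(occlusion)]
        selector = f"c={occlusion}"
    nonpref = 2 if preferred == 1 else 1
    pref_trains = [tr.spike_times for tr in session.trials(shape=preferred, levels=levels)]
    non_trains = [tr.spike_times for tr in session.trials(shape=nonpref, levels=levels)]
    if not pref_trains or not non_trains:
        raise ValueError(f"no trials for selector {selector!r}")
    centers = np.arange(t_range[0], t_range[1] + step, step)
    lo, hi = session.window
    if centers[0] - window / 2.0 < lo or centers[-1] + window / 2.0 > hi:
        warnings.warn("ROC window truncated at the edge of the recorded range",
                      stacklevel=2)
    auc = _roc_rows(
        _window_counts(pref_trains, centers, window),
        _window_counts(non_trains, centers, window),
    )
    return SelectivityTimecourse(time=centers, auc=auc, window=window, selector=selector)


# ---------------------------------------------------------------------------
# Latency, occlusion tuning, windowed measures
# ---------------------------------------------------------------------------

def peak_latency(
    session: SessionData,
    shape: int | None = None,
    search: tuple[float, float] = (50.0, 600.0),
    sigma: float = DEFAULT_SIGMA,
) -> float:
    """Time of maximal response in the across-occlusion average PSTH.

    The search range 50-600 ms excludes responses tied to the preceding
    reference stimulus or to post-stimulus saccades.  ``shape`` restricts to
    one shape (default: both pooled).
    """
    curves = []
    time = None
    for c in session.levels:
        trains = [tr.spike_times for tr in session.trials(shape=shape, levels=[c])]
        if trains:
            p = psth(trains, sigma=sigma, window=session.window)
            curves.append(p.rate)
            time = p.time
    if not curves:
        raise ValueError("no PSTHs available")
    avg = np.mean(curves, axis=0)
    mask = (time >= search[0]) & (time <= search[1])
    seg = avg[mask]
    if np.allclose(seg, seg[0]):
        warnings.warn("flat PSTH in the search range; returning earliest time",
                      stacklevel=2)
    return float(time[mask][np.argmax(seg)])


def occlusion_slope(
    session: SessionData,
    epoch: tuple[float, float] = RESPONSE_WINDOW,
    shape: int | None = None,
    per_trial: bool = False,
) -> RegressionResult:
    """OLS slope of normalized response on % visible area.

    Negative slopes indicate stronger responses under occlusion.  By default
    the regression uses per-level mean responses normalized to the maximum
    level (per-trial regression available via ``per_trial``).
    """
    levels = session.levels
    if len(levels) < 3:
        raise ValueError("occlusion_slope requires at least 3 occlusion levels")
    if shape is None:
        shape = preferred_shape(session)
    level_means = np.array([
        np.mean([tr.rate(*epoch) for tr in session.trials(shape=shape, levels=[c])])
        for c in levels
    ])
    peak = level_means.max()
    if peak <= 0:
        raise ValueError("neuron has no response in the chosen epoch")
    if per_trial:
        xs, ys = [], []
        for c in levels:
            for tr in session.trials(shape=shape, levels=[c]):
                xs.append(c)
                ys.append(tr.rate(*epoch) / peak)
        res = stats.linregress(xs, ys)
    else:
        res = stats.linregress(levels, level_means / peak)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_value=float(res.rvalue),
        n_levels=len(levels),
    )


def peak_window_response(
    session: SessionData,
    center_ms: float,
    half_width: float = 15.0,
    baseline: tuple[float, float] = (-115.0, -85.0),
    shape: int | None = None,
) -> dict[float, float]:
    """Baseline-subtracted mean rate in a 30 ms window around ``center_ms``.

    Returns one value per occlusion level (spikes/s relative to the
    pre-stimulus baseline window).
    """
    w0, w1 = center_ms - half_width, center_ms + half_width
    lo, hi = session.window
    if w0 < lo or w1 > hi or baseline[0] < lo or baseline[1] > hi:
        raise ValueError("analysis window outside the recorded range")
    if shape is None:
        shape = preferred_shape(session)
    out = {}
    for c in session.levels:
        trials = session.trials(shape=shape, levels=[c])
        resp = np.mean([tr.rate(w0, w1) for tr in trials])
        base = np.mean([tr.rate(*baseline) for tr in trials])
        out[c] = float(resp - base)
    return out


def fixed_window_difference(
    session: SessionData,
    early: tuple[float, float] = (69.0, 99.0),
    late: tuple[float, float] = (199.0, 229.0),
    shape: int | None = None,
    sigma: float = DEFAULT_SIGMA,
) -> dict[float, float]:
    """Late-minus-early normalized response per occlusion level.

    PSTHs are first normalized by the maximum across time (test epoch) and
    occlusion levels, so each neuron contributes on a common [0, 1] scale.
    The early window brackets the typical first transient, the late window
    the typical second-peak time.
    """
    lo, hi = session.window
    for w in (early, late):
        if w[0] < lo or w[1] > hi:
            raise ValueError("analysis window outside the recorded range")
    if shape is None:
        shape = preferred_shape(session)
    curves = {}
    for c in session.levels:
        p = condition_psth(session, shape, c, sigma=sigma)
        curves[c] = p
    t = next(iter(curves.values())).time
    in_epoch = (t >= TEST_EPOCH[0]) & (t <= TEST_EPOCH[1])
    norm = max(p.rate[in_epoch].max() for p in curves.values())
    if norm <= 0:
        raise ValueError("neuron has no response; cannot normalize")
    out = {}
    for c, p in curves.items():
        e = p.rate[(t >= early[0]) & (t < early[1])].mean() / norm
        l = p.rate[(t >= late[0]) & (t < late[1])].mean() / norm
        out[c] = float(l - e)
    return out
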