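"""Population-level aggregation of per-neuron results.

Normalized occlusion-tuning matrices and curves, population PSTHs and
selectivity timecourses, group comparisons between neurons with and without
two response peaks, peak-time distributions and exact proportion tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import (
    RESPONSE_WINDOW,
    TEST_EPOCH,
    condition_psth,
    fixed_window_difference,
    preferred_shape,
    roc_selectivity_timecourse,
)
from .session import SessionData

MIN_NEURONS_PER_CURVE = 5


def normalize_neuron(responses) -> np.ndarray:
    """Scale one neuron's per-level responses so the maximum level is 1."""
    r = np.asarray(responses, dtype=float)
    if r.size == 0:
        raise ValueError("no responses to normalize")
    peak = r.max()
    if peak <= 0:
        raise ValueError("all-zero responses cannot be normalized")
    return r / peak


def rank_order_matrix(
    sessions: list[SessionData],
    epoch: tuple[float, float] = RESPONSE_WINDOW,
) -> pd.DataFrame:
    """Per-neuron normalized epoch responses in rank order of % visible area.

    Columns are occlusion ranks (0 = most occluded ... last = unoccluded),
    so a column can mix different absolute levels across neurons; ties in
    level order are resolved by the level value (stable).  All-zero neurons
    are excluded with a warning.
    """
    rows = {}
    n_cols = max(len(s.levels) for s in sessions)
    for s in sessions:
        pref = preferred_shape(s)
        levels = sorted(s.levels)  # increasing % visible area
        means = [
            np.mean([tr.rate(*epoch) for tr in s.trials(shape=pref, levels=[c])])
            for c in levels
        ]
        try:
            norm = normalize_neuron(means)
        except ValueError:
            warnings.warn(f"excluding unresponsive neuron {s.neuron_id}", stacklevel=2)
            continue
        row = np.full(n_cols, np.nan)
        row[-len(norm):] = norm  # right-align so the last column is c=100
        rows[s.neuron_id] = row
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"rank_{i}" for i in range(n_cols)]
    )


def population_curves(
    sessions: list[SessionData],
    kind: str = "psth",
    min_neurons: int = MIN_NEURONS_PER_CURVE,
    sigma: float = 10.0,
) -> dict[float, dict]:
    """Across-neuron average response or selectivity curves per occlusion level.

    ``kind``: "psth" averages each neuron's normalized preferred-shape PSTH
    (normalized by its maximum across time and levels); "selectivity"
    averages per-level sliding-ROC timecourses.  Levels contributed to by
    fewer than ``min_neurons`` neurons are dropped.  Each entry reports the
    contributing neuron count ``n``.
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    if kind not in ("psth", "selectivity"):
        raise ValueError(f"unknown curve kind {kind!r}")
    acc: dict[float, list[np.ndarray]] = {}
    time = None
    for s in sessions:
        pref = preferred_shape(s)
        if kind == "psth":
            curves = {c: condition_psth(s, pref, c, sigma=sigma) for c in s.levels}
            t = next(iter(curves.values())).time
            in_epoch = (t >= TEST_EPOCH[0]) & (t <= TEST_EPOCH[1])
            norm = max(p.rate[in_epoch].max() for p in curves.values())
            if norm <= 0:
                warnings.warn(
                    f"excluding unresponsive neuron {s.neuron_id}", stacklevel=2
                )
                continue
            for c, p in curves.items():
                acc.setdefault(c, []).append(p.rate / norm)
                time = p.time
        else:
            for c in s.levels:
                tc = roc_selectivity_timecourse(s, pref, occlusion=c)
                acc.setdefault(c, []).append(tc.auc)
                time = tc.time
    out = {}
    for c, stack in sorted(acc.items(), reverse=True):
        if len(stack) < min_neurons:
            continue
        out[c] = {
            "time": time,
            "mean": np.mean(stack, axis=0),
            "n": len(stack),
        }
    if not out:
        raise ValueError(
            f"no occlusion level reached the minimum of {min_neurons} neurons"
        )
    return out


def group_window_comparison(
    group_a: list[SessionData],
    group_b: list[SessionData],
    early: tuple[float, float] = (69.0, 99.0),
    late: tuple[float, float] = (199.0, 229.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t-test per occlusion level on late-minus-early differences.

    Compares the fixed-window response-difference values of two neuron
    groups (e.g. with vs without two peaks) at every occlusion level both
    groups sampled.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 neurons")

    def collect(group):
        per_level: dict[float, list[float]] = {}
        for s in group:
            for c, v in fixed_window_difference(s, early=early, late=late).items():
                per_level.setdefault(c, []).append(v)
        return per_level

    a_vals = collect(group_a)
    b_vals = collect(group_b)
    rows = []
    for c in sorted(set(a_vals) & set(b_vals), reverse=True):
        xa, xb = a_vals[c], b_vals[c]
        t, p = stats.ttest_ind(xa, xb)
        rows.append(
            {
                "pct_visible": c,
                "mean_a": float(np.mean(xa)),
                "mean_b": float(np.mean(xb)),
                "n_a": len(xa),
                "n_b": len(xb),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def selectivity_peak_comparison(
    sessions: list[SessionData],
    classifications: dict[str, "TwoPeakClassification"],
    window: float = 30.0,
) -> dict:
    """Shape selectivity at the first vs second response peak, per neuron.

    For each neuron classified as two-peak, computes the pooled-occluded ROC
    area in a 30 ms window centered on the first and second peak times, and
    compares the time of maximal selectivity (unoccluded and pooled-
    occluded) to the second-peak time.  Neurons without both peak times are
    skipped with a warning.
    """
    rows = []
    for s in sessions:
        cls = classifications.get(s.neuron_id)
        if cls is None or not cls.is_two_peak or cls.first_peak_time is None:
            warnings.warn(f"skipping {s.neuron_id}: missing peak times", stacklevel=2)
            continue
        pref = preferred_shape(s)
        tc_occ = roc_selectivity_timecourse(s, pref, window=window, occlusion="pooled_occluded")
        tc_unocc = roc_selectivity_timecourse(s, pref, window=window, occlusion=100.0)

        def at(tc, when):
            return float(tc.auc[np.argmin(np.abs(tc.time - when))])

        rows.append(
            {
                "neuron_id": s.neuron_id,
                "auc_first": at(tc_occ, cls.first_peak_time),
                "auc_second": at(tc_occ, cls.second_peak_time),
                "t_max_selectivity_occluded": float(tc_occ.time[np.argmax(tc_occ.auc)]),
                "t_max_selectivity_unoccluded": float(tc_unocc.time[np.argmax(tc_unocc.auc)]),
                "second_peak_time": cls.second_peak_time,
            }
        )
    df = pd.DataFrame(rows)
    out = {"per_neuron": df}
    if len(df) >= 2:
        t1, p1 = stats.ttest_rel(df["auc_second"], df["auc_first"])
        t2, p2 = stats.ttest_rel(
            df["t_max_selectivity_unoccluded"], df["second_peak_time"]
        )
        t3, p3 = stats.ttest_rel(
            df["t_max_selectivity_occluded"], df["second_peak_time"]
        )
        out["second_vs_first"] = {"t": float(t1), "p": float(p1)}
        out["unoccluded_max_vs_second_time"] = {"t": float(t2), "p": float(p2)}
        out["occluded_max_vs_second_time"] = {"t": float(t3), "p": float(p3)}
    return out


def proportion_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test of k successes in n trials against p0.

    Two-sidedness by the point-probability rule: the p-value sums the
    probability of all outcomes no more likely than the observed one.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, {n}]")
    return float(stats.binomtest(k, n, p0).pvalue)


def peak_time_summary(
    classifications: dict[str, "TwoPeakClassification"],
    latencies: dict[str, float] | None = None,
) -> dict:
    """First/second-peak time distributions for two-peak neurons.

    Optionally summarizes a separate peak-latency distribution (e.g. for
    occlusion-sensitive vlPFC neurons) passed via ``latencies``.
    """
    firsts = [
        c.first_peak_time
        for c in classifications.values()
        if c.is_two_peak and c.first_peak_time is not None
    ]
    seconds = [
        c.second_peak_time for c in classifications.values() if c.is_two_peak
    ]
    if not seconds and latencies is None:
        raise ValueError("no two-peak neurons and no latencies to summarize")
    out = {
        "n_two_peak": len(seconds),
        "n_total": len(classifications),
        "first_peak_times": np.array(firsts),
        "second_peak_times": np.array(seconds),
        "median_first": float(np.median(firsts)) if firsts else float("nan"),
        "median_second": float(np.median(seconds)) if seconds else float("nan"),
    }
    if latencies is not None:
        vals = np.array(list(latencies.values()), dtype=float)
        if vals.size == 0:
            raise ValueError("empty latency group")
        out["latencies"] = vals
        out["median_latency"] = float(np.median(vals))
    return out
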