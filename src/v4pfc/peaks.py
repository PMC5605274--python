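"""Classification of neurons as having one vs two transient response peaks.

The procedure mirrors the screening logic used on the recorded data: build a
smoothed average PSTH of preferred-shape responses over occlusion levels that
drive the neuron at >= 33% of its unoccluded maximum, find local maxima by
zero crossings of the first difference within 300 ms of stimulus onset,
reject small peaks (< 50% of the first transient) and shallow modulations
(trough-to-peak ratio < 15%), and finally require a significant paired
increase of single-trial spike counts at the surviving peak relative to its
preceding trough (30 ms windows, Bonferroni-corrected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .analysis import DEFAULT_SIGMA, Psth, condition_psth, preferred_shape
from .session import SessionData


@dataclass
class PeakFinderConfig:
    """Thresholds and windows of the two-peak classification."""

    height_threshold: float = 0.50      # min peak height / first-transient height
    modulation_threshold: float = 0.15  # min (peak - trough) / peak
    inclusion_threshold: float = 0.33   # min level response / unoccluded max
    test_half_width: float = 15.0       # 30 ms count windows
    alpha: float = 0.05
    smoothing_sigma: float = DEFAULT_SIGMA
    search_window: tuple[float, float] = (0.0, 300.0)
    # Bonferroni denominator: "tested" = number of candidates beyond the
    # first transient subjected to the t-test
    bonferroni: str = "tested"


@dataclass
class PeakCandidate:
    peak_time: float
    peak_height: float
    trough_time: float
    trough_height: float

    def __post_init__(self) -> None:
        if self.trough_time >= self.peak_time:
            raise ValueError("trough must precede the peak")

    @property
    def modulation_ratio(self) -> float:
        if self.peak_height <= 0:
            return 0.0
        return (self.peak_height - self.trough_height) / self.peak_height


@dataclass
class RejectedCandidate:
    candidate: PeakCandidate
    reason: str
    p_value: float | None = None


@dataclass
class TwoPeakClassification:
    verdict: str  # "two_peak" | "not_two_peak"
    first_peak_time: float | None
    second_peak_time: float | None
    second_peak_p: float | None
    candidates: list[PeakCandidate]
    rejected: list[RejectedCandidate]
    included_levels: list[float]
    config: PeakFinderConfig

    @property
    def is_two_peak(self) -> bool:
        return self.verdict == "two_peak"


class UnclassifiableNeuron(ValueError):
    """No occlusion level passes the inclusion rule (e.g. a silent neuron)."""


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def inclusion_levels(
    session: SessionData,
    preferred: int,
    cfg: PeakFinderConfig | None = None,
) -> list[float]:
    """Occlusion levels driving the neuron at >= 33% of the unoccluded max.

    The response of each level is measured as the maximum of its smoothed
    preferred-shape PSTH over the test epoch.
    """
    cfg = cfg or PeakFinderConfig()
    if 100.0 not in session.levels:
        raise ValueError("inclusion rule needs the unoccluded condition")
    peak_by_level = {}
    for c in session.levels:
        p = condition_psth(session, preferred, c, sigma=cfg.smoothing_sigma)
        in_epoch = (p.time >= 0.0) & (p.time <= 600.0)
        peak_by_level[c] = float(p.rate[in_epoch].max())
    ref = peak_by_level[100.0]
    included = [c for c in session.levels if peak_by_level[c] >= cfg.inclusion_threshold * ref]
    if ref <= 0 or not included:
        raise UnclassifiableNeuron(
            f"session {session.neuron_id}: no occlusion level meets the "
            f"{cfg.inclusion_threshold:.0%} inclusion rule"
        )
    return included


def inclusion_average_psth(
    session: SessionData,
    preferred: int | None = None,
    cfg: PeakFinderConfig | None = None,
) -> tuple[Psth, list[float]]:
    """Average smoothed preferred-shape PSTH over the qualifying levels."""
    cfg = cfg or PeakFinderConfig()
    if preferred is None:
        preferred = preferred_shape(session)
    included = inclusion_levels(session, preferred, cfg)
    curves = [
        condition_psth(session, preferred, c, sigma=cfg.smoothing_sigma)
        for c in included
    ]
    avg = Psth(
        time=curves[0].time,
        rate=np.mean([p.rate for p in curves], axis=0),
        sigma=cfg.smoothing_sigma,
        n_trials=sum(p.n_trials for p in curves),
        label=f"inclusion-average (shape {preferred}, {len(included)} levels)",
    )
    return avg, included


def candidate_peaks(
    p: Psth, search_window: tuple[float, float] = (0.0, 300.0)
) -> list[PeakCandidate]:
    """Local maxima of the smoothed PSTH by sign change of the first difference.

    Each peak inside ``search_window`` (ms after stimulus onset) is paired
    with the minimum of the PSTH between the previous peak (or stimulus
    onset) and the peak itself.  Plateau ties break to the earliest sample.
    """
    t, r = p.time, p.rate
    d = np.diff(r)
    sign = np.sign(d)
    # zero-crossing + -> - marks a local maximum; propagate through plateaus
    nonzero = sign != 0
    filled = sign.copy()
    last = 0.0
    for i in range(filled.size):  # carry the last nonzero slope through flats
        if nonzero[i]:
            last = filled[i]
        else:
            filled[i] = last
    is_peak = np.where((filled[:-1] > 0) & (filled[1:] < 0))[0] + 1
    lo, hi = search_window
    onset_idx = int(np.searchsorted(t, 0.0))
    out: list[PeakCandidate] = []
    prev_peak_idx = onset_idx
    for idx in is_peak:
        if t[idx] <= lo or t[idx] > hi:
            if t[idx] > hi:
                break
            prev_peak_idx = max(prev_peak_idx, idx)
            continue
        if r[idx] <= 0.0:  # numerical ripple on a silent stretch
            prev_peak_idx = idx
            continue
        seg = r[prev_peak_idx : idx + 1]
        tr_rel = int(np.argmin(seg))
        tr_idx = prev_peak_idx + tr_rel
        if tr_idx >= idx:  # no preceding trough (peak at the window edge)
            prev_peak_idx = idx
            continue
        out.append(
            PeakCandidate(
                peak_time=float(t[idx]),
                peak_height=float(r[idx]),
                trough_time=float(t[tr_idx]),
                trough_height=float(r[tr_idx]),
            )
        )
        prev_peak_idx = idx
    return out


def apply_rejection_rules(
    candidates: list[PeakCandidate], cfg: PeakFinderConfig | None = None
) -> tuple[list[PeakCandidate], list[RejectedCandidate]]:
    """Drop small peaks and shallow modulations.

    The first transient anchors the height rule: it is the earliest
    candidate whose height reaches ``height_threshold`` of the largest
    candidate (so small pre-transient baseline ripples cannot anchor the
    comparison).  Ripples before the first transient are discarded; the
    first transient itself is never rejected.
    """
    cfg = cfg or PeakFinderConfig()
    if not candidates:
        return [], []
    tallest = max(c.peak_height for c in candidates)
    anchor = next(
        i
        for i, c in enumerate(candidates)
        if c.peak_height >= cfg.height_threshold * tallest
    )
    rejected = [
        RejectedCandidate(c, "pre_transient_ripple") for c in candidates[:anchor]
    ]
    first = candidates[anchor]
    kept = [first]
    for cand in candidates[anchor + 1 :]:
        if cand.peak_height < cfg.height_threshold * first.peak_height:
            rejected.append(RejectedCandidate(cand, "below_height_threshold"))
        elif cand.modulation_ratio < cfg.modulation_threshold:
            rejected.append(RejectedCandidate(cand, "below_modulation_threshold"))
        else:
            kept.append(cand)
    return kept, rejected


def peak_significance(
    spike_trains: list[np.ndarray],
    peak_time: float,
    trough_time: float,
    half_width: float = 15.0,
) -> float:
    """Paired t-test p-value: per-trial counts at the peak vs preceding trough."""
    if len(spike_trains) < 2:
        raise ValueError("peak_significance requires at least 2 trials")
    pk = np.array(
        [
            np.searchsorted(st, peak_time + half_width)
            - np.searchsorted(st, peak_time - half_width)
            for st in spike_trains
        ],
        dtype=float,
    )
    tr = np.array(
        [
            np.searchsorted(st, trough_time + half_width)
            - np.searchsorted(st, trough_time - half_width)
            for st in spike_trains
        ],
        dtype=float,
    )
    diffs = pk - tr
    if np.allclose(diffs.std(), 0.0):
        return 1.0
    _, p = stats.ttest_rel(pk, tr)
    return float(p)


def classify_two_peak(
    session: SessionData,
    preferred: int | None = None,
    cfg: PeakFinderConfig | None = None,
) -> TwoPeakClassification:
    """Full two-peak verdict for one session.

    A neuron is ``two_peak`` iff at least one candidate beyond the first
    transient survives the height and modulation rules *and* shows a
    significant paired count increase over its preceding trough (one-sided
    requirement via the sign of the mean difference, alpha Bonferroni-
    corrected over the number of tested candidates).  When several survive,
    the largest is reported as the second peak.
    """
    cfg = cfg or PeakFinderConfig()
    if preferred is None:
        preferred = preferred_shape(session)
    avg, included = inclusion_average_psth(session, preferred, cfg)
    cands = candidate_peaks(avg, cfg.search_window)
    kept, rejected = apply_rejection_rules(cands, cfg)
    first_time = kept[0].peak_time if kept else None

    tested = kept[1:]
    n_tests = max(len(tested), 1)
    alpha = cfg.alpha / n_tests if cfg.bonferroni == "tested" else cfg.alpha
    trains = [
        tr.spike_times
        for tr in session.trials(shape=preferred, levels=included)
    ]
    significant: list[tuple[PeakCandidate, float]] = []
    for cand in tested:
        p = peak_significance(trains, cand.peak_time, cand.trough_time, cfg.test_half_width)
        mean_rise = np.mean(
            [
                (np.searchsorted(st, cand.peak_time + cfg.test_half_width)
                 - np.searchsorted(st, cand.peak_time - cfg.test_half_width))
                - (np.searchsorted(st, cand.trough_time + cfg.test_half_width)
                   - np.searchsorted(st, cand.trough_time - cfg.test_half_width))
                for st in trains
            ]
        )
        if p < alpha and mean_rise > 0:
            significant.append((cand, p))
        else:
            rejected.append(RejectedCandidate(cand, "not_significant", p_value=p))

    if significant:
        best, best_p = max(significant, key=lambda cp: cp[0].peak_height)
        return TwoPeakClassification(
            verdict="two_peak",
            first_peak_time=first_time,
            second_peak_time=best.peak_time,
            second_peak_p=best_p,
            candidates=kept,
            rejected=rejected,
            included_levels=included,
            config=cfg,
        )
    return TwoPeakClassification(
        verdict="not_two_peak",
        first_peak_time=first_time,
        second_peak_time=None,
        second_peak_p=None,
        candidates=kept,
        rejected=rejected,
        included_levels=included,
        config=cfg,
    )


def rate_profile_peaks(
    time: np.ndarray,
    rate: np.ndarray,
    cfg: PeakFinderConfig | None = None,
) -> list[PeakCandidate]:
    """Height/modulation-screened peaks of a deterministic rate profile.

    Convenience entry point for noise-free model trajectories (no trial
    structure, hence no significance test).  ``smoothing_sigma`` in the
    config applies in grid units of ``time``.
    """
    cfg = cfg or PeakFinderConfig()
    time = np.asarray(time, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if cfg.smoothing_sigma > 0:
        from scipy.ndimage import gaussian_filter1d

        dt = time[1] - time[0]
        rate = gaussian_filter1d(rate, cfg.smoothing_sigma / dt, mode="constant")
    p = Psth(time=time, rate=rate, sigma=cfg.smoothing_sigma, n_trials=0)
    cands = candidate_peaks(p, cfg.search_window)
    kept, _ = apply_rejection_rules(cands, cfg)
    return kept
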