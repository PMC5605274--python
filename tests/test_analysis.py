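"""Tests for the per-neuron analysis operations."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import v4pfc as v
from conftest import constant_rate_session
from v4pfc.analysis import psth, roc_area, two_factor_anova


def brute_force_roc(x, y) -> float:
    """Independent oracle: P(X > Y) + 0.5 P(X = Y) over all cross-pairs."""
    wins = ties = 0
    for a, b in itertools.product(x, y):
        if a > b:
            wins += 1
        elif a == b:
            ties += 1
    return (wins + 0.5 * ties) / (len(x) * len(y))


def anova_oracle_balanced(cells: dict) -> dict:
    """Closed-form two-way ANOVA F statistics for a balanced design.

    ``cells`` maps (a, b) -> list of replicates, every cell equal size.
    """
    a_levels = sorted({a for a, _ in cells})
    b_levels = sorted({b for _, b in cells})
    n = len(next(iter(cells.values())))
    allvals = np.concatenate([np.asarray(cells[k], float) for k in sorted(cells)])
    grand = allvals.mean()
    mean_a = {a: np.mean([x for (aa, b) in cells for x in cells[(aa, b)] if aa == a]) for a in a_levels}
    mean_b = {b: np.mean([x for (a, bb) in cells for x in cells[(a, bb)] if bb == b]) for b in b_levels}
    ss_a = n * len(b_levels) * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (np.mean(cells[(a, b)]) - mean_a[a] - mean_b[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_err = sum(
        np.sum((np.asarray(cells[(a, b)], float) - np.mean(cells[(a, b)])) ** 2)
        for a in a_levels
        for b in b_levels
    )
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = len(allvals) - len(a_levels) * len(b_levels)
    ms_err = ss_err / df_err
    return {
        "A": (ss_a / df_a) / ms_err,
        "B": (ss_b / df_b) / ms_err,
        "AB": (ss_ab / df_ab) / ms_err,
    }


class TestPsth:
    def test_empty_trial_list_rejected(self):
        with pytest.raises(ValueError):
            psth([])

    def test_no_spikes_gives_zero_rate(self):
        p = psth([np.empty(0), np.empty(0)])
        assert np.all(p.rate == 0.0)

    def test_single_spike_smoothed_to_unit_mass_bump(self):
        p = psth([np.array([100.0])], sigma=10.0)
        # mass preservation: integral of the rate = 1 count
        mass = np.sum(p.rate) * 1e-3  # 1 ms bins
        assert mass == pytest.approx(1.0, rel=1e-3)
        assert abs(p.time[np.argmax(p.rate)] - 100.0) <= 1.0

    def test_constant_rate_recovered(self):
        t = np.array([-300.0, 700.0])
        n, rate = 200, 30.0
        trains = v.sample_spike_trains(t, np.array([rate, rate]), n, 3)
        p = psth(trains, sigma=10.0)
        interior = (p.time > -250.0) & (p.time < 650.0)
        # per-point sd after Gaussian smoothing: sqrt(rate/(n dt)) * sqrt(sum k^2)
        sd = np.sqrt(rate / (n * 1e-3)) * np.sqrt(1.0 / (2.0 * np.sqrt(np.pi) * 10.0))
        err = p.rate[interior] - rate
        assert abs(err.mean()) < 0.1 * rate  # estimate within 10% of the truth
        assert np.max(np.abs(err)) < 5.0 * sd  # no pointwise outliers


class TestVisualResponsiveness:
    def test_strong_response_detected(self):
        # 10 sp/s baseline vs 40 sp/s response: clearly significant at n=20
        t = np.arange(-300.0, 701.0, 1.0)
        rate = np.where((t >= 60.0) & (t < 260.0), 40.0, 10.0)
        hits = 0
        for seed in range(20):
            trains = v.sample_spike_trains(t, rate, 20, seed)
            trials = [v.Trial(st, shape=1, pct_visible=100.0) for st in trains]
            s = v.SessionData(
                area="vlPFC",
                neuron_id="x",
                conditions={(1, 100.0): v.SpikeTrainSet(trials, 1, 100.0)},
            )
            hits += v.visual_responsiveness(s).significant
        assert hits == 20

    def test_null_rate_rarely_significant(self):
        hits = sum(
            v.visual_responsiveness(constant_rate_session(seed=seed)).significant
            for seed in range(50)
        )
        assert hits <= 3  # alpha = 0.01

    def test_degenerate_zero_variance(self):
        trials = [v.Trial(np.empty(0), shape=1, pct_visible=100.0) for _ in range(10)]
        s = v.SessionData(
            area="V4", neuron_id="silent",
            conditions={(1, 100.0): v.SpikeTrainSet(trials, 1, 100.0)},
        )
        res = v.visual_responsiveness(s)
        assert res.p_value == 1.0 and not res.significant


class TestTwoFactorAnova:
    def test_matches_closed_form_oracle_on_balanced_table(self):
        rng = np.random.default_rng(11)
        cells = {
            (a, b): list(rng.poisson(8 + 3 * a + 2 * b, size=6))
            for a in (0, 1)
            for b in (0, 1, 2)
        }
        counts, fa, fb = [], [], []
        for (a, b), vals in cells.items():
            counts.extend(vals)
            fa.extend([a] * len(vals))
            fb.extend([b] * len(vals))
        res = two_factor_anova(np.array(counts), np.array(fa), np.array(fb), ("A", "B"))
        oracle = anova_oracle_balanced(cells)
        assert res.f_values["A"] == pytest.approx(oracle["A"], rel=1e-9)
        assert res.f_values["B"] == pytest.approx(oracle["B"], rel=1e-9)
        assert res.f_values["interaction"] == pytest.approx(oracle["AB"], rel=1e-9)

    def test_empty_cell_named_in_error(self):
        counts = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        fa = np.array([0, 0, 0, 0, 1, 1])
        fb = np.array([0, 0, 1, 1, 0, 0])  # cell (1, 1) empty
        with pytest.raises(ValueError, match="1"):
            two_factor_anova(counts, fa, fb)

    def test_injected_occlusion_effect_detected(self, double_session):
        res = v.two_factor_anova(
            np.array([tr.count(80.0, 230.0) for tr in double_session.trials()]),
            np.array([tr.shape for tr in double_session.trials()]),
            np.array([tr.pct_visible for tr in double_session.trials()]),
        )
        assert res.p_values["occlusion"] < 0.05
        assert res.p_values["shape"] < 0.05


class TestPreferredShape:
    def test_dominant_shape_wins(self):
        s = constant_rate_session(rate_hz=30.0, rate_hz_2=15.0, seed=4)
        assert v.preferred_shape(s) == 1

    def test_vlpfc_rule_uses_occluded_levels_only(self, vlpfc_session):
        pref = v.preferred_shape(vlpfc_session)
        assert pref == vlpfc_session.ground_truth["preferred_shape"]

    def test_exact_tie_breaks_to_shape_one_with_warning(self):
        trials1 = [v.Trial(np.array([10.0]), 1, 100.0) for _ in range(5)]
        trials2 = [v.Trial(np.array([20.0]), 2, 100.0) for _ in range(5)]
        s = v.SessionData(
            area="V4", neuron_id="tie",
            conditions={
                (1, 100.0): v.SpikeTrainSet(trials1, 1, 100.0),
                (2, 100.0): v.SpikeTrainSet(trials2, 2, 100.0),
            },
        )
        with pytest.warns(UserWarning, match="tie"):
            assert v.preferred_shape(s) == 1


class TestRocArea:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([3, 3, 3], [3, 3, 3], 0.5),
            ([5, 6, 7], [0, 1, 2], 1.0),
            ([1, 2], [1, 2], 0.5),  # 1 win, 2 ties, 1 loss of 4 pairs
        ],
    )
    def test_boundary_values(self, x, y, expected):
        assert roc_area(x, y) == expected
        assert brute_force_roc(x, y) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_area([], [1, 2])

    @given(
        x=st.lists(st.integers(0, 10), min_size=1, max_size=12),
        y=st.lists(st.integers(0, 10), min_size=1, max_size=12),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_and_complement(self, x, y):
        a = roc_area(x, y)
        assert a == pytest.approx(brute_force_roc(x, y), abs=1e-12)
        assert a + roc_area(y, x) == pytest.approx(1.0, abs=1e-12)

    @given(x=st.lists(st.integers(0, 20), min_size=2, max_size=10),
           y=st.lists(st.integers(0, 20), min_size=2, max_size=10))
    @settings(deadline=None, max_examples=50)
    def test_invariance_under_monotone_transform(self, x, y):
        f = lambda arr: [3.0 * val**2 + 1.0 for val in arr]  # strictly monotone on counts
        assert roc_area(x, y) == pytest.approx(roc_area(f(x), f(y)), abs=1e-12)


class TestSelectivityTimecourse:
    def test_unselective_neuron_near_half(self):
        s = constant_rate_session(rate_hz=20.0, n_trials=15, seed=8)
        tc = v.roc_selectivity_timecourse(s, preferred=1, occlusion=100.0)
        assert np.all(tc.auc >= 0.0) and np.all(tc.auc <= 1.0)
        assert abs(tc.auc.mean() - 0.5) < 0.1

    def test_sliding_roc_matches_brute_force(self, double_session):
        pref = v.preferred_shape(double_session)
        tc = v.roc_selectivity_timecourse(double_session, pref, occlusion="pooled_occluded")
        occluded = [c for c in double_session.levels if c < 100.0]
        pref_trains = [t.spike_times for t in double_session.trials(shape=pref, levels=occluded)]
        non_trains = [
            t.spike_times
            for t in double_session.trials(shape=2 if pref == 1 else 1, levels=occluded)
        ]
        w = tc.window / 2.0
        for i in [50, 150, 300, 500]:
            t0 = tc.time[i]
            cx = [np.sum((st >= t0 - w) & (st < t0 + w)) for st in pref_trains]
            cy = [np.sum((st >= t0 - w) & (st < t0 + w)) for st in non_trains]
            assert tc.auc[i] == pytest.approx(brute_force_roc(cx, cy), abs=1e-12)

    def test_late_selectivity_peaks_near_second_transient(self):
        # template selective only at the second peak: time of max selectivity
        # (pooled occluded) lands near the construction's second-peak time
        tmpl_args = dict(
            profile="v4_double", pref_ratio=1.0, peak2_time=214.0, peak2_amp=50.0
        )
        t_grid = np.arange(-300.0, 701.0, 1.0)
        rng = np.random.default_rng(21)
        conditions = {}
        for shape in (1, 2):
            for c in (100.0, 82.0, 72.0):
                tmpl = v.RateTemplate(
                    **{**tmpl_args, "peak2_amp": 50.0 if shape == 1 else 10.0}
                )
                rate = v.template_rate(tmpl, shape, c, t_grid, preferred_shape=shape)
                trains = v.sample_spike_trains(t_grid, rate, 20, rng)
                trials = [v.Trial(st, shape, c) for st in trains]
                conditions[(shape, c)] = v.SpikeTrainSet(trials, shape, c)
        s = v.SessionData(area="V4", neuron_id="late-sel", conditions=conditions)
        tc = v.roc_selectivity_timecourse(s, preferred=1, occlusion="pooled_occluded")
        t_max = tc.time[np.argmax(tc.auc)]
        # 75 ms centered window smears the onset by up to half a window
        assert 214.0 - 50.0 <= t_max <= 214.0 + 50.0


class TestPeakLatency:
    def test_single_bump_recovered(self):
        t_grid = np.arange(-300.0, 701.0, 1.0)
        rate = 5.0 + 60.0 * np.exp(-((t_grid - 120.0) ** 2) / (2 * 15.0**2))
        trains = v.sample_spike_trains(t_grid, rate, 100, 31)
        trials = [v.Trial(st, 1, 100.0) for st in trains]
        s = v.SessionData(
            area="V4", neuron_id="bump",
            conditions={(1, 100.0): v.SpikeTrainSet(trials, 1, 100.0)},
        )
        assert abs(v.peak_latency(s) - 120.0) <= 3.0

    def test_early_bump_clipped_to_search_start(self):
        t_grid = np.arange(-300.0, 701.0, 1.0)
        rate = 2.0 + 80.0 * np.exp(-((t_grid - 30.0) ** 2) / (2 * 8.0**2))
        trains = v.sample_spike_trains(t_grid, rate, 100, 32)
        trials = [v.Trial(st, 1, 100.0) for st in trains]
        s = v.SessionData(
            area="V4", neuron_id="early",
            conditions={(1, 100.0): v.SpikeTrainSet(trials, 1, 100.0)},
        )
        lat = v.peak_latency(s)
        assert 50.0 <= lat <= 60.0  # forced to the search boundary region

    def test_vlpfc_template_latency(self, vlpfc_session):
        pref = vlpfc_session.ground_truth["preferred_shape"]
        lat = v.peak_latency(vlpfc_session, shape=pref)
        assert abs(lat - vlpfc_session.ground_truth["peak1_time"]) <= 5.0


class TestOcclusionSlope:
    @staticmethod
    def _linear_session(slope_sign: float, seed: int = 41) -> v.SessionData:
        t_grid = np.array([-300.0, 700.0])
        rng = np.random.default_rng(seed)
        conditions = {}
        for c in (100.0, 90.0, 82.0, 59.0):
            base = 30.0 + slope_sign * 0.2 * (c - 80.0)
            for shape in (1, 2):
                trains = v.sample_spike_trains(t_grid, np.full(2, base), 200, rng)
                trials = [v.Trial(st, shape, c) for st in trains]
                conditions[(shape, c)] = v.SpikeTrainSet(trials, shape, c)
        return v.SessionData(area="vlPFC", neuron_id="lin", conditions=conditions)

    def test_occlusion_preferring_slope_negative(self):
        res = v.occlusion_slope(self._linear_session(-1.0))
        assert res.slope < 0.0 and res.p_value < 0.05

    def test_flat_response_slope_near_zero(self):
        res = v.occlusion_slope(self._linear_session(0.0))
        assert abs(res.slope) < 0.02

    def test_requires_three_levels(self):
        s = constant_rate_session()
        with pytest.raises(ValueError):
            v.occlusion_slope(s)


class TestWindowedMeasures:
    def test_flat_rate_gives_zero_peak_response(self):
        rate_hz, n = 25.0, 100
        s = constant_rate_session(rate_hz=rate_hz, n_trials=n, seed=51)
        resp = v.peak_window_response(s, center_ms=100.0, shape=1)
        # sd of the difference of two 30 ms window rate means
        sd = np.sqrt(2.0 * rate_hz / 0.03 / n)
        assert abs(resp[100.0]) < 3.0 * sd

    def test_double_template_tuning_signatures(self, double_session):
        pref = v.preferred_shape(double_session)
        gt = double_session.ground_truth
        first = v.peak_window_response(double_session, gt["peak1_time"], shape=pref)
        second = v.peak_window_response(double_session, gt["peak2_time"], shape=pref)
        levels = sorted(double_session.levels)  # increasing c
        # first peak: response grows with visible area
        assert first[levels[-1]] > first[levels[0]]
        # second peak: maximal at intermediate occlusion
        best = max(second, key=second.get)
        assert best not in (levels[-1],)

    def test_window_out_of_range_rejected(self, double_session):
        with pytest.raises(ValueError):
            v.peak_window_response(double_session, center_ms=695.0)

    @staticmethod
    def _unjittered_session(profile: str, seed: int) -> v.SessionData:
        # fixed peak times at the template defaults (the fixed 69-99 /
        # 199-229 ms windows presume peaks near 84 / 214 ms)
        tmpl = v.RateTemplate(
            profile=profile, peak2_time=214.0 if profile == "v4_double" else None
        )
        t_grid = np.arange(-300.0, 701.0, 1.0)
        rng = np.random.default_rng(seed)
        conditions = {}
        for shape in (1, 2):
            for c in (100.0, 90.0, 82.0, 72.0, 59.0):
                rate = v.template_rate(tmpl, shape, c, t_grid)
                trains = v.sample_spike_trains(t_grid, rate, 20, rng)
                trials = [v.Trial(st, shape, c) for st in trains]
                conditions[(shape, c)] = v.SpikeTrainSet(trials, shape, c)
        return v.SessionData(area="V4", neuron_id=profile, conditions=conditions)

    def test_fixed_window_difference_signs(self):
        d_double = v.fixed_window_difference(self._unjittered_session("v4_double", 61))
        d_single = v.fixed_window_difference(self._unjittered_session("v4_single", 62))
        # two-peak profile: positive late-minus-early at intermediate occlusion
        assert max(d_double[c] for c in (90.0, 82.0, 72.0)) > 0.0
        # inverted U: smaller at the extremes than at the best mid level
        assert d_double[max(d_double, key=d_double.get)] > d_double[100.0]
        # single-transient profile: flat-to-negative everywhere
        assert all(val <= 0.05 for val in d_single.values())

    def test_normalization_bounds_difference(self, double_session):
        d = v.fixed_window_difference(double_session)
        assert all(-1.0 <= val <= 1.0 for val in d.values())
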