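import numpy as np
import pytest

import v4pfc as v


@pytest.fixture(scope="session")
def coarse_params():
    """Reference parameters on a coarser Euler grid for fast unit tests.

    dt = 0.05 ms stays well inside the stability bound (min tau / 10) and
    was checked to match the dt = 0.01 ms trajectories to < 0.1 spikes/s.
    """
    return v.default_params(dt=0.05)


@pytest.fixture(scope="session")
def full_trajectory(coarse_params):
    """Preferred shape at 82% visible area, noise off."""
    return v.simulate_trial(coarse_params, v.StimulusCondition(1, 82.0))


@pytest.fixture(scope="session")
def double_session():
    """One synthetic neuron with a ground-truth two-peak profile."""
    spec = v.PopulationSpec(
        n_neurons=1, seed=101, mixture={"v4_double": 1.0}, n_trials=20
    )
    return v.generate_session(spec, 0)


@pytest.fixture(scope="session")
def single_session():
    spec = v.PopulationSpec(
        n_neurons=1, seed=102, mixture={"v4_single": 1.0}, n_trials=20
    )
    return v.generate_session(spec, 0)


@pytest.fixture(scope="session")
def vlpfc_session():
    spec = v.PopulationSpec(
        n_neurons=1, seed=103, area="vlPFC", mixture={"vlpfc_occlusion": 1.0},
        n_trials=20,
    )
    return v.generate_session(spec, 0)


def constant_rate_session(
    rate_hz: float = 15.0,
    n_trials: int = 20,
    seed: int = 0,
    area: str = "V4",
    rate_hz_2: float | None = None,
) -> v.SessionData:
    """Minimal one-level session with constant firing (both shapes).

    ``rate_hz_2`` sets a different rate for shape 2 (defaults to shape 1's).
    """
    rng = np.random.default_rng(seed)
    t_grid = np.array([-300.0, 700.0])
    conditions = {}
    for shape, r in ((1, rate_hz), (2, rate_hz_2 if rate_hz_2 is not None else rate_hz)):
        trains = v.sample_spike_trains(t_grid, np.full(2, r), n_trials, rng)
        trials = [
            v.Trial(st, shape=shape, pct_visible=100.0, match=(k % 2 == 0))
            for k, st in enumerate(trains)
        ]
        conditions[(shape, 100.0)] = v.SpikeTrainSet(trials, shape=shape, pct_visible=100.0)
    return v.SessionData(area=area, neuron_id=f"const-{seed}", conditions=conditions)
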