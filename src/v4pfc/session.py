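"""Trial-structured spike-train containers.

A recording session holds, for one neuron, spike times aligned to test-
stimulus onset (window -300 to +700 ms) for every (shape, % visible area)
condition, tagged with the cortical area (V4 or vlPFC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

DEFAULT_WINDOW = (-300.0, 700.0)

#: level-count ranges per cortical area (inclusive)
LEVEL_RANGE = {"V4": (4, 9), "vlPFC": (5, 6)}

MIN_TRIALS = 7


@dataclass
class Trial:
    """Spike times (ms, re test onset) plus the trial's condition labels."""

    spike_times: np.ndarray
    shape: int
    pct_visible: float
    match: bool = True
    correct: bool = True

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def count(self, t0: float, t1: float) -> int:
        """Spike count in [t0, t1) ms."""
        return int(
            np.searchsorted(self.spike_times, t1) - np.searchsorted(self.spike_times, t0)
        )

    def rate(self, t0: float, t1: float) -> float:
        """Mean firing rate (spikes/s) in [t0, t1) ms."""
        return self.count(t0, t1) / (t1 - t0) * 1000.0


@dataclass
class SpikeTrainSet:
    """All trials of one neuron under one (shape, occlusion) condition."""

    trials: list[Trial]
    shape: int
    pct_visible: float
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        t0, t1 = self.window
        for trial in self.trials:
            st = trial.spike_times
            if st.size and (np.any(np.diff(st) < 0)):
                raise ValueError("spike times must be sorted")
            if st.size and (st[0] < t0 or st[-1] > t1):
                raise ValueError(
                    f"spike times outside window [{t0}, {t1}] ms"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def spike_arrays(self) -> list[np.ndarray]:
        return [tr.spike_times for tr in self.trials]

    def counts(self, t0: float, t1: float) -> np.ndarray:
        return np.array([tr.count(t0, t1) for tr in self.trials])


@dataclass
class SessionData:
    """One neuron's full session across (shape, occlusion) conditions."""

    area: str
    neuron_id: str
    conditions: dict[tuple[int, float], SpikeTrainSet]
    ground_truth: dict | None = None
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.area not in ("V4", "vlPFC"):
            raise ValueError(f"area must be 'V4' or 'vlPFC', got {self.area!r}")

    # -- accessors -------------------------------------------------------
    @property
    def levels(self) -> list[float]:
        """Occlusion levels present, in decreasing % visible area."""
        return sorted({c for (_, c) in self.conditions}, reverse=True)

    @property
    def shapes(self) -> list[int]:
        return sorted({s for (s, _) in self.conditions})

    def trains(self, shape: int, pct_visible: float) -> SpikeTrainSet:
        return self.conditions[(shape, pct_visible)]

    def trials(
        self,
        shape: int | None = None,
        levels: Iterable[float] | None = None,
    ) -> list[Trial]:
        """All trials matching the given shape and/or occlusion levels."""
        sel = None if levels is None else set(levels)
        out: list[Trial] = []
        for (s, c), sts in self.conditions.items():
            if shape is not None and s != shape:
                continue
            if sel is not None and c not in sel:
                continue
            out.extend(sts.trials)
        return out

    def iter_condition_sets(self) -> Iterator[tuple[tuple[int, float], SpikeTrainSet]]:
        return iter(sorted(self.conditions.items()))

    # -- validation ------------------------------------------------------
    def validate(self, min_trials: int = MIN_TRIALS) -> None:
        """Enforce the session invariants used throughout the pipeline."""
        if not self.conditions:
            raise ValueError(f"session {self.neuron_id}: no conditions")
        if 100.0 not in self.levels:
            raise ValueError(
                f"session {self.neuron_id}: missing the unoccluded (100%) condition"
            )
        lo, hi = LEVEL_RANGE[self.area]
        if not (lo <= len(self.levels) <= hi):
            raise ValueError(
                f"session {self.neuron_id}: {len(self.levels)} occlusion levels; "
                f"{self.area} sessions use {lo}-{hi}"
            )
        for (s, c), sts in self.conditions.items():
            if sts.n_trials < min_trials:
                raise ValueError(
                    f"session {self.neuron_id}: condition (shape={s}, c={c}) has "
                    f"{sts.n_trials} trials; at least {min_trials} required"
                )
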