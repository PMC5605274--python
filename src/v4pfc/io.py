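"""Readers and writers for sessions, trajectories and report tables.

All formats are plain text: comma-separated CSV (UTF-8, header row, '.'
decimal, times in ms as floats) plus JSON sidecars carrying metadata
sufficient to re-run the producing command.
"""

from __future__ import annotations

import dataclasses
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .model import RateTrajectory
from .params import NetworkParams, StimulusCondition
from .session import SessionData, SpikeTrainSet, Trial


def _pkg_version() -> str:
    try:
        return version("v4pfc")
    except PackageNotFoundError:
        return "unknown"


def write_manifest(path: Path, command: str, seed=None, **extra) -> None:
    payload = {"command": command, "seed": seed, "package_version": _pkg_version()}
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: RateTrajectory, prefix: Path, include_drives: bool = True) -> None:
    """Write a simulated trial as ``<prefix>.csv`` + ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    traj.to_frame(include_drives=include_drives).to_csv(
        prefix.with_suffix(".csv"), index=False, float_format="%.17g"
    )
    meta = {
        "condition": {"shape_id": traj.condition.shape_id, "c": traj.condition.c},
        "params": traj.params.to_dict(),
        "diverged": traj.diverged,
        "package_version": _pkg_version(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_trajectory(prefix: Path) -> tuple[pd.DataFrame, dict]:
    prefix = Path(prefix)
    frame = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return frame, meta


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

def write_session(session: SessionData, directory: Path) -> None:
    """One session as three files: spikes CSV, trial-metadata CSV, JSON header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nid = session.neuron_id
    spike_rows = []
    trial_rows = []
    trial_id = 0
    for (shape, c), sts in session.iter_condition_sets():
        for trial in sts.trials:
            trial_rows.append(
                {
                    "trial_id": trial_id,
                    "shape": shape,
                    "pct_visible": c,
                    "match": trial.match,
                    "correct": trial.correct,
                }
            )
            for st in trial.spike_times:
                spike_rows.append(
                    {"neuron_id": nid, "trial_id": trial_id, "spike_time_ms": st}
                )
            trial_id += 1
    pd.DataFrame(
        spike_rows, columns=["neuron_id", "trial_id", "spike_time_ms"]
    ).to_csv(directory / f"{nid}.spikes.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        trial_rows, columns=["trial_id", "shape", "pct_visible", "match", "correct"]
    ).to_csv(directory / f"{nid}.trials.csv", index=False, float_format="%.17g")
    header = {
        "neuron_id": nid,
        "area": session.area,
        "levels": session.levels,
        "window": list(session.window),
        "ground_truth": session.ground_truth,
        "package_version": _pkg_version(),
    }
    (directory / f"{nid}.json").write_text(json.dumps(header, indent=2) + "\n")


def read_session(directory: Path, neuron_id: str) -> SessionData:
    directory = Path(directory)
    header = json.loads((directory / f"{neuron_id}.json").read_text())
    trials_df = pd.read_csv(
        directory / f"{neuron_id}.trials.csv", float_precision="round_trip"
    )
    spikes_df = pd.read_csv(
        directory / f"{neuron_id}.spikes.csv", float_precision="round_trip"
    )
    by_trial = {
        tid: grp["spike_time_ms"].to_numpy()
        for tid, grp in spikes_df.groupby("trial_id")
    }
    conditions: dict[tuple[int, float], list[Trial]] = {}
    for row in trials_df.itertuples(index=False):
        spikes = np.sort(by_trial.get(row.trial_id, np.empty(0)))
        key = (int(row.shape), float(row.pct_visible))
        conditions.setdefault(key, []).append(
            Trial(
                spikes,
                shape=int(row.shape),
                pct_visible=float(row.pct_visible),
                match=bool(row.match),
                correct=bool(row.correct),
            )
        )
    window = tuple(header["window"])
    sets = {
        key: SpikeTrainSet(trials, shape=key[0], pct_visible=key[1], window=window)
        for key, trials in conditions.items()
    }
    gt = header.get("ground_truth")
    return SessionData(
        area=header["area"],
        neuron_id=header["neuron_id"],
        conditions=sets,
        ground_truth=gt,
        window=window,
    )


def write_population(sessions: list[SessionData], directory: Path, seed=None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        write_session(s, directory)
    index = {"neuron_ids": [s.neuron_id for s in sessions]}
    (directory / "index.json").write_text(json.dumps(index, indent=2) + "\n")


def read_population(directory: Path) -> list[SessionData]:
    directory = Path(directory)
    index_path = directory / "index.json"
    if index_path.exists():
        ids = json.loads(index_path.read_text())["neuron_ids"]
    else:
        ids = sorted(p.stem for p in directory.glob("*.json") if p.name != "index.json")
    if not ids:
        raise ValueError(f"no sessions found in {directory}")
    return [read_session(directory, nid) for nid in ids]


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def classification_frame(classifications: dict) -> pd.DataFrame:
    """Two-peak verdicts as a tidy table (one row per neuron)."""
    rows = []
    for nid, cls in sorted(classifications.items()):
        cfg = cls.config
        rows.append(
            {
                "neuron_id": nid,
                "verdict": cls.verdict,
                "peak1_ms": cls.first_peak_time,
                "peak2_ms": cls.second_peak_time,
                "p_second": cls.second_peak_p,
                "height_threshold": cfg.height_threshold,
                "modulation_threshold": cfg.modulation_threshold,
                "inclusion_threshold": cfg.inclusion_threshold,
                "alpha": cfg.alpha,
            }
        )
    return pd.DataFrame(rows)
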