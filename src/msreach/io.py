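"""Plain-text trial and configuration I/O.

Each trial is one delimited table (columns ``time_s, eye_x_cm, eye_y_cm,
hand_x_cm, hand_y_cm, cursor_x_cm, cursor_y_cm``) on the 1000-Hz hand grid;
eye columns are populated only at the native 500-Hz instants (every other
row), cursor columns are empty when the cursor is invisible, and missing
samples are empty fields.  A JSON sidecar per trial stores the schedule,
condition, and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .preprocess import SampledSeries
from .types import (
    Condition,
    EventSchedule,
    GroundTruth,
    MicrosaccadeEvent,
    TrialRecord,
)

__all__ = ["write_trial", "read_trial", "write_dataset", "read_dataset",
           "load_config", "save_config"]


def write_trial(trial: TrialRecord, directory) -> Path:
    """Write one trial as <trial_id>.csv plus <trial_id>.json; returns the
    CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = trial.hand.n
    cols = {
        "time_s": trial.hand.t,
        "eye_x_cm": np.full(n, np.nan),
        "eye_y_cm": np.full(n, np.nan),
        "hand_x_cm": trial.hand.xy[:, 0],
        "hand_y_cm": trial.hand.xy[:, 1],
        "cursor_x_cm": np.full(n, np.nan),
        "cursor_y_cm": np.full(n, np.nan),
    }
    k = min(trial.gaze.n, (n + 1) // 2)
    cols["eye_x_cm"][: 2 * k : 2] = trial.gaze.xy[:k, 0]
    cols["eye_y_cm"][: 2 * k : 2] = trial.gaze.xy[:k, 1]
    if trial.cursor is not None:
        cols["cursor_x_cm"][:] = trial.cursor.xy[:, 0]
        cols["cursor_y_cm"][:] = trial.cursor.xy[:, 1]
    frame = pd.DataFrame(cols)
    csv_path = directory / f"{trial.trial_id}.csv"
    frame.to_csv(csv_path, index=False, float_format="%.6f", na_rep="")

    meta = {
        "trial_id": trial.trial_id,
        "participant": trial.participant,
        "schedule": {
            "condition": trial.schedule.condition.value,
            "t_show_target": trial.schedule.t_show_target,
            "t_go": trial.schedule.t_go,
            "t_trial_end": trial.schedule.t_trial_end,
            "post_cue_delay": trial.schedule.post_cue_delay,
            "cursor_move_duration": trial.schedule.cursor_move_duration,
        },
    }
    if trial.ground_truth is not None:
        gt = trial.ground_truth
        meta["ground_truth"] = {
            "injected_events": [dataclasses.asdict(e) for e in gt.injected_events],
            "true_hand_onset": gt.true_hand_onset,
            "true_hand_offset": gt.true_hand_offset,
            "reaction_time": gt.reaction_time,
            "rate_profile": gt.rate_profile,
            "violations": gt.violations,
        }
    with open(directory / f"{trial.trial_id}.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=float)
    return csv_path


def read_trial(csv_path) -> TrialRecord:
    """Reconstruct a :class:`TrialRecord` from its CSV + JSON sidecar."""
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    frame = pd.read_csv(csv_path)
    t = frame["time_s"].to_numpy()
    hand = SampledSeries(
        t, frame[["hand_x_cm", "hand_y_cm"]].to_numpy(), 1000.0
    )
    eye_rows = slice(0, None, 2)  # native 500-Hz instants
    gaze = SampledSeries(
        t[eye_rows], frame[["eye_x_cm", "eye_y_cm"]].to_numpy()[eye_rows], 500.0
    )
    cursor = None
    cxy = frame[["cursor_x_cm", "cursor_y_cm"]].to_numpy()
    if np.isfinite(cxy).any():
        cursor = SampledSeries(t, cxy, 1000.0)

    sched = meta["schedule"]
    schedule = EventSchedule(
        condition=Condition(sched["condition"]),
        t_show_target=sched["t_show_target"],
        t_go=sched["t_go"],
        t_trial_end=sched["t_trial_end"],
        post_cue_delay=sched.get("post_cue_delay", 0.3),
        cursor_move_duration=sched.get("cursor_move_duration"),
    )
    truth = None
    if "ground_truth" in meta:
        g = meta["ground_truth"]
        truth = GroundTruth(
            injected_events=[MicrosaccadeEvent(**e) for e in g["injected_events"]],
            true_hand_onset=g.get("true_hand_onset"),
            true_hand_offset=g.get("true_hand_offset"),
            reaction_time=g.get("reaction_time"),
            rate_profile=g.get("rate_profile", {}),
            violations=g.get("violations", []),
        )
    return TrialRecord(
        trial_id=meta["trial_id"],
        participant=meta["participant"],
        schedule=schedule,
        gaze=gaze,
        hand=hand,
        cursor=cursor,
        ground_truth=truth,
    )


def write_dataset(trials, directory) -> list[Path]:
    return [write_trial(trial, directory) for trial in trials]


def read_dataset(directory) -> list[TrialRecord]:
    paths = sorted(Path(directory).glob("*.csv"))
    return [read_trial(p) for p in paths]


def load_config(path) -> dict:
    """Load a YAML (or JSON) run-configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("configuration file must contain a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
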