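"""Serialization: HDF5 sessions, CSV event tables, JSON models, YAML configs."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .events import ActionEvent
from .simulate import GroundTruth, PlantedEvent, SessionData, SimConfig, StimTrialRecord

__all__ = [
    "save_session", "load_session",
    "events_to_frame", "save_events_csv", "load_events_csv",
    "save_ground_truth", "load_ground_truth",
    "save_decoder", "load_config", "save_config",
]

_STREAMS = ("force", "force_lateral", "touch", "lick_times", "emg", "frame_times",
            "fluorescence_raw", "fluorescence_neuropil")
_STIM_FIELDS = ("trial_index", "block", "trigger_identity", "pattern",
                "stim_onset_s", "stim_duration_s", "cross3g_s", "onset_s", "offset_s")


def save_session(session: SessionData, path):
    """Write a session as HDF5, one group per stream family."""
    with h5py.File(path, "w") as f:
        f.attrs.update(force_rate=session.force_rate, frame_rate=session.frame_rate,
                       duration_s=session.duration_s)
        g = f.create_group("streams")
        for name in _STREAMS:
            value = getattr(session, name)
            if value is not None:
                g.create_dataset(name, data=np.asarray(value))
        if session.celltype_labels is not None:
            g.create_dataset("celltype_labels",
                             data=np.asarray(session.celltype_labels, dtype="S3"))
        if session.stim_log is not None:
            rows = [{k: getattr(r, k) for k in _STIM_FIELDS} for r in session.stim_log]
            f.create_dataset("stim_log", data=json.dumps(rows, default=float))


def load_session(path) -> SessionData:
    with h5py.File(path, "r") as f:
        g = f["streams"]
        kwargs = {name: g[name][...] if name in g else None for name in _STREAMS}
        kwargs["touch"] = kwargs["touch"].astype(bool)
        celltype = (g["celltype_labels"][...].astype(str)
                    if "celltype_labels" in g else None)
        stim_log = None
        if "stim_log" in f:
            rows = json.loads(f["stim_log"][()])
            stim_log = [StimTrialRecord(**{**r, "trial_index": int(r["trial_index"]),
                                           "block": int(r["block"])}) for r in rows]
        return SessionData(
            force_rate=float(f.attrs["force_rate"]),
            frame_rate=float(f.attrs["frame_rate"]),
            duration_s=float(f.attrs["duration_s"]),
            celltype_labels=celltype, stim_log=stim_log, **kwargs,
        )


def events_to_frame(events) -> pd.DataFrame:
    """Event table, one row per event, times in seconds at 1 ms resolution."""
    rows = [dataclasses.asdict(e) for e in events]
    frame = pd.DataFrame(rows)
    for col in ("onset_s", "offset_s", "cross3g_s", "peak_s"):
        frame[col] = frame[col].round(3)
    return frame


def save_events_csv(events, path):
    events_to_frame(events).to_csv(path, index=False)


def load_events_csv(path):
    frame = pd.read_csv(path)
    return [ActionEvent(**{k: (None if pd.isna(v) and k.endswith("isolated") else v)
                           for k, v in row.items()})
            for row in frame.to_dict(orient="records")]


def save_ground_truth(truth: GroundTruth, path):
    payload = {
        "ensemble_membership": {str(k): v for k, v in truth.ensemble_membership.items()},
        "celltype": list(map(str, truth.celltype)),
        "planted_events": [dataclasses.asdict(e) for e in truth.planted_events],
        "timing_offsets": {str(k): v for k, v in truth.timing_offsets.items()},
        "stim_effect_g": truth.stim_effect_g,
        "stim_neural_effect": truth.stim_neural_effect,
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def load_ground_truth(path) -> GroundTruth:
    with open(path) as f:
        payload = json.load(f)
    return GroundTruth(
        ensemble_membership={int(k): v for k, v in payload["ensemble_membership"].items()},
        celltype=np.asarray(payload["celltype"]),
        planted_events=[PlantedEvent(**e) for e in payload["planted_events"]],
        timing_offsets={int(k): v for k, v in payload["timing_offsets"].items()},
        stim_effect_g=payload["stim_effect_g"],
        stim_neural_effect=payload["stim_neural_effect"],
    )


def save_decoder(decoder, path):
    payload = {
        "weights": decoder.weights.tolist(),
        "weights_z": decoder.weights_z.tolist(),
        "intercept": decoder.intercept,
        "chosen_regularization": decoder.chosen_regularization,
        "accuracy_mean": decoder.accuracy_mean,
        "accuracy_per_action": decoder.accuracy_per_action,
        "accuracy_sd": decoder.accuracy_sd,
        "n_trials_per_action": decoder.n_trials_per_action,
        "config": dataclasses.asdict(decoder.config) if decoder.config else None,
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def save_config(config: SimConfig, path):
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(config), f)


def load_config(path) -> SimConfig:
    with open(path) as f:
        payload = yaml.safe_load(f)
    for key in ("force_peak_range_g", "bump_rise_range_s", "bump_decay_range_s"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return SimConfig(**payload)
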