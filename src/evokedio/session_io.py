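"""Reading and writing the pipeline's on-disk formats.

Spike-event tables travel as CSV (``channel,trial,time_ms``), raw
recordings as HDF5 (``/data`` channels x samples, ``/stim_onsets``, attr
``sampling_rate_hz``) with a JSON fallback for small text-only fixtures,
and protocols/configs as JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .datatypes import RawRecording, StimulusProtocol, validate_spike_table

__all__ = [
    "write_spikes_csv", "read_spikes_csv",
    "write_recording_h5", "read_recording_h5",
    "write_recording_json", "read_recording_json",
    "write_protocol_json", "read_protocol_json",
    "load_config",
]


def write_spikes_csv(spikes: pd.DataFrame, path) -> None:
    validate_spike_table(spikes)
    spikes.to_csv(path, index=False, float_format="%.6f")


def read_spikes_csv(path) -> pd.DataFrame:
    return validate_spike_table(pd.read_csv(path))


def write_recording_h5(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.samples)
        f.create_dataset("stim_onsets", data=rec.stim_onsets)
        f.create_dataset("channel_ids", data=np.asarray(rec.channel_ids))
        f.attrs["sampling_rate_hz"] = rec.sampling_rate


def read_recording_h5(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(
            samples=f["data"][...],
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            stim_onsets=f["stim_onsets"][...],
            channel_ids=f["channel_ids"][...] if "channel_ids" in f else None,
        )


def write_recording_json(rec: RawRecording, path) -> None:
    """Plain-text sidecar format for small fixtures."""
    payload = {
        "sampling_rate_hz": rec.sampling_rate,
        "stim_onsets": rec.stim_onsets.tolist(),
        "channel_ids": np.asarray(rec.channel_ids).tolist(),
        "data": rec.samples.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_recording_json(path) -> RawRecording:
    payload = json.loads(Path(path).read_text())
    return RawRecording(
        samples=np.asarray(payload["data"], dtype=float),
        sampling_rate=float(payload["sampling_rate_hz"]),
        stim_onsets=np.asarray(payload["stim_onsets"], dtype=float),
        channel_ids=np.asarray(payload["channel_ids"]),
    )


def write_protocol_json(protocol: StimulusProtocol, path) -> None:
    payload = {
        "kind": protocol.kind,
        "inter_trial_s": protocol.inter_trial_s,
        "trials": protocol.trials.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_protocol_json(path) -> StimulusProtocol:
    payload = json.loads(Path(path).read_text())
    return StimulusProtocol(
        kind=payload["kind"],
        trials=pd.DataFrame(payload["trials"]),
        inter_trial_s=float(payload["inter_trial_s"]),
    )


def load_config(path) -> dict:
    """Load a JSON or YAML configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg
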