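"""Serialization: TSV trial tables, HDF5 signal containers, YAML configs."""
from __future__ import annotations

import dataclasses
import io as io_module
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .ddm import BehavioralTrial, frame_to_trials, trials_to_frame
from .errors import ConfigurationError
from .task_synth import (EffectConfig, EpochedSignal, GroupEffects, PupilTrace,
                         StimulusConfig, TaskDesign)

__all__ = [
    "save_design", "load_design",
    "save_trials", "load_trials",
    "save_epochs", "load_epochs",
    "save_pupil_traces", "load_pupil_traces",
    "save_array", "load_array",
    "load_stimulus_config", "load_effect_config",
    "save_effect_config",
]


# --- TSV -------------------------------------------------------------------

def save_design(design: TaskDesign, path: str | Path) -> None:
    frame = design.to_frame()
    frame.attrs = {}
    header = (f"# n_runs={design.n_runs} blocks_per_run={design.blocks_per_run} "
              f"trials_per_block={design.trials_per_block}\n")
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)


def load_design(path: str | Path) -> TaskDesign:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        frame = pd.read_csv(fh, sep="\t")
    return TaskDesign.from_frame(frame, int(meta["n_runs"]),
                                 int(meta["blocks_per_run"]),
                                 int(meta["trials_per_block"]))


def save_trials(trials: list[BehavioralTrial], path: str | Path) -> None:
    # %.17g keeps RTs bit-exact through the text round-trip
    trials_to_frame(trials).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_trials(path: str | Path) -> list[BehavioralTrial]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return frame_to_trials(frame)


# --- HDF5 containers -------------------------------------------------------

def save_epochs(epochs: EpochedSignal, path: str | Path, key: str = "epochs") -> None:
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.create_dataset("data", data=epochs.data)
        g.attrs["srate"] = epochs.srate
        g.attrs["t0"] = float(epochs.times[0])
        g.attrs["alignment"] = epochs.alignment
        g.attrs["channels"] = [c.encode() for c in epochs.channels]
        if epochs.neighbors is not None:
            g.attrs["neighbors"] = yaml.safe_dump(epochs.neighbors)
        if epochs.trial_info is not None:
            g.attrs["trial_info"] = epochs.trial_info.to_json()


def load_epochs(path: str | Path, key: str = "epochs") -> EpochedSignal:
    with h5py.File(path, "r") as f:
        if key not in f:
            raise ConfigurationError(f"no group {key!r} in {path}")
        g = f[key]
        data = g["data"][...]
        srate = float(g.attrs["srate"])
        t0 = float(g.attrs["t0"])
        channels = [c.decode() if isinstance(c, bytes) else str(c)
                    for c in g.attrs["channels"]]
        neighbors = (yaml.safe_load(g.attrs["neighbors"])
                     if "neighbors" in g.attrs else None)
        info = (pd.read_json(io_module.StringIO(g.attrs["trial_info"]))
                if "trial_info" in g.attrs else None)
        alignment = str(g.attrs["alignment"])
    times = t0 + np.arange(data.shape[1]) / srate
    return EpochedSignal(data=data, srate=srate, times=times,
                         alignment=alignment, channels=channels,
                         neighbors=neighbors, trial_info=info)


def save_pupil_traces(traces: list[PupilTrace], path: str | Path,
                      key: str = "pupil") -> None:
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        for i, tr in enumerate(traces):
            tg = g.create_group(f"trial_{i:04d}")
            tg.create_dataset("samples", data=tr.samples)
            if tr.gaze_y is not None:
                tg.create_dataset("gaze_y", data=tr.gaze_y)
            tg.attrs["srate"] = tr.srate
            tg.attrs["t0"] = tr.t0
            tg.attrs["blinks"] = np.asarray(tr.blinks, dtype=float).reshape(-1, 2)


def load_pupil_traces(path: str | Path, key: str = "pupil") -> list[PupilTrace]:
    traces = []
    with h5py.File(path, "r") as f:
        g = f[key]
        for name in sorted(g):
            tg = g[name]
            traces.append(PupilTrace(
                samples=tg["samples"][...],
                srate=float(tg.attrs["srate"]),
                t0=float(tg.attrs["t0"]),
                blinks=[tuple(b) for b in tg.attrs["blinks"]],
                gaze_y=tg["gaze_y"][...] if "gaze_y" in tg else None,
            ))
    return traces


def save_array(arr: np.ndarray, path: str | Path, key: str, **attrs) -> None:
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        d = f.create_dataset(key, data=arr)
        for k, v in attrs.items():
            d.attrs[k] = v


def load_array(path: str | Path, key: str) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        d = f[key]
        return d[...], dict(d.attrs)


# --- YAML configs ----------------------------------------------------------

def load_stimulus_config(path: str | Path) -> StimulusConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(StimulusConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(f"unknown stimulus config keys: {sorted(unknown)}")
    return StimulusConfig(**raw)


def load_effect_config(path: str | Path) -> EffectConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    groups = raw.pop("groups", None)
    allowed = {f.name for f in dataclasses.fields(EffectConfig)} - {"groups"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(f"unknown effect config keys: {sorted(unknown)}")
    cfg = EffectConfig(**raw)
    if groups is not None:
        gallowed = {f.name for f in dataclasses.fields(GroupEffects)}
        parsed = {}
        for gname, gvals in groups.items():
            gunknown = set(gvals) - gallowed
            if gunknown:
                raise ConfigurationError(
                    f"unknown group-effect keys for {gname!r}: {sorted(gunknown)}")
            parsed[gname] = GroupEffects(**gvals)
        cfg.groups = parsed
    return cfg


def save_effect_config(cfg: EffectConfig, path: str | Path) -> None:
    raw = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
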