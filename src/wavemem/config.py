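"""YAML run configurations.

A run file has up to four sections mirroring the library objects::

    network:            # NetworkConfig fields
      n_ex: 400
      n_inh: 100
      m_modules: 4
    drive:              # DriveSpec
      a_max: 12.0
      components:
        - {f_hz: 8.0, fraction: 0.5, psi_osc: 0.9}
    stimuli:            # StimulusSet (either explicit items or a sequence)
      a_inf: 15.0
      sigma_gamma: 4.0
      sequence: {labels: [A, B, C, D], f_gamma: 50.0, phi_i: 0.8}
    protocol:           # free-form options passed to the CLI subcommand
      seed: 1

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import fields

import yaml

from .network import (
    DriveComponent,
    DriveSpec,
    NetworkConfig,
    Stimulus,
    StimulusSet,
    stimulus_times_from_phase,
)

__all__ = ["load_run_config", "dump_run_config", "RunConfig"]


@dataclasses.dataclass
class RunConfig:
    network: NetworkConfig
    drive: DriveSpec
    stimuli: StimulusSet
    protocol: dict


def _build(cls, data: dict, what: str):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**data)


def _drive_from_dict(data: dict) -> DriveSpec:
    data = dict(data)
    comps = [_build(DriveComponent, c, "drive component")
             for c in data.pop("components", [])]
    spec_kwargs = {"components": tuple(comps)}
    if "a_max" in data:
        spec_kwargs["a_max"] = data.pop("a_max")
    if data:
        raise ValueError(f"unknown drive keys: {sorted(data)}")
    return DriveSpec(**spec_kwargs)


def _stimuli_from_dict(data: dict, drive: DriveSpec) -> StimulusSet:
    data = dict(data)
    seq = data.pop("sequence", None)
    items = tuple(Stimulus(d["label"], d["t_a"]) for d in data.pop("items", []))
    kwargs = {}
    for key in ("a_inf", "sigma_gamma", "f_gamma"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise ValueError(f"unknown stimuli keys: {sorted(data)}")
    if seq is not None:
        theta = min(drive.components, key=lambda c: (c.onset_ms, c.f_hz))
        t = stimulus_times_from_phase(seq.get("phi_i", 0.0), theta.f_hz,
                                      seq["f_gamma"], len(seq["labels"]))
        items = tuple(Stimulus(lab, ti) for lab, ti in zip(seq["labels"], t))
        kwargs["f_gamma"] = seq["f_gamma"]
    return StimulusSet(items=items, **kwargs)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    network = _build(NetworkConfig, raw.get("network", {}), "network")
    drive = _drive_from_dict(raw.get("drive", {"components": [
        {"f_hz": 8.0, "fraction": 0.5, "psi_osc": 0.9}]}))
    stimuli = _stimuli_from_dict(raw.get("stimuli", {}), drive)
    return RunConfig(network=network, drive=drive, stimuli=stimuli,
                     protocol=dict(raw.get("protocol", {})))


def dump_run_config(cfg: RunConfig, path) -> None:
    raw = {
        "network": dataclasses.asdict(cfg.network),
        "drive": {
            "a_max": cfg.drive.a_max,
            "components": [dataclasses.asdict(c) for c in cfg.drive.components],
        },
        "stimuli": {
            "a_inf": cfg.stimuli.a_inf,
            "sigma_gamma": cfg.stimuli.sigma_gamma,
            "f_gamma": cfg.stimuli.f_gamma,
            "items": [{"label": s.label, "t_a": s.t_a} for s in cfg.stimuli.items],
        },
        "protocol": cfg.protocol,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
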