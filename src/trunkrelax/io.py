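"""Tabular trial I/O.

One trial is stored as three files in a directory::

    <name>_angle.csv  time_s, angle_deg   (100 Hz stream)
    <name>_force.csv  time_s, force_N     (1000 Hz stream)
    <name>_meta.json  protocol + ground-truth fields, seed, moment arm

All files are UTF-8 with a header row; floats are written with "%.10g" so
that identical trials serialize to identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .models import params_from_dict, params_to_dict
from .synthetic import GroundTruthSpec, ProtocolSpec, TrialRecording

__all__ = ["write_trial", "read_trial", "list_trials"]

_FLOAT_FMT = "%.10g"


def _spec_to_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    if "params" in d:
        d["params"] = params_to_dict(spec.params)
    return d


def write_trial(trial: TrialRecording, out_dir: Path, name: str) -> Path:
    """Write one trial; returns the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": trial.angle_time, "angle_deg": trial.angle}).to_csv(
        out_dir / f"{name}_angle.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame({"time_s": trial.force_time, "force_N": trial.force}).to_csv(
        out_dir / f"{name}_force.csv", index=False, float_format=_FLOAT_FMT)

    meta = {"moment_arm_m": trial.moment_arm}
    for key, value in trial.metadata.items():
        if isinstance(value, ProtocolSpec):
            meta["protocol"] = _spec_to_dict(value)
        elif isinstance(value, GroundTruthSpec):
            meta["truth"] = _spec_to_dict(value)
        elif isinstance(value, (int, float, str, bool)) or value is None:
            meta[key] = value
    path = out_dir / f"{name}_meta.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_trial(trial_dir: Path, name: str) -> TrialRecording:
    """Read a trial written by :func:`write_trial` (or hand-assembled in
    the same dialect)."""
    trial_dir = Path(trial_dir)
    angle = pd.read_csv(trial_dir / f"{name}_angle.csv")
    force = pd.read_csv(trial_dir / f"{name}_force.csv")
    meta_path = trial_dir / f"{name}_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    metadata = {k: v for k, v in meta.items()
                if k not in ("protocol", "truth", "moment_arm_m")}
    if "protocol" in meta:
        metadata["protocol"] = ProtocolSpec(**meta["protocol"])
    if "truth" in meta:
        td = dict(meta["truth"])
        td["params"] = params_from_dict(td["params"])
        metadata["truth"] = GroundTruthSpec(**td)
    return TrialRecording(
        angle_time=angle["time_s"].to_numpy(),
        angle=angle["angle_deg"].to_numpy(),
        force_time=force["time_s"].to_numpy(),
        force=force["force_N"].to_numpy(),
        moment_arm=float(meta.get("moment_arm_m", 0.40)),
        metadata=metadata,
    )


def list_trials(trial_dir: Path) -> list[str]:
    """Trial names present in a directory, sorted."""
    return sorted(p.name[:-len("_angle.csv")]
                  for p in Path(trial_dir).glob("*_angle.csv"))
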