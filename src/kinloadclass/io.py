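"""Dataset serialization: one long-format CSV per trial, one JSON sidecar
per trial, and a dataset-level JSON manifest echoing the generator config.

CSV columns: ``t_ms``, the 7 angle channels, ``obj_x``, ``obj_y``,
``obj_z``.  Missing samples are empty cells.  Floats are written at full
repr precision so a read-back dataset is numerically identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthkin import ANGLE_CHANNELS, GeneratorConfig, Trial

__all__ = ["write_dataset", "read_dataset", "trial_frame"]

POSITION_COLUMNS = ("obj_x", "obj_y", "obj_z")
MANIFEST_NAME = "manifest.json"


def trial_frame(trial: Trial) -> pd.DataFrame:
    """Long-format frame of one trial's time series."""
    data = {"t_ms": trial.timestamps_ms}
    for i, name in enumerate(ANGLE_CHANNELS):
        data[name] = trial.angles[:, i]
    for i, name in enumerate(POSITION_COLUMNS):
        data[name] = trial.object_position[:, i]
    return pd.DataFrame(data)


def _trial_meta(trial: Trial) -> dict:
    return {
        "person_id": trial.person_id,
        "object_size": trial.object_size,
        "weight_class": trial.weight_class,
        "start_position": trial.start_position,
        "trial_index": trial.trial_index,
        "block": trial.block,
        "n_samples": trial.n_samples,
        # generator-only ground truth, kept for validation
        "lift_onset_true": trial.lift_onset_true,
        "lift_end_true": trial.lift_end_true,
    }


def write_dataset(
    trials: Sequence[Trial], config: GeneratorConfig, outdir: str | Path
) -> Path:
    """Write trials + sidecars + manifest into ``outdir``; returns the path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, trial in enumerate(trials):
        stem = f"trial_{i:04d}"
        trial_frame(trial).to_csv(outdir / f"{stem}.csv", index=False,
                                  float_format="%.17g")
        (outdir / f"{stem}.json").write_text(
            json.dumps(_trial_meta(trial), indent=1)
        )
        names.append(stem)
    manifest = {
        "format": "kinloadclass-dataset-v1",
        "config": dataclasses.asdict(config),
        "n_trials": len(trials),
        "trials": names,
    }
    (outdir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return outdir


def read_dataset(indir: str | Path) -> tuple[list[Trial], GeneratorConfig]:
    """Read back a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    manifest = json.loads((indir / MANIFEST_NAME).read_text())
    cfg_dict = manifest["config"]
    cfg_dict["duration_range_ms"] = tuple(cfg_dict["duration_range_ms"])
    config = GeneratorConfig(**cfg_dict)
    trials = []
    for stem in manifest["trials"]:
        frame = pd.read_csv(indir / f"{stem}.csv", float_precision="round_trip")
        meta = json.loads((indir / f"{stem}.json").read_text())
        trials.append(
            Trial(
                person_id=meta["person_id"],
                object_size=meta["object_size"],
                weight_class=meta["weight_class"],
                start_position=meta["start_position"],
                timestamps_ms=frame["t_ms"].to_numpy(dtype=float),
                angles=frame[list(ANGLE_CHANNELS)].to_numpy(),
                object_position=frame[list(POSITION_COLUMNS)].to_numpy(),
                lift_onset_true=meta["lift_onset_true"],
                lift_end_true=meta["lift_end_true"],
                trial_index=meta["trial_index"],
                block=meta["block"],
            )
        )
    return trials, config
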