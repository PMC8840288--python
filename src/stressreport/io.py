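"""On-disk recording layout: one CSV per channel plus a JSON sidecar.

A recording directory contains ``<channel>.csv`` files with columns
``t_s,value`` for each of the six channels and a ``recording.json``
sidecar holding the subject id, per-channel sampling rates and the
half-open condition-label intervals.  Readers validate the same
invariants the in-memory type enforces and name the offending channel or
interval in their errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import CHANNEL_NAMES, StressReportError
from .synthetic import Recording

SIDECAR_NAME = "recording.json"


def write_recording(rec: Recording, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": {name: fs for name, (_, fs) in sorted(rec.channels.items())},
        "label_intervals": [[s, e, c] for s, e, c in rec.label_intervals],
    }
    with open(directory / SIDECAR_NAME, "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)
    for name, (samples, fs) in sorted(rec.channels.items()):
        frame = pd.DataFrame(
            {"t_s": np.arange(len(samples)) / fs, "value": samples}
        )
        frame.to_csv(directory / f"{name}.csv", index=False)
    return directory


def read_recording(directory) -> Recording:
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise StressReportError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    fs_map = sidecar.get("fs", {})
    channels = {}
    for name in CHANNEL_NAMES:
        csv_path = directory / f"{name}.csv"
        if not csv_path.exists():
            raise StressReportError(f"missing channel file {csv_path}")
        if name not in fs_map:
            raise StressReportError(f"sidecar missing sampling rate for {name!r}")
        frame = pd.read_csv(csv_path)
        channels[name] = (frame["value"].to_numpy(dtype=float), float(fs_map[name]))
    rec = Recording(
        subject_id=str(sidecar["subject_id"]),
        channels=channels,
        label_intervals=[(float(s), float(e), str(c)) for s, e, c in sidecar["label_intervals"]],
    )
    rec.validate()
    return rec
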