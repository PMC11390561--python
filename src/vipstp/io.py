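"""CSV/JSON dialect for amplitude tables, metrics and ground truth.

Amplitude tables use SI-suffixed columns: cell_id, input_id, protocol_kind,
frequency_hz, trial, pulse_index, stim_time_s, amplitude_mV (pulse_index is
1-based). Files written by the pipeline carry a leading ``#`` comment line
with the run's config hash and seed; readers skip comment lines, so files
round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import AmplitudeTrain

AMPLITUDE_COLUMNS = ["cell_id", "input_id", "protocol_kind", "frequency_hz",
                     "trial", "pulse_index", "stim_time_s", "amplitude_mV"]


def trains_to_frame(trains) -> pd.DataFrame:
    rows = []
    for t in trains:
        for k, (ts, amp) in enumerate(zip(t.times, t.amplitudes), start=1):
            rows.append((t.cell_id, t.input_id, t.protocol_kind, t.frequency,
                         t.trial, k, ts, amp))
    return pd.DataFrame(rows, columns=AMPLITUDE_COLUMNS)


def frame_to_trains(df: pd.DataFrame) -> list:
    trains = []
    keys = ["cell_id", "input_id", "protocol_kind", "frequency_hz", "trial"]
    for (cid, iid, kind, freq, trial), g in df.groupby(keys, sort=True):
        g = g.sort_values("pulse_index")
        trains.append(AmplitudeTrain(
            cell_id=int(cid), input_id=int(iid), protocol_kind=str(kind),
            frequency=float(freq), trial=int(trial),
            times=g["stim_time_s"].to_numpy(),
            amplitudes=g["amplitude_mV"].to_numpy()))
    return trains


def write_table(df: pd.DataFrame, path, config_hash: str = "", seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={config_hash} seed={seed}\n" if config_hash else ""
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
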