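"""HDF5 container and CSV exports.

Layout of the subject container:

    /epochs/data    (channels x samples x trials)
    /epochs/times   ms relative to stimulus onset
    /layout/gain    (channels x nodes), fT per a.u.
    /layout/channel_ids, /layout/node_ids
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import pandas as pd

from .nmm import NetworkModel
from .observation import GainMatrix
from .preprocess import ERF, EpochSet

__all__ = [
    "save_subject",
    "load_subject",
    "save_model",
    "load_model",
    "erf_to_csv",
    "evidence_rows_to_csv",
    "ep_table_to_csv",
]


def save_subject(path, epochs: EpochSet, gain: GainMatrix,
                 attrs: dict | None = None) -> None:
    from .observation import sensor_layout

    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("data", data=epochs.data)
        g.create_dataset("times", data=epochs.times)
        lay = f.create_group("layout")
        lay.create_dataset("gain", data=gain.values)
        lay.create_dataset("positions",
                           data=sensor_layout(len(gain.channel_ids)))
        lay.attrs["channel_ids"] = json.dumps(list(gain.channel_ids))
        lay.attrs["node_ids"] = json.dumps(list(gain.node_ids))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_subject(path):
    """Returns ``(EpochSet, GainMatrix, attrs)``."""
    with h5py.File(path, "r") as f:
        times = f["epochs/times"][()]
        data = f["epochs/data"][()]
        gain = GainMatrix(
            values=f["layout/gain"][()],
            channel_ids=tuple(json.loads(f["layout"].attrs["channel_ids"])),
            node_ids=tuple(json.loads(f["layout"].attrs["node_ids"])),
        )
        attrs = dict(f.attrs)
    epochs = EpochSet(times=times, data=data, channel_ids=gain.channel_ids)
    return epochs, gain, attrs


def save_model(path, model: NetworkModel) -> None:
    Path(path).write_text(model.to_json())


def load_model(path) -> NetworkModel:
    return NetworkModel.from_json(Path(path).read_text())


def gain_to_csv(path, gain: GainMatrix) -> None:
    """Per-node sensor topographies with the hemisphere layout coordinates."""
    from .observation import sensor_layout

    pos = sensor_layout(len(gain.channel_ids))
    df = pd.DataFrame(pos, columns=["x", "y", "z"])
    df.insert(0, "channel", list(gain.channel_ids))
    for j, node in enumerate(gain.node_ids):
        df[node] = gain.values[:, j]
    df.to_csv(path, index=False)


def erf_to_csv(path, erf: ERF) -> None:
    df = pd.DataFrame(erf.data.T, columns=list(erf.channel_ids)
                      or range(erf.data.shape[0]))
    df.insert(0, "time_ms", erf.times)
    df.to_csv(path, index=False)


def evidence_rows_to_csv(path, rows) -> pd.DataFrame:
    """rows: dicts with subject, model, window_start, window_len, F,
    accuracy, complexity and parameter means."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def ep_table_to_csv(path, results, model_labels) -> pd.DataFrame:
    """Per-window Dirichlet summary: alpha, expected frequency, EP."""
    rows = []
    for entry in results:
        window, dp = entry[0], entry[1]
        row = {"window_start_ms": window.start, "window_len_ms": window.length}
        for k, lab in enumerate(model_labels):
            row[f"alpha_{lab}"] = dp.alpha[k]
            row[f"freq_{lab}"] = dp.expected_freq[k]
            row[f"ep_{lab}"] = dp.exceedance_prob[k]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
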