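"""Persistence: named-array containers (.npz) with JSON metadata sidecars.

Layout on disk for a dataset directory:
    data.npz   — one float array per recording, keyed ``rec_<index>``
    meta.json  — labels, layout, sampling rate, generator config

Spike/real sample sets are stored as a single stacked array plus a labels
table; model checkpoints live in :mod:`spikemyo.snn`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import ElectrodeLayout, EmgRecording

__all__ = [
    "save_recordings",
    "load_recordings",
    "save_samples",
    "load_samples",
    "recording_to_csv",
]


def _layout_meta(layout: ElectrodeLayout) -> list:
    return [list(a) for a in layout.arrays]


def save_recordings(directory, recordings) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays, meta = {}, []
    layout = None
    fs = None
    for i, rec in enumerate(recordings):
        arrays[f"rec_{i}"] = rec.signal
        meta.append(rec.labels)
        layout, fs = rec.layout, rec.sampling_rate
    np.savez(directory / "data.npz", **arrays)
    (directory / "meta.json").write_text(json.dumps({
        "sampling_rate": fs,
        "layout": _layout_meta(layout),
        "recordings": meta,
    }, indent=1))


def load_recordings(directory) -> list:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    layout = ElectrodeLayout(arrays=tuple(tuple(a) for a in meta["layout"]))
    out = []
    with np.load(directory / "data.npz") as z:
        for i, labels in enumerate(meta["recordings"]):
            out.append(EmgRecording(signal=z[f"rec_{i}"],
                                    sampling_rate=meta["sampling_rate"],
                                    layout=layout, **labels))
    return out


def save_samples(directory, X: np.ndarray, labels: pd.DataFrame,
                 provenance: dict | None = None) -> None:
    """Stacked sample array (real or packed spike) + labels table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "samples.npz", X=X)
    labels.to_csv(directory / "labels.csv", index=False)
    (directory / "meta.json").write_text(json.dumps(provenance or {}, indent=1))


def load_samples(directory) -> tuple:
    directory = Path(directory)
    with np.load(directory / "samples.npz") as z:
        X = z["X"]
    labels = pd.read_csv(directory / "labels.csv")
    meta = json.loads((directory / "meta.json").read_text())
    return X, labels, meta


def recording_to_csv(path, recording: EmgRecording) -> None:
    """Single-recording export: one column per channel."""
    df = pd.DataFrame(recording.signal.T,
                      columns=[f"ch{c}" for c in range(recording.signal.shape[0])])
    df.to_csv(path, index=False)
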