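"""HDF5 containers for recordings and epochs; TSV for tables.

Layout of the epochs container::

    /epochs/data      trials x channels x time, float64
    /epochs/times     seconds relative to stimulus onset
    /epochs/metadata  typed table (one row per epoch)
    attrs: sampling_rate

Recordings store ``/recording/data`` (channels x samples), the event list and
the full trial sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .preprocessing import SensorEpochs
from .sequence import StimulusSequence
from .simulate import SensorRecording

__all__ = ["save_epochs", "load_epochs", "save_recording", "load_recording"]

_STR_COLS = ("entropy",)


def _frame_to_records(df: pd.DataFrame) -> np.ndarray:
    df = df.copy()
    for c in _STR_COLS:
        if c in df:
            df[c] = df[c].astype("S16")
    return df.to_records(index=False)


def _records_to_frame(rec: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(rec)
    for c in _STR_COLS:
        if c in df:
            df[c] = df[c].str.decode("utf-8")
    return df


def save_epochs(epochs: SensorEpochs, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("data", data=epochs.data)
        g.create_dataset("times", data=epochs.times)
        g.create_dataset("metadata", data=_frame_to_records(epochs.metadata))
        f.attrs["sampling_rate"] = epochs.sampling_rate


def load_epochs(path) -> SensorEpochs:
    with h5py.File(path, "r") as f:
        return SensorEpochs(
            data=f["epochs/data"][()],
            times=f["epochs/times"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            metadata=_records_to_frame(f["epochs/metadata"][()]),
        )


def save_recording(rec: SensorRecording, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("recording")
        g.create_dataset("data", data=rec.data)
        g.create_dataset("events", data=rec.events)
        f.attrs["sampling_rate"] = rec.sampling_rate
        if rec.sequence is not None:
            f.create_dataset(
                "sequence", data=_frame_to_records(rec.sequence.to_frame())
            )


def load_recording(path) -> SensorRecording:
    with h5py.File(path, "r") as f:
        seq = None
        if "sequence" in f:
            df = _records_to_frame(f["sequence"][()])
            seq = StimulusSequence(
                stimulus=df["stimulus"].to_numpy(),
                entropy=df["entropy"].to_numpy(),
                block=df["block"].to_numpy(),
                segment=df["segment"].to_numpy(),
                omitted=df["omitted"].to_numpy().astype(bool),
                burn_in=df["burn_in"].to_numpy().astype(bool),
            )
        return SensorRecording(
            data=f["recording/data"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            events=f["recording/events"][()],
            sequence=seq,
        )
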