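"""Filtering, resampling and epoching to the analysis geometry.

The analysis grid is the standard one for slow evoked dynamics: a 0.1-30 Hz
zero-phase FIR band-pass, downsampling to 100 Hz, and 1200 ms epochs from
400 ms before stimulus onset to 800 ms after. Epoch time axes use the
half-open convention [tmin, tmax) with onset at t = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from mne.filter import filter_data
from scipy.signal import resample_poly

from .sequence import StimulusSequence
from .simulate import SensorRecording

__all__ = ["SensorEpochs", "bandpass_filter", "resample", "epoch", "preprocess"]

logger = logging.getLogger(__name__)


@dataclass
class SensorEpochs:
    """Epoched data (trials x channels x time) with aligned trial metadata.

    ``metadata`` carries the sequence fields for each retained trial plus the
    stimulus identity (and omission flag) at t-1 and t-2, which the decoding
    trial selection conditions on.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.metadata):
            raise ValueError("metadata rows must align one-to-one with epochs")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def bandpass_filter(
    rec: SensorRecording, low: float = 0.1, high: float = 30.0
) -> SensorRecording:
    """Zero-phase FIR band-pass, applied per channel in the continuous domain."""
    nyq = rec.sampling_rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz invalid for Nyquist {nyq} Hz")
    filtered = filter_data(
        rec.data.astype(np.float64), rec.sampling_rate, low, high, verbose="error"
    )
    return SensorRecording(
        data=filtered,
        sampling_rate=rec.sampling_rate,
        events=rec.events.copy(),
        sequence=rec.sequence,
    )


def resample(rec: SensorRecording, target_rate: float) -> SensorRecording:
    """Polyphase downsampling with consistent event-index remapping."""
    if target_rate >= rec.sampling_rate:
        raise ValueError("only downsampling is supported")
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    events = rec.events.copy()
    events[:, 0] = np.round(events[:, 0] * float(frac)).astype(np.int64)
    return SensorRecording(
        data=data, sampling_rate=target_rate, events=events, sequence=rec.sequence
    )


def _shifted(values: np.ndarray, k: int, fill=-1) -> np.ndarray:
    out = np.full(len(values), fill, dtype=values.dtype)
    out[k:] = values[:-k]
    return out


def epoch(
    rec: SensorRecording, tmin: float = -0.4, tmax: float = 0.8
) -> SensorEpochs:
    """Cut one epoch per event on the half-open grid [tmin, tmax).

    Events whose epoch would exceed the recording bounds are dropped (the
    count is logged). Metadata joins the sequence fields and adds the
    stimulus/omission history at t-1 and t-2 (-1 where no predecessor exists).
    """
    if rec.sequence is None:
        raise ValueError("recording carries no sequence metadata")
    fs = rec.sampling_rate
    start_off = int(round(tmin * fs))
    n_times = int(round((tmax - tmin) * fs))
    times = (start_off + np.arange(n_times)) / fs

    onsets = rec.events[:, 0]
    keep = (onsets + start_off >= 0) & (onsets + start_off + n_times <= rec.n_samples)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d edge events without a full epoch window", n_dropped)
    if not keep.any():
        raise ValueError("no events with a complete epoch window")

    idx = np.flatnonzero(keep)
    starts = onsets[idx] + start_off
    data = np.stack([rec.data[:, s : s + n_times] for s in starts])

    seq = rec.sequence
    meta = seq.to_frame()
    stim = meta["stimulus"].to_numpy()
    omit = meta["omitted"].to_numpy()
    meta["prev_stimulus"] = _shifted(stim, 1)
    meta["prev2_stimulus"] = _shifted(stim, 2)
    meta["prev_omitted"] = np.r_[True, omit[:-1]]
    meta["prev2_omitted"] = np.r_[True, True, omit[:-2]]
    meta = meta.iloc[idx].reset_index(drop=True)
    return SensorEpochs(data=data, times=times, sampling_rate=fs, metadata=meta)


def preprocess(
    rec: SensorRecording,
    low: float = 0.1,
    high: float = 30.0,
    target_rate: float = 100.0,
    tmin: float = -0.4,
    tmax: float = 0.8,
) -> SensorEpochs:
    """Band-pass, downsample (when needed) and epoch a recording."""
    rec = bandpass_filter(rec, low, high)
    if target_rate < rec.sampling_rate:
        rec = resample(rec, target_rate)
    return epoch(rec, tmin, tmax)
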