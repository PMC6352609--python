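"""Band-pass filtering and protocol-aware epoch extraction.

The analysis band is 8-30 Hz (mu + beta). Filtering is applied to the
continuous recording (before epoching, so filter transients never fall
inside an epoch) with a 5th-order Butterworth band-pass run
forward-backward (zero phase; the analysis is offline so non-causal
filtering is appropriate). Epochs are the two classification windows of
each trial:

* KMI window: 3.5 s starting 0.5 s after the GREEN (imagery go) cue;
* REST window: 3.5 s starting 2.5 s after the RED (rest) cue,

so at 256 Hz every epoch has T = 896 samples. The EMG channel is
excluded from epoch data.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .containers import LABEL_KMI, LABEL_REST, EEGSession, EpochSet
from .errors import ValidationError

logger = logging.getLogger(__name__)

EPOCH_LENGTH_S = 3.5
KMI_OFFSET_S = 0.5
REST_OFFSET_S = 2.5


def bandpass(
    session: EEGSession, low: float = 8.0, high: float = 30.0, order: int = 5
) -> EEGSession:
    """Zero-phase Butterworth band-pass of all EEG channels.

    The EMG channel (if present) is passed through untouched; it is a
    movement monitor, not part of the analysed signal.
    """
    nyq = session.fs / 2.0
    if not 0 < low < high:
        raise ValidationError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValidationError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=session.fs, output="sos")
    out = session.signal.copy()
    eeg = session.eeg_indices
    out[eeg] = sps.sosfiltfilt(sos, session.signal[eeg], axis=1)
    return session.copy_with(signal=out)


def design_bandpass_sos(fs: float, low: float = 8.0, high: float = 30.0, order: int = 5):
    """The filter design used by :func:`bandpass`, exposed for inspection."""
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def extract_epochs(session: EEGSession) -> EpochSet:
    """Cut the per-trial KMI and REST classification windows.

    One KMI epoch per GREEN event at [onset+0.5, onset+4.0) and one REST
    epoch per RED event at [onset+2.5, onset+6.0), both of
    T = round(3.5 * fs) samples with the start index floored, so T is
    exact regardless of the fractional onset. Windows that would run past
    the end of the recording are dropped with a warning. Epochs are
    emitted in event order (each trial's REST precedes its KMI).
    """
    fs = session.fs
    T = int(round(EPOCH_LENGTH_S * fs))
    offsets = {"GREEN": (KMI_OFFSET_S, LABEL_KMI), "RED": (REST_OFFSET_S, LABEL_REST)}
    eeg = session.eeg_indices
    labels_kept = [session.channel_labels[i] for i in eeg]

    data, labels, dropped = [], [], 0
    for onset, code in session.events:
        if code not in offsets:
            continue
        off, label = offsets[code]
        start = int(np.floor((onset + off) * fs))
        if start < 0 or start + T > session.n_samples:
            dropped += 1
            continue
        data.append(session.signal[eeg, start : start + T])
        labels.append(label)
    if dropped:
        logger.warning("dropped %d epoch(s) whose window fell outside the recording", dropped)
    if not data:
        raise ValidationError("no usable trials: every epoch window fell outside the recording")
    return EpochSet(
        data=np.stack(data),
        labels=np.array(labels, dtype=object),
        fs=fs,
        channel_labels=labels_kept,
    )


__all__ = ["bandpass", "extract_epochs", "design_bandpass_sos", "EPOCH_LENGTH_S", "KMI_OFFSET_S", "REST_OFFSET_S"]
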