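"""Core in-memory containers: EEG sessions, epoch sets, subject records.

These are plain dataclasses around numpy arrays / python scalars with
validation at construction, shared by the simulator, the I/O layer and
every analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .montage import EMG_CHANNEL

#: Allowed event codes: RED = rest onset, ORANGE = warning, GREEN = imagery onset.
EVENT_CODES = ("RED", "ORANGE", "GREEN")

#: Epoch class labels: kinesthetic-imagery window vs rest window.
LABEL_KMI = "KMI"
LABEL_REST = "REST"

#: Six-point frequency-of-practice scale for the everyday-activity survey items.
FREQUENCY_LEVELS = ("never", "rarely", "annually", "monthly", "weekly", "daily")


@dataclass
class EEGSession:
    """A continuous multichannel recording plus its event table.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per signal row; the EMG channel (if present) is labelled
        ``"EMG"`` and is treated as non-EEG by every analysis stage.
    events : list of (float, str)
        ``(onset_s, code)`` pairs sorted by onset, codes in ``EVENT_CODES``.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        onsets = [o for o, _ in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("events must be sorted by onset")
        bad = sorted({c for _, c in self.events if c not in EVENT_CODES})
        if bad:
            raise ValidationError(
                f"unknown event codes {bad}; allowed codes are {list(EVENT_CODES)}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_indices(self) -> np.ndarray:
        """Indices of non-EMG channels."""
        return np.array(
            [i for i, ch in enumerate(self.channel_labels) if ch != EMG_CHANNEL],
            dtype=int,
        )

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValidationError(f"channel {label!r} not present") from None

    def event_onsets(self, code: str) -> np.ndarray:
        return np.array([o for o, c in self.events if c == code], dtype=float)

    def copy_with(self, **kwargs) -> "EEGSession":
        return replace(self, **kwargs)


@dataclass
class EpochSet:
    """Labelled fixed-length trial segments.

    ``data`` has shape (n_epochs, C, T) where C counts EEG channels only
    (the EMG channel is excluded at extraction time) and T is identical
    for every epoch.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError("one label per epoch required")
        bad = sorted({l for l in self.labels if l not in (LABEL_KMI, LABEL_REST)})
        if bad:
            raise ValidationError(f"unknown epoch labels {bad}")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValidationError("channel label count does not match epoch data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class SubjectRecord:
    """One subject's questionnaire answers and personal factors.

    ``miq_answers`` holds the 14 imagery-questionnaire items in the fixed
    order K1..K7 (kinesthetic) then V1..V7 (visual), each an integer on
    the 1..7 Likert scale. The five frequency-of-practice ratings use the
    six-point ordinal scale 0 (never) .. 5 (daily). Derived fields
    (scores, decoding accuracy) are filled by later stages and default to
    None.
    """

    subject_id: str
    miq_answers: list[int]
    age: float
    gender: str
    education_years: float
    freq_manual: int
    freq_sport: int
    freq_music: int
    freq_craft: int
    freq_gaming: int
    kmi_score: float | None = None
    vmi_score: float | None = None
    accuracy: float | None = None

    FREQ_FIELDS = ("freq_manual", "freq_sport", "freq_music", "freq_craft", "freq_gaming")

    def __post_init__(self):
        if len(self.miq_answers) != 14:
            raise ValidationError(
                f"subject {self.subject_id}: expected 14 questionnaire answers, "
                f"got {len(self.miq_answers)}"
            )
        for i, a in enumerate(self.miq_answers, start=1):
            if not (1 <= int(a) <= 7) or int(a) != a:
                raise ValidationError(
                    f"subject {self.subject_id}: answer #{i} = {a!r} outside 1..7"
                )
        self.miq_answers = [int(a) for a in self.miq_answers]
        for name in self.FREQ_FIELDS:
            v = getattr(self, name)
            if not (0 <= int(v) <= 5) or int(v) != v:
                raise ValidationError(
                    f"subject {self.subject_id}: {name} = {v!r} outside 0..5"
                )
            setattr(self, name, int(v))

    @property
    def kinesthetic_answers(self) -> list[int]:
        return self.miq_answers[:7]

    @property
    def visual_answers(self) -> list[int]:
        return self.miq_answers[7:]
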