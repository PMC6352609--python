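"""On-disk formats: EDF recordings, events TSV, subject CSV, results tables.

Sessions are stored as plain EDF (European Data Format): 16-bit samples,
one-second data records, physical units microvolts with a fixed +/-500 uV
physical range declared in the header. Reading goes through MNE's EDF
reader; the writer is a minimal single-purpose EDF encoder (writing
needs no third-party backend). Event tables are TSV with columns
``onset_s`` (seconds from recording start, 6 decimals) and ``code``
(RED / ORANGE / GREEN). Subject tables are CSV with one row per subject.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EVENT_CODES, EEGSession, SubjectRecord
from .errors import ValidationError
from .montage import EEG_CHANNELS, EMG_CHANNEL

PHYS_RANGE_UV = 500.0
_DIG_MIN, _DIG_MAX = -32768, 32767

SUBJECT_COLUMNS = (
    ["subject_id"]
    + [f"K{i}" for i in range(1, 8)]
    + [f"V{i}" for i in range(1, 8)]
    + ["age", "gender", "education_years"]
    + list(SubjectRecord.FREQ_FIELDS)
)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValidationError(f"EDF header field {text!r} exceeds {width} ascii bytes")
    return b.ljust(width)


def write_edf(session: EEGSession, path) -> None:
    """Write a session as minimal EDF (16-bit, 1-s records, uV units).

    The signal is zero-padded to a whole number of one-second records;
    samples are clipped to the declared +/-500 uV physical range. The
    sampling rate must be an integer (samples per record must be whole).
    """
    fs = session.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError(f"EDF writer requires integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_ch = session.n_channels
    n_rec = int(np.ceil(session.n_samples / fs))
    sig = np.zeros((n_ch, n_rec * fs))
    sig[:, : session.n_samples] = session.signal

    scale = (_DIG_MAX - _DIG_MIN) / (2 * PHYS_RANGE_UV)
    dig = np.clip(np.round(sig * scale), _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    labels = b"".join(_pad(ch, 16) for ch in session.channel_labels)
    transducer = b"".join(_pad("", 80) for _ in range(n_ch))
    phys_dim = b"".join(_pad("uV", 8) for _ in range(n_ch))
    phys_min = b"".join(_pad(str(-PHYS_RANGE_UV), 8) for _ in range(n_ch))
    phys_max = b"".join(_pad(str(PHYS_RANGE_UV), 8) for _ in range(n_ch))
    dig_min = b"".join(_pad(str(_DIG_MIN), 8) for _ in range(n_ch))
    dig_max = b"".join(_pad(str(_DIG_MAX), 8) for _ in range(n_ch))
    prefilter = b"".join(_pad("", 80) for _ in range(n_ch))
    n_samp = b"".join(_pad(str(fs), 8) for _ in range(n_ch))
    reserved = b"".join(_pad("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + phys_dim + phys_min + phys_max)
        fh.write(dig_min + dig_max + prefilter + n_samp + reserved)
        for r in range(n_rec):
            block = dig[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def write_events(events: list[tuple[float, str]], path) -> None:
    df = pd.DataFrame(events, columns=["onset_s", "code"])
    df["onset_s"] = df["onset_s"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> list[tuple[float, str]]:
    df = pd.read_csv(path, sep="\t")
    missing = {"onset_s", "code"} - set(df.columns)
    if missing:
        raise ValidationError(f"events file missing columns {sorted(missing)}")
    bad = sorted(set(df["code"]) - set(EVENT_CODES))
    if bad:
        raise ValidationError(
            f"unknown event codes {bad}; allowed codes are {list(EVENT_CODES)}"
        )
    onsets = df["onset_s"].astype(float).to_numpy()
    if np.any(np.diff(onsets) < 0):
        raise ValidationError("event onsets must be sorted ascending")
    return [(float(o), str(c)) for o, c in zip(onsets, df["code"])]


def write_session(session: EEGSession, edf_path, events_path) -> None:
    write_edf(session, edf_path)
    write_events(session.events, events_path)


def read_session(edf_path, events_path, required_channels=None) -> EEGSession:
    """Load an EDF recording and its events TSV into an :class:`EEGSession`.

    ``required_channels`` (default: the 32-channel analysis montage)
    must all be present in the file; a missing label raises a
    :class:`ValidationError` naming it.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    required = list(required_channels) if required_channels is not None else list(EEG_CHANNELS)
    for ch in required:
        if ch not in labels:
            raise ValidationError(f"required channel {ch!r} missing from {edf_path}")
    signal = raw.get_data() * 1e6  # MNE holds EEG in volts; sessions are in uV
    events = read_events(events_path)
    return EEGSession(
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        events=events,
    )


def record_to_row(record: SubjectRecord) -> dict:
    row = {"subject_id": record.subject_id}
    row.update({f"K{i + 1}": a for i, a in enumerate(record.kinesthetic_answers)})
    row.update({f"V{i + 1}": a for i, a in enumerate(record.visual_answers)})
    row.update(
        {
            "age": record.age,
            "gender": record.gender,
            "education_years": record.education_years,
        }
    )
    row.update({f: getattr(record, f) for f in SubjectRecord.FREQ_FIELDS})
    return row


def write_subjects(records: list[SubjectRecord], path) -> None:
    pd.DataFrame([record_to_row(r) for r in records])[SUBJECT_COLUMNS].to_csv(path, index=False)


def read_subjects(path) -> list[SubjectRecord]:
    """Read and validate the subject table (one record per row).

    Row-level violations (answers outside 1..7, ordinal factors out of
    range, duplicate ids) raise :class:`ValidationError` naming the
    subject and field.
    """
    df = pd.read_csv(path)
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"subject table missing columns {sorted(missing)}")
    records, seen = [], set()
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid in seen:
            raise ValidationError(f"duplicate subject_id {sid!r}")
        seen.add(sid)
        answers = [row[f"K{i}"] for i in range(1, 8)] + [row[f"V{i}"] for i in range(1, 8)]
        records.append(
            SubjectRecord(
                subject_id=sid,
                miq_answers=[int(a) for a in answers],
                age=float(row["age"]),
                gender=str(row["gender"]),
                education_years=float(row["education_years"]),
                **{f: int(row[f]) for f in SubjectRecord.FREQ_FIELDS},
            )
        )
    return records


def write_ground_truth(truth: list[dict], path) -> None:
    pd.DataFrame(truth).to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def is_emg(label: str) -> bool:
    """Whether a channel label denotes the (non-EEG) EMG monitor channel."""
    return label.upper() == EMG_CHANNEL
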