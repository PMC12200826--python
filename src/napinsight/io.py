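"""File formats: EDF recordings, plain-text hypnograms, CSV trial tables.

The EDF writer emits standard EDF (16-bit integers, physical units µV,
1-s data records), sufficient for interchange with the usual EEG readers;
recordings whose duration is not a whole number of seconds are truncated
to the last full record. Reading goes through MNE.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, Recording, SessionData, TrialRecord


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as 16-bit EDF with physical units µV."""
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = len(recording.channel_names)
    n_records = recording.samples.shape[1] // fs
    data = recording.samples[:, : n_records * fs]

    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768, 32767

    header = bytearray()
    header += _pad("0", 8)
    header += _pad("X X X X", 80)  # local patient id (anonymous)
    header += _pad("Startdate X", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (n_sig + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)  # record duration, seconds
    header += _pad(str(n_sig), 4)
    for name in recording.channel_names:
        header += _pad(f"EEG {name}", 16)
    for _ in range(n_sig):
        header += _pad("AgAgCl electrode", 80)
    for _ in range(n_sig):
        header += _pad("uV", 8)
    for v in phys_min:
        header += _pad(f"{v:.0f}", 8)
    for v in phys_max:
        header += _pad(f"{v:.0f}", 8)
    header += _pad(str(dig_min), 8) * n_sig
    header += _pad(str(dig_max), 8) * n_sig
    header += _pad("", 80) * n_sig  # prefiltering
    header += _pad(str(fs), 8) * n_sig
    header += _pad("", 32) * n_sig

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / gain[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())  # signal-major within each record


def read_edf(path: str | os.PathLike) -> Recording:
    """Read an EDF file into a Recording (lazy import of MNE)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    return Recording(
        samples=data, sampling_rate=float(raw.info["sfreq"]), channel_names=names
    )


# ---------------------------------------------------------------------------
# hypnogram text
# ---------------------------------------------------------------------------

def write_hypnogram(hypnogram: Hypnogram, path: str | os.PathLike) -> None:
    """One AASM code (W/N1/N2/N3/R) per line per 30-s epoch."""
    Path(path).write_text("\n".join(hypnogram.epoch_labels) + "\n")


def read_hypnogram(path: str | os.PathLike) -> Hypnogram:
    labels = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return Hypnogram(epoch_labels=labels)


# ---------------------------------------------------------------------------
# session CSV
# ---------------------------------------------------------------------------

SESSION_COLUMNS = [
    "block", "trial", "coherence", "colour", "direction",
    "response", "correct", "rt_ms",
]


def write_session_csv(session: SessionData, path: str | os.PathLike) -> None:
    session.to_frame()[SESSION_COLUMNS].to_csv(path, index=False)


def read_session_csv(path: str | os.PathLike, subject_id: str = "") -> SessionData:
    df = pd.read_csv(path)
    trials = [
        TrialRecord(
            block=int(r.block),
            trial_index=int(r.trial),
            coherence=float(r.coherence),
            colour=str(r.colour),
            direction=str(r.direction),
            response=str(r.response),
            correct=bool(r.correct),
            rt_ms=float(r.rt_ms),
            colour_predictive=int(r.trial) >= 351,
            instructed=int(r.block) == 9,
        )
        for r in df.itertuples()
    ]
    return SessionData(trials=trials, subject_id=subject_id)
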