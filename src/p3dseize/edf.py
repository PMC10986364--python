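"""Minimal European Data Format (EDF) writer and an mne-backed reader.

The writer emits plain EDF (not EDF+): 16-bit samples, one-second data
records, per-channel physical scaling in µV. Seizure onsets travel in a
plain-text sidecar ``<file>.seizures.tsv`` with columns subject_id, onset_s,
since plain EDF has no annotation channel.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .synth import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | os.PathLike) -> Path:
    """Write one recording to ``path`` and its onsets to ``<path>.seizures.tsv``."""
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record, per signal
    n_ch, n = recording.signal.shape
    n_records = int(np.ceil(n / spr)) if n else 0

    data = np.zeros((n_ch, n_records * spr))
    data[:, :n] = recording.signal
    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6) * (1 + 1e-6)
    pmin = -pmax
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join([
        _field(0, 8),
        _field(recording.subject_id, 80),
        _field("synthetic EEG", 80),
        _field("01.01.20", 8),
        _field("00.00.00", 8),
        _field(256 * (n_ch + 1), 8),
        _field("", 44),
        _field(n_records, 8),
        _field(1, 8),
        _field(n_ch, 4),
    ])
    cols = [
        [_field(name, 16) for name in recording.channel_names],
        [_field("AgAgCl electrode", 80)] * n_ch,
        [_field("uV", 8)] * n_ch,
        [_field(f"{v:.5g}"[:8], 8) for v in pmin],
        [_field(f"{v:.5g}"[:8], 8) for v in pmax],
        [_field(_DIG_MIN, 8)] * n_ch,
        [_field(_DIG_MAX, 8)] * n_ch,
        [_field("", 80)] * n_ch,
        [_field(spr, 8)] * n_ch,
        [_field("", 32)] * n_ch,
    ]
    signal_header = b"".join(b"".join(col) for col in cols)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        # record-major, signal-major within a record
        records = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(records).tobytes())

    sidecar = path.with_name(path.name + ".seizures.tsv")
    with open(sidecar, "w") as fh:
        fh.write("subject_id\tonset_s\n")
        for onset in recording.onsets_s:
            fh.write(f"{recording.subject_id}\t{onset:g}\n")
    return path


def read_seizure_sidecar(path: str | os.PathLike) -> list[float]:
    onsets = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = header.index("onset_s")
        for line in fh:
            if line.strip():
                onsets.append(float(line.rstrip("\n").split("\t")[idx]))
    return sorted(onsets)


def read_edf(path: str | os.PathLike) -> Recording:
    """Read an EDF file (µV) plus its seizure sidecar if present."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne loads volts
    subject = (raw.info.get("subject_info") or {}).get("his_id") or path.stem
    sidecar = path.with_name(path.name + ".seizures.tsv")
    onsets = read_seizure_sidecar(sidecar) if sidecar.exists() else []
    return Recording(
        signal=signal,
        channel_names=tuple(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        onsets_s=tuple(onsets),
        subject_id=str(subject),
    )
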