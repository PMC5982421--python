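"""Readers and writers for the package's file formats.

Formats: mono PCM WAV or headerless single-column CSV for recordings;
CSV for coefficient series, frame labels and classified timelines; JSON
for the trained network.  All writers go through a write-then-rename step
so an interrupted run never leaves a partially written file behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .spectral import AcousticRecord

__all__ = [
    "read_wav",
    "write_wav",
    "read_csv_signal",
    "write_coeffs_csv",
    "read_coeffs_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_timeline_csv",
    "read_timeline_csv",
    "atomic_write_text",
]

COEFF_COLUMNS = ["time", "a", "b", "c", "d", "sse", "r_square", "rmse"]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_wav(path: str | Path) -> AcousticRecord:
    """Read a mono PCM or float WAV file.

    Integer samples are rescaled to [-1, 1); stereo files are rejected
    because the acquisition chain is single-microphone.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    return AcousticRecord(samples=data, sample_rate=float(rate))


def write_wav(path: str | Path, record: AcousticRecord) -> None:
    """Write a record as 16-bit PCM mono WAV, peak-normalized to 0.9 FS."""
    samples = record.samples
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak * 0.9
    pcm = np.round(samples * 32767).astype(np.int16)
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        wavfile.write(tmp, int(record.sample_rate), pcm)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_csv_signal(path: str | Path, sample_rate: float) -> AcousticRecord:
    """Read a headerless single-column CSV of voltage samples."""
    data = pd.read_csv(path, header=None)
    if data.shape[1] != 1:
        raise ValueError(f"{path}: expected a single column, got {data.shape[1]}")
    return AcousticRecord(samples=data[0].to_numpy(float), sample_rate=sample_rate)


def write_coeffs_csv(path: str | Path, coeffs) -> None:
    """Write a coefficient series as `time,a,b,c,d,sse,r_square,rmse`."""
    rows = [
        (c.time, c.a, c.b, c.c, c.d, c.sse, c.r_square, c.rmse) for c in coeffs
    ]
    df = pd.DataFrame(rows, columns=COEFF_COLUMNS)
    atomic_write_text(path, df.to_csv(index=False))


def read_coeffs_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COEFF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_labels_csv(path: str | Path, times, labels) -> None:
    df = pd.DataFrame({"time": times, "label": labels})
    atomic_write_text(path, df.to_csv(index=False))


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time", "label"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time,label")
    return df


def write_timeline_csv(path: str | Path, times, scores, labels) -> None:
    """Classified timeline: `time,score,label` with -1 marking UNDECIDED."""
    df = pd.DataFrame({"time": times, "score": scores, "label": labels})
    atomic_write_text(path, df.to_csv(index=False))


def read_timeline_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time", "score", "label"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time,score,label")
    return df


def save_json(path: str | Path, obj: dict) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True))


def load_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
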