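"""Dual-channel audio I/O, framing, and cohort manifests.

The acquisition setup is a nasalance device: two microphones separated by a
baffle record the sound radiated from the nasal and oral cavities on separate
channels, sampled at 11,025 Hz.  All downstream analysis consumes the
:class:`DualChannelSignal` container defined here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile

#: Default phoneme inventory: aspirated unvoiced consonants and nonnasalized vowels.
CONSONANTS: tuple[str, ...] = ("p", "t", "k", "q", "c", "h", "x", "sh", "f")
VOWELS: tuple[str, ...] = ("a", "e", "i", "u")
PHONEME_INVENTORY: tuple[str, ...] = CONSONANTS + VOWELS

MANIFEST_COLUMNS = [
    "subject_id",
    "phoneme",
    "phoneme_class",
    "label",
    "nasal_wav",
    "oral_wav",
    "start_s",
    "end_s",
]


@dataclass
class DualChannelSignal:
    """Paired nasal/oral sample sequences at a shared sampling rate."""

    nasal: np.ndarray
    oral: np.ndarray
    fs: float
    subject_id: str = ""
    phoneme: str = ""
    phoneme_class: str = "consonant"  # "consonant" | "vowel"
    label: str = "unknown"  # "vpi" | "control" | "unknown"

    def __post_init__(self) -> None:
        self.nasal = np.asarray(self.nasal, dtype=np.float64)
        self.oral = np.asarray(self.oral, dtype=np.float64)
        if self.nasal.ndim != 1 or self.oral.ndim != 1:
            raise ValueError("channels must be 1-D sample sequences")
        if len(self.nasal) != len(self.oral):
            raise ValueError("channel length mismatch")
        if len(self.nasal) == 0:
            raise ValueError("empty segment")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (np.all(np.isfinite(self.nasal)) and np.all(np.isfinite(self.oral))):
            raise ValueError("samples must be finite")
        if self.phoneme_class not in ("consonant", "vowel"):
            raise ValueError(f"unknown phoneme class {self.phoneme_class!r}")
        if self.label not in ("vpi", "control", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.nasal)


@dataclass
class FrameMatrix:
    """Contiguous analysis frames of one channel (rows = frames)."""

    frames: np.ndarray  # (Nf, Lf)
    Lf: int
    Ls: int
    fs: float

    @property
    def Nf(self) -> int:
        return self.frames.shape[0]


@dataclass
class ManifestRecord:
    subject_id: str
    phoneme: str
    phoneme_class: str
    label: str
    nasal_wav: str
    oral_wav: str  # empty string for stereo input
    start_s: float
    end_s: float


@dataclass
class CohortManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)


def _to_float(x: np.ndarray) -> np.ndarray:
    """Decode integer PCM to floats in [-1, 1]; pass float data through."""
    if x.dtype == np.int16:
        return x.astype(np.float64) / 32768.0
    if x.dtype == np.int32:
        return x.astype(np.float64) / 2147483648.0
    if x.dtype == np.uint8:
        return (x.astype(np.float64) - 128.0) / 128.0
    return x.astype(np.float64)


def read_dual_wav(
    nasal_path: str | os.PathLike,
    oral_path: str | os.PathLike | None = None,
    start_s: float = 0.0,
    end_s: float | None = None,
    **meta: str,
) -> DualChannelSignal:
    """Read a nasal/oral pair from one stereo file or two mono files.

    Stereo convention: channel 0 = nasal, channel 1 = oral.  The returned
    signal is the ``[start_s, end_s)`` slice of both channels.
    """
    fs, data = wavfile.read(os.fspath(nasal_path))
    data = _to_float(np.asarray(data))
    if oral_path is None or str(oral_path) == "":
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError("mono file given with no oral_path")
        nasal, oral = data[:, 0], data[:, 1]
    else:
        if data.ndim != 1:
            data = data[:, 0]
        nasal = data
        fs2, oral = wavfile.read(os.fspath(oral_path))
        oral = _to_float(np.asarray(oral))
        if oral.ndim != 1:
            oral = oral[:, 0]
        if fs2 != fs:
            raise ValueError("sampling rate mismatch between channel files")
        if len(oral) != len(nasal):
            raise ValueError("channel length mismatch")

    n = len(nasal)
    if end_s is None:
        end_s = n / fs
    if not (0.0 <= start_s < end_s):
        raise ValueError("empty segment")
    i0 = int(round(start_s * fs))
    i1 = min(int(round(end_s * fs)), n)
    if i1 <= i0:
        raise ValueError("empty segment")
    return DualChannelSignal(nasal[i0:i1], oral[i0:i1], fs=float(fs), **meta)


def write_dual_wav(sig: DualChannelSignal, nasal_path: str | os.PathLike,
                   oral_path: str | os.PathLike | None = None) -> None:
    """Write a signal as two mono float32 WAVs, or one stereo file if no oral path."""
    fs = int(round(sig.fs))
    if oral_path is None:
        stereo = np.stack([sig.nasal, sig.oral], axis=1).astype(np.float32)
        wavfile.write(os.fspath(nasal_path), fs, stereo)
    else:
        wavfile.write(os.fspath(nasal_path), fs, sig.nasal.astype(np.float32))
        wavfile.write(os.fspath(oral_path), fs, sig.oral.astype(np.float32))


def frame_signal(signal: np.ndarray, fs: float, frame_ms: float = 20.0,
                 shift_ms: float = 6.0) -> FrameMatrix:
    """Split a signal into overlapping rectangular frames.

    Frame length and shift are ``floor(ms * fs / 1000)`` samples (220 and 66
    at 11,025 Hz with the 20 ms / 6 ms defaults).  No taper is applied: the
    spectral-ratio features downstream are ratio-based, so a common window
    would cancel anyway, and the rectangular window keeps the per-frame
    autocorrelation estimator in its plain summation form.
    """
    x = np.asarray(signal, dtype=np.float64)
    Lf = int(np.floor(frame_ms * fs / 1000.0))
    Ls = int(np.floor(shift_ms * fs / 1000.0))
    if Lf < 1 or Ls < 1:
        raise ValueError("frame/shift too short for this sampling rate")
    if len(x) < Lf:
        raise ValueError("segment too short")
    frames = np.ascontiguousarray(sliding_window_view(x, Lf)[::Ls])
    return FrameMatrix(frames=frames, Lf=Lf, Ls=Ls, fs=float(fs))


def read_manifest(path: str | os.PathLike, allow_extra_phonemes: bool = False) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Header: ``subject_id,phoneme,phoneme_class,label,nasal_wav,oral_wav,start_s,end_s``
    (``oral_wav`` may be empty when ``nasal_wav`` is a stereo file).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "phoneme": str,
                                  "phoneme_class": str, "label": str},
                     keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        if not str(row["subject_id"]):
            raise ValueError(f"row {idx}: empty subject_id")
        ph = str(row["phoneme"])
        if not allow_extra_phonemes and ph not in PHONEME_INVENTORY:
            raise ValueError(f"row {idx}: phoneme {ph!r} not in inventory")
        try:
            start_s = float(row["start_s"])
            end_s = float(row["end_s"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx}: unparseable segment bounds") from exc
        if not start_s < end_s:
            raise ValueError(f"row {idx}: start_s >= end_s")
        records.append(ManifestRecord(
            subject_id=str(row["subject_id"]), phoneme=ph,
            phoneme_class=str(row["phoneme_class"]), label=str(row["label"]),
            nasal_wav=str(row["nasal_wav"]), oral_wav=str(row["oral_wav"]),
            start_s=start_s, end_s=end_s))
    return CohortManifest(records=records)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    df = pd.DataFrame([vars(r) for r in manifest.records], columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def load_segment(record: ManifestRecord, root: str | os.PathLike = ".") -> DualChannelSignal:
    """Load the audio segment a manifest row points at."""
    root = Path(root)
    nasal = root / record.nasal_wav
    oral = root / record.oral_wav if record.oral_wav else None
    return read_dual_wav(nasal, oral, record.start_s, record.end_s,
                         subject_id=record.subject_id, phoneme=record.phoneme,
                         phoneme_class=record.phoneme_class, label=record.label)
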