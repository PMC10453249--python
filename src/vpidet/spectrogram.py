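"""Spectrogram-pair input layer for the vowel network.

Hypernasality shows up as extra low-frequency resonance and raised energy in
the nasal channel of a vowel.  Both channels of a vowel segment are turned
into log-magnitude spectrograms on a shared time/frequency grid and
normalized *jointly*, so the inter-channel level difference — the diagnostic
signal — survives normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal_io import DualChannelSignal

NFFT = 128          # 64 positive-frequency bins; DC dropped
MIN_FRAMES = 8


@dataclass
class SpectrogramPair:
    """Two side x side log-magnitude time-frequency images (rows = frequency
    ascending, columns = time), jointly min-max normalized to [0, 1]."""

    S_n: np.ndarray
    S_o: np.ndarray
    smin: float
    smax: float
    label: str = "unknown"
    subject_id: str = ""
    phoneme: str = ""


def _stft_mag(x: np.ndarray, hop: int, window: np.ndarray) -> np.ndarray:
    frames = sliding_window_view(x, NFFT)[::hop] * window
    return np.abs(np.fft.rfft(frames, axis=1))[:, 1:NFFT // 2 + 1]  # drop DC


def _resample_time(img: np.ndarray, side: int) -> np.ndarray:
    """Linearly interpolate the time axis (axis 0 = frames) to `side` columns."""
    n = img.shape[0]
    if n == side:
        return img
    src = np.arange(n)
    dst = np.linspace(0, n - 1, side)
    out = np.empty((side, img.shape[1]))
    for k in range(img.shape[1]):
        out[:, k] = np.interp(dst, src, img[:, k])
    return out


def make_spectrogram_pair(sig: DualChannelSignal, side: int = 64) -> SpectrogramPair:
    """Build the paired network input from a vowel segment.

    Short-time analysis uses 128-sample Hann-windowed frames (~11.6 ms at
    11,025 Hz) with the hop chosen so the frame count is at least ``side``;
    magnitudes are log-compressed with log(1 + |S|) and the time axis is
    linearly resampled to exactly ``side`` columns.
    """
    L = len(sig)
    if L < NFFT + MIN_FRAMES - 1:
        raise ValueError("segment too short for spectrogram analysis")
    hop = max(1, (L - NFFT) // (side - 1))
    window = np.hanning(NFFT)
    mats = []
    for x in (sig.nasal, sig.oral):
        S = np.log1p(_stft_mag(x, hop, window))
        mats.append(_resample_time(S, side).T)  # rows = frequency ascending
    smin = min(m.min() for m in mats)
    smax = max(m.max() for m in mats)
    scale = smax - smin if smax > smin else 1.0
    S_n, S_o = [(m - smin) / scale for m in mats]
    return SpectrogramPair(S_n=S_n, S_o=S_o, smin=float(smin), smax=float(smax),
                           label=sig.label, subject_id=sig.subject_id,
                           phoneme=sig.phoneme)


def spectrogram_bin_hz(fs: float) -> float:
    """Frequency spacing of the spectrogram rows (row r is (r+1) * fs / NFFT)."""
    return fs / NFFT
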