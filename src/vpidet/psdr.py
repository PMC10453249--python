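"""Per-frame power spectral density ratio (PSDR) under a linear crosstalk model.

Each microphone picks up a crosstalk-attenuated copy of the opposite cavity's
radiation: x_o = o + alpha*n, x_n = alpha*o + n.  Because the two cavities'
frication sources are uncorrelated and alpha^2 is negligible, the PSD of each
recorded channel approximates the PSD of its own cavity's radiated signal, so

    R(w, i) = S_nn(w, i) / (S_oo(w, i) + S_nn(w, i))

is estimated directly from the recorded channels, frame by frame.  A robust
per-frequency average keeps only the interquartile frames.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import DualChannelSignal, FrameMatrix, frame_signal

log = logging.getLogger(__name__)

EPS_REL = 1e-12
EPS_FLOOR = 1e-20


@dataclass
class CrosstalkModel:
    """Baffle attenuation of the opposite channel (beta is taken equal to alpha).

    Advisory only: the ratio estimator already embeds the alpha^2 ~ 0
    approximation and never divides by alpha.
    """

    alpha: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass
class PSDRMatrix:
    """Per-frame, per-frequency ratio R(w, i) in [0, 1]."""

    R: np.ndarray          # (Nf, Nb)
    freqs: np.ndarray      # (Nb,) bin centers in Hz
    Ns: int                # FFT length
    delta_omega: float     # bin width fs/Ns in Hz
    fs: float

    @property
    def Nf(self) -> int:
        return self.R.shape[0]

    @property
    def Nb(self) -> int:
        return self.R.shape[1]


@dataclass
class AveragedPSDR:
    """Interquartile-averaged ratio per frequency bin."""

    rbar: np.ndarray       # (Nb,)
    Nf_used: int
    freqs: np.ndarray
    delta_omega: float
    fs: float

    @property
    def Nb(self) -> int:
        return len(self.rbar)


def autocorr_biased(frame: np.ndarray, Ns: int) -> np.ndarray:
    """Biased (unnormalized-sum) autocorrelation r[m] = sum_t x[t] x[t+m], m = 0..Ns-1.

    Lags at or beyond the frame length are zero.
    """
    x = np.asarray(frame, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty frame")
    full = np.correlate(x, x, mode="full")[x.size - 1:]  # lags 0..Lf-1
    r = np.zeros(Ns)
    m = min(Ns, full.size)
    r[:m] = full[:m]
    return r


def frame_psd(frame: np.ndarray, Ns: int = 256) -> np.ndarray:
    """One-sided periodogram |FFT_Ns(x)|^2 / Lf, length Ns//2 + 1.

    By the Wiener-Khinchin theorem this equals the Fourier transform of the
    biased autocorrelation (circularly folded into Ns points); the periodogram
    form guarantees nonnegativity, which the ratio below presupposes.
    Frames shorter than Ns are zero-padded; longer frames are truncated with
    a logged warning.
    """
    x = np.asarray(frame, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty frame")
    Lf = x.size
    if Lf > Ns:
        log.warning("frame length %d exceeds FFT length %d; truncating", Lf, Ns)
        x = x[:Ns]
    spec = np.fft.rfft(x, n=Ns)
    return (spec.real ** 2 + spec.imag ** 2) / Lf


def psdr_frame(psd_nasal: np.ndarray, psd_oral: np.ndarray,
               eps: float | None = None) -> np.ndarray:
    """Ratio R[k] = (P_n[k] + eps/2) / (P_n[k] + P_o[k] + eps), always in (0, 1).

    The symmetric eps placement makes channel swap map R to exactly 1 - R and
    turns an all-zero bin into the uninformative value 0.5.  By default eps is
    tied to the largest total bin power (relative 1e-12, floor 1e-20).
    """
    pn = np.asarray(psd_nasal, dtype=np.float64)
    po = np.asarray(psd_oral, dtype=np.float64)
    if pn.shape != po.shape:
        raise ValueError("spectra must have equal length")
    if np.any(pn < 0) or np.any(po < 0):
        raise ValueError("negative PSD entry (upstream bug)")
    tot = pn + po
    if eps is None:
        eps = max(EPS_REL * float(tot.max(initial=0.0)), EPS_FLOOR)
    return (pn + eps / 2.0) / (tot + eps)


def psdr_matrix(nasal_frames: FrameMatrix, oral_frames: FrameMatrix,
                Ns: int = 256, window: str = "hann") -> PSDRMatrix:
    """Stack per-frame ratios into an Nf x (Ns/2+1) matrix.

    A Hann analysis taper is applied to each frame before the PSD estimate:
    the identical taper on both channels cancels in the in-band ratio, while
    its low sidebands stop spectral leakage from smearing band-limited energy
    across distant bins — with a rectangular window, leaked nasal energy
    inflates the ratio at frequencies the nasal source never excited.
    Pass ``window="rect"`` for the plain periodogram.
    """
    if nasal_frames.Nf != oral_frames.Nf:
        raise ValueError("frame count mismatch between channels")
    fs = nasal_frames.fs
    if window == "hann":
        taper = np.hanning(nasal_frames.Lf)
    elif window == "rect":
        taper = np.ones(nasal_frames.Lf)
    else:
        raise ValueError(f"unknown analysis window {window!r}")
    rows = []
    for i in range(nasal_frames.Nf):
        pn = frame_psd(nasal_frames.frames[i] * taper, Ns)
        po = frame_psd(oral_frames.frames[i] * taper, Ns)
        rows.append(psdr_frame(pn, po))
    R = np.vstack(rows)
    delta = fs / Ns
    freqs = np.arange(R.shape[1]) * delta
    return PSDRMatrix(R=R, freqs=freqs, Ns=Ns, delta_omega=delta, fs=fs)


def average_psdr(matrix: PSDRMatrix) -> AveragedPSDR:
    """Interquartile average across frames, per frequency bin.

    The Nf values of each bin are sorted ascending; the mean is taken over the
    1-based order statistics ceil(Nf/4) .. ceil(3*Nf/4) inclusive.  With
    Nf = 1 the single value is returned unchanged.
    """
    Nf = matrix.Nf
    if Nf < 1:
        raise ValueError("empty matrix")
    lo = int(np.ceil(Nf / 4.0))        # 1-based
    hi = int(np.ceil(3.0 * Nf / 4.0))
    srt = np.sort(matrix.R, axis=0)
    rbar = srt[lo - 1:hi].mean(axis=0)
    return AveragedPSDR(rbar=rbar, Nf_used=Nf, freqs=matrix.freqs,
                        delta_omega=matrix.delta_omega, fs=matrix.fs)


def averaged_psdr_of(sig: DualChannelSignal, frame_ms: float = 20.0,
                     shift_ms: float = 6.0, Ns: int = 256) -> AveragedPSDR:
    """Convenience composition: frame both channels, ratio, robust average."""
    nf = frame_signal(sig.nasal, sig.fs, frame_ms, shift_ms)
    of = frame_signal(sig.oral, sig.fs, frame_ms, shift_ms)
    return average_psdr(psdr_matrix(nf, of, Ns))


def estimate_crosstalk(control_signals: list[DualChannelSignal]) -> CrosstalkModel:
    """Estimate the baffle attenuation from oral-only control recordings.

    For a recording with no nasal radiation, the nasal channel carries only
    alpha-scaled oral sound, so sqrt(nasal energy / oral energy) estimates
    alpha.  The median over recordings is returned.  Diagnostic only.
    """
    if not control_signals:
        raise ValueError("need at least one control recording")
    ests = []
    for sig in control_signals:
        eo = float(np.sum(sig.oral ** 2))
        en = float(np.sum(sig.nasal ** 2))
        if eo == 0.0:
            raise ValueError("zero oral energy")
        ests.append(np.sqrt(en / eo))
    alpha = float(np.median(ests))
    if alpha >= 1.0:
        warnings.warn("estimated crosstalk alpha >= 1: channels have comparable "
                      "energy; recording is not oral-only", stacklevel=2)
    return CrosstalkModel(alpha=alpha)


def dump_psdr_matrix(matrix: PSDRMatrix, path: str) -> None:
    """Debug dump: tab-separated, one frame per row."""
    np.savetxt(path, matrix.R, delimiter="\t")
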