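"""Synthetic dual-channel cohort generator.

Emulates the statistical structure the detection method relies on:

* Unvoiced consonants: two *independent* band-shaped noise sources, one per
  cavity.  A leakage fraction lambda routes source energy to the nasal
  cavity (sqrt(lambda)-scaled nasal source, sqrt(1-lambda)-scaled oral
  source); each band-filtered source is RMS-normalized before scaling so
  lambda is exactly the nasal share of pre-mixing source energy.
* Vowels: one shared glottal source (jittered impulse train shaped by a
  smooth decaying pulse) split between an oral branch (cascaded two-pole
  formant resonators) and a nasal branch (a single low nasal resonance),
  scaled by (1 - lambda) and lambda respectively.
* Both are mixed with linear inter-microphone crosstalk:
  x_o = o + alpha * n,  x_n = alpha * o + n  (beta = alpha).

VPI subjects draw lambda ~ U(0.30, 0.70), controls ~ U(0.00, 0.05), one draw
per subject shared across all of that subject's phonemes, so subject-level
voting is a genuinely subject-structured task.  Everything is reproducible
from the cohort seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import (CONSONANTS, VOWELS, CohortManifest, DualChannelSignal,
                        ManifestRecord, write_dual_wav, write_manifest)

DEFAULT_FS = 11025.0
DEFAULT_ALPHA = 0.1

#: Oral formants (center Hz, bandwidth Hz) per vowel; standard-phonetics-style
#: presets, fully overridable.
VOWEL_FORMANTS: dict[str, list[tuple[float, float]]] = {
    "a": [(800.0, 80.0), (1200.0, 90.0), (2500.0, 120.0)],
    "e": [(500.0, 70.0), (1800.0, 100.0), (2500.0, 120.0)],
    "i": [(300.0, 60.0), (2300.0, 100.0), (3000.0, 120.0)],
    "u": [(350.0, 60.0), (800.0, 80.0), (2250.0, 120.0)],
}
NASAL_RESONANCE: tuple[float, float] = (300.0, 100.0)

#: Frication bands: oral frication sits high (within the top linear subband
#: at fs = 11,025 Hz), nasal air emission low.
DEFAULT_ORAL_BAND: tuple[float, float] = (4200.0, 5400.0)
DEFAULT_NASAL_BAND: tuple[float, float] = (200.0, 1300.0)


@dataclass
class ConsonantNoiseModel:
    oral_band: tuple[float, float] = DEFAULT_ORAL_BAND
    nasal_band: tuple[float, float] = DEFAULT_NASAL_BAND
    leakage: float = 0.0
    duration_s: float = 0.3
    #: power fraction of a broadband noise floor in the oral source: oral
    #: frication is high-band-emphasized but not strictly band-limited, so the
    #: low-band nasal/oral ratio grows smoothly with leakage instead of
    #: saturating the moment any nasal energy appears
    oral_floor: float = 0.1


@dataclass
class VowelSourceFilterModel:
    f0: float = 140.0
    oral_formants: list[tuple[float, float]] = field(
        default_factory=lambda: list(VOWEL_FORMANTS["a"]))
    nasal_resonance: tuple[float, float] = NASAL_RESONANCE
    leakage: float = 0.0
    duration_s: float = 0.5


@dataclass
class CohortSpec:
    n_vpi: int = 15
    n_control: int = 15
    phonemes: tuple[str, ...] = CONSONANTS + VOWELS
    lambda_vpi: tuple[float, float] = (0.30, 0.70)
    lambda_control: tuple[float, float] = (0.00, 0.05)
    alpha: float = DEFAULT_ALPHA
    fs: float = DEFAULT_FS
    seed: int = 0
    hard: bool = False   # narrow the lambda gap for stress testing

    def lambda_ranges(self) -> tuple[tuple[float, float], tuple[float, float]]:
        if self.hard:
            return (0.15, 0.45), (0.00, 0.12)
        return self.lambda_vpi, self.lambda_control


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Exact FFT-domain bandpass: zero response outside [lo, hi].

    A sharp band edge keeps each source's energy inside its nominal band, so
    the leakage fraction maps cleanly onto per-subband ratio structure.
    """
    lo, hi = band
    if not 0.0 < lo < hi < fs / 2.0:
        raise ValueError(f"invalid band edges {band} for fs={fs}")
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), d=1.0 / fs)
    X[(f < lo) | (f > hi)] = 0.0
    return np.fft.irfft(X, n=len(x))


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _mix(o: np.ndarray, n: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    x_o = o + alpha * n
    x_n = alpha * o + n
    peak = max(np.abs(x_o).max(initial=0.0), np.abs(x_n).max(initial=0.0))
    if peak > 0:
        x_o = x_o / (peak * 1.01)
        x_n = x_n / (peak * 1.01)
    return x_n, x_o


def gen_unvoiced_consonant(model: ConsonantNoiseModel, alpha: float = DEFAULT_ALPHA,
                           fs: float = DEFAULT_FS, seed: int = 0,
                           **meta: str) -> DualChannelSignal:
    """Two independent band-shaped noise sources, leakage split, crosstalk mix."""
    lam = model.leakage
    if not 0.0 <= lam <= 1.0:
        raise ValueError("leakage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_samp = int(round(model.duration_s * fs))
    o_band = _unit_rms(_bandpass(rng.standard_normal(n_samp), model.oral_band, fs))
    o = (np.sqrt(1.0 - model.oral_floor) * o_band
         + np.sqrt(model.oral_floor) * rng.standard_normal(n_samp))
    n = _unit_rms(_bandpass(rng.standard_normal(n_samp), model.nasal_band, fs))
    o = np.sqrt(1.0 - lam) * o
    n = np.sqrt(lam) * n
    x_n, x_o = _mix(o, n, alpha)
    return DualChannelSignal(x_n, x_o, fs=fs, phoneme_class="consonant", **meta)


def _glottal_source(f0: float, duration_s: float, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Jittered impulse train convolved with a smooth decaying glottal pulse."""
    n_samp = int(round(duration_s * fs))
    period = fs / f0
    src = np.zeros(n_samp)
    t = 0.0
    while t < n_samp:
        i = int(round(t))
        if i < n_samp:
            src[i] = 1.0 + 0.05 * rng.standard_normal()     # shimmer
        t += period * (1.0 + 0.01 * rng.standard_normal())  # jitter
    tau = 1e-3 * fs   # 1 ms pulse time constant
    k = np.arange(int(6 * tau))
    pulse = k * np.exp(-k / tau)
    pulse /= pulse.max()
    return sps.fftconvolve(src, pulse)[:n_samp]


def _resonator_sos(center: float, bandwidth: float, fs: float) -> np.ndarray:
    r = np.exp(-np.pi * bandwidth / fs)
    theta = 2.0 * np.pi * center / fs
    return np.array([[1.0 - r, 0.0, 0.0, 1.0, -2.0 * r * np.cos(theta), r * r]])


def gen_vowel(model: VowelSourceFilterModel, alpha: float = DEFAULT_ALPHA,
              fs: float = DEFAULT_FS, seed: int = 0, **meta: str) -> DualChannelSignal:
    """Shared glottal source through oral formant cascade and nasal resonator."""
    lam = model.leakage
    if not 0.0 <= lam <= 1.0:
        raise ValueError("leakage must be in [0, 1]")
    for c, _ in model.oral_formants:
        if c >= fs / 2.0:
            raise ValueError(f"formant {c} Hz at or above Nyquist")
    if model.nasal_resonance[0] >= fs / 2.0:
        raise ValueError("nasal resonance above Nyquist")
    rng = np.random.default_rng(seed)
    src = _glottal_source(model.f0, model.duration_s, fs, rng)
    oral = src.copy()
    for center, bw in model.oral_formants:
        oral = sps.sosfilt(_resonator_sos(center, bw, fs), oral)
    nasal = sps.sosfilt(_resonator_sos(*model.nasal_resonance, fs), src)
    o = (1.0 - lam) * _unit_rms(oral)
    n = lam * _unit_rms(nasal)
    x_n, x_o = _mix(o, n, alpha)
    return DualChannelSignal(x_n, x_o, fs=fs, phoneme_class="vowel", **meta)


def _phoneme_signal(phoneme: str, lam: float, f0: float, alpha: float, fs: float,
                    seed: int, **meta: str) -> DualChannelSignal:
    if phoneme in VOWELS:
        model = VowelSourceFilterModel(f0=f0, oral_formants=list(VOWEL_FORMANTS[phoneme]),
                                       leakage=lam)
        return gen_vowel(model, alpha, fs, seed, phoneme=phoneme, **meta)
    # small per-phoneme band perturbation so consonants are not clones
    rng = np.random.default_rng(seed + 7919)
    lo, hi = DEFAULT_ORAL_BAND
    shift = rng.uniform(-300.0, 100.0)  # keep the upper edge below Nyquist
    model = ConsonantNoiseModel(oral_band=(lo + shift, hi + shift), leakage=lam)
    return gen_unvoiced_consonant(model, alpha, fs, seed, phoneme=phoneme, **meta)


def synthesize_cohort(spec: CohortSpec) -> tuple[list[DualChannelSignal], pd.DataFrame]:
    """In-memory cohort: one signal per (subject, phoneme), plus the truth table."""
    root = np.random.SeedSequence(spec.seed)
    lam_vpi, lam_ctl = spec.lambda_ranges()
    signals: list[DualChannelSignal] = []
    truth_rows = []
    subjects = ([("vpi", i) for i in range(spec.n_vpi)]
                + [("control", i) for i in range(spec.n_control)])
    children = root.spawn(len(subjects))
    for (label, i), child in zip(subjects, children):
        rng = np.random.default_rng(child)
        lo, hi = lam_vpi if label == "vpi" else lam_ctl
        lam = float(rng.uniform(lo, hi))
        f0 = float(rng.uniform(100.0, 220.0))
        sid = f"{label}_{i:03d}"
        truth_rows.append({"subject_id": sid, "lambda": lam, "label": label})
        for ph in spec.phonemes:
            seed = int(rng.integers(0, 2 ** 31 - 1))
            signals.append(_phoneme_signal(ph, lam, f0, spec.alpha, spec.fs, seed,
                                           subject_id=sid, label=label))
    return signals, pd.DataFrame(truth_rows)


def gen_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortManifest:
    """Write the cohort as WAV pairs + manifest.csv + truth.csv under out_dir."""
    out = Path(out_dir)
    (out / "wav").mkdir(parents=True, exist_ok=True)
    signals, truth = synthesize_cohort(spec)
    records = []
    for sig in signals:
        base = f"{sig.subject_id}_{sig.phoneme}"
        nasal_rel = f"wav/{base}_nasal.wav"
        oral_rel = f"wav/{base}_oral.wav"
        write_dual_wav(sig, out / nasal_rel, out / oral_rel)
        records.append(ManifestRecord(
            subject_id=sig.subject_id, phoneme=sig.phoneme,
            phoneme_class=sig.phoneme_class, label=sig.label,
            nasal_wav=nasal_rel, oral_wav=oral_rel,
            start_s=0.0, end_s=len(sig) / sig.fs))
    manifest = CohortManifest(records=records)
    write_manifest(manifest, out / "manifest.csv")
    truth.to_csv(out / "truth.csv", index=False)
    return manifest
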