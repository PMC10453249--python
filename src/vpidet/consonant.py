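"""Consonant features (RPFD + RFD) and the phoneme-level margin classifier.

Nasal air emission during unvoiced consonants shifts acoustic energy from the
oral to the nasal channel.  Two feature families summarize the averaged PSD
ratio curve R̄(w):

* RPFD (relative prominent frequency description): the maximum of R̄, the
  maximum of its first forward difference, and the frequencies of both.
* RFD (relative frequency distribution): the fraction of the area under R̄
  in each of Nh equal linear subbands (default 4; at fs = 11,025 Hz and an
  FFT length of 256 the top subband starts at 3fs/8 ≈ 4134 Hz, where oral
  frication concentrates).

The DC bin is excluded from both the extremum search and the subband mass:
it carries no frication information and its exclusion leaves 128 bins that
split evenly into 4 subbands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .psdr import AveragedPSDR, averaged_psdr_of
from .signal_io import DualChannelSignal

FEATURE_NAMES_RPFD = ["MR", "locMR_hz", "MDR", "locMDR_hz"]


@dataclass
class RPFDFeatures:
    MR: float        # max of rbar over non-DC bins, in [0, 1]
    locMR: float     # frequency of MR in Hz
    MDR: float       # max forward difference of rbar, in [-1, 1]
    locMDR: float    # lower frequency of the maximizing pair, in Hz

    def to_array(self) -> np.ndarray:
        return np.array([self.MR, self.locMR, self.MDR, self.locMDR])


@dataclass
class RFDFeatures:
    rfd: np.ndarray  # (Nh,) subband area fractions, summing to 1

    @property
    def Nh(self) -> int:
        return len(self.rfd)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.rfd)


@dataclass
class ConsonantFeatureVector:
    rpfd: RPFDFeatures
    rfd: RFDFeatures
    phoneme: str = ""
    subject_id: str = ""

    def to_array(self) -> np.ndarray:
        """Order: [MR, locMR, MDR, locMDR, RFD_1..RFD_Nh]."""
        return np.concatenate([self.rpfd.to_array(), self.rfd.to_array()])

    @property
    def names(self) -> list[str]:
        return FEATURE_NAMES_RPFD + [f"rfd_{j + 1}" for j in range(self.rfd.Nh)]


def rpfd(avg: AveragedPSDR) -> RPFDFeatures:
    """Extract the prominent-frequency description from an averaged ratio curve.

    The search runs over bins 1..Nb-1 (DC excluded).  Forward differences are
    rbar[k+1] - rbar[k]; the reported locMDR is the lower frequency of the
    pair.  Argmax ties break toward the lowest frequency.
    """
    r = np.asarray(avg.rbar)
    if len(r) < 3:
        raise ValueError("too few frequency bins")
    body = r[1:]                        # bins 1..Nb-1
    k = int(np.argmax(body)) + 1
    MR = float(r[k])
    locMR = k * avg.delta_omega
    d = body[1:] - body[:-1]            # d[j] at bins (j+1, j+2)
    j = int(np.argmax(d)) + 1
    MDR = float(d[j - 1])
    locMDR = j * avg.delta_omega
    return RPFDFeatures(MR=MR, locMR=locMR, MDR=MDR, locMDR=locMDR)


def rfd(avg: AveragedPSDR, Nh: int = 4) -> RFDFeatures:
    """Fraction of averaged-ratio area in each of Nh equal linear subbands."""
    if Nh < 2:
        raise ValueError("Nh must be at least 2")
    body = np.asarray(avg.rbar)[1:]     # DC excluded
    if len(body) % Nh != 0:
        raise ValueError(f"{len(body)} non-DC bins not divisible into {Nh} subbands")
    total = float(body.sum())
    assert total > 0, "zero total area cannot occur under the eps scheme"
    fractions = body.reshape(Nh, -1).sum(axis=1) / total
    return RFDFeatures(rfd=fractions)


def subband_edges_hz(fs: float, Nh: int = 4) -> np.ndarray:
    """Linear subband boundary frequencies j*fs/(2*Nh), j = 0..Nh."""
    return np.arange(Nh + 1) * fs / (2.0 * Nh)


@dataclass
class AnalysisConfig:
    """Shared framing / spectral-analysis parameters."""

    frame_ms: float = 20.0
    shift_ms: float = 6.0
    Ns: int = 256
    Nh: int = 4


def extract_consonant_features(sig: DualChannelSignal,
                               cfg: AnalysisConfig | None = None) -> ConsonantFeatureVector:
    """Frame both channels, estimate the averaged PSD ratio, extract RPFD + RFD."""
    cfg = cfg or AnalysisConfig()
    avg = averaged_psdr_of(sig, cfg.frame_ms, cfg.shift_ms, cfg.Ns)
    return ConsonantFeatureVector(rpfd=rpfd(avg), rfd=rfd(avg, cfg.Nh),
                                  phoneme=sig.phoneme, subject_id=sig.subject_id)


@dataclass
class ClassifierConfig:
    kind: str = "svm"        # "svm" | "lda" | "adaboost"
    C: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    seed: int = 0


@dataclass
class ConsonantClassifier:
    """Standardization + margin classifier over the 4 + Nh consonant features."""

    cfg: ClassifierConfig = field(default_factory=ClassifierConfig)
    pipeline: Pipeline | None = None
    n_features: int | None = None

    @property
    def fitted(self) -> bool:
        return self.pipeline is not None

    def _make_estimator(self):
        if self.cfg.kind == "svm":
            return SVC(C=self.cfg.C, kernel=self.cfg.kernel, gamma=self.cfg.gamma,
                       random_state=self.cfg.seed)
        if self.cfg.kind == "lda":
            from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
            return LinearDiscriminantAnalysis()
        if self.cfg.kind == "adaboost":
            from sklearn.ensemble import AdaBoostClassifier
            return AdaBoostClassifier(random_state=self.cfg.seed)
        raise ValueError(f"unknown classifier kind {self.cfg.kind!r}")

    def fit(self, X: np.ndarray, labels: list[str]) -> "ConsonantClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(labels)
        if X.shape[0] < 4:
            raise ValueError("need at least 4 training samples")
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes in the training set")
        self.pipeline = Pipeline([("scale", StandardScaler()),
                                  ("clf", self._make_estimator())])
        self.pipeline.fit(X, y)
        self.n_features = X.shape[1]
        return self

    def predict(self, fv: np.ndarray) -> tuple[str, float]:
        """Deterministic label plus a signed decision score for one feature vector."""
        if not self.fitted:
            raise ValueError("classifier not fitted")
        x = np.atleast_2d(np.asarray(fv, dtype=np.float64))
        if x.shape[1] != self.n_features:
            raise ValueError("feature length mismatch vs training")
        label = str(self.pipeline.predict(x)[0])
        clf = self.pipeline.named_steps["clf"]
        if hasattr(clf, "decision_function"):
            score = float(self.pipeline.decision_function(x)[0])
        else:  # pragma: no cover - probabilistic fallback
            score = float(self.pipeline.predict_proba(x)[0, -1])
        return label, score


def fit_consonant_classifier(features: list[ConsonantFeatureVector], labels: list[str],
                             cfg: ClassifierConfig | None = None) -> ConsonantClassifier:
    X = np.vstack([fv.to_array() for fv in features])
    model = ConsonantClassifier(cfg=cfg or ClassifierConfig())
    return model.fit(X, labels)


def predict_consonant(model: ConsonantClassifier,
                      fv: ConsonantFeatureVector) -> tuple[str, float]:
    return model.predict(fv.to_array())
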