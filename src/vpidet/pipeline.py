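"""End-to-end orchestration: features, per-fold training, voting, evaluation.

The default protocol is subject-grouped, label-stratified k-fold
cross-validation: no subject contributes phonemes to both the train and test
side of any fold, which avoids speaker leakage.  Within each fold a margin
classifier is fitted on the consonant features and a CARS-Net on the vowel
spectrogram pairs; held-out phonemes are predicted and fused per subject by
strict-majority vote.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import (MetricSet, PhonemePrediction, SubjectPrediction,
                        compute_metrics, vote_subject)
from .carsnet import CARSNet, VowelNetConfig, predict_vowel, train_vowel_model
from .consonant import (AnalysisConfig, ClassifierConfig, ConsonantClassifier,
                        extract_consonant_features, fit_consonant_classifier,
                        predict_consonant)
from .signal_io import CohortManifest, DualChannelSignal, load_segment
from .spectrogram import make_spectrogram_pair

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    vowel: VowelNetConfig = field(default_factory=VowelNetConfig)
    folds: int = 10
    group_folds: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CrossvalResult:
    subject_predictions: list[SubjectPrediction]
    subject_truth: dict[str, str]
    subject_metrics: MetricSet
    phoneme_metrics: MetricSet
    consonant_metrics: MetricSet
    vowel_metrics: MetricSet
    fold_assignment: dict[str, int]

    def predictions_frame(self) -> pd.DataFrame:
        truth = self.subject_truth
        return pd.DataFrame([
            {"subject_id": p.subject_id, "n_phonemes": p.n_phonemes,
             "n_vpi_votes": p.n_vpi_votes, "vote_fraction": p.vote_fraction,
             "pred_label": p.label, "true_label": truth[p.subject_id]}
            for p in self.subject_predictions])


def load_manifest_signals(manifest: CohortManifest,
                          root: str = ".") -> list[DualChannelSignal]:
    return [load_segment(r, root) for r in manifest.records]


def grouped_fold_assignment(subject_labels: dict[str, str], n_folds: int,
                            seed: int) -> dict[str, int]:
    """Deterministic label-stratified round-robin assignment of subjects to folds."""
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for label in sorted(set(subject_labels.values())):
        subs = sorted(s for s, lab in subject_labels.items() if lab == label)
        if len(subs) < n_folds:
            raise ValueError(f"class {label!r} has {len(subs)} subjects "
                             f"for {n_folds} folds")
        rng.shuffle(subs)
        for i, s in enumerate(subs):
            assignment[s] = i % n_folds
    return assignment


def ungrouped_fold_assignment(signals: list[DualChannelSignal], n_folds: int,
                              seed: int) -> np.ndarray:
    """Phoneme-level stratified folds (subjects may straddle folds)."""
    from sklearn.model_selection import StratifiedKFold
    y = [s.label for s in signals]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(signals), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_of[test_idx] = f
    return fold_of


@dataclass
class TrainedModels:
    consonant: ConsonantClassifier
    vowel: CARSNet
    analysis: AnalysisConfig


def train_models(signals: list[DualChannelSignal], cfg: RunConfig) -> TrainedModels:
    """Fit the consonant classifier and CARS-Net on a labeled signal set."""
    cons = [s for s in signals if s.phoneme_class == "consonant"]
    vows = [s for s in signals if s.phoneme_class == "vowel"]
    feats = [extract_consonant_features(s, cfg.analysis) for s in cons]
    cons_model = fit_consonant_classifier(feats, [s.label for s in cons],
                                          cfg.classifier)
    pairs = [(make_spectrogram_pair(s, cfg.vowel.side), s.label) for s in vows]
    vowel_model, _ = train_vowel_model(pairs, cfg.vowel)
    return TrainedModels(consonant=cons_model, vowel=vowel_model,
                         analysis=cfg.analysis)


def predict_phoneme(models: TrainedModels, sig: DualChannelSignal) -> PhonemePrediction:
    if sig.phoneme_class == "consonant":
        label, score = predict_consonant(
            models.consonant, extract_consonant_features(sig, models.analysis))
    elif sig.phoneme_class == "vowel":
        label, score = predict_vowel(
            models.vowel, make_spectrogram_pair(sig, models.vowel.cfg.side))
    else:
        raise ValueError(f"no model for phoneme class {sig.phoneme_class!r}")
    return PhonemePrediction(subject_id=sig.subject_id, phoneme=sig.phoneme,
                             label=label, score=score)


def predict_subject(signals: list[DualChannelSignal],
                    models: TrainedModels) -> SubjectPrediction:
    """Route one subject's phonemes to the right model and vote."""
    if not signals:
        raise ValueError("empty subject")
    preds = [predict_phoneme(models, s) for s in signals]
    return vote_subject(preds)


def run_crossval(signals: list[DualChannelSignal], cfg: RunConfig) -> CrossvalResult:
    """Subject-level cross-validated evaluation of the full system."""
    subject_labels = {}
    for s in signals:
        subject_labels.setdefault(s.subject_id, s.label)

    if cfg.group_folds:
        assignment = grouped_fold_assignment(subject_labels, cfg.folds, cfg.seed)
        fold_of = np.array([assignment[s.subject_id] for s in signals])
    else:
        fold_of = ungrouped_fold_assignment(signals, cfg.folds, cfg.seed)
        assignment = {}

    all_preds: list[PhonemePrediction] = []
    true_of_pred: list[str] = []
    class_of_pred: list[str] = []
    for f in range(cfg.folds):
        train_sigs = [s for s, ff in zip(signals, fold_of) if ff != f]
        test_sigs = [s for s, ff in zip(signals, fold_of) if ff == f]
        labels = {s.label for s in train_sigs}
        if len(labels) < 2:
            raise ValueError(f"fold {f}: training data has a single class")
        fold_cfg = RunConfig(analysis=cfg.analysis, classifier=cfg.classifier,
                             vowel=cfg.vowel, folds=cfg.folds,
                             group_folds=cfg.group_folds, seed=cfg.seed)
        models = train_models(train_sigs, fold_cfg)
        log.info("fold %d: train=%d test=%d", f, len(train_sigs), len(test_sigs))
        for s in test_sigs:
            all_preds.append(predict_phoneme(models, s))
            true_of_pred.append(s.label)
            class_of_pred.append(s.phoneme_class)

    pred_labels = [p.label for p in all_preds]
    phoneme_metrics = compute_metrics(pred_labels, true_of_pred)
    cons_idx = [i for i, c in enumerate(class_of_pred) if c == "consonant"]
    vow_idx = [i for i, c in enumerate(class_of_pred) if c == "vowel"]
    consonant_metrics = compute_metrics([pred_labels[i] for i in cons_idx],
                                        [true_of_pred[i] for i in cons_idx])
    vowel_metrics = compute_metrics([pred_labels[i] for i in vow_idx],
                                    [true_of_pred[i] for i in vow_idx])

    by_subject: dict[str, list[PhonemePrediction]] = {}
    for p in all_preds:
        by_subject.setdefault(p.subject_id, []).append(p)
    subject_preds = [vote_subject(plist) for plist in by_subject.values()]
    subject_metrics = compute_metrics(
        [sp.label for sp in subject_preds],
        [subject_labels[sp.subject_id] for sp in subject_preds])
    return CrossvalResult(subject_predictions=subject_preds,
                          subject_truth=subject_labels,
                          subject_metrics=subject_metrics,
                          phoneme_metrics=phoneme_metrics,
                          consonant_metrics=consonant_metrics,
                          vowel_metrics=vowel_metrics,
                          fold_assignment=assignment)


def write_results(result: CrossvalResult, out_dir: str | Path,
                  cfg: RunConfig | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.predictions_frame().to_csv(out / "predictions.csv", index=False)
    payload = {"subject": result.subject_metrics.as_dict(),
               "phoneme": result.phoneme_metrics.as_dict(),
               "consonant": result.consonant_metrics.as_dict(),
               "vowel": result.vowel_metrics.as_dict()}
    (out / "metrics.json").write_text(json.dumps(payload, indent=2) + "\n")
    if cfg is not None:
        (out / "config.json").write_text(
            json.dumps(cfg.to_dict(), indent=2, default=str) + "\n")
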