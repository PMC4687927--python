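"""End-to-end orchestration: corpus -> trained predictor -> regions -> scores.

Bundles the stage modules into the three workflows a user actually runs —
training (segment extraction, SOM split, grid search, class-weighted fit,
preference estimation), batch prediction over a multi-record input, and
corpus evaluation.  The command-line interface and the worked examples are
thin wrappers over this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotatedProtein
from .dataset import (
    NTM,
    TM,
    DatasetSplit,
    LabeledSegment,
    class_counts,
    extract_labeled_segments,
    som_split,
)
from .encoding import ProteinSequence
from .evaluation import EvaluationResult, evaluate_corpus
from .predictor import PredictParams, TMPrediction, predict_protein
from .preference import PreferenceTable, estimate_preference_table
from .svm import SVMConfig, TrainedClassifier, class_weights, grid_search, train_svm

logger = logging.getLogger(__name__)

#: Default training-time grid: a coarse power-of-two scan plus a narrow
#: fine level, sized for corpora of a few thousand 400-dim segments.
TRAIN_C_EXP = (-1.0, 1.0, 3.0, 5.0, 7.0, 9.0)
TRAIN_GAMMA_EXP = (-11.0, -9.0, -7.0, -5.0, -3.0, -1.0)


@dataclass
class TrainingResult:
    model: TrainedClassifier
    table: PreferenceTable
    split: DatasetSplit
    config: SVMConfig
    cv_accuracy: float
    validation_accuracy: float

    def report(self) -> str:
        cfg = self.config
        return "\n".join(
            [
                f"training segments:    {len(self.split.training)}",
                f"validation segments:  {len(self.split.validation)}",
                f"grid-search optimum:  C={cfg.C:.4f} gamma={cfg.gamma:.4f}",
                f"per-class margins:    C_tm={cfg.C_tm:.4f} C_ntm={cfg.C_ntm:.4f}",
                f"CV accuracy:          {self.cv_accuracy:.2f}%",
                f"self-consistency:     {self.model.train_recall:.2f}%",
                f"validation accuracy:  {self.validation_accuracy:.2f}%",
            ]
        )


def segment_accuracy(
    model: TrainedClassifier, segments: list[LabeledSegment]
) -> float:
    """Plain classification accuracy (percent) on labeled segments."""
    X = np.vstack([ls.descriptor for ls in segments]).astype(float)
    pred = model.predict(X)
    hits = sum(p == ls.label for p, ls in zip(pred, segments))
    return 100.0 * hits / len(segments)


def segment_balanced_accuracy(
    model: TrainedClassifier, segments: list[LabeledSegment]
) -> float:
    """Mean of per-class recalls (percent); chance level is exactly 50."""
    X = np.vstack([ls.descriptor for ls in segments]).astype(float)
    pred = model.predict(X)
    recalls = []
    for label in (TM, NTM):
        idx = [i for i, ls in enumerate(segments) if ls.label == label]
        if not idx:
            continue
        recalls.append(sum(pred[i] == label for i in idx) / len(idx))
    return 100.0 * float(np.mean(recalls))


def window_truth_labels(
    protein: AnnotatedProtein, w: int = 10, min_tm_residues: int = 6
) -> list[str]:
    """Ground-truth tm/ntm labels for a protein's sliding windows.

    A window is transmembrane when at least ``min_tm_residues`` of its
    residues lie inside annotated strands (majority rule for w = 10).
    """
    from .encoding import segment_protein

    labels = []
    for win in segment_protein(protein.sequence, w):
        covered = sum(
            max(0, min(win.end, e) - max(win.start, s) + 1)
            for s, e in protein.tm_regions
        )
        labels.append(TM if covered >= min_tm_residues else NTM)
    return labels


def window_balanced_accuracy(
    model: TrainedClassifier,
    proteins: list[AnnotatedProtein],
    params: PredictParams = PredictParams(),
) -> float:
    """Balanced accuracy (percent) of window calls against majority-rule truth.

    All windows share one length, so no length signal enters; for a model
    carrying no information about the truth the expectation is exactly 50.
    """
    from .predictor import window_labels

    hits = {TM: 0, NTM: 0}
    totals = {TM: 0, NTM: 0}
    for p in proteins:
        truth = window_truth_labels(p, params.w)
        pred = window_labels(p.sequence, model, params)
        for t, q in zip(truth, pred):
            totals[t] += 1
            hits[t] += t == q
    recalls = [hits[c] / totals[c] for c in (TM, NTM) if totals[c]]
    return 100.0 * float(np.mean(recalls))


def train_pipeline(
    proteins: list[AnnotatedProtein],
    seed: int = 0,
    folds: int = 5,
    c_exponents: tuple[float, ...] = TRAIN_C_EXP,
    gamma_exponents: tuple[float, ...] = TRAIN_GAMMA_EXP,
    refine_radius: float = 0.5,
    val_fraction: float = 0.16,
) -> TrainingResult:
    """Train the full two-layer predictor from an annotated corpus.

    Extracts labeled segments, splits them on a self-organizing map, tunes
    (C, gamma) by two-level grid search on the training set only, fits the
    class-weighted RBF SVM, and estimates the boundary preference table from
    the same corpus.  Deterministic given ``seed``.
    """
    segments: list[LabeledSegment] = []
    for p in proteins:
        segments.extend(extract_labeled_segments(p))
    n_tm, n_ntm = class_counts(segments)
    logger.info(
        "extracted %d segments (%d tm / %d ntm) from %d proteins",
        len(segments), n_tm, n_ntm, len(proteins),
    )
    split = som_split(segments, val_fraction=val_fraction, seed=seed)
    C, gamma, cv_acc = grid_search(
        split.training,
        folds=folds,
        c_exponents=c_exponents,
        gamma_exponents=gamma_exponents,
        refine_radius=refine_radius,
        seed=seed,
    )
    n_tm, n_ntm = class_counts(split.training)
    c_tm, c_ntm = class_weights(C, n_tm, n_ntm)
    config = SVMConfig(C=C, gamma=gamma, C_tm=c_tm, C_ntm=c_ntm)
    model = train_svm(split.training, config)
    val_acc = segment_accuracy(model, split.validation)
    table = estimate_preference_table(proteins)
    return TrainingResult(
        model=model,
        table=table,
        split=split,
        config=config,
        cv_accuracy=cv_acc,
        validation_accuracy=val_acc,
    )


def predict_corpus(
    sequences: list[ProteinSequence],
    model: TrainedClassifier,
    table: PreferenceTable,
    params: PredictParams = PredictParams(),
) -> dict[str, list[TMPrediction]]:
    """Predict regions for every sequence; short sequences yield empty lists."""
    return {
        seq.id: predict_protein(seq, model, table, params)
        for seq in sequences
    }


def predictions_to_regions(
    predictions: dict[str, list[TMPrediction]]
) -> dict[str, list[tuple[int, int]]]:
    return {
        pid: [(p.start, p.end) for p in preds]
        for pid, preds in predictions.items()
    }


def write_predictions(
    predictions: dict[str, list[TMPrediction]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tscore\tstretch_id\n")
        for pid in predictions:
            for p in predictions[pid]:
                fh.write(
                    f"{pid}\t{p.start}\t{p.end}\t{p.score:.4f}\t{p.stretch_id}\n"
                )


def evaluate_predictions(
    predictions: dict[str, list[TMPrediction]],
    annotated: list[AnnotatedProtein],
) -> EvaluationResult:
    annotations = {p.id: list(p.tm_regions) for p in annotated}
    return evaluate_corpus(predictions_to_regions(predictions), annotations)
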