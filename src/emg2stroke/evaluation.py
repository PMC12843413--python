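"""Dataset splitting, confusion-matrix metrics and the evaluation grid.

The positive class is **stroke**.  Metrics are the four standard
percentages

    accuracy  = (TP + TN) / (TP + TN + FP + FN) * 100
    precision = TP / (TP + FP) * 100
    recall    = TP / (TP + FN) * 100
    F1        = 2 * precision * recall / (precision + recall)   (as a %)

with the convention that a zero denominator yields 0 together with a
``degenerate`` flag (the outcome seen when a model predicts a single class
for every test item).

Splits are holdout splits at configurable train fractions (0.70 / 0.80 /
0.90 by default), stratified by class, with the per-class train size taken
as floor(fraction * n_class) so sizing is deterministic and
seed-independent.  A subject-level mode keeps all segments of a subject on
one side of the split (the leakage-safe alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .features import LabeledDataset
from .models import TrainingConfig, build_model, predict, train

SPLIT_FRACTIONS = (0.70, 0.80, 0.90)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    level: str = "segment"          # segment | subject
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.level not in ("segment", "subject"):
            raise ConfigurationError(f"unknown split level {self.level!r}")


def _subject_of(label_id: str) -> str:
    return label_id.rsplit("_", 1)[0] if "_" in label_id else label_id


def split_dataset(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random holdout split; returns (train, test) datasets.

    Per class, floor(train_fraction * n) items go to train and the
    remainder to test; identical seeds give identical partitions.
    """
    rng = np.random.default_rng(spec.seed)
    images = dataset.images
    labels = [img.label for img in images]

    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.level == "subject":
        subjects = np.array([_subject_of(img.label_id) for img in images])
        for cls in sorted(set(labels)):
            cls_subjects = sorted({s for s, l in zip(subjects, labels) if l == cls})
            if len(cls_subjects) < 2:
                raise ValidationError("need >= 2 subjects per class for a subject split")
            order = rng.permutation(len(cls_subjects))
            n_train = int(np.floor(spec.train_fraction * len(cls_subjects)))
            if n_train == 0 or n_train == len(cls_subjects):
                raise ConfigurationError("train_fraction leaves an empty split side")
            train_subj = {cls_subjects[i] for i in order[:n_train]}
            for i, (s, l) in enumerate(zip(subjects, labels)):
                if l != cls:
                    continue
                (train_idx if s in train_subj else test_idx).append(i)
    else:
        for cls in sorted(set(labels)):
            cls_idx = [i for i, l in enumerate(labels) if l == cls]
            if spec.stratified and len(cls_idx) < 2:
                raise ValidationError("need >= 2 items per class for a stratified split")
            order = rng.permutation(len(cls_idx))
            n_train = int(np.floor(spec.train_fraction * len(cls_idx)))
            if n_train == 0 or n_train == len(cls_idx):
                raise ConfigurationError("train_fraction leaves an empty split side")
            train_idx.extend(cls_idx[i] for i in order[:n_train])
            test_idx.extend(cls_idx[i] for i in order[n_train:])

    train_set = LabeledDataset([images[i] for i in sorted(train_idx)], dataset.kind)
    test_set = LabeledDataset([images[i] for i in sorted(test_idx)], dataset.kind)
    return train_set, test_set


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = stroke."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels_true: Sequence[int], labels_pred: Sequence[int]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN for binary labels (1 = stroke = positive)."""
    yt = np.asarray(labels_true)
    yp = np.asarray(labels_pred)
    if yt.shape != yp.shape:
        raise ValidationError("label vectors must have equal length")
    if not np.isin(yt, (0, 1)).all() or not np.isin(yp, (0, 1)).all():
        raise ValidationError("labels must be binary (0 = control, 1 = stroke)")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """The four percentage metrics; zero denominators yield 0 + a flag."""
    if cm.n == 0:
        raise ValidationError("confusion matrix is empty")
    degenerate = False
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.n
    if cm.tp + cm.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = 100.0 * cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = 100.0 * cm.tp / (cm.tp + cm.fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricSet(accuracy, precision, recall, f1, degenerate)


def evaluate_one(
    architecture: str,
    dataset: LabeledDataset,
    split: SplitSpec,
    config: TrainingConfig | None = None,
    image_size: int | None = None,
) -> dict:
    """Train one model on one split of one dataset and score the test side."""
    config = config or TrainingConfig()
    work = dataset.resized(image_size) if image_size else dataset
    train_set, test_set = split_dataset(work, split)
    h, w = train_set.images[0].pixels.shape[:2]
    model = build_model(architecture, input_shape=(h, w, 3), seed=config.seed)
    clf = train(model, train_set, config)
    y_pred, _ = predict(clf, test_set)
    cm = confusion(test_set.labels(), y_pred)
    m = metrics(cm)
    return {
        "architecture": architecture,
        "dataset_kind": dataset.kind,
        "split": split.train_fraction,
        "seed": config.seed,
        "TP": cm.tp, "TN": cm.tn, "FP": cm.fp, "FN": cm.fn,
        "accuracy": m.accuracy, "precision": m.precision,
        "recall": m.recall, "f1": m.f1, "degenerate": m.degenerate,
    }


def evaluate_matrix(
    architectures: Sequence[str],
    datasets: dict[str, LabeledDataset],
    train_fractions: Sequence[float] = SPLIT_FRACTIONS,
    seeds: Sequence[int] = (0,),
    config: TrainingConfig | None = None,
    image_size: int | None = None,
    split_level: str = "segment",
) -> pd.DataFrame:
    """Full architecture x dataset x split (x seed) grid of holdout runs."""
    base = config or TrainingConfig()
    rows = []
    for kind, dataset in datasets.items():
        if kind != dataset.kind:
            raise ConfigurationError(
                f"dataset registered under kind {kind!r} has kind {dataset.kind!r}")
    for arch in architectures:
        for kind, dataset in datasets.items():
            for frac in train_fractions:
                for seed in seeds:
                    split = SplitSpec(train_fraction=frac, level=split_level, seed=seed)
                    cfg = TrainingConfig(
                        learning_rate=base.learning_rate,
                        momentum=base.momentum,
                        batch_size=base.batch_size,
                        epochs=base.epochs,
                        seed=seed,
                    )
                    rows.append(evaluate_one(arch, dataset, split, cfg, image_size))
    return pd.DataFrame(rows)


def mean_accuracy_table(results: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per (architecture, dataset_kind) across splits/seeds."""
    return (
        results.groupby(["architecture", "dataset_kind"], as_index=False)["accuracy"]
        .mean()
        .rename(columns={"accuracy": "mean_accuracy"})
    )
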