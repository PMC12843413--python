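"""Split arithmetic, confusion counts (cross-checked against scikit-learn),
the percentage metric formulas, and the evaluation grid."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion

from emg2stroke.errors import ConfigurationError, ValidationError
from emg2stroke.evaluation import (
    ConfusionMatrix,
    SplitSpec,
    confusion,
    evaluate_matrix,
    mean_accuracy_table,
    metrics,
    split_dataset,
)
from emg2stroke.features import FeatureImage, LabeledDataset


def dummy_dataset(n_per_class=50, n_subjects=10, size=8, kind="spectrogram",
                  identical=False, seed=0):
    """Tiny labeled images; one subject owns n_per_class / (n_subjects/2) items."""
    rng = np.random.default_rng(seed)
    images = []
    per_subj = n_per_class // (n_subjects // 2)
    for cls, prefix in [("control", "H"), ("stroke", "P")]:
        for i in range(n_per_class):
            subj = f"{prefix}{i // per_subj + 1:03d}"
            if identical:
                pix = np.full((size, size, 3), 128, dtype=np.uint8)
            else:
                base = 60 if cls == "control" else 190
                pix = np.clip(base + rng.integers(-20, 21, (size, size, 3)),
                              0, 255).astype(np.uint8)
            images.append(FeatureImage(pix, kind, cls,
                                       f"{subj}_{i % per_subj + 1:02d}"))
    return LabeledDataset(images, kind)


class TestSplit:
    @pytest.mark.parametrize("frac,n_train,n_test", [
        (0.70, 70, 30), (0.80, 80, 20), (0.90, 90, 10),
    ])
    def test_split_ratios_on_100_items(self, frac, n_train, n_test):
        ds = dummy_dataset()
        train_set, test_set = split_dataset(ds, SplitSpec(frac, seed=0))
        assert (len(train_set), len(test_set)) == (n_train, n_test)
        assert train_set.class_counts == {"control": n_train // 2,
                                          "stroke": n_train // 2}
        assert test_set.class_counts == {"control": n_test // 2,
                                         "stroke": n_test // 2}

    def test_split_conservation_and_disjointness(self):
        ds = dummy_dataset()
        train_set, test_set = split_dataset(ds, SplitSpec(0.7, seed=1))
        ids_train = {img.label_id for img in train_set.images}
        ids_test = {img.label_id for img in test_set.images}
        assert len(ids_train & ids_test) == 0
        assert len(ids_train | ids_test) == len(ds)

    def test_same_seed_identical_partition(self):
        ds = dummy_dataset()
        a = split_dataset(ds, SplitSpec(0.8, seed=5))
        b = split_dataset(ds, SplitSpec(0.8, seed=5))
        assert [i.label_id for i in a[0].images] == [i.label_id for i in b[0].images]

    def test_subject_level_split_keeps_subjects_together(self):
        ds = dummy_dataset()
        train_set, test_set = split_dataset(
            ds, SplitSpec(0.8, level="subject", seed=2))
        subj_train = {i.label_id.rsplit("_", 1)[0] for i in train_set.images}
        subj_test = {i.label_id.rsplit("_", 1)[0] for i in test_set.images}
        assert subj_train & subj_test == set()

    def test_empty_side_rejected(self):
        ds = dummy_dataset(n_per_class=2, n_subjects=2)
        with pytest.raises(ConfigurationError):
            split_dataset(ds, SplitSpec(0.1, seed=0))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitSpec(1.5)


class TestConfusion:
    def test_hand_enumerated_example(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        cm = confusion([0, 1, 0, 1], [0, 1, 0, 1])
        assert cm.fp == cm.fn == 0

    def test_all_positive_on_balanced_set(self):
        y = [0] * 15 + [1] * 15
        cm = confusion(y, [1] * 30)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (15, 15, 0, 0)

    def test_random_vectors_match_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 60))
            yt = rng.integers(0, 2, n)
            yp = rng.integers(0, 2, n)
            cm = confusion(yt, yp)
            tn, fp, fn, tp = sk_confusion(yt, yp, labels=[0, 1]).ravel()
            assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion([0, 1], [0, 1, 1])


class TestMetrics:
    def test_accuracy_example(self):
        m = metrics(ConfusionMatrix(tp=2, tn=1, fp=1, fn=1))
        assert m.accuracy == pytest.approx(60.0)

    def test_precision_example(self):
        m = metrics(ConfusionMatrix(tp=3, tn=0, fp=1, fn=1))
        assert m.precision == pytest.approx(75.0)

    def test_f1_zero_when_recall_zero(self):
        m = metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=5))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0
        assert m.degenerate

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_formulas_against_brute_force(self):
        """The four percentages recomputed by direct enumeration on random
        label vectors agree exactly."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            yt = rng.integers(0, 2, n)
            yp = rng.integers(0, 2, n)
            tp = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(yt, yp) if a == 0 and b == 0)
            fp = sum(1 for a, b in zip(yt, yp) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 0)
            m = metrics(confusion(yt, yp))
            assert m.accuracy == 100.0 * (tp + tn) / n
            if tp + fp:
                assert m.precision == 100.0 * tp / (tp + fp)
            if tp + fn:
                assert m.recall == 100.0 * tp / (tp + fn)
            if m.precision + m.recall:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall))
            assert 0.0 <= m.f1 <= 100.0


class TestGrid:
    def test_grid_shape_and_summary(self):
        ds = dummy_dataset(n_per_class=10, n_subjects=2, size=8)
        res = evaluate_matrix(
            ["shallow"], {"spectrogram": ds},
            train_fractions=(0.7, 0.8), seeds=(0,),
            image_size=None,
        )
        assert len(res) == 2
        assert set(res.columns) >= {"architecture", "dataset_kind", "split",
                                    "accuracy", "TP", "TN", "FP", "FN"}
        summary = mean_accuracy_table(res)
        assert len(summary) == 1
        assert summary.loc[0, "mean_accuracy"] == res["accuracy"].mean()

    def test_chance_level_on_identical_images(self):
        """When both classes share one identical image, accuracy sits at
        chance (50 % on a balanced test side)."""
        ds = dummy_dataset(n_per_class=20, n_subjects=4, size=8, identical=True)
        res = evaluate_matrix(["shallow"], {"spectrogram": ds},
                              train_fractions=(0.7,), seeds=(0,))
        acc = res.loc[0, "accuracy"]
        assert 30.0 <= acc <= 70.0  # 95 % binomial band around 50 %, n=12

    def test_separable_dataset_learned(self):
        from emg2stroke.models import TrainingConfig

        ds = dummy_dataset(n_per_class=20, n_subjects=4, size=8)
        res = evaluate_matrix(["shallow"], {"spectrogram": ds},
                              train_fractions=(0.8,), seeds=(0,),
                              config=TrainingConfig(learning_rate=0.01))
        assert res.loc[0, "accuracy"] >= 75.0

    def test_missing_dataset_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluate_matrix(["shallow"], {"wavelet": dummy_dataset(4, 2, kind="spectrogram")})
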