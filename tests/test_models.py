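"""CNN engine: architecture fidelity, seeded determinism, gradient
correctness against finite differences, and capacity on separable data."""

import numpy as np
import pytest

from emg2stroke.errors import ConfigurationError, ValidationError
from emg2stroke.models import (
    ArchitectureSpec,
    TrainingConfig,
    build_model,
    cross_entropy,
    load_classifier,
    predict,
    save_classifier,
    softmax,
    train,
)

SMALL = (32, 32, 3)


def solid_dataset(n_per_class=8, size=16, seed=0):
    """Trivially separable images: dark class 0 vs bright class 1."""
    rng = np.random.default_rng(seed)
    imgs, labels = [], []
    for cls, base in [(0, 40), (1, 200)]:
        for _ in range(n_per_class):
            img = np.clip(base + rng.integers(-15, 16, (size, size, 3)), 0, 255)
            imgs.append(img.astype(np.uint8))
            labels.append(cls)
    return np.stack(imgs), np.array(labels)


class TestArchitectures:
    def test_forward_probabilities_sum_to_one(self):
        model = build_model("tri_ccnn", input_shape=SMALL, seed=0)
        x = np.random.default_rng(0).random((3, 3, 32, 32)).astype(np.float32)
        probs = softmax(model.forward(x))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (3, 2)

    @pytest.mark.parametrize("name,kernels,filters", [
        ("tri_ccnn", [5, 3, 2], [8, 8, 4]),
        ("lenet5", [5, 5, 5], [6, 16, 120]),
        ("shallow", [5], [8]),
    ])
    def test_conv_kernels_and_filters(self, name, kernels, filters):
        model = build_model(name, input_shape=SMALL)
        assert model.conv_kernel_sizes == kernels
        assert model.conv_filter_counts == filters

    def test_tri_ccnn_layer_sequence(self):
        """Conv->pool->ReLU stages with batch norm after the second conv."""
        model = build_model("tri_ccnn", input_shape=SMALL)
        types = [d["type"] for d in model.layer_summary()]
        assert types == [
            "Conv2d", "MaxPool2d", "ReLU",
            "Conv2d", "BatchNorm2d", "MaxPool2d", "ReLU",
            "Conv2d", "MaxPool2d", "ReLU",
            "Flatten", "Dense",
        ]

    def test_tri_ccnn_kernels_strictly_shrink(self):
        model = build_model("tri_ccnn", input_shape=SMALL)
        ks = model.conv_kernel_sizes
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_pooling_geometry(self):
        summary = build_model("tri_ccnn", input_shape=SMALL).layer_summary()
        pools = [d for d in summary if d["type"] == "MaxPool2d"]
        assert all(d["pool"] == 2 and d["stride"] == 2 for d in pools)

    def test_too_small_input_rejected(self):
        with pytest.raises(ConfigurationError, match="zero features"):
            build_model("tri_ccnn", input_shape=(16, 16, 3))

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model("vgg", input_shape=SMALL)
        with pytest.raises(ConfigurationError):
            ArchitectureSpec("resnet")


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences through the
        whole tri_ccnn stack (conv, pool, batch norm, dense)."""
        rng = np.random.default_rng(0)
        model = build_model("tri_ccnn", input_shape=(20, 20, 3), seed=1)
        x = rng.random((4, 3, 20, 20)).astype(np.float32)
        y = np.array([0, 1, 0, 1])

        def loss_value():
            return cross_entropy(softmax(model.forward(x, train=True)), y)

        probs = softmax(model.forward(x, train=True))
        grad = probs.copy()
        grad[np.arange(len(y)), y] -= 1.0
        grad /= len(y)
        model.backward(grad.astype(np.float32))

        # Central differences match analytic gradients except where the +/-eps
        # perturbation crosses a ReLU or max-pool kink; such isolated
        # non-differentiable points are tolerated, systematic errors are not.
        eps = 1e-3
        errors = []
        for p, g in model.parameters():
            flat_p, flat_g = p.ravel(), g.ravel()
            for idx in rng.choice(flat_p.size, size=min(3, flat_p.size), replace=False):
                old = flat_p[idx]
                flat_p[idx] = old + eps
                up = loss_value()
                flat_p[idx] = old - eps
                down = loss_value()
                flat_p[idx] = old
                numeric = (up - down) / (2 * eps)
                errors.append(abs(numeric - flat_g[idx]))
        errors = np.array(errors)
        assert len(errors) >= 20
        assert np.mean(errors < 2e-3) >= 0.9
        assert errors.max() < 0.1


class TestTraining:
    def test_seeded_training_is_bit_reproducible(self):
        x, y = solid_dataset()
        runs = []
        for _ in range(2):
            model = build_model("shallow", input_shape=(16, 16, 3), seed=3)
            xf = (x.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)
            clf = train(model, xf, TrainingConfig(epochs=2, seed=3), labels=y)
            runs.append((clf.history, [p.copy() for p, _ in model.parameters()]))
        assert runs[0][0] == runs[1][0]
        for a, b in zip(runs[0][1], runs[1][1]):
            np.testing.assert_array_equal(a, b)

    def test_zero_epochs_leaves_model_at_initialization(self):
        x, y = solid_dataset()
        xf = (x.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)
        model = build_model("shallow", input_shape=(16, 16, 3), seed=4)
        before = [p.copy() for p, _ in model.parameters()]
        clf = train(model, xf, TrainingConfig(epochs=0, seed=4), labels=y)
        assert clf.history == []
        for a, (p, _) in zip(before, model.parameters()):
            np.testing.assert_array_equal(a, p)

    def test_single_class_training_rejected(self):
        x, y = solid_dataset()
        xf = (x.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)
        model = build_model("shallow", input_shape=(16, 16, 3))
        with pytest.raises(ValidationError):
            train(model, xf[y == 0], TrainingConfig(epochs=1), labels=y[y == 0])

    def test_capacity_on_separable_images(self):
        """Solid-intensity classes are learned to 100 % train accuracy and
        >= 95 % on held-out samples (higher learning rate: capacity check)."""
        x, y = solid_dataset(n_per_class=12, size=20, seed=5)
        xf = (x.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)
        tr = np.r_[0:10, 12:22]
        te = np.r_[10:12, 22:24]
        model = build_model("tri_ccnn", input_shape=(20, 20, 3), seed=5)
        clf = train(model, xf[tr], TrainingConfig(learning_rate=0.01, epochs=10, seed=5),
                    labels=y[tr])
        assert clf.history[-1]["accuracy"] == 1.0
        assert clf.history[-1]["loss"] < clf.history[0]["loss"]
        pred, probs = predict(clf, xf[te])
        assert (pred == y[te]).mean() >= 0.95
        assert len(pred) == len(te)

    def test_predict_geometry_validation(self):
        x, y = solid_dataset()
        xf = (x.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)
        model = build_model("shallow", input_shape=(16, 16, 3), seed=1)
        clf = train(model, xf, TrainingConfig(epochs=1, seed=1), labels=y)
        wrong = np.zeros((2, 8, 8, 3), dtype=np.uint8)
        with pytest.raises(ConfigurationError):
            predict(clf, wrong)

    def test_save_load_roundtrip(self, tmp_path):
        x, y = solid_dataset(size=20)
        xf = (x.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)
        model = build_model("tri_ccnn", input_shape=(20, 20, 3), seed=6)
        clf = train(model, xf, TrainingConfig(epochs=1, seed=6), labels=y)
        path = save_classifier(clf, tmp_path / "model.npz")
        back = load_classifier(path)
        p1, _ = predict(clf, xf)
        p2, _ = predict(back, xf)
        np.testing.assert_array_equal(p1, p2)
        assert back.history == clf.history
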