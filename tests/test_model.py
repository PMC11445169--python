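"""Residual-network classifier: construction, training, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropclass import (
    PreprocessConfig,
    SyntheticSceneConfig,
    TrainConfig,
    build_classifier,
    filter_by_confidence,
    load_model,
    predict,
    render_dataset_arrays,
    save_model,
    train_classifier,
)
from dropclass.model import Prediction
from dropclass.preprocess import preprocess_batch


@pytest.fixture(scope="module")
def tiny_dataset():
    images, labels = render_dataset_arrays(60, SyntheticSceneConfig(), seed=42)
    return preprocess_batch(images, PreprocessConfig()), labels


def test_forward_pass_probabilities_sum_to_one(rng):
    x = rng.uniform(0, 65535, (5, 55, 55))
    for depth in ("small", 50):
        model = build_classifier(TrainConfig(arch_depth=depth, seed=7))
        probs = model.predict_proba(x)
        assert probs.shape == (5, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_initial_weights_deterministic_under_seed():
    a = build_classifier(TrainConfig(seed=5)).net.state_arrays()
    b = build_classifier(TrainConfig(seed=5)).net.state_arrays()
    c = build_classifier(TrainConfig(seed=6)).net.state_arrays()
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    assert any(not np.array_equal(x, z) for x, z in zip(a, c))


def test_wrong_spatial_size_is_an_error(rng):
    model = build_classifier(TrainConfig(seed=0))
    with pytest.raises(ValueError, match="expected"):
        model.predict_proba(rng.uniform(0, 1, (2, 54, 54)))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(validation_fraction=0.0)
    with pytest.raises(ValueError):
        TrainConfig(arch_depth=50, input_side=28)
    with pytest.raises(ValueError):
        TrainConfig(arch_depth=18)


def test_missing_class_raises(tiny_dataset):
    x, y = tiny_dataset
    keep = np.asarray(y) != 2
    with pytest.raises(ValueError, match="class"):
        train_classifier(x[keep], np.asarray(y)[keep], TrainConfig(seed=0))


def test_training_descends_and_splits_95_5(tiny_dataset):
    x, y = tiny_dataset
    cfg = TrainConfig(epochs=2, batch_size=32, seed=1)
    model, history = train_classifier(x, y, cfg)
    n_val = int(round(60 * 0.05)) * 3
    # stratified 95/5 split: 3 per class in validation at 60/class
    assert history[0]["epoch"] == 0
    assert history[1]["train_loss"] < history[0]["train_loss"]
    # validation entries exist and come from a 5% split
    assert "val_loss" in history[-1]
    assert len(x) - n_val == 171


def test_small_model_beats_chance_at_fixture_scale():
    images, labels = render_dataset_arrays(200, SyntheticSceneConfig(), seed=77)
    x = preprocess_batch(images, PreprocessConfig())
    model, _ = train_classifier(x, labels, TrainConfig(seed=3))
    timages, tlabels = render_dataset_arrays(50, SyntheticSceneConfig(), seed=78)
    xt = preprocess_batch(timages, PreprocessConfig())
    preds = predict(model, xt)
    acc = np.mean([p.label == t for p, t in zip(preds, tlabels)])
    assert acc >= 1 / 3 + 0.20


def test_strong_signal_classes_are_recoverable():
    """With low noise and no occluding structures the class structure is
    fully recoverable from the generative signal."""
    scene = SyntheticSceneConfig(noise_sd=50.0, beadline=False, beadline_irregularity=0.0)
    images, labels = render_dataset_arrays(500, scene, seed=21)
    x = preprocess_batch(images, PreprocessConfig())
    model, _ = train_classifier(x, labels, TrainConfig(seed=2))
    timages, tlabels = render_dataset_arrays(100, scene, seed=22)
    xt = preprocess_batch(timages, PreprocessConfig())
    preds = predict(model, xt)
    acc = np.mean([p.label == t for p, t in zip(preds, tlabels)])
    assert acc >= 0.95


def test_predict_contract_and_determinism(tiny_dataset):
    x, y = tiny_dataset
    model = build_classifier(TrainConfig(seed=9))
    preds1 = predict(model, x[:10])
    preds2 = predict(model, x[:10])
    assert len(preds1) == 10
    for p1, p2 in zip(preds1, preds2):
        np.testing.assert_array_equal(p1.probabilities, p2.probabilities)
        assert p1.label == int(np.argmax(p1.probabilities))
        assert p1.confidence == pytest.approx(100 * p1.probabilities.max())
        assert p1.probabilities.sum() == pytest.approx(1.0, abs=1e-6)


def test_save_load_round_trip(tiny_dataset, tmp_path):
    x, y = tiny_dataset
    cfg = TrainConfig(epochs=1, batch_size=32, seed=4)
    model, _ = train_classifier(x, y, cfg)
    save_model(model, tmp_path / "m", preprocess_config=PreprocessConfig())
    back = load_model(tmp_path / "m")
    np.testing.assert_allclose(
        back.predict_proba(x[:8]), model.predict_proba(x[:8]), atol=1e-6
    )


# ----------------------------------------------------- confidence filtering


def _preds_from_confidences(confs):
    out = []
    for c in confs:
        p = np.zeros(3)
        p[0] = c / 100.0
        p[1] = 1 - c / 100.0
        if p[1] > p[0]:
            p = p[[1, 0, 2]]
        out.append(Prediction(label=int(p.argmax()), confidence=100 * p.max(), probabilities=p))
    return out


def test_filter_threshold_zero_keeps_all():
    preds = _preds_from_confidences([55, 70, 99])
    kept, frac = filter_by_confidence(preds, 0)
    assert frac == 1.0 and len(kept) == 3


def test_filter_threshold_100_keeps_only_certainty():
    preds = _preds_from_confidences([55, 100])
    kept, frac = filter_by_confidence(preds, 100)
    assert len(kept) == 1 and kept[0].confidence == 100


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.floats(min_value=34, max_value=100), min_size=1, max_size=30))
def test_retention_fraction_non_increasing_in_threshold(confs):
    preds = _preds_from_confidences(confs)
    fracs = [filter_by_confidence(preds, t)[1] for t in (0, 25, 50, 75, 90, 100)]
    assert all(b <= a for a, b in zip(fracs, fracs[1:]))
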