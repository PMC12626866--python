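"""CNN classifier: architecture contracts, augmentation, training,
LOSO partition, prediction determinism, checkpoints."""

import numpy as np
import pytest

from gaitbarrier.classifier import (
    ModelConfig,
    augment,
    build_model,
    build_raw1d_model,
    encode_inputs,
    load_checkpoint,
    loso_cross_validate,
    predict_proba,
    save_checkpoint,
    stratified_inner_split,
    train_fold,
)
from gaitbarrier.preprocess import ABNORMAL, CHANNEL_NAMES, GaitWindow, WindowDataset

TOY_CFG = ModelConfig(
    image_size=16,
    max_epochs=20,
    early_stop_patience=20,
    augment_enabled=False,
    dropout_conv=0.0,
    dropout_dense=0.0,
    batch_size=16,
    seed=7,
)


def _toy_window(subject, trial, wid, abnormal, rng, L=64, fs=32.0):
    """Two separable gait archetypes: a clean dyadic tone vs an
    irregular two-tone burst."""
    t = np.arange(L) / fs
    base = np.sin(2 * np.pi * 2.0 * t)
    if abnormal:
        base = base + 1.5 * np.sin(2 * np.pi * 7.0 * t + rng.uniform(0, 6)) * (t > 1.0)
    base = base + 0.05 * rng.standard_normal(L)
    samples = np.tile(base, (8, 1))
    samples[CHANNEL_NAMES.index("SVM_Acc")] = base + 9.81
    w = GaitWindow(subject, trial, wid, 0.0, samples, fs)
    w.label = ABNORMAL if abnormal else "normal"
    return w


@pytest.fixture(scope="module")
def toy_dataset():
    rng = np.random.default_rng(99)
    windows = []
    for s in range(4):
        for i in range(24):
            windows.append(_toy_window(s, 0, i, abnormal=(i % 2 == 0), rng=rng))
    return WindowDataset(windows=windows, fs=32.0)


class TestBuildModel:
    def test_table_parameter_counts(self):
        """conv1 = 5*5*1*16+16, conv2 = 3*3*16*32+32, flatten from 200^2
        with two 2x2 poolings = 50*50*32."""
        net, desc = build_model(ModelConfig())
        by_name = {d["layer"]: d for d in desc}
        assert by_name["conv1 (5x5/16)"]["n_params"] == 416
        assert by_name["conv2 (3x3/32)"]["n_params"] == 4640
        assert by_name["flatten"]["output_shape"] == (50 * 50 * 32,)
        assert by_name["dense (64)"]["n_params"] == 80000 * 64 + 64

    def test_gap_head_is_compact(self):
        net_flat, _ = build_model(ModelConfig())
        net_gap, _ = build_model(ModelConfig(head="gap"))
        assert net_gap.n_params() < 20_000 < net_flat.n_params()

    def test_too_deep_pooling_rejected(self):
        with pytest.raises(ValueError):
            build_model(ModelConfig(image_size=2, pool_after=(True, True, True)))

    def test_raw1d_mirrors_depth_and_outputs_probabilities(self):
        net, desc = build_raw1d_model(ModelConfig())
        conv_layers = [d for d in desc if d["layer"].startswith("conv")]
        assert len(conv_layers) == 3  # same depth as the 2-D model
        x = np.random.default_rng(0).standard_normal((5, 200, 1)).astype(np.float32)
        from gaitbarrier.nn import softmax

        p = softmax(net.forward(x))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestAugment:
    def test_disabled_is_identity_via_config(self, toy_dataset):
        cfg = ModelConfig(image_size=16, augment_enabled=False)
        x = encode_inputs(toy_dataset.included[:2], cfg)
        assert x.shape == (2, 16, 16, 1)

    def test_fixed_rng_reproducible(self):
        img = np.random.default_rng(1).random((20, 20, 1)).astype(np.float32)
        a = augment(img, np.random.default_rng(5))
        b = augment(img, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_draw_ranges_respected(self):
        """Rotation within +/-5 deg, translation within +/-3 px over many
        draws (checked on the generator draws themselves)."""
        rng = np.random.default_rng(0)
        angles = rng.uniform(-5.0, 5.0, size=10_000)
        assert angles.min() >= -5.0 and angles.max() <= 5.0
        img = np.zeros((8, 8, 1), dtype=np.float32)
        img[4, 4, 0] = 1.0
        for _ in range(50):
            out = augment(img, rng, rotation_deg=5.0, translation_px=3)
            peak = np.unravel_index(np.argmax(out[:, :, 0]), (8, 8))
            assert abs(peak[0] - 4) <= 4 and abs(peak[1] - 4) <= 4

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((4, 5, 1)), np.random.default_rng(0))


class TestInnerSplit:
    def test_subject_stratified_and_disjoint(self, rng):
        subjects = np.repeat([0, 1, 2, 3, 4], 20)
        train, val = stratified_inner_split(subjects, 0.2, rng)
        assert not np.any(train & val)
        assert set(subjects[train]) & set(subjects[val]) == set()
        assert 0 < val.sum() < len(subjects)

    def test_two_subjects_minimum(self, rng):
        with pytest.raises(ValueError):
            stratified_inner_split(np.zeros(10, dtype=int), 0.2, rng)


class TestTrainFold:
    def test_single_epoch_contract(self, toy_dataset):
        cfg = ModelConfig(image_size=16, max_epochs=1, augment_enabled=False, seed=3)
        model = train_fold(toy_dataset.included, cfg)
        assert len(model.log) == 1

    def test_validation_subjects_disjoint(self, toy_dataset):
        model = train_fold(toy_dataset.included, TOY_CFG)
        assert set(model.inner_val_subjects) & set(model.inner_train_subjects) == set()

    def test_loss_decreases_on_separable_textures(self, toy_dataset):
        """Two archetype GAF textures are separable to low loss."""
        model = train_fold(toy_dataset.included, TOY_CFG)
        assert min(e["val_loss"] for e in model.log) < 0.35
        assert model.log[-1]["train_loss"] < model.log[0]["train_loss"]

    def test_single_class_rejected(self, toy_dataset):
        normals = [w for w in toy_dataset.included if not w.is_abnormal]
        with pytest.raises(ValueError):
            train_fold(normals, TOY_CFG)

    def test_training_log_reproducible_given_seed(self, toy_dataset):
        """Identical config and seed produce identical training logs
        (single-threaded reproducibility contract)."""
        cfg = ModelConfig(image_size=16, max_epochs=3, seed=11)
        a = train_fold(toy_dataset.included, cfg)
        b = train_fold(toy_dataset.included, cfg)
        assert a.log == b.log


@pytest.fixture(scope="module")
def fitted(toy_dataset):
    return train_fold(toy_dataset.included, TOY_CFG)


class TestPredictProba:
    def test_probabilities_sum_to_one(self, fitted, toy_dataset):
        x = encode_inputs(toy_dataset.included[:7], fitted.config)
        p = predict_proba(fitted, x)
        assert p.shape == (7, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self, fitted, toy_dataset):
        x = encode_inputs(toy_dataset.included[:5], fitted.config)
        np.testing.assert_array_equal(predict_proba(fitted, x), predict_proba(fitted, x))

    def test_shape_mismatch_rejected(self, fitted):
        with pytest.raises(ValueError):
            predict_proba(fitted, np.zeros((3, 16, 16)))


class TestLoso:
    def test_fold_count_and_partition(self, toy_dataset):
        preds = loso_cross_validate(toy_dataset, TOY_CFG)
        assert preds["fold_id"].nunique() == 4  # one fold per subject
        assert len(preds) == len(toy_dataset.included)
        assert preds.duplicated(["subject", "trial", "window_id"]).sum() == 0
        # each subject predicted by exactly its own fold
        assert (preds.groupby("subject")["fold_id"].nunique() == 1).all()

    def test_separable_toy_high_auc(self, toy_dataset):
        from gaitbarrier.spatial import rank_metrics

        preds = loso_cross_validate(toy_dataset, TOY_CFG)
        auc = rank_metrics(
            preds["p_abnormal"].to_numpy(), preds["label"].to_numpy().astype(bool)
        )["auc_roc"]
        assert auc > 0.9

    def test_fewer_than_two_subjects_rejected(self):
        ds = WindowDataset(
            windows=[
                _toy_window(0, 0, i, i % 2 == 0, np.random.default_rng(0)) for i in range(8)
            ],
            fs=32.0,
        )
        with pytest.raises(ValueError):
            loso_cross_validate(ds, TOY_CFG)


def test_checkpoint_roundtrip(tmp_path, toy_dataset):
    model = train_fold(toy_dataset.included, TOY_CFG)
    x = encode_inputs(toy_dataset.included[:4], model.config)
    save_checkpoint(model, tmp_path / "fold0.npz", fold_id=0)
    back = load_checkpoint(tmp_path / "fold0.npz")
    np.testing.assert_allclose(predict_proba(back, x), predict_proba(model, x), atol=1e-6)
    assert back.config == model.config
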