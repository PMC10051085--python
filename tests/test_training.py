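"""Training protocol: loss values, early stopping, determinism, checkpoints."""

import numpy as np
import pytest

import lesionseg as ls


def make_samples(rng, n, size=32):
    spec = ls.SyntheticSceneSpec(
        size=(size, size), n_lesions=1, radius_range=(4.0, 8.0), seed=int(rng.integers(2**31 - 1))
    )
    return ls.generate_dataset(spec, n)


@pytest.fixture()
def tiny_setup(rng, tiny_config):
    samples = make_samples(rng, 12)
    return ls.build_model(tiny_config, seed=4), samples[:8], samples[8:]


def test_bce_loss_known_values():
    y = np.array([[1.0, 0.0], [1.0, 0.0]])
    assert ls.bce_loss(np.full((2, 2), 0.5), y) == pytest.approx(np.log(2), rel=1e-6)
    p = np.array([[0.9, 0.1], [0.8, 0.2]])
    expected = -np.mean([np.log(0.9), np.log(0.9), np.log(0.8), np.log(0.8)])
    assert ls.bce_loss(p, y) == pytest.approx(expected, rel=1e-6)
    near_perfect = ls.bce_loss(np.array([[1.0 - 1e-7, 1e-7]]), np.array([[1.0, 0.0]]))
    assert near_perfect == pytest.approx(0.0, abs=1e-5)


def test_bce_loss_shape_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        ls.bce_loss(np.full((2, 2), 0.5), np.zeros((3, 2)))


def freeze_batch_norm_stats(model):
    """Zero BN momentum so running statistics stay fixed during training.

    Isolates optimizer/early-stopping contracts from normalization-statistic
    drift, which moves even when the learning rate is zero.
    """
    from lesionseg.nn import BatchNorm2d

    for m in model.modules():
        if isinstance(m, BatchNorm2d):
            m.momentum = 0.0


def test_lr_zero_leaves_parameters_unchanged(tiny_setup):
    model, train_set, val_set = tiny_setup
    freeze_batch_norm_stats(model)
    before = {k: v.copy() for k, v in model.state_dict().items()}
    cfg = ls.TrainConfig(batch_size=4, epochs=3, learning_rate=0.0, seed=1)
    model, history = ls.train(model, train_set, val_set, cfg)
    after = model.state_dict()
    for k, v in before.items():
        np.testing.assert_array_equal(after[k], v)
    # constant loss across epochs (no parameter movement)
    losses = [r.val_loss for r in history.records]
    assert max(losses) - min(losses) < 1e-7


def test_early_stopping_patience_one(tiny_setup):
    """lr=0 with frozen statistics makes validation loss flat, so patience 1
    stops after exactly 2 epochs (1 best + 1 non-improving)."""
    model, train_set, val_set = tiny_setup
    freeze_batch_norm_stats(model)
    cfg = ls.TrainConfig(batch_size=4, epochs=50, learning_rate=0.0, early_stop_patience=1, seed=1)
    _, history = ls.train(model, train_set, val_set, cfg)
    assert len(history) == 2


def test_early_stop_restores_best_weights(tiny_setup):
    model, train_set, val_set = tiny_setup
    cfg = ls.TrainConfig(batch_size=4, epochs=6, learning_rate=1e-3, early_stop_patience=2, seed=2)
    model, history = ls.train(model, train_set, val_set, cfg)
    best = min(r.val_loss for r in history.records)
    # re-evaluating the returned model reproduces the best epoch's loss
    from lesionseg.training import _evaluate_epoch

    loss, _, _ = _evaluate_epoch(model, val_set, cfg.batch_size, cfg.loss)
    assert loss == pytest.approx(best, abs=1e-6)


def test_training_reduces_loss_on_repeated_batch(rng, tiny_config):
    model = ls.build_model(tiny_config, seed=6)
    samples = make_samples(rng, 4)
    cfg = ls.TrainConfig(batch_size=4, epochs=5, learning_rate=1e-3, seed=3)
    _, history = ls.train(model, samples, samples, cfg)
    assert history.records[-1].train_loss < history.records[0].train_loss


def test_identical_seeds_identical_histories(rng, tiny_config):
    samples = make_samples(rng, 10)
    cfg = ls.TrainConfig(
        batch_size=4, epochs=3, seed=9, augmentation=ls.AugmentationPolicy(seed=9)
    )
    histories = []
    for _ in range(2):
        model = ls.build_model(tiny_config, seed=9)
        _, h = ls.train(model, samples[:7], samples[7:], cfg)
        histories.append([(r.train_loss, r.val_loss, r.val_dice) for r in h.records])
    assert histories[0] == histories[1]


def test_history_csv_format(tmp_path, tiny_setup):
    model, train_set, val_set = tiny_setup
    cfg = ls.TrainConfig(batch_size=4, epochs=1, seed=0)
    _, history = ls.train(model, train_set, val_set, cfg)
    path = tmp_path / "history.csv"
    history.write_csv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "epoch,train_loss,val_loss,train_acc,val_acc,val_dice"
    assert len(lines) == 1 + len(history)


def test_train_config_validation():
    with pytest.raises(ValueError, match=">= 1"):
        ls.TrainConfig(batch_size=0)
    with pytest.raises(ValueError, match="betas"):
        ls.TrainConfig(beta2=1.0)
    with pytest.raises(ValueError, match="loss"):
        ls.TrainConfig(loss="focal")


def test_checkpoint_round_trip(tmp_path, tiny_setup, rng):
    model, _, _ = tiny_setup
    path = tmp_path / "model.npz"
    ls.checkpoint_save(model, path)
    rebuilt = ls.checkpoint_load(path)
    assert rebuilt.config == model.config
    assert rebuilt.n_parameters() == model.n_parameters()
    probe = rng.random((2, 3, 32, 32)).astype(np.float32)
    np.testing.assert_array_equal(model.predict(probe), rebuilt.predict(probe))


def test_checkpoint_config_mismatch(tmp_path, tiny_setup):
    model, _, _ = tiny_setup
    path = tmp_path / "model.npz"
    ls.checkpoint_save(model, path)
    other = ls.build_model(
        ls.ModelConfig(architecture="unet", input_size=(32, 32), depth=2, base_filters=4)
    )
    with pytest.raises(ValueError, match="does not match"):
        ls.checkpoint_load(path, model=other)
    with pytest.raises(FileNotFoundError):
        ls.checkpoint_load(tmp_path / "missing.npz")


def test_train_rejects_empty_or_mismatched(tiny_setup, rng):
    model, train_set, val_set = tiny_setup
    with pytest.raises(ValueError, match="nonempty"):
        ls.train(model, [], val_set, ls.TrainConfig(epochs=1))
    big = make_samples(rng, 3, size=64)
    with pytest.raises(ValueError, match="model expects"):
        ls.train(model, big, val_set, ls.TrainConfig(epochs=1))
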