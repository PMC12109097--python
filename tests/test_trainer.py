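import numpy as np
import pytest
from dataclasses import replace

import pemt
from pemt import (DatasetSpec, TrainConfig, ema_update, fit, generate_dataset,
                  init_state, load_checkpoint, predict, save_checkpoint,
                  train_step)
from pemt.trainer import Checkpoint, _augment, ablate


TINY = dict(t_max=10, batch_labeled=2, batch_unlabeled=2, base_width=4,
            depth=2, k_passes=4, decay_every=5)


@pytest.fixture(scope="module")
def tiny_dataset():
    spec = DatasetSpec(n_total=12, labeled_fraction=0.25, image_size=16,
                       boundary_blur_sigma=0.5, n_val=4, seed=3)
    return generate_dataset(spec)


def run_steps(dataset, config, n_steps):
    state = init_state(config)
    rng = np.random.default_rng(99)
    for t in range(1, n_steps + 1):
        li = rng.integers(0, len(dataset.labeled), config.batch_labeled)
        ui = rng.integers(0, len(dataset.unlabeled), config.batch_unlabeled)
        state, bundle = train_step(
            state, (dataset.labeled.images[li], dataset.labeled.masks[li]),
            dataset.unlabeled.images[ui], t, config)
    return state, bundle


class TestVariantLattice:
    """The ablation lattice collapses exactly at its degenerate corners."""

    def test_pemt_beta_zero_equals_uamt_rum(self, tiny_dataset):
        a, _ = run_steps(tiny_dataset, TrainConfig(variant="pemt", beta=0.0,
                                                   seed=5, **TINY), 10)
        b, _ = run_steps(tiny_dataset, TrainConfig(variant="uamt_rum",
                                                   seed=5, **TINY), 10)
        assert a.student.equal(b.student)
        assert a.teacher.equal(b.teacher)

    def test_uamt_infinite_tau_equals_mt(self, tiny_dataset):
        a, _ = run_steps(tiny_dataset, TrainConfig(variant="uamt",
                                                   tau_fixed=np.inf,
                                                   seed=5, **TINY), 10)
        b, _ = run_steps(tiny_dataset, TrainConfig(variant="mt",
                                                   seed=5, **TINY), 10)
        assert a.student.equal(b.student)
        assert a.teacher.equal(b.teacher)

    def test_mt_lambda_zero_equals_supervised(self, tiny_dataset):
        a, _ = run_steps(tiny_dataset, TrainConfig(variant="mt",
                                                   lambda_scale=0.0,
                                                   seed=5, **TINY), 10)
        b, _ = run_steps(tiny_dataset, TrainConfig(variant="supervised",
                                                   seed=5, **TINY), 10)
        assert a.student.equal(b.student)

    def test_default_rum_mask_retains_everything(self, tiny_dataset):
        """With upsilon=2 the RUM maximum (~0.354) sits below the smallest
        tau (~0.521), so uamt_rum's trajectory coincides with mt's."""
        a, _ = run_steps(tiny_dataset, TrainConfig(variant="uamt_rum",
                                                   seed=5, **TINY), 10)
        b, _ = run_steps(tiny_dataset, TrainConfig(variant="mt",
                                                   seed=5, **TINY), 10)
        assert a.student.equal(b.student)


class TestTrainStep:
    def test_supervised_leaves_teacher_untouched(self, tiny_dataset):
        config = TrainConfig(variant="supervised", seed=1, **TINY)
        state = init_state(config)
        teacher_before = state.teacher.copy()
        state, bundle = run_steps(tiny_dataset, config, 5)
        assert state.teacher.equal(teacher_before)
        assert bundle.consistency == 0.0

    def test_mt_first_step_copies_student_into_teacher(self, tiny_dataset):
        config = TrainConfig(variant="mt", seed=1, **TINY)
        state = init_state(config)
        state, _ = train_step(
            state,
            (tiny_dataset.labeled.images[:2], tiny_dataset.labeled.masks[:2]),
            tiny_dataset.unlabeled.images[:2], 1, config)
        # alpha(1) = 0: the teacher must equal the post-step student exactly
        assert state.teacher.equal(state.student)

    def test_teacher_changes_only_through_ema(self, tiny_dataset):
        """Teacher never accumulates gradients: across any step its update is
        exactly the EMA of (teacher_before, student_after)."""
        config = TrainConfig(variant="uamt", seed=2, **TINY)
        state = init_state(config)
        for t in range(1, 6):
            teacher_before = state.teacher.copy()
            state, _ = train_step(
                state,
                (tiny_dataset.labeled.images[:2], tiny_dataset.labeled.masks[:2]),
                tiny_dataset.unlabeled.images[:2], t, config)
            alpha = pemt.ema_alpha(t)
            expected = ema_update(teacher_before, state.student, alpha)
            assert state.teacher.equal(expected)

    def test_rejects_empty_labeled_batch(self, tiny_dataset):
        config = TrainConfig(variant="mt", seed=1, **TINY)
        state = init_state(config)
        with pytest.raises(ValueError):
            train_step(state,
                       (tiny_dataset.labeled.images[:0],
                        tiny_dataset.labeled.masks[:0]),
                       tiny_dataset.unlabeled.images[:2], 1, config)

    def test_loss_bundle_total_identity(self, tiny_dataset):
        config = TrainConfig(variant="uamt", seed=3, **TINY)
        _, bundle = run_steps(tiny_dataset, config, 3)
        assert bundle.total == pytest.approx(
            bundle.supervised + bundle.lambda_t * bundle.consistency, abs=1e-6)
        assert 0.0 <= bundle.masked_fraction <= 1.0


class TestFit:
    def test_same_seed_reproduces_validation_metrics(self, tiny_dataset):
        config = TrainConfig(variant="pemt", seed=11, **TINY)
        r1 = fit(tiny_dataset, config)
        r2 = fit(tiny_dataset, config)
        assert r1.val_metrics == r2.val_metrics
        assert r1.checkpoint.student.equal(r2.checkpoint.student)

    def test_zero_iterations_returns_initial_state(self, tiny_dataset):
        config = replace(TrainConfig(variant="mt", seed=4, **TINY), t_max=0)
        result = fit(tiny_dataset, config)
        fresh = init_state(config)
        assert result.checkpoint.student.equal(fresh.student)
        assert result.log == []

    def test_log_schema_and_lengths(self, tiny_dataset):
        config = TrainConfig(variant="uamt", seed=5, **TINY)
        result = fit(tiny_dataset, config)
        assert len(result.log) == config.t_max
        assert set(result.log[0]) == {"t", "lr", "lambda", "tau", "supervised",
                                      "consistency", "masked_fraction", "total"}

    def test_log_csv_round_trip(self, tiny_dataset, tmp_path):
        config = TrainConfig(variant="mt", seed=6, **TINY)
        path = tmp_path / "log.csv"
        fit(tiny_dataset, config, log_path=path)
        rows = path.read_text().strip().splitlines()
        assert len(rows) == config.t_max + 1  # header + one row per iteration


class TestPredictAndCheckpoint:
    def test_predict_deterministic_and_teacher_equals_student_at_init(
            self, tiny_dataset):
        config = TrainConfig(variant="pemt", seed=7, **TINY)
        state = init_state(config)
        ckpt = Checkpoint(config=config, student=state.student,
                          teacher=state.teacher, t=0, velocity=state.velocity)
        imgs = tiny_dataset.validation.images[:2]
        a = predict(ckpt, imgs, use_teacher=False)
        b = predict(ckpt, imgs, use_teacher=True)
        c = predict(ckpt, imgs, use_teacher=False)
        for m1, m2 in zip(a, b):
            np.testing.assert_array_equal(m1, m2)
        for m1, m2 in zip(a, c):
            np.testing.assert_array_equal(m1, m2)
        assert set(np.unique(a[0])) <= {0, 1}

    def test_checkpoint_h5_round_trip(self, tiny_dataset, tmp_path):
        config = TrainConfig(variant="pemt", seed=8, **TINY)
        result = fit(tiny_dataset, config)
        path = tmp_path / "ckpt.h5"
        save_checkpoint(path, result.checkpoint)
        loaded = load_checkpoint(path)
        assert loaded.config == config
        assert loaded.student.equal(result.checkpoint.student)
        assert loaded.teacher.equal(result.checkpoint.teacher)
        assert loaded.t == config.t_max


class TestAugment:
    def test_image_and_mask_transform_jointly(self):
        rng = np.random.default_rng(0)
        images = rng.random((6, 1, 8, 8)).astype(np.float32)
        masks = (images[:, 0] > 0.5).astype(np.int64)
        aug_i, aug_m = _augment(images, masks, np.random.default_rng(1),
                                rotation=True, flip=True)
        np.testing.assert_array_equal((aug_i[:, 0] > 0.5).astype(np.int64),
                                      aug_m)

    def test_disabled_augmentation_is_identity(self):
        rng = np.random.default_rng(2)
        images = rng.random((3, 1, 8, 8)).astype(np.float32)
        aug_i, _ = _augment(images, None, np.random.default_rng(3),
                            rotation=False, flip=False)
        np.testing.assert_array_equal(aug_i, images)


def test_ablate_emits_table_shaped_csv(tiny_dataset, tmp_path):
    config = TrainConfig(variant="pemt", seed=9, **TINY)
    path = tmp_path / "ablation.csv"
    rows = ablate(tiny_dataset, config, upsilons=(1.0, 2.0), betas=(0.001,),
                  csv_path=path)
    assert [r["parameter"] for r in rows] == ["upsilon", "upsilon", "beta"]
    text = path.read_text().strip().splitlines()
    assert text[0].split(",") == ["parameter", "value", "dsc", "jac",
                                  "hd95", "asd"]
    assert len(text) == 4


def test_config_yaml_round_trip():
    config = TrainConfig(variant="uamt", t_max=123, beta=0.0005, seed=17)
    assert TrainConfig.from_yaml(config.to_yaml()) == config
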