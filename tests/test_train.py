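"""Splitting, the BCE objective, and training-loop contracts."""

import numpy as np
import pytest

from colonyqc.augment import AugmentSpec
from colonyqc.exceptions import ParameterError, ValidationError
from colonyqc.image import BAD, GOOD
from colonyqc.models import build_model
from colonyqc.preprocess import PreprocessSpec
from colonyqc.synth import GeneratorParams, generate_dataset
from colonyqc.train import (TrainConfig, bce_loss, dataset_to_arrays,
                            evaluate_model, fit, split_dataset)

from conftest import make_flat_dataset


class TestSplit:
    def test_study_sizes_269_to_54(self):
        ds = make_flat_dataset(137, 132)
        tr, va = split_dataset(ds, (4, 1), seed=0)
        assert len(va) == 54
        assert len(tr) == 215

    def test_tiny_split(self):
        ds = make_flat_dataset(3, 2)
        tr, va = split_dataset(ds, (4, 1), seed=1)
        assert (len(tr), len(va)) == (4, 1)

    def test_partition_property(self):
        ds = make_flat_dataset(20, 17)
        for seed in range(5):
            tr, va = split_dataset(ds, (4, 1), seed=seed)
            ids = sorted(im.source_id for im in tr) + \
                sorted(im.source_id for im in va)
            assert sorted(ids) == sorted(im.source_id for im in ds)
            assert not ({im.source_id for im in tr}
                        & {im.source_id for im in va})

    def test_stratified_class_balance(self):
        ds = make_flat_dataset(40, 40)
        tr, va = split_dataset(ds, (4, 1), seed=3, stratified=True)
        assert va.n_good == va.n_bad == 8

    def test_same_seed_identical(self):
        ds = make_flat_dataset(10, 10)
        a = split_dataset(ds, (4, 1), seed=9)
        b = split_dataset(ds, (4, 1), seed=9)
        assert [im.source_id for im in a[1]] == [im.source_id for im in b[1]]

    def test_single_class_falls_back_with_warning(self):
        ds = make_flat_dataset(10, 0)
        with pytest.warns(UserWarning, match="unstratified"):
            tr, va = split_dataset(ds, (4, 1), seed=0, stratified=True)
        assert len(tr) + len(va) == 10

    def test_bad_ratio(self):
        with pytest.raises(ParameterError):
            split_dataset(make_flat_dataset(4, 4), (0, 1), seed=0)


class TestBceLoss:
    def test_printed_formula_hand_values(self):
        assert bce_loss([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2))
        assert bce_loss([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == pytest.approx(
            0.164252, abs=1e-6)

    def test_perfect_prediction_limit(self):
        assert bce_loss([1.0], [1.0 - 1e-12]) < 1e-6
        assert bce_loss([1.0, 0.0], [1.0, 0.0]) < 1e-6   # clamped, not inf

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            y = rng.integers(0, 2, n).astype(float)
            p = rng.uniform(1e-6, 1 - 1e-6, n)
            oracle = -sum(yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                          for yi, pi in zip(y, p)) / n
            assert bce_loss(y, p) == pytest.approx(oracle, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            bce_loss([1, 0], [0.5])


def _fit_tiny(seed=0, augment=None, epochs=3):
    params = GeneratorParams(image_size_px=(32, 32), um_per_px=290 / 32)
    ds = generate_dataset(10, 10, params, seed=50)
    tr, va = split_dataset(ds, (4, 1), seed=seed)
    model = build_model("VGG12", 32, seed=seed, width_multiplier=0.0625)
    cfg = TrainConfig(epochs=epochs, batch_size=8, seed=seed,
                      early_stop_patience=None)
    pp = PreprocessSpec(method="none", target_side_px=32)
    model, history = fit(model, tr, va, cfg, pp, augment)
    return model, history, (tr, va, pp)


class TestFit:
    def test_reproducible_history(self):
        _, h1, _ = _fit_tiny(seed=4)
        _, h2, _ = _fit_tiny(seed=4)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        assert h1.best_epoch == h2.best_epoch

    def test_history_bookkeeping(self):
        _, h, _ = _fit_tiny(epochs=3)
        assert h.n_epochs == 3 == len(h.val_loss) == len(h.val_metrics)
        assert all(l >= 0 for l in h.train_loss)
        assert 0 <= h.best_epoch < 3

    def test_checkpoint_is_best_val_loss(self):
        model, h, (tr, va, pp) = _fit_tiny(epochs=3)
        Xva, yva = dataset_to_arrays(va, pp)
        loss, report = evaluate_model(model, Xva, yva)
        assert loss == pytest.approx(min(h.val_loss), abs=1e-9)
        assert report.accuracy == pytest.approx(
            h.best_report().accuracy, abs=1e-12)

    def test_validation_never_augmented(self):
        """The returned model scores the raw validation set exactly as logged."""
        aug = AugmentSpec(use_crop=True, use_rotation=True, seed=2)
        model, h, (tr, va, pp) = _fit_tiny(augment=aug)
        Xva, yva = dataset_to_arrays(va, pp)
        loss1, r1 = evaluate_model(model, Xva, yva)
        loss2, r2 = evaluate_model(model, Xva, yva)
        assert loss1 == loss2 == pytest.approx(min(h.val_loss), abs=1e-9)
        assert r1.confusion == r2.confusion

    def test_preprocess_side_mismatch_rejected(self):
        params = GeneratorParams(image_size_px=(32, 32), um_per_px=290 / 32)
        ds = generate_dataset(4, 4, params, seed=1)
        tr, va = split_dataset(ds, (4, 1), seed=0)
        model = build_model("VGG12", 32, 0, 0.0625)
        with pytest.raises(ValidationError):
            fit(model, tr, va, TrainConfig(epochs=1),
                PreprocessSpec(target_side_px=64))
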