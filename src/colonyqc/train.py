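"""Dataset splitting, the binary cross-entropy objective, and the training loop.

The split follows the 4:1 train:validation convention by default and is
stratified by phenotype.  Training minimizes mean binary cross-entropy

    L = -(1/N) * sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]

with y = 1 for the good phenotype and p the network's predicted
good-colony probability, using Adam.  The checkpoint with the best
validation loss is returned.  Augmentation is applied online to training
images only; validation images are never augmented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentSpec, compose
from .evaluate import EvalReport, report_from_scores
from .exceptions import ParameterError, TrainingDivergedError, ValidationError
from .image import BAD, GOOD, ColonyImage, LabeledDataset
from .models import ModelHandle
from .nn import Adam, bce_with_logits
from .preprocess import PreprocessSpec, apply_preprocess, to_model_array

__all__ = ["TrainConfig", "TrainHistory", "split_dataset", "bce_loss", "fit",
           "dataset_to_arrays", "evaluate_model"]

_EPS = 1e-7  # probability clamp in the loss, avoids log(0)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters; the positive label is fixed to good (y=1)."""

    split_ratio: tuple[int, int] = (4, 1)
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0
    early_stop_patience: int | None = 10
    stratified: bool = True

    def __post_init__(self):
        if self.split_ratio[0] <= 0 or self.split_ratio[1] <= 0:
            raise ParameterError(f"split_ratio parts must be positive, got {self.split_ratio}")
        if self.batch_size < 1:
            raise ParameterError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ParameterError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.epochs < 1:
            raise ParameterError(f"epochs must be >= 1, got {self.epochs}")
        if self.optimizer not in ("adam", "sgd"):
            raise ParameterError(f"optimizer must be adam or sgd, got {self.optimizer!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metrics: list[EvalReport] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def best_report(self) -> EvalReport:
        return self.val_metrics[self.best_epoch]


def split_dataset(ds: LabeledDataset, ratio: tuple[int, int] = (4, 1),
                  seed: int = 0, stratified: bool = True
                  ) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive train/validation partition.

    Validation size is ``round(n * val_part / (train_part + val_part))``;
    under stratification the per-class validation counts are apportioned by
    largest remainder so they sum exactly to that size.
    """
    n = len(ds)
    if n == 0:
        raise ValidationError("cannot split an empty dataset")
    t, v = ratio
    if t <= 0 or v <= 0:
        raise ParameterError(f"ratio parts must be positive, got {ratio}")
    n_val = int(round(n * v / (t + v)))
    n_val = min(max(n_val, 0), n)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5B117)))

    labels = np.asarray(ds.labels(), dtype=object)
    if stratified and not (set(labels) >= {GOOD, BAD}):
        warnings.warn("a class is absent; falling back to an unstratified split",
                      stacklevel=2)
        stratified = False

    if not stratified:
        order = rng.permutation(n)
        val_idx = np.sort(order[:n_val])
    else:
        classes = [GOOD, BAD]
        idx_by_class = [np.flatnonzero(labels == c) for c in classes]
        exact = [len(ix) * n_val / n for ix in idx_by_class]
        base = [int(np.floor(e)) for e in exact]
        rem = n_val - sum(base)
        order_by_frac = np.argsort([-(e - b) for e, b in zip(exact, base)])
        for j in order_by_frac[:rem]:
            base[j] += 1
        picks = []
        for ix, k in zip(idx_by_class, base):
            picks.append(rng.permutation(ix)[:k])
        val_idx = np.sort(np.concatenate(picks).astype(int))
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    train_idx = np.flatnonzero(~val_mask)
    return ds.subset(train_idx), ds.subset(val_idx)


def bce_loss(y, p) -> float:
    """Mean binary cross-entropy on probabilities, clamped at 1e-7."""
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValidationError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _labels01(ds_or_labels) -> np.ndarray:
    labels = ds_or_labels.labels() if isinstance(ds_or_labels, LabeledDataset) \
        else list(ds_or_labels)
    bad_vals = sorted({str(v) for v in labels if v not in (GOOD, BAD)})
    if bad_vals:
        raise ValidationError(f"unlabeled/unknown items in training data: {bad_vals}")
    return np.asarray([1.0 if v == GOOD else 0.0 for v in labels])


def dataset_to_arrays(ds: LabeledDataset, preprocess: PreprocessSpec
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every image once; returns ``(X (N,1,S,S) in [0,1], y {0,1}^N)``."""
    xs = [to_model_array(apply_preprocess(im, preprocess)) for im in ds]
    return np.stack(xs), _labels01(ds)


def evaluate_model(model: ModelHandle, X: np.ndarray, y01: np.ndarray,
                   threshold: float = 0.5) -> tuple[float, EvalReport]:
    """Validation loss + metrics for a fixed model (no augmentation, no RNG)."""
    scores = model.predict_proba(X)
    labels = np.where(y01 > 0.5, GOOD, BAD)
    return bce_loss(y01, scores), report_from_scores(labels, scores, threshold)


def fit(model: ModelHandle, train_set: LabeledDataset, val_set: LabeledDataset,
        cfg: TrainConfig, preprocess: PreprocessSpec | None = None,
        augment: AugmentSpec | None = None, verbose: bool = False
        ) -> tuple[ModelHandle, TrainHistory]:
    """Train in place and return the best-validation-loss checkpoint + history.

    Fully reproducible: shuffling and augmentation derive from ``cfg.seed``
    and ``augment.seed``; the model's initial weights from its build seed.
    """
    preprocess = preprocess or PreprocessSpec(
        target_side_px=model.architecture.input_side)
    if preprocess.target_side_px != model.architecture.input_side:
        raise ValidationError(
            f"preprocess target side {preprocess.target_side_px} != model "
            f"input side {model.architecture.input_side}")
    Xtr, ytr = dataset_to_arrays(train_set, preprocess)
    Xva, yva = dataset_to_arrays(val_set, preprocess)

    transform = compose(augment) if augment is not None and augment.enabled else None
    rng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), 0xF17)))
    opt = Adam(model.network.parameters(), lr=cfg.learning_rate) \
        if cfg.optimizer == "adam" else None
    if opt is None:
        from .nn import SGD
        opt = SGD(model.network.parameters(), lr=cfg.learning_rate)

    history = TrainHistory()
    best_loss = np.inf
    best_weights = model.get_weights()
    since_best = 0
    n = len(Xtr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Xtr[idx]
            if transform is not None:
                xb = np.stack([transform.apply_array(im[0])[None] for im in xb])
            yb = ytr[idx]
            opt.zero_grad()
            z = model.network.forward(xb, train=True).ravel()
            loss, dz = bce_with_logits(z, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}")
            model.network.backward(dz.reshape(-1, 1))
            opt.step()
            epoch_losses.append(loss)
        val_loss, report = evaluate_model(model, Xva, yva)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_metrics.append(report)
        if verbose:
            print(f"epoch {epoch:3d}  train_loss {history.train_loss[-1]:.4f}  "
                  f"val_loss {val_loss:.4f}  val_acc {report.accuracy:.3f}")
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if (cfg.early_stop_patience is not None
                    and since_best >= cfg.early_stop_patience):
                break
    model.set_weights(best_weights)
    return model, history
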