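"""High-level Model/Results interface over the training pipeline.

``ColonyClassifier`` is constructed from a labelled dataset plus the
architecture, preprocessing, augmentation and training configuration;
``fit()`` performs the stratified split, trains the network, and returns a
``ClassifierResults`` carrying the best checkpoint, the full epoch history,
the validation metrics under both positive-class conventions, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentSpec
from .evaluate import EvalReport, dual_report
from .image import BAD, GOOD, LabeledDataset
from .models import ModelHandle, build_model
from .preprocess import PreprocessSpec
from .train import (TrainConfig, TrainHistory, dataset_to_arrays,
                    evaluate_model, fit, split_dataset)

__all__ = ["ColonyClassifier", "ClassifierResults"]


class ColonyClassifier:
    """A binary good/bad colony phenotype classifier bound to a dataset.

    Parameters
    ----------
    dataset
        Labelled images; split into train/validation at ``fit()`` time.
    architecture
        One of the registry names (e.g. ``"VGG13"``, ``"VGG12"``).
    preprocess, augment, config
        The pipeline configuration; defaults follow the package defaults
        (no preprocessing beyond the resize, no augmentation, Adam).
    width_multiplier
        Channel-width scaling for reduced desk-scale variants.
    """

    def __init__(self, dataset: LabeledDataset, architecture: str = "VGG13",
                 preprocess: PreprocessSpec | None = None,
                 augment: AugmentSpec | None = None,
                 config: TrainConfig | None = None,
                 width_multiplier: float = 1.0):
        self.dataset = dataset
        self.architecture = architecture
        self.preprocess = preprocess or PreprocessSpec()
        self.augment = augment
        self.config = config or TrainConfig()
        self.width_multiplier = width_multiplier

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs) -> "ColonyClassifier":
        from .synth import read_manifest
        return cls(read_manifest(manifest_path), **kwargs)

    def fit(self, verbose: bool = False) -> "ClassifierResults":
        train_set, val_set = split_dataset(self.dataset, self.config.split_ratio,
                                           seed=self.config.seed,
                                           stratified=self.config.stratified)
        model = build_model(self.architecture, self.preprocess.target_side_px,
                            seed=self.config.seed,
                            width_multiplier=self.width_multiplier)
        model, history = fit(model, train_set, val_set, self.config,
                             self.preprocess, self.augment, verbose=verbose)
        Xva, yva = dataset_to_arrays(val_set, self.preprocess)
        scores = model.predict_proba(Xva)
        labels = np.where(yva > 0.5, GOOD, BAD)
        reports = dual_report(labels, scores)
        return ClassifierResults(model=self, model_handle=model,
                                 history=history, train_set=train_set,
                                 val_set=val_set, reports=reports)

    def __repr__(self):
        return (f"ColonyClassifier({self.architecture!r}, n={len(self.dataset)}, "
                f"preprocess={self.preprocess.method!r})")


@dataclass
class ClassifierResults:
    """Fitted-classifier results: checkpoint, history, validation metrics."""

    model: ColonyClassifier
    model_handle: ModelHandle
    history: TrainHistory
    train_set: LabeledDataset
    val_set: LabeledDataset
    reports: dict[str, EvalReport]

    @property
    def report(self) -> EvalReport:
        """Headline metrics (good-positive convention)."""
        return self.reports[GOOD]

    def predict_proba(self, dataset: LabeledDataset) -> np.ndarray:
        X, _ = dataset_to_arrays(dataset, self.model.preprocess)
        return self.model_handle.predict_proba(X)

    def predict(self, dataset: LabeledDataset, threshold: float = 0.5):
        return np.where(self.predict_proba(dataset) >= threshold, GOOD, BAD)

    def summary(self) -> str:
        r = self.report
        rb = self.reports[BAD]
        cm = r.confusion
        arch = self.model_handle.architecture
        lines = [
            "Colony phenotype classifier".center(62),
            "=" * 62,
            f"Architecture:      {arch.name} (input {arch.input_side}px, "
            f"width x{arch.width_multiplier:g})",
            f"Parameters:        {self.model_handle.parameter_count:,}",
            f"Preprocessing:     {self.model.preprocess.method}",
            f"Augmentation:      crop={getattr(self.model.augment, 'use_crop', False)}, "
            f"rotation={getattr(self.model.augment, 'use_rotation', False)}",
            f"Train/validation:  {len(self.train_set)}/{len(self.val_set)} "
            f"(ratio {self.model.config.split_ratio[0]}:{self.model.config.split_ratio[1]})",
            f"Epochs run:        {self.history.n_epochs} "
            f"(best epoch {self.history.best_epoch})",
            "-" * 62,
            "Validation confusion matrix (rows = actual):",
            f"                 pred good   pred bad",
            f"  actual good   {cm.tp:9d}  {cm.fn:9d}",
            f"  actual bad    {cm.fp:9d}  {cm.tn:9d}",
            "-" * 62,
            f"{'metric':<12}{'good-positive':>16}{'bad-positive':>16}",
            f"{'accuracy':<12}{r.accuracy:>16.4f}{rb.accuracy:>16.4f}",
            f"{'precision':<12}{r.precision:>16.4f}{rb.precision:>16.4f}",
            f"{'recall':<12}{r.recall:>16.4f}{rb.recall:>16.4f}",
            f"{'f1':<12}{r.f1:>16.4f}{rb.f1:>16.4f}",
            f"{'auc':<12}{(r.auc if r.auc is not None else float('nan')):>16.4f}"
            f"{(rb.auc if rb.auc is not None else float('nan')):>16.4f}",
            "=" * 62,
        ]
        return "\n".join(lines)
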