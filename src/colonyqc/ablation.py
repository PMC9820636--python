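"""Ablation harness: rerun the architecture x preprocessing x augmentation grid.

``run_ablation`` trains one classifier per grid combination on a shared
dataset and collects the five quality measures per row.  Completed
combinations are registered on disk (JSON keyed by a config hash), so an
interrupted grid resumes without retraining.  ``staged=True`` reproduces the
sequential protocol — scan architectures first, fix the winner, scan
preprocessing, fix, scan augmentation — instead of the full factorial.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentSpec
from .classifier import ColonyClassifier
from .image import LabeledDataset
from .preprocess import PreprocessSpec
from .train import TrainConfig

__all__ = ["RunConfig", "run_ablation", "report", "run_one"]

_METRICS = ("accuracy", "precision", "recall", "f1", "auc")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """One fully specified run; serializable, hashable, reproducible."""

    architecture: str
    preprocess: PreprocessSpec
    augment: AugmentSpec
    train: TrainConfig
    width_multiplier: float = 1.0

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "preprocess": dataclasses.asdict(self.preprocess),
            "augment": dataclasses.asdict(self.augment),
            "train": dataclasses.asdict(self.train),
            "width_multiplier": self.width_multiplier,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        train = dict(d["train"])
        if "split_ratio" in train:
            train["split_ratio"] = tuple(train["split_ratio"])
        return cls(architecture=d["architecture"],
                   preprocess=PreprocessSpec(**d["preprocess"]),
                   augment=AugmentSpec(**d["augment"]),
                   train=TrainConfig(**train),
                   width_multiplier=d.get("width_multiplier", 1.0))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_one(cfg: RunConfig, dataset: LabeledDataset, verbose: bool = False) -> dict:
    """Train + evaluate one configuration; returns a metrics row."""
    clf = ColonyClassifier(dataset, architecture=cfg.architecture,
                           preprocess=cfg.preprocess, augment=cfg.augment,
                           config=cfg.train,
                           width_multiplier=cfg.width_multiplier)
    res = clf.fit(verbose=verbose)
    r = res.report
    return {"architecture": cfg.architecture,
            "preprocess": cfg.preprocess.method,
            "augment_crop": cfg.augment.use_crop,
            "augment_rotation": cfg.augment.use_rotation,
            "accuracy": r.accuracy, "precision": r.precision,
            "recall": r.recall, "f1": r.f1,
            "auc": r.auc if r.auc is not None else np.nan,
            "config_hash": cfg.digest(), "failed": False}


def _augment_choices(base: AugmentSpec) -> dict[str, AugmentSpec]:
    return {
        "none": dataclasses.replace(base, use_crop=False, use_rotation=False),
        "rotations": dataclasses.replace(base, use_crop=False, use_rotation=True),
        "cropping": dataclasses.replace(base, use_crop=True, use_rotation=False),
        "rotations+cropping": dataclasses.replace(base, use_crop=True,
                                                  use_rotation=True),
    }


def run_ablation(architectures: list[str], preprocess_methods: list[str],
                 augment_modes: list[str], base: RunConfig,
                 dataset: LabeledDataset, out_dir: str | Path | None = None,
                 staged: bool = True, verbose: bool = False) -> pd.DataFrame:
    """Run the ablation grid; resumable via an on-disk registry.

    staged=True: architectures (no preprocess/augment) -> best by accuracy;
    preprocessing with that architecture -> best; augmentation with both
    fixed.  staged=False: full factorial.  Failed runs are recorded with NaN
    metrics and the grid continues.
    """
    if not (architectures and preprocess_methods and augment_modes):
        raise ValueError("grid must be nonempty in every dimension")
    registry = Path(out_dir) / "runs" if out_dir is not None else None
    if registry is not None:
        registry.mkdir(parents=True, exist_ok=True)

    def run_cached(cfg: RunConfig, stage: str) -> dict:
        path = registry / f"{cfg.digest()}.json" if registry is not None else None
        if path is not None and path.exists():
            row = json.loads(path.read_text())
        else:
            try:
                row = run_one(cfg, dataset, verbose=verbose)
            except Exception as err:       # record the failure, keep scanning
                row = {"architecture": cfg.architecture,
                       "preprocess": cfg.preprocess.method,
                       "augment_crop": cfg.augment.use_crop,
                       "augment_rotation": cfg.augment.use_rotation,
                       **{m: np.nan for m in _METRICS},
                       "config_hash": cfg.digest(), "failed": True,
                       "error": str(err)}
            if path is not None:
                path.write_text(json.dumps(row))
        return {**row, "stage": stage}

    aug_choices = _augment_choices(base.augment)
    rows: list[dict] = []

    def cfg_for(arch: str, method: str, aug_mode: str) -> RunConfig:
        return dataclasses.replace(
            base, architecture=arch,
            preprocess=dataclasses.replace(base.preprocess, method=method),
            augment=aug_choices[aug_mode])

    if staged:
        for arch in architectures:
            rows.append(run_cached(cfg_for(arch, "none", "none"), "architecture"))
        best_arch = _best(rows, "architecture")["architecture"]
        pp_rows = [run_cached(cfg_for(best_arch, m, "none"), "preprocess")
                   for m in preprocess_methods]
        rows.extend(pp_rows)
        best_pp = _best(pp_rows, "preprocess")["preprocess"]
        aug_rows = [run_cached(cfg_for(best_arch, best_pp, a), "augment")
                    for a in augment_modes]
        rows.extend(aug_rows)
    else:
        for arch in architectures:
            for m in preprocess_methods:
                for a in augment_modes:
                    rows.append(run_cached(cfg_for(arch, m, a), "factorial"))
    return pd.DataFrame(rows)


def _best(rows: list[dict], stage: str) -> dict:
    ok = [r for r in rows if r.get("stage") == stage and not r.get("failed")]
    if not ok:
        raise RuntimeError(f"every run in stage {stage!r} failed")
    return max(ok, key=lambda r: r["accuracy"])


def report(results: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write CSV + JSON + a rendered text summary with per-measure maxima."""
    if results.empty:
        raise ValueError("results table is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "ablation.csv"
    json_path = out / "ablation.json"
    txt_path = out / "ablation.txt"
    results.to_csv(csv_path, index=False)
    json_path.write_text(results.to_json(orient="records", indent=1))
    lines = []
    for _, row in results.iterrows():
        tag = (f"{row['architecture']:<18} pp={row['preprocess']:<10} "
               f"crop={str(row['augment_crop']):<5} "
               f"rot={str(row['augment_rotation']):<5} ")
        if row.get("failed"):
            lines.append(tag + "FAILED")
            continue
        cells = []
        for m in _METRICS:
            star = "*" if row[m] == results[m].max() else " "
            cells.append(f"{m}={row[m]:.3f}{star}")
        lines.append(tag + " ".join(cells))
    txt_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "json": json_path, "txt": txt_path}
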