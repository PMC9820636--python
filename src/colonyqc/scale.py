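"""Characteristic-spatial-scale experiment: recursive image quartering.

Each image is cut into four equal quadrants, each quadrant inheriting the
parent's phenotype label and half the physical extent; repeating the cut k
times yields a level-k dataset of ``n0 * 4**k`` images covering
``base_um / 2**k`` each (linear scale = crop width).  Training the same
classifier at every level and comparing validation quality locates the crop
size that is most informative about the phenotype — in the reference
imaging geometry, level 1 of a 290 µm field is 145 µm, i.e. the ~144 µm
scale between a single cell (~15 µm) and a whole colony (~540 µm).

The train/validation split is made once at level 0 and propagated, so all
crops of one parent image stay on one side of the split (no leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import AugmentSpec
from .evaluate import EvalReport
from .exceptions import ParameterError, TrainingDivergedError
from .image import ColonyImage, LabeledDataset
from .models import build_model
from .preprocess import PreprocessSpec
from .train import TrainConfig, fit, split_dataset

__all__ = ["ScaleLevel", "quarter", "quarter_dataset", "build_pyramid",
           "crop_size_um", "scale_scan"]


@dataclass(frozen=True)
class ScaleLevel:
    """One pyramid depth: k = 0 is the full image."""

    k: int
    crop_px: tuple[int, int]
    crop_um: tuple[float, float]
    n_images: int
    metrics: EvalReport | None = None


def quarter(img: ColonyImage) -> list[ColonyImage]:
    """Cut into four non-overlapping quadrants covering the input exactly.

    Odd sides are padded by edge replication first (with a warning), so the
    quadrants always tile the (padded) input.  Order: top-left, top-right,
    bottom-left, bottom-right.
    """
    px = np.asarray(img.pixels)
    h, w = px.shape[:2]
    if h % 2 or w % 2:
        warnings.warn(f"padding odd-sized image {h}x{w} by edge replication",
                      stacklevel=2)
        pad = [(0, h % 2), (0, w % 2)] + [(0, 0)] * (px.ndim - 2)
        px = np.pad(px, pad, mode="edge")
        h, w = px.shape[:2]
    hh, hw = h // 2, w // 2
    out = []
    for qi, (ys, xs) in enumerate(((0, 0), (0, hw), (hh, 0), (hh, hw))):
        out.append(img.with_pixels(px[ys:ys + hh, xs:xs + hw],
                                   source_id=f"{img.source_id}/q{qi}"))
    return out


def quarter_dataset(ds: LabeledDataset) -> LabeledDataset:
    items = []
    for im in ds:
        items.extend(quarter(im))
    return LabeledDataset(items=items)


def crop_size_um(k: int, base_um_width: float) -> float:
    """Linear crop scale at level k: ``base_um_width / 2**k``."""
    if k < 0:
        raise ParameterError(f"k must be >= 0, got {k}")
    if base_um_width <= 0:
        raise ParameterError(f"base_um_width must be > 0, got {base_um_width}")
    return base_um_width / 2**k


def build_pyramid(ds: LabeledDataset, max_k: int
                  ) -> list[tuple[ScaleLevel, LabeledDataset]]:
    """Level-k datasets for k = 0..max_k; class balance preserved exactly.

    Stops early (with a warning) if images become too small to quarter.
    """
    if max_k < 0:
        raise ParameterError(f"max_k must be >= 0, got {max_k}")
    levels = []
    current = ds
    for k in range(max_k + 1):
        if len(current):
            h, w = current[0].pixels.shape[:2]
            um = (current[0].extent_um)
        else:
            h = w = 0
            um = (0.0, 0.0)
        levels.append((ScaleLevel(k=k, crop_px=(h, w), crop_um=um,
                                  n_images=len(current)), current))
        if k == max_k:
            break
        if len(current) and min(h, w) < 2:
            warnings.warn(f"stopping pyramid at k={k}: images are {h}x{w}",
                          stacklevel=2)
            break
        current = quarter_dataset(current)
    return levels


def scale_scan(ds: LabeledDataset, max_k: int, model_name: str,
               train_cfg: TrainConfig, preprocess: PreprocessSpec,
               augment: AugmentSpec | None = None,
               seeds: tuple[int, ...] = (0,),
               width_multiplier: float = 1.0,
               verbose: bool = False) -> pd.DataFrame:
    """Train from scratch at every pyramid level and tabulate quality.

    For each seed the level-0 dataset is split train/validation, both sides
    are quartered independently down to ``max_k`` (so crops of one parent
    never straddle the split), and a fresh ``model_name`` classifier is
    trained and evaluated per level.  Returns one row per (level, seed) with
    columns level, crop_px, crop_um, seed, accuracy, f1 (NaN metrics mark a
    diverged run), i.e. ``(max_k + 1) * len(seeds)`` rows.
    """
    if not seeds:
        raise ParameterError("at least one seed is required")
    rows = []
    for seed in seeds:
        tr0, va0 = split_dataset(ds, train_cfg.split_ratio, seed=seed,
                                 stratified=train_cfg.stratified)
        tr_levels = build_pyramid(tr0, max_k)
        va_levels = build_pyramid(va0, max_k)
        for (lvl, tr_k), (_, va_k) in zip(tr_levels, va_levels):
            # leakage guard: no parent image contributes to both sides
            tr_src = {im.source_id.split("/")[0] for im in tr_k}
            va_src = {im.source_id.split("/")[0] for im in va_k}
            assert not (tr_src & va_src), "split leaked across pyramid levels"
            model = build_model(model_name, preprocess.target_side_px,
                                seed=seed, width_multiplier=width_multiplier)
            cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
            acc = f1 = np.nan
            try:
                model, history = fit(model, tr_k, va_k, cfg, preprocess,
                                     augment, verbose=verbose)
                report = history.best_report()
                acc, f1 = report.accuracy, report.f1
            except TrainingDivergedError as err:
                warnings.warn(f"level {lvl.k} seed {seed} diverged: {err}",
                              stacklevel=2)
            rows.append({"level": lvl.k, "crop_px": lvl.crop_px[1],
                         "crop_um": lvl.crop_um[1], "seed": seed,
                         "accuracy": acc, "f1": f1})
            if verbose:
                print(f"seed {seed} level {lvl.k} "
                      f"({lvl.crop_um[1]:.0f} um): acc={acc:.3f} f1={f1:.3f}")
    return pd.DataFrame(rows)
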