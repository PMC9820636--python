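"""Synthetic phase-contrast colony images with ground-truth phenotype labels.

The generator renders a pseudo-phase-contrast colony: dark cell bodies on a
brighter background, a bright halo rim at the colony edge, and inter-cell
gaps whose brightness is a class parameter.  The two phenotype presets encode
the morphological cues that distinguish healthy from differentiating
colonies:

* ``good`` — tightly packed, nearly round cells of uniform size; smooth,
  well-defined colony edge; almost no visible inter-cell background.
* ``bad`` — loosely packed, elongated cells of variable size; phase-bright
  gaps between cells; spiky colony edge.

A single ``separation`` knob interpolates the bad-class preset between the
good preset (0 = classes statistically identical) and the full bad preset
(1 = maximal morphological contrast), giving a controllable effect size for
benchmarking classifiers.

Everything is deterministic: one master seed spawns per-image child seeds by
counter, so datasets are reproducible and insertion-order independent.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import binary_erosion, gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .exceptions import ParameterError, ValidationError
from .image import BAD, GOOD, ColonyImage, LabeledDataset

__all__ = [
    "ClassPreset",
    "GeneratorParams",
    "generate_colony",
    "generate_colony_with_mask",
    "generate_dataset",
    "generate_scale_probe_dataset",
    "write_manifest",
    "read_manifest",
]


@dataclass(frozen=True)
class ClassPreset:
    """Morphological parameters of one phenotype class.

    cell_eccentricity : ellipse eccentricity of cell bodies, in [0, 1).
    packing_fraction  : fraction of the colony area covered by cells, (0, 1].
    size_cv           : coefficient of variation of cell radius.
    edge_spikiness    : relative amplitude of radial noise on the colony
                        boundary (0 = smooth circle).
    gap_brightness    : brightness of inter-cell background inside the
                        colony, 0 = same as colony bed, 1 = phase-bright.
    """

    cell_eccentricity: float
    packing_fraction: float
    size_cv: float
    edge_spikiness: float
    gap_brightness: float

    def validate(self, who: str) -> None:
        for name in ("cell_eccentricity", "packing_fraction", "size_cv",
                     "edge_spikiness", "gap_brightness"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ParameterError(f"{who}.{name} must be finite, got {v!r}")
        if not 0.0 <= self.cell_eccentricity < 1.0:
            raise ParameterError(
                f"{who}.cell_eccentricity must be in [0, 1), got {self.cell_eccentricity}")
        if not 0.0 < self.packing_fraction <= 1.0:
            raise ParameterError(
                f"{who}.packing_fraction must be in (0, 1], got {self.packing_fraction}")
        if self.size_cv < 0:
            raise ParameterError(f"{who}.size_cv must be >= 0, got {self.size_cv}")
        if self.edge_spikiness < 0:
            raise ParameterError(
                f"{who}.edge_spikiness must be >= 0, got {self.edge_spikiness}")

    def blend(self, other: "ClassPreset", t: float) -> "ClassPreset":
        """Component-wise interpolation ``self + t * (other - self)``."""
        return ClassPreset(*(a + t * (b - a) for a, b in
                             zip(self._astuple(), other._astuple())))

    def _astuple(self):
        return (self.cell_eccentricity, self.packing_fraction, self.size_cv,
                self.edge_spikiness, self.gap_brightness)


GOOD_PRESET = ClassPreset(cell_eccentricity=0.30, packing_fraction=0.90,
                          size_cv=0.10, edge_spikiness=0.02, gap_brightness=0.0)
BAD_PRESET = ClassPreset(cell_eccentricity=0.85, packing_fraction=0.50,
                         size_cv=0.35, edge_spikiness=0.25, gap_brightness=0.6)


@dataclass(frozen=True)
class GeneratorParams:
    """Full configuration of the synthetic colony renderer.

    Defaults render a 256x256 px field at 290/256 µm/px, so the whole
    ~290 µm field of view of the reference imaging geometry fits in a small
    image; the real-camera geometry (1280x960 px at 0.2266 µm/px) is
    available by overriding ``image_size_px`` and ``um_per_px``.
    """

    image_size_px: tuple[int, int] = (256, 256)       # (H, W)
    um_per_px: float = 290.0 / 256.0
    cell_diameter_um: float = 15.0                    # typical hPSC cell, ~10-15 µm
    good: ClassPreset = field(default_factory=lambda: GOOD_PRESET)
    bad: ClassPreset = field(default_factory=lambda: BAD_PRESET)
    noise_sd: float = 0.02
    separation: float = 1.0

    def validate(self) -> None:
        h, w = self.image_size_px
        if not (isinstance(h, (int, np.integer)) and isinstance(w, (int, np.integer))
                and h >= 8 and w >= 8):
            raise ParameterError(
                f"image_size_px must be an integer pair >= 8, got {self.image_size_px}")
        if self.um_per_px <= 0:
            raise ParameterError(f"um_per_px must be > 0, got {self.um_per_px}")
        if self.cell_diameter_um <= 0:
            raise ParameterError(
                f"cell_diameter_um must be > 0, got {self.cell_diameter_um}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.separation <= 1.0:
            raise ParameterError(
                f"separation must be in [0, 1], got {self.separation}")
        self.good.validate("good")
        self.bad.validate("bad")

    @classmethod
    def real_geometry(cls, **overrides) -> "GeneratorParams":
        """Parameters matching the reference camera: 1280x960 px, 290x218 µm²."""
        return cls(image_size_px=(960, 1280), um_per_px=290.0 / 1280.0, **overrides)

    def preset_for(self, label: str) -> ClassPreset:
        """Effective preset: good is fixed; bad is blended by ``separation``."""
        if label == GOOD:
            return self.good
        if label == BAD:
            return self.good.blend(self.bad, self.separation)
        raise ParameterError(f"label must be 'good' or 'bad', got {label!r}")


# rendering intensities (float, [0, 1] after clipping)
_BG_OUT = 0.60       # medium outside the colony
_BED = 0.48          # colony bed (inter-cell background at gap_brightness=0)
_GAP_BRIGHT = 0.88   # inter-cell background at gap_brightness=1 (phase-bright)
_CELL = 0.34         # cell body
_RIM = 0.95          # phase halo at the colony edge


def _colony_mask(rng: np.random.Generator, shape: tuple[int, int],
                 preset: ClassPreset) -> np.ndarray:
    """Radial polygon with per-vertex noise amplitude = edge_spikiness."""
    h, w = shape
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    base_r = 0.38 * min(h, w) * rng.uniform(0.9, 1.05)
    n_vert = 32
    theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    radial = rng.standard_normal(n_vert)
    radii = base_r * np.clip(1.0 + preset.edge_spikiness * radial, 0.4, 1.8)
    rr, cc = draw_polygon(cy + radii * np.sin(theta), cx + radii * np.cos(theta),
                          shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _render(params: GeneratorParams, preset: ClassPreset, seed: int):
    """Render one colony; returns (float01 pixels, masks dict)."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC010)))
    h, w = params.image_size_px
    colony = _colony_mask(rng, (h, w), preset)
    colony_area = int(colony.sum())

    cell_r_px = max(1.5, 0.5 * params.cell_diameter_um / params.um_per_px)
    mean_cell_area = np.pi * cell_r_px**2
    # Boolean model: randomly placed cells overlap, so to reach a target
    # covered fraction p the intensity must be -log(1-p) cells per cell-area.
    lam = -np.log(1.0 - min(preset.packing_fraction, 0.995))
    n_cells = max(1, int(round(lam * colony_area / mean_cell_area)))

    cells = np.zeros((h, w), dtype=bool)
    cell_shade = np.zeros((h, w), dtype=np.float64)
    ys, xs = np.nonzero(colony)
    if len(ys):
        idx = rng.integers(0, len(ys), size=n_cells)
        ecc = preset.cell_eccentricity
        flat = (1.0 - ecc**2) ** 0.25          # area-preserving axis scaling
        for i in range(n_cells):
            r = cell_r_px * max(0.3, 1.0 + preset.size_cv * rng.standard_normal())
            a, b = r / flat, r * flat          # major, minor semi-axes
            rot = rng.uniform(0, np.pi)
            shade = _CELL + rng.uniform(-0.04, 0.04)
            rr, cc = draw_ellipse(ys[idx[i]], xs[idx[i]], a, b,
                                  shape=(h, w), rotation=rot)
            cells[rr, cc] = True
            cell_shade[rr, cc] = shade
    cells &= colony

    gap_val = _BED + preset.gap_brightness * (_GAP_BRIGHT - _BED)
    img = np.full((h, w), _BG_OUT)
    img[colony] = gap_val
    img[cells] = cell_shade[cells]
    rim = colony & ~binary_erosion(colony, iterations=2)
    img[rim] = _RIM

    img = gaussian_filter(img, sigma=1.0)
    img += params.noise_sd * rng.standard_normal((h, w))
    np.clip(img, 0.0, 1.0, out=img)
    return img, {"colony": colony, "cells": cells}


def generate_colony_with_mask(params: GeneratorParams, label: str, seed: int):
    """Like :func:`generate_colony` but also returns the ground-truth masks.

    Returns ``(image, masks)`` where ``masks`` has boolean ``"colony"`` and
    ``"cells"`` arrays.  The inter-cell background inside the colony is
    ``colony & ~cells``.
    """
    params.validate()
    preset = params.preset_for(label)
    pixels, masks = _render(params, preset, seed)
    img = ColonyImage(pixels=pixels,
                      um_per_px=(params.um_per_px, params.um_per_px),
                      label=label, intensity_range="float01",
                      source_id=f"synth-{label}-{seed}")
    return img, masks


def generate_colony(params: GeneratorParams, label: str, seed: int) -> ColonyImage:
    """Render one synthetic colony image, deterministic in (params, label, seed)."""
    img, _ = generate_colony_with_mask(params, label, seed)
    return img


def _child_seed(master: int, counter: int) -> int:
    """Per-image child seed derived from the master seed by counter."""
    ss = np.random.SeedSequence((int(master), int(counter)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_dataset(n_good: int, n_bad: int, params: GeneratorParams,
                     seed: int) -> LabeledDataset:
    """Generate a dataset with exact class counts.

    Each item gets an independent child seed spawned from the master seed by
    counter, so any item can be regenerated without the rest.  Items are
    ordered good-first; downstream splits shuffle/stratify explicitly.
    """
    if n_good < 0 or n_bad < 0:
        raise ParameterError(f"n_good/n_bad must be >= 0, got ({n_good}, {n_bad})")
    params.validate()
    items = []
    for i in range(n_good + n_bad):
        label = GOOD if i < n_good else BAD
        img, _ = generate_colony_with_mask(params, label, _child_seed(seed, i))
        items.append(replace(img, source_id=f"synth-{label}-{i:04d}"))
    return LabeledDataset(items=items)


def generate_scale_probe_dataset(n_good: int, n_bad: int, seed: int,
                                 image_size: tuple[int, int] = (128, 128),
                                 contrast: float = 0.18,
                                 noise_sd: float = 0.03) -> LabeledDataset:
    """Dataset whose discriminative signal exists only below whole-image scale.

    Both classes share the colony outline, edge and mean intensity.  The bad
    class carries a 1-px-period bright/dark lattice inside the colony —
    zero-mean contrast emulating thin phase-bright gaps between rows of
    tightly packed cells.  Because the lattice has period 2 px, an exact 2x
    local-mean downsample cancels it, so a classifier fed whole images at
    half resolution sees (almost) no class signal while quarter-crops at
    native resolution retain it.  This is the constructed-signal input for
    the characteristic-spatial-scale experiment.
    """
    if n_good < 0 or n_bad < 0:
        raise ParameterError(f"n_good/n_bad must be >= 0, got ({n_good}, {n_bad})")
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    checker = ((yy + xx) % 2) * 2.0 - 1.0       # ±1, zero mean on 2x2 blocks
    items = []
    preset = ClassPreset(cell_eccentricity=0.3, packing_fraction=0.9,
                         size_cv=0.1, edge_spikiness=0.05, gap_brightness=0.0)
    for i in range(n_good + n_bad):
        label = GOOD if i < n_good else BAD
        rng = np.random.default_rng(
            np.random.SeedSequence((int(seed), int(i), 0x5CA1)))
        colony = _colony_mask(rng, (h, w), preset)
        img = np.full((h, w), _BG_OUT)
        img[colony] = _BED
        rim = colony & ~binary_erosion(colony, iterations=2)
        img[rim] = _RIM
        if label == BAD:
            img[colony] += contrast * checker[colony]
        img += noise_sd * rng.standard_normal((h, w))
        np.clip(img, 0.0, 1.0, out=img)
        items.append(ColonyImage(pixels=img, um_per_px=(290.0 / w, 290.0 / w),
                                 label=label, intensity_range="float01",
                                 source_id=f"probe-{label}-{i:04d}"))
    return LabeledDataset(items=items)


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def write_manifest(ds: LabeledDataset, out_dir: str | Path) -> Path:
    """Write images as 8-bit PNGs plus a CSV manifest and its JSON mirror.

    Returns the path of the CSV manifest.  Reading it back with
    :func:`read_manifest` reconstructs identical labels and counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(ds):
        name = f"{i:05d}_{im.label}.png"
        px = im.pixels
        if im.intensity_range == "float01":
            px = np.round(np.asarray(px) * 255.0)
        arr = np.asarray(px, dtype=np.uint8)
        Image.fromarray(arr).save(out / name)
        rows.append({"path": name, "label": im.label,
                     "um_per_px_y": im.um_per_px[0], "um_per_px_x": im.um_per_px[1]})
    csv_path = out / "manifest.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label",
                                                "um_per_px_y", "um_per_px_x"])
        writer.writeheader()
        writer.writerows(rows)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"items": rows, "n_good": ds.n_good, "n_bad": ds.n_bad}, fh,
                  indent=1)
    return csv_path


def read_manifest(manifest: str | Path) -> LabeledDataset:
    """Read a dataset back from a CSV manifest (``path,label`` + optional µm columns).

    Rows with labels outside {good, bad, unlabeled} are collected and
    reported together in a single validation error.
    """
    manifest = Path(manifest)
    if manifest.is_dir():
        manifest = manifest / "manifest.csv"
    base = manifest.parent
    items, offenders = [], []
    with open(manifest, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            label = row["label"]
            if label not in (GOOD, BAD, "unlabeled"):
                offenders.append(f"line {lineno}: {label!r}")
                continue
            arr = np.asarray(Image.open(base / row["path"]))
            um = (float(row.get("um_per_px_y", 1.0) or 1.0),
                  float(row.get("um_per_px_x", 1.0) or 1.0))
            items.append(ColonyImage(pixels=arr, um_per_px=um, label=label,
                                     intensity_range="uint8",
                                     source_id=row["path"]))
    if offenders:
        raise ValidationError(
            "manifest contains unknown labels: " + "; ".join(offenders))
    return LabeledDataset(items=items, manifest_path=str(manifest))
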