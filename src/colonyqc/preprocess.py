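"""Image preprocessing operators, each a pure transform on :class:`ColonyImage`.

Four operators — grayscale conversion, min–max intensity normalization,
fixed-threshold binarization, and global histogram equalization — plus the
resize to the network input side.  Operators never mutate their input and
compose freely; their range contracts are:

=================  =================
operator           output range
=================  =================
``to_gray``        [0, 255] (uint8 scale kept as float)
``minmax``         [0, 1]
``binarize``       {0, 1}
``equalize``       [0, 1]
=================  =================

Downscaling uses local-mean (area) interpolation: each output pixel is the
mean of the source area it covers, which is the natural choice for
photometric data and keeps per-axis µm/px bookkeeping exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.exposure import equalize_hist
from skimage.filters import threshold_otsu
from skimage.transform import resize_local_mean

from .exceptions import ParameterError, ValidationError
from .image import ColonyImage

__all__ = [
    "PreprocessSpec", "METHODS",
    "resize_to_input", "to_gray", "minmax_normalize", "binarize",
    "equalize_histogram", "apply_preprocess", "to_model_array",
]

METHODS = ("none", "gray", "normalize", "binarize", "equalize")

# Rec. 601 luma weights; they sum to exactly 1.000 so gray pixels are fixed points.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessSpec:
    """Which operator to apply, and the shared resize target.

    ``method`` is one of ``{"none", "gray", "normalize", "binarize",
    "equalize"}``; ``binarize_threshold`` is a float in (0, 1) on the
    normalized intensity scale or the string ``"otsu"``; ``target_side_px``
    is the square network input side.
    """

    method: str = "none"
    binarize_threshold: float | str = "otsu"
    target_side_px: int = 256

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(
                f"method must be one of {METHODS}, got {self.method!r}")
        if self.method == "binarize" and self.binarize_threshold != "otsu":
            t = self.binarize_threshold
            if not (isinstance(t, (int, float)) and 0.0 < t < 1.0):
                raise ParameterError(
                    f"binarize_threshold must be in (0, 1) or 'otsu', got {t!r}")
        if self.target_side_px < 8:
            raise ParameterError(
                f"target_side_px must be >= 8, got {self.target_side_px}")


def resize_to_input(img: ColonyImage, side: int) -> ColonyImage:
    """Resize to ``side x side`` with area interpolation.

    The source aspect ratio is not preserved (the network input is square);
    µm/px is rescaled independently per axis, so the physical field of view
    is unchanged.
    """
    if side < 8:
        raise ParameterError(f"side must be >= 8, got {side}")
    px = np.asarray(img.pixels, dtype=np.float64)
    if px.size == 0:
        raise ValidationError("cannot resize an empty image")
    h, w = px.shape[:2]
    if (h, w) == (side, side):
        return img
    if px.ndim == 2:
        out = resize_local_mean(px, (side, side))
    else:
        out = resize_local_mean(px, (side, side, px.shape[2]))
    lo = 0.0
    hi = 1.0 if img.intensity_range == "float01" else 255.0
    out = np.clip(out, lo, hi)
    um_y = img.um_per_px[0] * (h / side)
    um_x = img.um_per_px[1] * (w / side)
    return img.with_pixels(out, um_per_px=(um_y, um_x))


def to_gray(img: ColonyImage) -> ColonyImage:
    """Luma grayscale conversion, Y = 0.299 R + 0.587 G + 0.114 B.

    Grayscale inputs pass through unchanged; the result stays float through
    the pipeline (rounded only on export).
    """
    if img.n_channels == 1:
        return img
    if img.n_channels != 3:
        raise ValidationError(
            f"to_gray expects 1 or 3 channels, got {img.n_channels}")
    px = np.asarray(img.pixels, dtype=np.float64)
    return img.with_pixels(px @ _LUMA)


def minmax_normalize(img: ColonyImage) -> ColonyImage:
    """Min–max scaling to [0, 1]; a constant image maps to all zeros."""
    px = np.asarray(img.pixels, dtype=np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    return img.with_pixels(out, intensity_range="float01")


def binarize(img: ColonyImage, threshold: float | str = "otsu") -> ColonyImage:
    """Threshold to {0, 1} on the normalized scale; pixel >= threshold -> 1.

    ``threshold`` is a float in (0, 1) applied after min–max normalization,
    or ``"otsu"`` for the parameter-free Otsu threshold.
    """
    norm = minmax_normalize(img)
    px = norm.pixels
    if threshold == "otsu":
        t = float(threshold_otsu(px)) if px.min() != px.max() else 0.5
    else:
        if not (isinstance(threshold, (int, float)) and 0.0 < threshold < 1.0):
            raise ParameterError(
                f"threshold must be in (0, 1) or 'otsu', got {threshold!r}")
        t = float(threshold)
    return img.with_pixels((px >= t).astype(np.float64), intensity_range="float01")


def equalize_histogram(img: ColonyImage) -> ColonyImage:
    """Global CDF histogram equalization on 256 bins, output in [0, 1].

    The remap is monotone (pixel order is preserved) and stretches the
    intensity histogram toward uniform over the unit interval.  Multi-channel
    images are equalized per channel.
    """
    px = np.asarray(img.pixels, dtype=np.float64)
    if px.ndim == 2:
        out = equalize_hist(px, nbins=256)
    else:
        out = np.stack([equalize_hist(px[..., c], nbins=256)
                        for c in range(px.shape[2])], axis=-1)
    return img.with_pixels(out, intensity_range="float01")


def apply_preprocess(img: ColonyImage, spec: PreprocessSpec,
                     resize: bool = True) -> ColonyImage:
    """Resize to the input side, then apply the configured operator."""
    out = resize_to_input(img, spec.target_side_px) if resize else img
    if spec.method == "none":
        return out
    if spec.method == "gray":
        return to_gray(out)
    if spec.method == "normalize":
        return minmax_normalize(out)
    if spec.method == "binarize":
        return binarize(out, spec.binarize_threshold)
    if spec.method == "equalize":
        return equalize_histogram(to_gray(out) if out.n_channels == 3 else out)
    raise ParameterError(f"unknown method {spec.method!r}")


def to_model_array(img: ColonyImage) -> np.ndarray:
    """Single-channel float [0, 1] array ``(1, H, W)`` for network ingestion."""
    out = to_gray(img) if img.n_channels == 3 else img
    px = np.asarray(out.pixels, dtype=np.float64)
    if out.intensity_range == "uint8":
        px = px / 255.0
    px = np.clip(px, 0.0, 1.0)
    return px[None, :, :]
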