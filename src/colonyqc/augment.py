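"""Training-time augmentations: random cropping and the dihedral group of the square.

The dihedral family is the 8 symmetries of a square — rotations by multiples
of 90° plus horizontal/vertical flips and the two transpositions — all of
which preserve the pixel multiset exactly and never change a phenotype
label.  Random cropping keeps a fixed linear fraction of the side at a
uniformly random offset and resizes back to the model input side.

Augmentation is applied online, per epoch, to training items only;
validation images are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, ValidationError
from .image import ColonyImage
from .preprocess import resize_to_input

__all__ = ["AugmentSpec", "random_crop", "random_dihedral", "dihedral",
           "compose", "ComposedAugment", "random_crop_array",
           "random_dihedral_array"]


@dataclass(frozen=True)
class AugmentSpec:
    """Which augmentations to apply and with what randomness."""

    use_crop: bool = False
    crop_fraction: float = 0.875     # linear fraction of the side retained
    use_rotation: bool = False       # the full 8-element dihedral family
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ParameterError(
                f"crop_fraction must be in (0, 1], got {self.crop_fraction}")

    @property
    def enabled(self) -> bool:
        return self.use_crop or self.use_rotation


def random_crop_array(px: np.ndarray, crop_fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Crop a random window of the given linear fraction; offsets uniform."""
    if not 0.0 < crop_fraction <= 1.0:
        raise ParameterError(
            f"crop_fraction must be in (0, 1], got {crop_fraction}")
    if crop_fraction == 1.0:
        return px
    h, w = px.shape[:2]
    ch = max(1, int(round(crop_fraction * h)))
    cw = max(1, int(round(crop_fraction * w)))
    oy = int(rng.integers(0, h - ch + 1))
    ox = int(rng.integers(0, w - cw + 1))
    return px[oy:oy + ch, ox:ox + cw]


def random_crop(img: ColonyImage, crop_fraction: float,
                rng: np.random.Generator) -> ColonyImage:
    """Random crop, resized back to the original side.

    The physical field of view shrinks by ``crop_fraction`` while the pixel
    grid is restored, so µm/px bookkeeping shrinks accordingly.
    """
    if crop_fraction == 1.0:
        return img
    h, w = img.pixels.shape[:2]
    window = random_crop_array(np.asarray(img.pixels), crop_fraction, rng)
    cropped = img.with_pixels(window)
    if window.shape[0] == window.shape[1] == h == w:
        return cropped
    # resize back to the model input side (square inputs in this pipeline)
    return resize_to_input(cropped, h) if h == w else cropped


def dihedral(px: np.ndarray, element: int) -> np.ndarray:
    """Apply dihedral element ``k`` in 0..7: rot90^k for k<4, then flipped rotations."""
    if not 0 <= element < 8:
        raise ParameterError(f"dihedral element must be in 0..7, got {element}")
    if element < 4:
        return np.rot90(px, k=element)
    return np.rot90(px[:, ::-1], k=element - 4)


def random_dihedral_array(px: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if px.shape[0] != px.shape[1]:
        raise ValidationError(
            f"dihedral transforms require a square image, got {px.shape[:2]}")
    return dihedral(px, int(rng.integers(0, 8)))


def random_dihedral(img: ColonyImage, rng: np.random.Generator) -> ColonyImage:
    """One of the 8 square symmetries chosen uniformly; pixel multiset preserved."""
    return img.with_pixels(random_dihedral_array(np.asarray(img.pixels), rng))


class ComposedAugment:
    """Crop-then-dihedral transform sharing one seeded random stream.

    With both augmentations disabled this is the identity.  A fresh instance
    (or :meth:`reset`) restores the stream, making augmented epochs
    reproducible end to end.
    """

    def __init__(self, spec: AugmentSpec):
        self.spec = spec
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng(
            np.random.SeedSequence((int(self.spec.seed), 0xA06)))

    def __call__(self, img: ColonyImage) -> ColonyImage:
        out = img
        if self.spec.use_crop:
            out = random_crop(out, self.spec.crop_fraction, self._rng)
        if self.spec.use_rotation:
            out = random_dihedral(out, self._rng)
        return out

    def apply_array(self, px: np.ndarray) -> np.ndarray:
        """Same transform on a bare 2-D array (training-loop fast path)."""
        out = px
        if self.spec.use_crop and self.spec.crop_fraction < 1.0:
            side = out.shape[0]
            window = random_crop_array(out, self.spec.crop_fraction, self._rng)
            if window.shape != out.shape:
                from skimage.transform import resize_local_mean
                out = resize_local_mean(window, (side, side))
        if self.spec.use_rotation:
            out = random_dihedral_array(out, self._rng)
        return out


def compose(spec: AugmentSpec) -> ComposedAugment:
    """Build the configured crop→dihedral transform (identity if both off)."""
    return ComposedAugment(spec)
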