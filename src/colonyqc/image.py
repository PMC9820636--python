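"""Core containers: a single colony image and a labelled image collection.

A :class:`ColonyImage` couples a pixel array with the physical pixel size
(µm/px, per axis, so anisotropic resizes keep honest bookkeeping), a declared
intensity range and an optional phenotype label.  ``good`` denotes the
morphology associated with maintained pluripotency (flat colony, well-defined
smooth edge, tightly packed cells); ``bad`` the morphology associated with
spontaneous differentiation (loose packing, phase-bright inter-cell gaps,
elongated cells, spiky edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = ["ColonyImage", "LabeledDataset", "GOOD", "BAD", "UNLABELED"]

GOOD = "good"
BAD = "bad"
UNLABELED = "unlabeled"

Label = Literal["good", "bad", "unlabeled"]

#: declared intensity ranges -> (lo, hi)
_RANGES = {"float01": (0.0, 1.0), "uint8": (0, 255)}


@dataclass(frozen=True)
class ColonyImage:
    """One colony image with physical-scale metadata.

    Parameters
    ----------
    pixels
        ``(H, W)`` or ``(H, W, C)`` array, ``C`` in {1, 3}.
    um_per_px
        Physical pixel size as ``(um_y, um_x)``; a scalar is broadcast.
    label
        ``"good"``, ``"bad"`` or ``"unlabeled"``.
    intensity_range
        ``"float01"`` (values in [0, 1]) or ``"uint8"`` (values in [0, 255]).
    source_id
        Provenance string, e.g. ``"synth-good-0007"`` or a file path.
    """

    pixels: np.ndarray
    um_per_px: tuple[float, float] = (1.0, 1.0)
    label: Label = UNLABELED
    intensity_range: str = "float01"
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if px.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got shape {px.shape}")
        if px.ndim == 3 and px.shape[2] not in (1, 3):
            raise ValueError(f"channel count must be 1 or 3, got {px.shape[2]}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have H, W >= 1")
        if self.label not in (GOOD, BAD, UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")
        if self.intensity_range not in _RANGES:
            raise ValueError(f"unknown intensity_range {self.intensity_range!r}")
        lo, hi = _RANGES[self.intensity_range]
        if px.size and (px.min() < lo - 1e-9 or px.max() > hi + 1e-9):
            raise ValueError(
                f"pixel values [{px.min():g}, {px.max():g}] outside declared "
                f"range {self.intensity_range!r}"
            )
        um = self.um_per_px
        if np.isscalar(um):
            um = (float(um), float(um))
        um = (float(um[0]), float(um[1]))
        if um[0] <= 0 or um[1] <= 0:
            raise ValueError("um_per_px must be positive")
        object.__setattr__(self, "um_per_px", um)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical field of view ``(height_um, width_um)``."""
        return (self.height * self.um_per_px[0], self.width * self.um_per_px[1])

    def with_pixels(self, pixels: np.ndarray, **changes) -> "ColonyImage":
        """Copy of this image with new pixels (and optional metadata changes)."""
        return replace(self, pixels=pixels, **changes)

    def as_float01(self) -> np.ndarray:
        """Pixel array scaled to [0, 1] floats regardless of declared range."""
        px = np.asarray(self.pixels, dtype=np.float64)
        if self.intensity_range == "uint8":
            px = px / 255.0
        return px


@dataclass
class LabeledDataset:
    """Ordered collection of :class:`ColonyImage` with class bookkeeping."""

    items: list[ColonyImage] = field(default_factory=list)
    manifest_path: str | None = None

    @property
    def n_good(self) -> int:
        return sum(1 for im in self.items if im.label == GOOD)

    @property
    def n_bad(self) -> int:
        return sum(1 for im in self.items if im.label == BAD)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ColonyImage]:
        return iter(self.items)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return LabeledDataset(items=self.items[i])
        return self.items[i]

    def labels(self) -> list[str]:
        return [im.label for im in self.items]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(items=[self.items[i] for i in indices])

    def good_fraction(self) -> float:
        n = self.n_good + self.n_bad
        if n == 0:
            raise ValueError("dataset has no labeled items")
        return self.n_good / n
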