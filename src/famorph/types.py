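"""Core calibrated-image containers shared by every pipeline stage.

A micrograph is carried through the pipeline together with its spatial
calibration (micrometres per pixel side) so that every size filter and
every reported feature can live in physical units while the image
processing itself runs in pixel space.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class Channel(str, Enum):
    """Fluorescence channel identity of a single-plane micrograph."""

    ACTIN = "actin"
    NUCLEUS = "nucleus"
    FA = "fa"


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D grayscale intensity image with physical pixel calibration.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite, non-negative intensities (any dtype; the
        pipeline rescales to [0, 1] before thresholding).
    pixel_size_um : float
        Side length of one pixel in micrometres; strictly positive.
    channel : Channel, optional
        Which stain the image carries (actin / nucleus / fa).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: Channel | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(
                f"expected a 2-D image with >=2 rows and columns, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if np.any(px < 0):
            raise ValueError("image intensities must be non-negative")
        if not (self.pixel_size_um > 0 and np.isfinite(self.pixel_size_um)):
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Return a copy carrying new pixel data, same calibration/channel."""
        return CalibratedImage(pixels, self.pixel_size_um, self.channel)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean foreground mask with the calibration of its source image."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            raise ValueError(f"mask must be boolean, got dtype {px.dtype}")
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LabelMap:
    """Integer object labels: 0 = background, k > 0 = object k.

    After compaction the label set is contiguous {1..K}; each positive
    label forms one 8-connected component.
    """

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"label map must be 2-D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError(f"label map must be integer, got dtype {lab.dtype}")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the map."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)

    def with_labels(self, labels: np.ndarray) -> "LabelMap":
        return LabelMap(labels, self.pixel_size_um)


def compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel positive ids to 1..K preserving ascending order."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros_like(labels)
    lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    lut[ids] = np.arange(1, ids.size + 1, dtype=labels.dtype)
    return lut[labels]
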