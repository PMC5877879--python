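"""Shared low-level image operators.

All stages of the pipeline are built from six primitives: affine contrast
rescaling, white top-hat with a flat disk, median-background subtraction,
Otsu binarization, hole filling, and box closing. Conventions that the
literature leaves open are fixed here and documented per function.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .types import BinaryMask, CalibratedImage

__all__ = [
    "rescale_unit_range",
    "white_tophat",
    "median_background_subtract",
    "otsu_threshold",
    "otsu_binarize",
    "fill_holes",
    "morph_close",
    "disk_offsets",
]


def rescale_unit_range(img: CalibratedImage) -> CalibratedImage:
    """Affinely map intensities onto [0, 1]: x -> (x - min) / (max - min).

    A constant image (max == min) maps to all zeros.
    """
    px = np.asarray(img.pixels, dtype=np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return img.with_pixels(np.zeros_like(px))
    return img.with_pixels((px - lo) / (hi - lo))


def disk_offsets(diameter_px: int) -> np.ndarray:
    """Boolean footprint of the flat disk {(dy,dx) : dy^2+dx^2 <= (d/2)^2}."""
    if diameter_px < 1:
        raise ValueError("disk diameter must be >= 1 px")
    r = diameter_px / 2.0
    rmax = int(np.floor(r))
    dy, dx = np.mgrid[-rmax : rmax + 1, -rmax : rmax + 1]
    return (dy * dy + dx * dx) <= r * r


def _disk_row_halfwidths(diameter_px: int) -> list[tuple[int, int]]:
    """Decompose the disk into horizontal runs: (dy, half-width rx)."""
    r = diameter_px / 2.0
    rmax = int(np.floor(r))
    return [
        (dy, int(np.floor(np.sqrt(r * r - dy * dy))))
        for dy in range(-rmax, rmax + 1)
    ]


def _disk_min_or_max(px: np.ndarray, diameter_px: int, *, erode: bool) -> np.ndarray:
    """Flat disk erosion (min) or dilation (max), exact, via 1-D row filters.

    The disk is a union of horizontal segments, so min/max over the disk
    equals the row-wise min/max over each segment combined across row
    offsets. Out-of-frame pixels count as +inf for erosion and -inf for
    dilation (callers pad first to impose a boundary convention).
    """
    rows = _disk_row_halfwidths(diameter_px)
    pad = np.inf if erode else -np.inf
    filt = ndi.minimum_filter1d if erode else ndi.maximum_filter1d
    comb = np.minimum if erode else np.maximum
    h = px.shape[0]
    out = np.full(px.shape, pad, dtype=np.float64)
    for dy, rx in rows:
        f = filt(px, size=2 * rx + 1, axis=1, mode="constant", cval=pad)
        if dy >= 0:
            out[: h - dy] = comb(out[: h - dy], f[dy:])
        else:
            out[-dy:] = comb(out[-dy:], f[: h + dy])
    return out


def white_tophat(img: CalibratedImage, disk_diameter_px: int) -> CalibratedImage:
    """Image minus its morphological opening with a flat disk.

    Keeps objects that are brighter than their surroundings and too
    small to contain the disk; slowly varying background (uneven
    illumination, diffuse cytosolic stain) is removed. Output is
    everywhere >= 0 and <= input.

    The world outside the frame counts as darkest-observed background
    (the image minimum), so a bright object clipped by the frame is
    preserved in full rather than partially flattened — border objects
    must survive intact for the border-exclusion rule to remove them
    as whole objects downstream.
    """
    if disk_diameter_px < 1:
        raise ValueError("disk diameter must be >= 1 px")
    px = np.asarray(img.pixels, dtype=np.float64)
    rmax = int(np.floor(disk_diameter_px / 2.0))
    span = 2 * rmax + 1
    if span > px.shape[0] or span > px.shape[1]:
        raise ValueError(
            f"structuring element ({span} px across) larger than image {px.shape}"
        )
    # pad by the full element so the opening inside the frame is exact
    # under the outside-equals-background convention
    big = np.pad(px, 2 * rmax, mode="constant", constant_values=px.min())
    opened = _disk_min_or_max(
        _disk_min_or_max(big, disk_diameter_px, erode=True),
        disk_diameter_px,
        erode=False,
    )
    if rmax > 0:
        opened = opened[2 * rmax : -2 * rmax, 2 * rmax : -2 * rmax]
    return img.with_pixels(px - opened)


def median_kernel_px(kernel_um: float, pixel_size_um: float) -> int:
    """Convert a physical window side to the nearest odd pixel count >= 3."""
    k = kernel_um / pixel_size_um
    if k < 1:
        raise ValueError(
            f"median kernel {kernel_um} um is below one pixel at {pixel_size_um} um/px"
        )
    m = int(np.floor((k - 1) / 2 + 0.5))  # nearest odd, ties toward larger
    return max(2 * m + 1, 3)


def median_background_subtract(img: CalibratedImage, kernel_um: float) -> CalibratedImage:
    """Subtract the local median background; negatives clamp to zero.

    The window side is chosen as the pixel width of the largest objects
    of interest, so compact bright structures do not dominate their own
    background estimate. Reflect boundary handling.
    """
    w = median_kernel_px(kernel_um, img.pixel_size_um)
    px = np.asarray(img.pixels, dtype=np.float64)
    background = ndi.median_filter(px, size=w, mode="reflect")
    return img.with_pixels(np.maximum(px - background, 0.0))


def otsu_threshold(img: CalibratedImage) -> tuple[float, int]:
    """Otsu threshold of the unit-rescaled image over a 256-bin histogram.

    Returns ``(t_star, bin_index)`` where ``t_star`` is the upper edge of
    the chosen bin: the split after bin k maximises the between-class
    variance  w0*w1*(mu0-mu1)^2; ties resolve to the lowest bin.
    Foreground is defined strictly as intensity > t_star.
    """
    px = np.asarray(rescale_unit_range(img).pixels)
    if np.unique(px).size < 2:
        raise ValueError("cannot threshold a constant image")
    hist, edges = np.histogram(px, bins=256, range=(0.0, 1.0))
    hist = hist.astype(np.float64)
    w0 = np.cumsum(hist)
    total = w0[-1]
    mu_cum = np.cumsum(hist * np.arange(256))
    w1 = total - w0
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    mu0 = np.divide(mu_cum[:-1], w0[:-1], out=np.zeros(255), where=w0[:-1] > 0)
    mu1 = np.divide(
        mu_cum[-1] - mu_cum[:-1], w1[:-1], out=np.zeros(255), where=w1[:-1] > 0
    )
    sigma_b = np.where(valid, w0[:-1] * w1[:-1] * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1]), k


def otsu_binarize(img: CalibratedImage) -> BinaryMask:
    """Binarize by Otsu's method: foreground = rescaled intensity > t*."""
    t_star, _ = otsu_threshold(img)
    px = np.asarray(rescale_unit_range(img).pixels)
    return BinaryMask(px > t_star, img.pixel_size_um)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background regions not 4-connected to the image border."""
    filled = ndi.binary_fill_holes(mask.pixels)
    return BinaryMask(filled, mask.pixel_size_um)


def morph_close(mask: BinaryMask, r: int = 1) -> BinaryMask:
    """Binary closing with a (2r+1) x (2r+1) box: dilation then erosion.

    Bridges gaps narrower than the box and smooths small concavities;
    idempotent by construction.
    """
    if r < 1:
        raise ValueError("closing radius must be >= 1")
    footprint = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    closed = morphology.closing(mask.pixels, footprint)
    return BinaryMask(closed.astype(bool), mask.pixel_size_um)
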