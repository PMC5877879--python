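"""Per-object morphological features and adhesion maturation classes.

All features are computed from the labelled pixel sets and reported in
physical units. Shape descriptors come from the moment-equivalent
ellipse: the unique ellipse with the same second central moments as the
pixel set. Conventions:

* coordinates are (x, y) = (column, row) pixel centers;
* orientation is the major-axis angle against the image x-axis,
  counter-clockwise toward +y, reported in [0, 180) degrees;
* ``length_um`` / ``width_um`` are the moment-ellipse major/minor axis
  lengths (4 sqrt(eigenvalue)); the Feret diameter — the maximum
  caliper, i.e. the largest distance between any two pixel centers —
  is reported separately;
* perimeter uses the weighted-step boundary estimate (exact on
  axis-aligned edges, sqrt(2)-weighted on diagonal steps), with an
  isolated pixel counted as 4 pixel sides by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as skmeasure

from .config import PipelineConfig
from .types import LabelMap

#: Sentinel aspect ratio for degenerate (collinear) regions.
ASPECT_RATIO_CAP = 1e3

FEATURE_COLUMNS = [
    "label",
    "type",
    "area_um2",
    "perimeter_um",
    "orientation_deg",
    "aspect_ratio",
    "length_um",
    "width_um",
    "feret_um",
    "centroid_x_um",
    "centroid_y_um",
    "maturation",
    "dist_to_nucleus_um",
    "source_image",
]


class Maturation(str, Enum):
    NASCENT = "nascent"
    MATURE = "mature"
    SUPERMATURE = "supermature"


@dataclass(frozen=True)
class RegionRecord:
    """Morphometric feature vector of one segmented object."""

    label: int
    type: str
    area_um2: float
    perimeter_um: float
    orientation_deg: float
    aspect_ratio: float
    length_um: float
    width_um: float
    feret_um: float
    centroid_x_um: float
    centroid_y_um: float
    source_image: str = ""

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "type": self.type,
            "area_um2": self.area_um2,
            "perimeter_um": self.perimeter_um,
            "orientation_deg": self.orientation_deg,
            "aspect_ratio": self.aspect_ratio,
            "length_um": self.length_um,
            "width_um": self.width_um,
            "feret_um": self.feret_um,
            "centroid_x_um": self.centroid_x_um,
            "centroid_y_um": self.centroid_y_um,
            "maturation": "",
            "dist_to_nucleus_um": float("nan"),
            "source_image": self.source_image,
        }


@dataclass(frozen=True)
class FAMeasurement(RegionRecord):
    """RegionRecord extended with maturation class and nucleus distance."""

    maturation: Maturation = Maturation.NASCENT
    dist_to_nucleus_um: float = float("nan")

    def as_row(self) -> dict:
        row = super().as_row()
        row["maturation"] = self.maturation.value
        row["dist_to_nucleus_um"] = self.dist_to_nucleus_um
        return row


def fit_ellipse(coords_xy: np.ndarray) -> tuple[float, float, float, float]:
    """Moment-equivalent ellipse of a pixel set.

    Parameters
    ----------
    coords_xy : (N, 2) array
        Pixel-center coordinates (x, y) in *pixel* units.

    Returns
    -------
    (orientation_deg, aspect_ratio, major_px, minor_px)
        Orientation of the major axis in [0, 180) degrees; axis lengths
        are 4 sqrt(eigenvalue) of the coordinate covariance, which for a
        solid ellipse equals its full axis length. Collinear sets get a
        capped aspect ratio and an orientation from the point spread; a
        perfectly isotropic set (e.g. a disk) reports orientation 0.
    """
    pts = np.asarray(coords_xy, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("expected an (N, 2) array of coordinates")
    if pts.shape[0] == 1:
        return 0.0, 1.0, 0.0, 0.0
    c = pts - pts.mean(axis=0)
    cxx = np.mean(c[:, 0] ** 2)
    cyy = np.mean(c[:, 1] ** 2)
    cxy = np.mean(c[:, 0] * c[:, 1])
    common = 0.5 * (cxx + cyy)
    diff = 0.5 * math.hypot(cxx - cyy, 2 * cxy)
    lam1 = common + diff
    lam2 = max(common - diff, 0.0)
    theta = 0.5 * math.atan2(2 * cxy, cxx - cyy)
    orientation = math.degrees(theta) % 180.0
    major = 4.0 * math.sqrt(lam1)
    minor = 4.0 * math.sqrt(lam2)
    if lam1 <= 0:  # all points coincident
        return 0.0, 1.0, 0.0, 0.0
    if lam2 / lam1 < 1e-12:  # collinear
        return orientation, ASPECT_RATIO_CAP, major, minor
    return orientation, math.sqrt(lam1 / lam2), major, minor


def feret_length(coords_xy: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Maximum caliper: largest distance between any two pixel centers.

    A single-pixel region has Feret length 0 by convention. The maximum
    pair always lies on the convex hull, which keeps this exact and fast
    for large regions.
    """
    pts = np.unique(np.asarray(coords_xy, dtype=np.float64), axis=0)
    if pts.shape[0] < 2:
        return 0.0
    if pts.shape[0] > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) — brute-force the small set
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max())) * pixel_size_um


def perimeter(region_mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Boundary length of a region mask in physical units.

    Weighted-step estimate (4-connected boundary steps count 1, diagonal
    corner configurations sqrt(2)/... per the standard weighting); an
    isolated pixel counts its 4 sides.
    """
    mask = np.asarray(region_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        return 0.0
    if n == 1:
        return 4.0 * pixel_size_um
    return float(skmeasure.perimeter(mask, neighborhood=4)) * pixel_size_um


def fa_nucleus_distance(
    fa_centroid_um: tuple[float, float], nucleus_centroid_um: tuple[float, float]
) -> float:
    """Euclidean distance between two centroids given in micrometres."""
    fx, fy = fa_centroid_um
    nx, ny = nucleus_centroid_um
    if not all(map(math.isfinite, (fx, fy, nx, ny))):
        raise ValueError("centroids must be finite")
    return math.hypot(fx - nx, fy - ny)


def classify_maturation(
    length_um: float, bins_um: tuple[float, ...] = (2.0, 6.0)
) -> Maturation:
    """Maturation stage from adhesion length: nascent < 2, mature < 6,
    supermature >= 6 um (left-closed bins; breakpoints configurable)."""
    if length_um < 0:
        raise ValueError("length must be >= 0")
    lo, hi = bins_um[0], bins_um[-1]
    if length_um < lo:
        return Maturation.NASCENT
    if length_um < hi:
        return Maturation.MATURE
    return Maturation.SUPERMATURE


def measure_all(
    lab: LabelMap,
    cfg: PipelineConfig | None = None,
    kind: str = "cell",
    nucleus_centroid_um: tuple[float, float] | None = None,
    source_image: str = "",
) -> list[RegionRecord]:
    """Feature vector for every label, in ascending label order.

    ``kind`` tags the record type ("cell" / "nucleus" / "fa"); focal
    adhesion records additionally carry the maturation class and — when
    a parent-nucleus centroid is supplied (single-cell analysis) — the
    centroid-to-centroid distance.
    """
    cfg = cfg or PipelineConfig()
    px = lab.pixel_size_um
    labels = lab.labels
    records: list[RegionRecord] = []
    slices = ndi.find_objects(labels)
    for lbl in lab.ids:
        sl = slices[lbl - 1]
        sub = labels[sl] == lbl
        rows, cols = np.nonzero(sub)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        coords = np.column_stack([cols, rows]).astype(np.float64)  # (x, y)
        orientation, aspect, major_px, minor_px = fit_ellipse(coords)
        centroid = coords.mean(axis=0) * px
        common = dict(
            label=int(lbl),
            type=kind,
            area_um2=float(coords.shape[0]) * px * px,
            perimeter_um=perimeter(sub, px),
            orientation_deg=orientation,
            aspect_ratio=aspect,
            length_um=major_px * px,
            width_um=minor_px * px,
            feret_um=feret_length(coords, px),
            centroid_x_um=float(centroid[0]),
            centroid_y_um=float(centroid[1]),
            source_image=source_image,
        )
        if kind == "fa":
            maturation = classify_maturation(common["length_um"], cfg.maturation_bins_um)
            dist = (
                fa_nucleus_distance(
                    (common["centroid_x_um"], common["centroid_y_um"]),
                    nucleus_centroid_um,
                )
                if nucleus_centroid_um is not None
                else float("nan")
            )
            records.append(
                FAMeasurement(maturation=maturation, dist_to_nucleus_um=dist, **common)
            )
        else:
            records.append(RegionRecord(**common))
    return records
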