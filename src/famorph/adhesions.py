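"""Focal adhesion detection from the vinculin channel.

Soluble vinculin in the cytosol produces a strong diffuse background on
top of which the adhesions sit as small bright puncta. A two-step filter
— white top-hat with an 80-px disk, then subtraction of the local median
background (window = width of the largest adhesions) — suppresses the
cytosolic signal; Otsu thresholding and 8-connected component labelling
then index individual adhesions. Objects below the minimum area are
noise, objects longer than the Feret cap are non-adhesion staining
artifacts; an optional polygonal ROI restricts analysis to one traced
cell. Adhesions that merge into a single thresholded component are not
split further.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage as ndi
from skimage import measure as skmeasure

from .config import PipelineConfig
from .io import log_stage
from .morphometrics import feret_length
from .preprocessing import (
    median_background_subtract,
    otsu_binarize,
    rescale_unit_range,
    white_tophat,
)
from .types import CalibratedImage, LabelMap, compact_labels

logger = logging.getLogger("famorph")


@dataclass(frozen=True)
class PolygonROI:
    """A simple (non-self-intersecting) polygon in pixel coordinates."""

    vertices: np.ndarray  # (N, 2) array of (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("ROI needs >= 3 (x, y) vertices")
        poly = shapely.Polygon(v)
        if poly.area == 0 or not poly.is_valid:
            raise ValueError("ROI polygon must be simple and non-degenerate")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    @classmethod
    def from_file(cls, path: str | Path) -> "PolygonROI":
        """Load vertices from JSON ({"vertices": [[x, y], ...]}) or a
        two-column x,y CSV."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
            verts = data["vertices"] if isinstance(data, dict) else data
        else:
            verts = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(np.asarray(verts, dtype=np.float64))


def fa_enhance(vinc: CalibratedImage, cfg: PipelineConfig | None = None) -> CalibratedImage:
    """Two-step background suppression of the vinculin channel.

    Contrast rescale to [0, 1], white top-hat (removes structures larger
    than the disk, i.e. the diffuse cytosolic pool and uneven
    illumination), then subtraction of the median-filtered residual
    background. Output stays within [0, 1] and never exceeds the
    rescaled input.
    """
    cfg = cfg or PipelineConfig()
    out = white_tophat(rescale_unit_range(vinc), cfg.fa_tophat_disk_diameter_px)
    return median_background_subtract(out, cfg.fa_median_kernel_um)


def fa_label(enhanced: CalibratedImage) -> LabelMap:
    """Otsu-binarize the enhanced image and index 8-connected components."""
    mask = otsu_binarize(enhanced)
    labels = skmeasure.label(mask.pixels, connectivity=2)
    if labels.max() == 0:
        logger.warning("no foreground after thresholding: empty adhesion map")
    return LabelMap(labels.astype(np.int32), enhanced.pixel_size_um)


def fa_filter(lab: LabelMap, cfg: PipelineConfig | None = None) -> LabelMap:
    """Apply the adhesion exclusion rules; compact the survivors.

    Removes labels with area strictly below ``min_fa_area_um2`` (noise)
    or Feret length strictly above ``max_fa_length_um`` (elongated
    staining artifacts). Objects exactly on a bound are kept.
    """
    cfg = cfg or PipelineConfig()
    labels = lab.labels
    if labels.max() == 0:
        return lab.with_labels(labels.copy())
    px = lab.pixel_size_um
    counts = np.bincount(labels.ravel())
    n0 = lab.n_objects
    keep = counts.astype(np.float64) * px * px >= cfg.min_fa_area_um2
    keep[0] = False
    slices = ndi.find_objects(labels)
    max_len_px = cfg.max_fa_length_um / px
    for lbl in np.flatnonzero(keep):
        sl = slices[lbl - 1]
        # the Feret length never exceeds the bounding-box diagonal, so
        # most objects need no pairwise-distance computation at all
        h_box = sl[0].stop - sl[0].start - 1
        w_box = sl[1].stop - sl[1].start - 1
        if np.hypot(h_box, w_box) <= max_len_px:
            continue
        rows, cols = np.nonzero(labels[sl] == lbl)
        coords = np.column_stack([cols, rows])
        if feret_length(coords, px) > cfg.max_fa_length_um:
            keep[lbl] = False
    result = lab.with_labels(compact_labels(np.where(keep[labels], labels, 0)))
    log_stage(
        f"FA exclusions (area<{cfg.min_fa_area_um2} um^2 or "
        f"Feret>{cfg.max_fa_length_um} um)",
        n0,
        result.n_objects,
    )
    return result


def restrict_to_roi(lab: LabelMap, roi: PolygonROI) -> LabelMap:
    """Keep labels whose centroid lies in the polygon (boundary inclusive).

    Membership is decided by the object centroid, which is unambiguous
    for adhesions straddling the traced cell edge; each exclusion is
    logged.
    """
    labels = lab.labels
    if labels.max() == 0:
        return lab.with_labels(labels.copy())
    poly = roi.polygon
    ids = lab.ids
    centroids = ndi.center_of_mass(np.ones_like(labels), labels, ids)  # (row, col)
    keep = np.zeros(int(labels.max()) + 1, dtype=bool)
    for lbl, (cy, cx) in zip(ids, centroids):
        if poly.covers(shapely.Point(cx, cy)):
            keep[lbl] = True
        else:
            logger.info("FA %d centroid (%.1f, %.1f) outside ROI: removed", lbl, cx, cy)
    return lab.with_labels(compact_labels(np.where(keep[labels], labels, 0)))


def segment_fas(
    vinc: CalibratedImage,
    cfg: PipelineConfig | None = None,
    roi: PolygonROI | None = None,
) -> LabelMap:
    """Full adhesion pipeline: enhance, threshold+label, filter, ROI."""
    cfg = cfg or PipelineConfig()
    lab = fa_filter(fa_label(fa_enhance(vinc, cfg)), cfg)
    if roi is not None:
        n0 = lab.n_objects
        lab = restrict_to_roi(lab, roi)
        log_stage("ROI restriction", n0, lab.n_objects)
    return lab
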