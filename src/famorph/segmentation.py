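"""Single-cell and nucleus segmentation by marker-controlled watershed.

The actin and nucleus channels are segmented independently with the same
recipe — contrast rescale, top-hat, Otsu, hole filling, box closing,
then a watershed seeded by h-maxima of the Euclidean distance transform —
followed by border-object removal, a minimum-area criterion, and pairing
of each surviving nucleus with the cell that contains it.

Conventions: 8-connectivity for foreground components and regional
maxima, 4-connectivity for background (hole definition); the image frame
counts as background for the distance transform; watershed ridge pixels
are assigned to a region (no watershed lines) so regions partition the
foreground exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation as skseg

from .config import PipelineConfig
from .io import log_stage
from .preprocessing import (
    fill_holes,
    morph_close,
    otsu_binarize,
    rescale_unit_range,
    white_tophat,
)
from .types import BinaryMask, CalibratedImage, LabelMap, compact_labels

_FOOTPRINT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CellNucleusPairing:
    """Assignment of segmented nuclei to segmented cells.

    ``pairs`` maps every cell label to its nucleus label, or ``None``
    when the cell has no unambiguous nucleus (zero nuclei, or more than
    one — such cells stay in the table with nucleus-dependent features
    missing). ``orphan_nuclei`` lists nuclei assigned to no cell.
    """

    pairs: dict[int, int | None] = field(default_factory=dict)
    orphan_nuclei: frozenset[int] = field(default_factory=frozenset)

    @property
    def nucleus_to_cell(self) -> dict[int, int]:
        return {n: c for c, n in self.pairs.items() if n is not None}


def distance_map(mask: BinaryMask) -> CalibratedImage:
    """Euclidean distance (px) from each foreground pixel to background.

    The image frame counts as background, so objects touching the border
    get finite distances (they are removed later anyway).
    """
    if not mask.pixels.any():
        raise ValueError("distance transform of an empty mask is undefined")
    padded = np.pad(mask.pixels, 1, mode="constant", constant_values=False)
    dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    return CalibratedImage(dist, mask.pixel_size_um)


def extract_markers(dist: CalibratedImage, h: float) -> LabelMap:
    """Watershed seeds: regional maxima of the distance map after
    h-maxima suppression.

    Maxima whose prominence above their surroundings is below ``h`` are
    merged away, so ``h`` directly controls over-segmentation: the
    marker count is non-increasing in ``h``. ``h = 0`` keeps every
    regional maximum. Maxima are 8-connected plateaus; one label each.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    d = np.asarray(dist.pixels, dtype=np.float64)
    if h == 0:
        peaks = morphology.local_maxima(d, connectivity=2)
    else:
        # h-maxima transform: flood (d - h) up under d, then take the
        # regional maxima of the reconstruction. Taking the maxima of
        # the reconstruction (rather than thresholding the residue at h)
        # correctly merges equal-height peaks above a shallow saddle —
        # the typical shape of a distance-map ridge — into one plateau.
        rec = morphology.reconstruction(
            d - h, d, method="dilation", footprint=_FOOTPRINT8
        )
        peaks = morphology.local_maxima(rec, connectivity=2)
    peaks &= d > 0
    labels = measure.label(peaks, connectivity=2)
    return LabelMap(labels.astype(np.int32), dist.pixel_size_um)


def marker_watershed(mask: BinaryMask, markers: LabelMap) -> LabelMap:
    """Flood the negated distance map from the markers, one region each.

    Every marker must lie inside the mask. Foreground 8-connected to a
    marker is partitioned into exactly one connected region per marker;
    ridge pixels go to a region (ties broken by flooding order, then
    lower label), background stays 0.
    """
    if mask.shape != markers.shape:
        raise ValueError("mask and markers must share a shape")
    if np.any(markers.labels[~mask.pixels] > 0):
        raise ValueError("markers must lie inside the mask")
    dist = distance_map(mask)
    ws = skseg.watershed(
        -np.asarray(dist.pixels),
        markers=markers.labels,
        mask=mask.pixels,
        connectivity=2,
        watershed_line=False,
    )
    return LabelMap(ws.astype(np.int32), mask.pixel_size_um)


def remove_border_objects(lab: LabelMap) -> LabelMap:
    """Delete every label touching the image border; compact the rest."""
    labels = lab.labels
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    doomed = np.unique(border[border > 0])
    out = labels.copy()
    out[np.isin(out, doomed)] = 0
    return lab.with_labels(compact_labels(out))


def filter_small(lab: LabelMap, min_area_um2: float) -> LabelMap:
    """Remove labels with area strictly below ``min_area_um2``; compact.

    Area is pixel count times pixel_size_um squared; an object exactly
    at the threshold is kept (the exclusion rule reads "smaller than").
    """
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    labels = lab.labels
    if labels.max() == 0:
        return lab.with_labels(labels.copy())
    counts = np.bincount(labels.ravel())
    area = counts * lab.pixel_size_um**2
    doomed = np.flatnonzero(area < min_area_um2)
    doomed = doomed[doomed > 0]
    out = labels.copy()
    out[np.isin(out, doomed)] = 0
    return lab.with_labels(compact_labels(out))


def pair_nuclei(cells: LabelMap, nuclei: LabelMap) -> CellNucleusPairing:
    """Assign each nucleus to the cell containing most of its pixels.

    Nucleus pixels outside every cell are discarded first (mask
    multiplication); a nucleus left with no in-cell pixels is an orphan.
    Ties between cells break toward the lower cell label. A cell claimed
    by several nuclei is flagged unpaired and those nuclei are reported
    as unassigned.
    """
    if cells.shape != nuclei.shape:
        raise ValueError("cell and nucleus maps must share a shape")
    cell_ids = cells.ids
    pairs: dict[int, int | None] = {int(c): None for c in cell_ids}
    claims: dict[int, list[int]] = {}
    orphans: set[int] = set()
    for n in nuclei.ids:
        inside = cells.labels[nuclei.labels == n]
        inside = inside[inside > 0]
        if inside.size == 0:
            orphans.add(int(n))
            continue
        counts = np.bincount(inside)
        host = int(np.argmax(counts))  # argmax takes the lowest label on ties
        claims.setdefault(host, []).append(int(n))
    for cell, nucs in claims.items():
        if cell in pairs and len(nucs) == 1:
            pairs[cell] = nucs[0]
        else:
            orphans.update(nucs)
    return CellNucleusPairing(pairs=pairs, orphan_nuclei=frozenset(orphans))


def _segment_channel(
    img: CalibratedImage, tophat_diameter_px: int, cfg: PipelineConfig
) -> LabelMap:
    """One channel through the full recipe up to the size criterion."""
    enhanced = white_tophat(rescale_unit_range(img), tophat_diameter_px)
    mask = morph_close(fill_holes(otsu_binarize(enhanced)), cfg.closing_radius_px)
    if not mask.pixels.any():
        return LabelMap(np.zeros(img.shape, dtype=np.int32), img.pixel_size_um)
    dist = distance_map(mask)
    markers = extract_markers(dist, cfg.h_marker_suppression)
    if markers.n_objects == 0:
        return LabelMap(np.zeros(img.shape, dtype=np.int32), img.pixel_size_um)
    lab = marker_watershed(mask, markers)
    n0 = lab.n_objects
    lab = remove_border_objects(lab)
    log_stage("border removal", n0, lab.n_objects)
    n0 = lab.n_objects
    lab = filter_small(lab, cfg.min_cell_area_um2)
    log_stage(f"size criterion (<{cfg.min_cell_area_um2} um^2)", n0, lab.n_objects)
    return lab


def segment_cells_and_nuclei(
    actin: CalibratedImage,
    dapi: CalibratedImage,
    cfg: PipelineConfig | None = None,
) -> tuple[LabelMap, LabelMap, CellNucleusPairing]:
    """Segment single cells (actin) and nuclei (DAPI) and pair them up.

    Returns (cell labels, nucleus labels, pairing). Both channels must
    share shape and calibration.
    """
    cfg = cfg or PipelineConfig()
    if actin.shape != dapi.shape:
        raise ValueError("actin and nucleus images must share a shape")
    if actin.pixel_size_um != dapi.pixel_size_um:
        raise ValueError("actin and nucleus images must share a calibration")
    cells = _segment_channel(actin, cfg.cell_tophat_disk_diameter_px, cfg)
    nuclei = _segment_channel(dapi, cfg.nucleus_tophat_disk_diameter_px, cfg)
    pairing = pair_nuclei(cells, nuclei)
    return cells, nuclei, pairing
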