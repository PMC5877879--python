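"""Reading and writing of micrographs, label maps and feature tables.

Images come in and go out as single-plane grayscale TIFF (8- or 16-bit);
label maps are written as 16-bit TIFF so any viewer can overlay them;
feature tables are plain CSV with one row per object.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .morphometrics import FEATURE_COLUMNS, FAMeasurement, RegionRecord
from .types import CalibratedImage, Channel, LabelMap

logger = logging.getLogger("famorph")


def read_image(
    path: str | Path,
    pixel_size_um: float,
    channel: str | Channel | None = None,
) -> CalibratedImage:
    """Read a single-plane grayscale TIFF with its physical calibration.

    Intensities are returned at original bit depth, unrescaled; contrast
    normalisation happens inside the pipeline. Multi-plane or RGB input
    is rejected rather than silently collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not pixel_size_um > 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um}")
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(
            f"{path} is not a single-plane grayscale image (shape {data.shape}); "
            "extract one channel/plane first"
        )
    ch = Channel(channel) if channel is not None else None
    return CalibratedImage(data, pixel_size_um, ch)


def write_image(img: CalibratedImage, path: str | Path) -> None:
    """Write a calibrated image as TIFF, preserving dtype exactly."""
    tifffile.imwrite(Path(path), np.asarray(img.pixels))


def write_label_map(lab: LabelMap, path: str | Path) -> None:
    """Write a label map as 16-bit TIFF (lossless for < 65536 objects)."""
    labels = lab.labels
    if labels.size and labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map has more than 65535 objects; cannot store as uint16")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_map(path: str | Path, pixel_size_um: float) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim != 2 or not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path} does not contain a single-plane integer label map")
    return LabelMap(data.astype(np.int32), pixel_size_um)


def write_feature_table(
    records: Sequence[RegionRecord | FAMeasurement],
    path: str | Path,
) -> None:
    """Write per-object features as CSV, one row per object.

    Rows are emitted in ascending label order; the header names every
    feature with its unit embedded in the column name (``area_um2``,
    ``perimeter_um``, ...). An empty record list yields a header-only
    file so downstream joins never fail on a missing file.
    """
    rows = [r.as_row() for r in records]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if len(df):
        df = df.sort_values("label", kind="stable")
    df.to_csv(Path(path), index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV back into a DataFrame (column schema preserved)."""
    return pd.read_csv(Path(path))


def log_stage(stage: str, before: int, after: int) -> None:
    """Audit-trail logging for every exclusion rule: counts before/after."""
    logger.info("%s: %d -> %d objects", stage, before, after)
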