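"""Pipeline parameters with published defaults.

All size thresholds are stored in micrometres and converted to pixels at
run time, so the same configuration applies across objectives; the two
structuring-element sizes that are natively pixel quantities (top-hat
disk diameters) stay in pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the segmentation/morphometry pipeline.

    Attributes
    ----------
    h_marker_suppression : float
        Depth ``h`` (in px of distance-map height) below which regional
        maxima of the distance transform are suppressed before seeding
        the watershed. Image-set specific; must be tuned per objective
        and cell type.
    min_cell_area_um2 : float
        Objects smaller than this are rejected as non-cells (default 20).
    min_fa_area_um2 : float
        Focal adhesions smaller than this are treated as noise (default 0.1).
    max_fa_length_um : float
        Structures with a Feret diameter above this are rejected as
        non-adhesion staining artifacts (default 30).
    fa_tophat_disk_diameter_px : int
        Disk diameter of the white top-hat used on the vinculin channel
        (default 80 px).
    fa_median_kernel_um : float
        Side of the square median window used to estimate residual
        cytosolic background, chosen as the width of the largest
        adhesions (default 4 um).
    closing_radius_px : int
        Radius r of the (2r+1)x(2r+1) box closing applied after hole
        filling (default 1, i.e. 3x3).
    nucleus_tophat_disk_diameter_px : int
        Disk diameter for the nucleus-channel top-hat (default 80 px).
    cell_tophat_disk_diameter_px : int
        Disk diameter for the actin-channel top-hat (default 80 px).
    maturation_bins_um : tuple of float
        Length breakpoints separating nascent / mature / supermature
        adhesions (default (2, 6) um).
    """

    h_marker_suppression: float = 3.0
    min_cell_area_um2: float = 20.0
    min_fa_area_um2: float = 0.1
    max_fa_length_um: float = 30.0
    fa_tophat_disk_diameter_px: int = 80
    fa_median_kernel_um: float = 4.0
    closing_radius_px: int = 1
    nucleus_tophat_disk_diameter_px: int = 80
    cell_tophat_disk_diameter_px: int = 80
    maturation_bins_um: tuple[float, ...] = (2.0, 6.0)

    def __post_init__(self) -> None:
        if self.h_marker_suppression < 0:
            raise ValueError("h_marker_suppression must be >= 0")
        for name in (
            "min_cell_area_um2",
            "min_fa_area_um2",
            "max_fa_length_um",
            "fa_median_kernel_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "fa_tophat_disk_diameter_px",
            "nucleus_tophat_disk_diameter_px",
            "cell_tophat_disk_diameter_px",
            "closing_radius_px",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        bins = tuple(float(b) for b in self.maturation_bins_um)
        if len(bins) < 1 or any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValueError("maturation_bins_um must be strictly increasing")
        if bins[0] <= 0:
            raise ValueError("maturation breakpoints must be positive")
        object.__setattr__(self, "maturation_bins_um", bins)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maturation_bins_um"] = list(self.maturation_bins_um)
        return d


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a flat YAML mapping.

    Keys absent from the file keep their defaults; keys that are not
    pipeline parameters raise ``ValueError`` (a misspelt threshold must
    never be silently ignored).
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config file must be a flat key-value mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "maturation_bins_um" in data:
        data["maturation_bins_um"] = tuple(data["maturation_bins_um"])
    return PipelineConfig(**data)
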