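"""Ground-truthed synthetic three-channel micrographs.

Emulates the imagery the pipeline is built for: bright ellipsoidal
nuclei on a dark background, larger elongated cell bodies (actin), and
punctate elongated adhesion spots riding on a diffuse cytosolic
background, with uneven illumination, additive Gaussian noise, optional
touching cell pairs and objects clipped by the image border. Every
object is described geometrically first (the scene), then rendered, so
noiseless label maps are available as exact oracles.

All geometry uses (x, y) = (column, row) pixel-center coordinates and
the same orientation convention as the morphometry: angle of the major
axis against the x-axis, counter-clockwise toward +y (rows increasing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import CalibratedImage, Channel, LabelMap


@dataclass(frozen=True)
class EllipseSpec:
    """One rendered object: a solid (optionally soft-edged) ellipse."""

    center_xy_px: tuple[float, float]
    major_um: float  # full major-axis length
    minor_um: float
    orientation_deg: float
    intensity: float
    parent: int | None = None  # index of the owning cell, for nuclei / FAs


@dataclass(frozen=True)
class SyntheticScene:
    """Geometric ground truth from which the channel images render."""

    image_shape: tuple[int, int]
    pixel_size_um: float
    cells: tuple[EllipseSpec, ...] = ()
    nuclei: tuple[EllipseSpec, ...] = ()
    fas: tuple[EllipseSpec, ...] = ()
    background_level: float = 0.1
    cytosol_level: float = 0.15
    illumination_gradient: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.05
    soft_edge_px: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class SceneParams:
    """Sampling ranges for :func:`sample_scene`.

    Defaults describe a field of well-separated spindle-shaped
    myofibroblast-like cells imaged at 0.25 um/px (a 40x objective)
    with 5% additive noise. Cell widths stay below the 80-px top-hat
    disk so background suppression preserves whole cells, and nuclei
    are large and bright enough that the nucleus channel keeps a
    workable foreground fraction even in sparse five-cell fields —
    global histogram thresholds degrade when the bright class occupies
    well under half a percent of the frame.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.25
    n_cells: int = 8
    cell_major_um: tuple[float, float] = (28.0, 48.0)
    cell_minor_um: tuple[float, float] = (12.0, 19.0)
    cell_intensity: tuple[float, float] = (0.5, 0.7)
    nucleus_major_um: tuple[float, float] = (14.0, 22.0)
    nucleus_minor_um: tuple[float, float] = (8.0, 12.0)
    nucleus_intensity: tuple[float, float] = (0.75, 0.95)
    fas_per_cell: tuple[int, int] = (30, 60)
    fa_length_um: tuple[float, float] = (0.6, 7.0)
    fa_width_um: tuple[float, float] = (0.5, 1.2)
    fa_intensity: tuple[float, float] = (0.5, 0.75)
    background_level: float = 0.1
    cytosol_level: float = 0.15
    illumination_gradient: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.05
    min_separation_um: float = 4.0
    n_touching_pairs: int = 0
    n_border_cells: int = 0
    soft_edge_px: float = 0.0
    max_tries: int = 5000


def _uniform(rng: np.random.Generator, lohi: tuple[float, float]) -> float:
    return float(rng.uniform(lohi[0], lohi[1]))


def sample_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Draw a reproducible scene from the given parameter ranges.

    Interior cells are placed fully inside the frame with pairwise
    bounding-circle separation of at least ``min_separation_um``;
    ``n_border_cells`` extra cells are centred on the frame edge so
    their masks provably touch the border; ``n_touching_pairs`` pairs
    get centre distances below the sum of their semi-minor axes so
    their masks provably overlap. Raises if placement is infeasible
    within ``max_tries`` attempts.
    """
    rng = np.random.default_rng(seed)
    rows, cols = params.image_shape
    px = params.pixel_size_um
    sep_px = params.min_separation_um / px

    placed: list[EllipseSpec] = []  # interior cells
    radii: list[float] = []  # bounding-circle radii, px

    def try_place(border: bool) -> EllipseSpec:
        for _ in range(params.max_tries):
            major = _uniform(rng, params.cell_major_um)
            minor = _uniform(rng, params.cell_minor_um)
            minor = min(minor, major)
            r = major / 2 / px
            if border:
                edge = rng.integers(4)
                t = rng.uniform(0.1, 0.9)
                cx, cy = {
                    0: (t * (cols - 1), 0.0),
                    1: (t * (cols - 1), rows - 1.0),
                    2: (0.0, t * (rows - 1)),
                    3: (cols - 1.0, t * (rows - 1)),
                }[int(edge)]
            else:
                margin = r + 2
                if cols - 1 - margin <= margin or rows - 1 - margin <= margin:
                    continue
                cx = rng.uniform(margin, cols - 1 - margin)
                cy = rng.uniform(margin, rows - 1 - margin)
            ok = all(
                math.hypot(cx - e.center_xy_px[0], cy - e.center_xy_px[1])
                >= r + ri + sep_px
                for e, ri in zip(placed, radii)
            )
            if ok:
                spec = EllipseSpec(
                    (cx, cy),
                    major,
                    minor,
                    float(rng.uniform(0, 180)),
                    _uniform(rng, params.cell_intensity),
                )
                placed.append(spec)
                radii.append(r)
                return spec
        raise RuntimeError("could not place a cell; relax the scene parameters")

    n_interior = params.n_cells - params.n_border_cells - 2 * params.n_touching_pairs
    if n_interior < 0:
        raise ValueError("n_cells too small for the requested border/touching cells")
    for _ in range(n_interior):
        try_place(border=False)
    for _ in range(params.n_border_cells):
        try_place(border=True)
    for _ in range(params.n_touching_pairs):
        first = try_place(border=False)
        for _ in range(params.max_tries):
            major = _uniform(rng, params.cell_major_um)
            minor = min(_uniform(rng, params.cell_minor_um), major)
            # centre distance below the sum of semi-minor axes: each
            # ellipse contains its inscribed circle, so the masks overlap
            d = 0.85 * (first.minor_um / 2 + minor / 2) / px
            ang = rng.uniform(0, 2 * math.pi)
            cx = first.center_xy_px[0] + d * math.cos(ang)
            cy = first.center_xy_px[1] + d * math.sin(ang)
            r = major / 2 / px
            if not (r < cx < cols - 1 - r and r < cy < rows - 1 - r):
                continue
            ok = all(
                math.hypot(cx - e.center_xy_px[0], cy - e.center_xy_px[1])
                >= r + ri + sep_px
                for e, ri in zip(placed[:-1], radii[:-1])
            )
            if ok:
                placed.append(
                    EllipseSpec(
                        (cx, cy),
                        major,
                        minor,
                        float(rng.uniform(0, 180)),
                        _uniform(rng, params.cell_intensity),
                    )
                )
                radii.append(r)
                break
        else:
            raise RuntimeError("could not place a touching partner")

    cells = tuple(placed)
    nuclei = []
    fas = []
    for i, cell in enumerate(cells):
        # same centre and orientation as the cell, axes clipped so the
        # nucleus provably lies inside it
        n_major = min(_uniform(rng, params.nucleus_major_um), 0.85 * cell.major_um)
        n_minor = min(_uniform(rng, params.nucleus_minor_um), 0.85 * cell.minor_um)
        nuclei.append(
            EllipseSpec(
                cell.center_xy_px,
                n_major,
                max(n_minor, 1e-3),
                cell.orientation_deg,
                _uniform(rng, params.nucleus_intensity),
                parent=i,
            )
        )
        n_fa = int(rng.integers(params.fas_per_cell[0], params.fas_per_cell[1] + 1))
        theta = math.radians(cell.orientation_deg)
        a = cell.major_um / 2 / px
        b = cell.minor_um / 2 / px
        spots: list[EllipseSpec] = []
        for _ in range(n_fa):
            for _ in range(200):
                phi = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0.55, 0.85)
                u, v = rad * a * math.cos(phi), rad * b * math.sin(phi)
                cx = cell.center_xy_px[0] + u * math.cos(theta) - v * math.sin(theta)
                cy = cell.center_xy_px[1] + u * math.sin(theta) + v * math.cos(theta)
                if not (2 < cx < cols - 3 and 2 < cy < rows - 3):
                    continue
                length = _uniform(rng, params.fa_length_um)
                width = min(_uniform(rng, params.fa_width_um), length)
                clear = all(
                    math.hypot(cx - s.center_xy_px[0], cy - s.center_xy_px[1])
                    >= (length + s.major_um) / 2 / px + 3
                    for s in spots
                )
                if clear:
                    spots.append(
                        EllipseSpec(
                            (cx, cy),
                            length,
                            width,
                            float(rng.uniform(0, 180)),
                            _uniform(rng, params.fa_intensity),
                            parent=i,
                        )
                    )
                    break
        fas.extend(spots)

    return SyntheticScene(
        image_shape=params.image_shape,
        pixel_size_um=px,
        cells=cells,
        nuclei=tuple(nuclei),
        fas=tuple(fas),
        background_level=params.background_level,
        cytosol_level=params.cytosol_level,
        illumination_gradient=params.illumination_gradient,
        noise_sd=params.noise_sd,
        soft_edge_px=params.soft_edge_px,
        seed=seed,
    )


def _ellipse_support(
    shape: tuple[int, int], spec: EllipseSpec, pixel_size_um: float
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Bounding-box slices and the normalized radial coordinate rho
    (rho <= 1 inside the ellipse) evaluated on the box."""
    rows, cols = shape
    a = max(spec.major_um / 2 / pixel_size_um, 1e-6)
    b = max(spec.minor_um / 2 / pixel_size_um, 1e-6)
    cx, cy = spec.center_xy_px
    r = math.ceil(a) + 2
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, rows)
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, cols)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    th = math.radians(spec.orientation_deg)
    u = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
    v = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return (slice(y0, y1), slice(x0, x1)), rho


def ellipse_mask(
    shape: tuple[int, int], spec: EllipseSpec, pixel_size_um: float
) -> np.ndarray:
    """Boolean rasterization: pixel centers with rho <= 1."""
    out = np.zeros(shape, dtype=bool)
    sl, rho = _ellipse_support(shape, spec, pixel_size_um)
    out[sl] = rho <= 1.0
    return out


def _paint(
    canvas: np.ndarray,
    spec: EllipseSpec,
    pixel_size_um: float,
    soft_edge_px: float,
) -> None:
    sl, rho = _ellipse_support(canvas.shape, spec, pixel_size_um)
    if soft_edge_px > 0:
        b = max(spec.minor_um / 2 / pixel_size_um, 1e-6)
        w = soft_edge_px / b  # ramp width in normalized units
        weight = np.clip((1.0 - rho) / w, 0.0, 1.0)
    else:
        weight = (rho <= 1.0).astype(np.float64)
    canvas[sl] = np.maximum(canvas[sl], spec.intensity * weight)


def render_channels(
    scene: SyntheticScene,
) -> tuple[CalibratedImage, CalibratedImage, CalibratedImage]:
    """Render (actin, dapi, vinculin) float images in [0, 1].

    Each channel = background level + linear illumination gradient +
    its objects (cells / nuclei / adhesion spots, painted at their
    intensity) + Gaussian noise of sd ``noise_sd``, clipped to [0, 1].
    The vinculin channel additionally carries ``cytosol_level`` of
    diffuse signal inside every cell mask.
    """
    rows, cols = scene.image_shape
    px = scene.pixel_size_um
    yy, xx = np.mgrid[0:rows, 0:cols]
    gx, gy = scene.illumination_gradient
    base = (
        scene.background_level
        + gx * xx / max(cols - 1, 1)
        + gy * yy / max(rows - 1, 1)
    )

    channels = []
    rng = np.random.default_rng([scene.seed, 0x5EED])
    for name, objects in (
        (Channel.ACTIN, scene.cells),
        (Channel.NUCLEUS, scene.nuclei),
        (Channel.FA, scene.fas),
    ):
        canvas = np.zeros((rows, cols), dtype=np.float64)
        if name is Channel.FA and scene.cytosol_level > 0:
            for cell in scene.cells:
                canvas[ellipse_mask((rows, cols), cell, px)] = scene.cytosol_level
        for spec in objects:
            _paint(canvas, spec, px, scene.soft_edge_px)
        img = base + canvas
        if scene.noise_sd > 0:
            img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
        channels.append(CalibratedImage(np.clip(img, 0.0, 1.0), px, name))
    return tuple(channels)


def ground_truth_labels(scene: SyntheticScene) -> tuple[LabelMap, LabelMap, LabelMap]:
    """Noiseless label maps (cells, nuclei, fas); object k gets label k+1.

    Where objects of the same class overlap (touching pairs), the
    later-listed object wins the shared pixels.
    """
    px = scene.pixel_size_um
    maps = []
    for objects in (scene.cells, scene.nuclei, scene.fas):
        lab = np.zeros(scene.image_shape, dtype=np.int32)
        for k, spec in enumerate(objects, start=1):
            lab[ellipse_mask(scene.image_shape, spec, px)] = k
        maps.append(LabelMap(lab, px))
    return tuple(maps)


def fa_grid_scene(
    lengths_um: np.ndarray,
    widths_um: np.ndarray,
    orientations_deg: np.ndarray,
    pixel_size_um: float = 0.2,
    intensity: float = 0.8,
    noise_sd: float = 0.0,
    cytosol_level: float = 0.0,
    seed: int = 0,
    margin_um: float = 2.0,
) -> SyntheticScene:
    """Adhesion-only scene with spots of programmed geometry on a grid.

    Spots are laid out row-major with enough spacing that no two
    thresholded components can merge, so the ground-truth geometry of
    every spot is exactly recoverable. Used to exercise the exclusion
    rules and maturation classification against brute-force counts.
    """
    lengths = np.atleast_1d(np.asarray(lengths_um, dtype=np.float64))
    widths = np.broadcast_to(np.asarray(widths_um, dtype=np.float64), lengths.shape)
    angles = np.broadcast_to(
        np.asarray(orientations_deg, dtype=np.float64), lengths.shape
    )
    px = pixel_size_um
    pitch = float(lengths.max() + 2 * margin_um) / px  # px between spot centres
    n = lengths.size
    ncols = max(int(math.ceil(math.sqrt(n))), 1)
    nrows = int(math.ceil(n / ncols))
    shape = (int(nrows * pitch + pitch), int(ncols * pitch + pitch))
    fas = tuple(
        EllipseSpec(
            ((c + 1) * pitch, (r + 1) * pitch),
            float(lengths[i]),
            float(min(widths[i], lengths[i])),
            float(angles[i]),
            intensity,
        )
        for i, (r, c) in enumerate(
            (divmod(i, ncols) for i in range(n)), start=0
        )
    )
    return SyntheticScene(
        image_shape=shape,
        pixel_size_um=px,
        fas=fas,
        background_level=0.0,
        cytosol_level=cytosol_level,
        illumination_gradient=(0.0, 0.0),
        noise_sd=noise_sd,
        seed=seed,
    )


def dumbbell_scene(
    lobe_radius_um: float = 12.0,
    neck_fraction: float = 0.4,
    pixel_size_um: float = 0.5,
    intensity: float = 0.6,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Two equal circular cells overlapping into a dumbbell.

    ``neck_fraction`` is the neck width as a fraction of the lobe width
    (2R): for circles of radius R at centre distance d the union's neck
    half-width is sqrt(R^2 - (d/2)^2), so d = 2 sqrt(R^2 - (w/2)^2)
    with w = neck_fraction * 2R.
    """
    if not 0 < neck_fraction < 1:
        raise ValueError("neck_fraction must be in (0, 1)")
    R = lobe_radius_um
    w = neck_fraction * 2 * R
    d_um = 2 * math.sqrt(R * R - (w / 2) ** 2)
    px = pixel_size_um
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0, math.pi)
    margin = (R * 2 + d_um) / px
    size = int(margin + 4 * R / px)
    cx, cy = size / 2, size / 2
    dx = d_um / 2 / px * math.cos(angle)
    dy = d_um / 2 / px * math.sin(angle)
    cells = (
        EllipseSpec((cx - dx, cy - dy), 2 * R, 2 * R, 0.0, intensity),
        EllipseSpec((cx + dx, cy + dy), 2 * R, 2 * R, 0.0, intensity),
    )
    return SyntheticScene(
        image_shape=(size, size),
        pixel_size_um=px,
        cells=cells,
        background_level=0.05,
        cytosol_level=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )
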