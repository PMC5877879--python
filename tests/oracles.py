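"""Brute-force reference implementations used only as test oracles.

Every function here recomputes a quantity by direct enumeration or
exhaustive search, independently of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def otsu_best_bin(values01: np.ndarray) -> int:
    """Exhaustive search over all 256 split points of the unit histogram.

    Returns the bin k whose split (bins <= k vs > k) maximises the
    between-class variance, computed naively per candidate.
    """
    hist, _ = np.histogram(values01, bins=256, range=(0.0, 1.0))
    centers = np.arange(256, dtype=np.float64)
    best_k, best_v = -1, -np.inf
    for k in range(255):
        n0 = hist[: k + 1].sum()
        n1 = hist[k + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / n1
        v = n0 * n1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_k = v, k
    return best_k


def disk_offsets(diameter_px: int) -> list[tuple[int, int]]:
    r = diameter_px / 2.0
    m = int(np.floor(r))
    return [
        (dy, dx)
        for dy in range(-m, m + 1)
        for dx in range(-m, m + 1)
        if dy * dy + dx * dx <= r * r
    ]


def brute_opening(img: np.ndarray, diameter_px: int) -> np.ndarray:
    """Grey opening with a flat disk by explicit min-then-max loops.

    The world outside the frame counts as the image minimum (darkest
    background), matching the library's boundary convention.
    """
    offs = disk_offsets(diameter_px)
    m = int(np.ceil(diameter_px))
    big = np.pad(img.astype(np.float64), m, mode="constant",
                 constant_values=float(img.min()))
    h, w = big.shape
    eroded = np.full_like(big, np.inf)
    for y in range(h):
        for x in range(w):
            vals = [
                big[y + dy, x + dx]
                for dy, dx in offs
                if 0 <= y + dy < h and 0 <= x + dx < w
            ]
            eroded[y, x] = min(vals)
    opened = np.full_like(big, -np.inf)
    for y in range(h):
        for x in range(w):
            vals = [
                eroded[y + dy, x + dx]
                for dy, dx in offs
                if 0 <= y + dy < h and 0 <= x + dx < w
            ]
            opened[y, x] = max(vals)
    return opened[m:-m, m:-m]


def brute_median_background(img: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel neighborhood median by exhaustive sort, reflect-padded."""
    r = window // 2
    padded = np.pad(img.astype(np.float64), r, mode="symmetric")
    out = np.empty_like(img, dtype=np.float64)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            win = np.sort(padded[y : y + window, x : x + window].ravel())
            out[y, x] = np.median(win)
    return out


def flood_fill_from_border(mask: np.ndarray) -> np.ndarray:
    """Hole filling by BFS over 4-connected background from the border."""
    h, w = mask.shape
    reach = np.zeros_like(mask, dtype=bool)
    stack = [
        (y, x)
        for y in range(h)
        for x in range(w)
        if (y in (0, h - 1) or x in (0, w - 1)) and not mask[y, x]
    ]
    for y, x in stack:
        reach[y, x] = True
    while stack:
        y, x = stack.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not reach[ny, nx]:
                reach[ny, nx] = True
                stack.append((ny, nx))
    return mask | ~reach


def brute_distance_map(mask: np.ndarray) -> np.ndarray:
    """Nearest-background Euclidean distance with the frame as background."""
    h, w = mask.shape
    bg = [
        (y, x)
        for y in range(-1, h + 1)
        for x in range(-1, w + 1)
        if not (0 <= y < h and 0 <= x < w) or not mask[y, x]
    ]
    bg = np.asarray(bg, dtype=np.float64)
    out = np.zeros((h, w), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                d2 = (bg[:, 0] - y) ** 2 + (bg[:, 1] - x) ** 2
                out[y, x] = np.sqrt(d2.min())
    return out


def brute_regional_maxima(img: np.ndarray) -> np.ndarray:
    """8-connected plateaus with no strictly greater neighbor."""
    h, w = img.shape
    # plateau labelling by flood over equal values
    plateau = -np.ones((h, w), dtype=int)
    n = 0
    for y in range(h):
        for x in range(w):
            if plateau[y, x] >= 0:
                continue
            v = img[y, x]
            stack = [(y, x)]
            plateau[y, x] = n
            while stack:
                cy, cx = stack.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if (
                            0 <= ny < h
                            and 0 <= nx < w
                            and plateau[ny, nx] < 0
                            and img[ny, nx] == v
                        ):
                            plateau[ny, nx] = n
                            stack.append((ny, nx))
            n += 1
    is_max = np.ones(n, dtype=bool)
    for y in range(h):
        for x in range(w):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and img[ny, nx] > img[y, x]:
                        is_max[plateau[y, x]] = False
    return is_max[plateau]


def brute_feret(coords_xy: np.ndarray) -> float:
    """O(n^2) maximum pairwise distance between pixel centers."""
    pts = np.asarray(coords_xy, dtype=np.float64)
    if len(pts) < 2:
        return 0.0
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def point_in_polygon_evenodd(point, vertices) -> bool:
    """Even-odd ray casting; points exactly on an edge count as inside."""
    x, y = point
    verts = np.asarray(vertices, dtype=np.float64)
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-edge check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside
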