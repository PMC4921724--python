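"""Seeded region-growing lesion segmentation.

Healthy skin in dermoscopy images is mostly homogeneous, so the background
is segmented first: a single seed placed on healthy skin near the image
corner grows into the maximal connected homogeneous region, and the lesion
is recovered as the largest connected component of the complement.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu

__all__ = [
    "DEFAULT_SEED",
    "region_grow",
    "default_tolerance",
    "lesion_mask_from_background",
    "segment_lesion",
    "extract_contour",
    "rasterize_contour",
    "border_error",
]

#: Seed pixel (row, col) after frame cropping; offset from (0, 0) to avoid
#: residual border pixels.
DEFAULT_SEED = (5, 5)



def region_grow(
    gray: np.ndarray,
    seed: tuple[int, int],
    tolerance: float,
    criterion: str = "mean",
) -> np.ndarray:
    """Grow a 4-connected region from ``seed``.

    Unallocated 4-neighbors of the region are examined in first-in-first-out
    order; a candidate is merged when its gray value is within ``tolerance``
    of the similarity reference, which is the running region mean
    (``criterion='mean'``, updated after every merge) or the fixed seed value
    (``criterion='seed'``). A rejected pixel is not revisited, which together
    with the FIFO frontier makes the result deterministic. Only the
    fixed-seed variant is monotone in the tolerance.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if criterion not in ("mean", "seed"):
        raise ValueError(f"unknown criterion {criterion!r}")
    g = np.asarray(gray, dtype=np.float64)
    h, w = g.shape
    r0, c0 = seed
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"seed {seed} outside image of shape {g.shape}")
    if not np.isfinite(g[r0, c0]):
        raise ValueError("seed lies on an invalid (non-finite) pixel")

    vals = g.ravel().tolist()
    visited = bytearray(h * w)  # queued-or-decided
    region = np.zeros(h * w, dtype=bool)
    start = r0 * w + c0
    visited[start] = 1
    region[start] = True
    total = vals[start]
    count = 1
    ref = vals[start]
    use_mean = criterion == "mean"

    frontier: deque[int] = deque()
    for nb in (start - w, start + w):
        if 0 <= nb < h * w:
            visited[nb] = 1
            frontier.append(nb)
    if c0 > 0:
        visited[start - 1] = 1
        frontier.append(start - 1)
    if c0 < w - 1:
        visited[start + 1] = 1
        frontier.append(start + 1)

    while frontier:
        p = frontier.popleft()
        if abs(vals[p] - ref) <= tolerance:
            region[p] = True
            if use_mean:
                total += vals[p]
                count += 1
                ref = total / count
            r, c = divmod(p, w)
            if r > 0 and not visited[p - w]:
                visited[p - w] = 1
                frontier.append(p - w)
            if r < h - 1 and not visited[p + w]:
                visited[p + w] = 1
                frontier.append(p + w)
            if c > 0 and not visited[p - 1]:
                visited[p - 1] = 1
                frontier.append(p - 1)
            if c < w - 1 and not visited[p + 1]:
                visited[p + 1] = 1
                frontier.append(p + 1)
    return region.reshape(h, w)


def default_tolerance(gray: np.ndarray) -> float:
    """Data-driven growing tolerance: half the typical skin-lesion contrast.

    The Otsu threshold splits the histogram into a skin mode and a lesion
    mode; the tolerance is half the distance between the two mode medians.
    Background growth from the skin seed then stops at the half-amplitude
    crossing of the lesion edge, which is the unbiased boundary estimate for
    an edge blurred by a symmetric (Gaussian) kernel — a smaller tolerance
    systematically over-segments the lesion by a blur-width margin.
    """
    g = np.asarray(gray, dtype=np.float64)
    if g.std() == 0:
        return 0.0
    t = float(threshold_otsu(g))
    above, below = g[g >= t], g[g < t]
    if above.size == 0 or below.size == 0:
        return 0.0
    return float(np.median(above) - np.median(below)) / 2.0


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def lesion_mask_from_background(background: np.ndarray) -> np.ndarray:
    """Complement of the grown background, reduced to its largest 4-connected
    component with internal holes filled."""
    comp = ~background
    if not comp.any():
        raise ValueError("no lesion found: background covers the whole image")
    labels, n = ndimage.label(comp, structure=_FOUR_CONN)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    lesion = labels == largest
    return ndimage.binary_fill_holes(lesion, structure=_FOUR_CONN)


def segment_lesion(
    gray: np.ndarray,
    seed: tuple[int, int] = DEFAULT_SEED,
    tolerance: float | None = None,
) -> np.ndarray:
    """Background region growing from a healthy-skin corner seed, then
    complement: the standard lesion extraction chain."""
    if tolerance is None:
        tolerance = default_tolerance(gray)
    background = region_grow(gray, seed, tolerance)
    return lesion_mask_from_background(background)


# Moore neighborhood in clockwise order starting from west, as (dr, dc).
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary of a single-component mask.

    Moore-neighbor tracing, clockwise, starting at the topmost-leftmost
    boundary pixel, with Jacob's stopping criterion (the trace ends when the
    start pixel is re-entered from the start direction). Returns an (n, 2)
    array of (row, col) positions; raises on masks too small to enclose area.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask has no contour")
    if m.sum() < 3:
        raise ValueError("mask too small: contour would not enclose area")

    padded = np.zeros((m.shape[0] + 2, m.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = m
    rs, cs = np.nonzero(padded)
    top = rs.min()
    start = (top, cs[rs == top].min())

    # Trace state = (current boundary pixel, background pixel the clockwise
    # search starts from). The trace is deterministic given the state, so the
    # boundary cycle is complete when the initial state recurs.
    init_state = (start, (start[0], start[1] - 1))  # west of start is background
    points = [start]
    cur, prev = init_state
    seen = {init_state}
    while True:
        k0 = _MOORE.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for step in range(1, 9):
            k = (k0 + step) % 8
            nb = (cur[0] + _MOORE[k][0], cur[1] + _MOORE[k][1])
            if padded[nb]:
                nxt = nb
                newprev = (cur[0] + _MOORE[(k - 1) % 8][0], cur[1] + _MOORE[(k - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            break
        state = (nxt, newprev)
        if state in seen:
            break
        seen.add(state)
        points.append(nxt)
        cur, prev = state
    pts = np.asarray(points, dtype=np.int64) - 1  # undo padding
    # drop the duplicated closing point if present
    if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    # remove consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if len(pts) < 3:
        raise ValueError("degenerate contour: fewer than 3 distinct points")
    return pts


def rasterize_contour(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Filled polygon of the contour, for round-trip checks against the mask."""
    rr, cc = draw_polygon(contour[:, 0], contour[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def border_error(mask: np.ndarray, truth: np.ndarray) -> float:
    """Relative segmentation error: XOR pixel count over truth pixel count."""
    if mask.shape != truth.shape:
        raise ValueError("mask and truth must share a shape")
    t = int(np.count_nonzero(truth))
    if t == 0:
        raise ValueError("empty ground-truth mask")
    return int(np.count_nonzero(mask ^ truth)) / t
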