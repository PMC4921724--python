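"""Dermoscopy image enhancement.

Dermoscopic images carry acquisition artifacts — a black frame from the
camera adapter, air bubbles from the immersion fluid, and hairs — that
corrupt both segmentation and feature statistics. The enhancement stage
removes the black frame (detected on the HSL lightness channel and cropped
away), detects thick dark hairs with a morphological black top-hat transform
and inpaints them from their neighborhood, and smooths air bubbles and light
hairs with a Gaussian filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, skeletonize

__all__ = [
    "BLACK_LIGHTNESS_MAX",
    "lightness",
    "rgb_to_gray",
    "detect_black_frame",
    "clear_rectangle",
    "remove_frame",
    "smooth",
    "black_top_hat",
    "detect_hair",
    "inpaint_hair",
    "PreprocessResult",
    "preprocess_pipeline",
]

#: A pixel is "black" when its HSL lightness (0..255 scale) is strictly below this.
BLACK_LIGHTNESS_MAX = 15.0

#: Minimum top-hat response (gray levels) for a pixel to be a hair candidate.
MIN_HAIR_RESPONSE = 10.0

#: Curvilinear-component test: skeleton length / mean width must reach this.
HAIR_ELONGATION_MIN = 4.0

#: Hairs are dark structures: candidate pixels must lie below this gray level
#: (rejects the bright halo a closing leaves around air bubbles).
HAIR_MAX_GRAY = 100.0

#: Minimum component area (px) for a hair stroke; rejects noise specks.
MIN_HAIR_AREA = 30

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def lightness(image: np.ndarray) -> np.ndarray:
    """HSL lightness L = (max(R,G,B) + min(R,G,B)) / 2, on the 0..255 scale."""
    img = np.asarray(image, dtype=np.float64)
    return (img.max(axis=2) + img.min(axis=2)) / 2.0


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """NTSC 1953 luma: Y = 0.299 R + 0.587 G + 0.114 B."""
    img = np.asarray(image, dtype=np.float64)
    return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114


def detect_black_frame(image: np.ndarray) -> np.ndarray:
    """Black pixels (lightness < 15) that are 4-connected to the image border.

    Dark pixels in the interior (the lesion itself) are deliberately
    excluded: only border-connected darkness is frame.
    """
    dark = lightness(image) < BLACK_LIGHTNESS_MAX
    if not dark.any():
        return dark
    labels, _ = ndimage.label(dark, structure=_FOUR_CONN)
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border_labels = border_labels[border_labels != 0]
    frame = np.isin(labels, border_labels)
    if frame.all():
        warnings.warn("entire image is below the black-lightness threshold")
    return frame


def clear_rectangle(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Maximal-area axis-aligned rectangle containing no True pixel of
    ``mask``; returned as half-open bounds (r0, r1, c0, c1).

    Classic largest-rectangle-in-a-binary-matrix sweep: per row, a histogram
    of consecutive clear pixels above, resolved with a monotonic stack.
    """
    h, w = mask.shape
    heights = np.zeros(w, dtype=np.int64)
    best = (0, 0, 0, 0)
    best_area = 0
    for r in range(h):
        row = mask[r]
        heights = np.where(row, 0, heights + 1)
        stack: list[int] = []  # column indices with increasing heights
        for c in range(w + 1):
            cur = heights[c] if c < w else 0
            while stack and heights[stack[-1]] >= cur:
                top = stack.pop()
                height = int(heights[top])
                left = stack[-1] + 1 if stack else 0
                area = height * (c - left)
                if area > best_area:
                    best_area = area
                    best = (r + 1 - height, r + 1, left, c)
            stack.append(c)
    return best


def remove_frame(image: np.ndarray, frame_mask: np.ndarray) -> np.ndarray:
    """Crop the image to the maximal axis-aligned rectangle free of frame
    pixels; identity when the mask is empty.

    Cropping (rather than painting skin tone under the frame) avoids
    inventing pixel values that would bias downstream color statistics.
    """
    if not frame_mask.any():
        return image
    if frame_mask.mean() > 0.5:
        raise ValueError("unusable image: black frame covers more than 50% of pixels")
    r0, r1, c0, c1 = clear_rectangle(frame_mask)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("unusable image: no frame-free rectangle found")
    return image[r0:r1, c0:c1]


def smooth(image: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Per-channel Gaussian smoothing (reflective boundary), clipped to [0, 255]."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    img = np.asarray(image, dtype=np.float64)
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[..., ch] = ndimage.gaussian_filter(img[..., ch], sigma=sigma, mode="reflect")
    return np.clip(out, 0.0, 255.0)


def black_top_hat(gray: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Morphological closing minus the input: responds to dark features
    narrower than the structuring element, zero on bright features."""
    g = np.asarray(gray, dtype=np.float64)
    return closing(g, selem) - g


def detect_hair(gray: np.ndarray, selem_diameter: int = 7) -> np.ndarray:
    """Thick dark hairs via black top-hat + curvilinearity filter.

    The top-hat response is thresholded (Otsu over nonzero responses, with an
    absolute floor so noise-only images yield an empty mask), restricted to
    pixels that are dark in absolute terms (hairs are; the halo a closing
    leaves around bright bubbles is not), and connected components are kept
    only when large enough and elongated: skeleton length divided by mean
    stroke width (area / skeleton length) must reach ``HAIR_ELONGATION_MIN``,
    which rejects compact blobs such as bubble shadows.
    """
    th = black_top_hat(gray, disk(selem_diameter // 2))
    nz = th[th > 0]
    if nz.size == 0:
        return np.zeros(gray.shape, dtype=bool)
    thresh = max(float(threshold_otsu(nz)), MIN_HAIR_RESPONSE)
    cand = (th > thresh) & (np.asarray(gray, dtype=float) < HAIR_MAX_GRAY)
    if not cand.any():
        return cand
    labels, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=bool))
    keep = np.zeros(gray.shape, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        area = comp.sum()
        if area < MIN_HAIR_AREA:
            continue
        skel_len = skeletonize(comp).sum()
        if skel_len == 0:
            continue
        mean_width = area / skel_len
        if skel_len / mean_width >= HAIR_ELONGATION_MIN:
            keep |= comp
    return keep


def inpaint_hair(image: np.ndarray, hair_mask: np.ndarray) -> np.ndarray:
    """Fill masked pixels from their neighborhood, layer by layer.

    Each masked pixel adjacent to at least one unmasked pixel takes the mean
    of its unmasked 8-neighbors; the process repeats until the mask is empty.
    Unmasked pixels are returned unchanged. Converges in at most max(H, W)
    iterations for any mask leaving at least one pixel uncovered.
    """
    mask = hair_mask.copy()
    if not mask.any():
        return image
    if mask.all():
        raise ValueError("cannot inpaint: mask covers the entire image")
    img = np.asarray(image, dtype=np.float64).copy()
    kernel = np.ones((3, 3), dtype=np.float64)
    max_iter = max(mask.shape)
    for _ in range(max_iter):
        if not mask.any():
            break
        known = ~mask
        counts = ndimage.convolve(known.astype(np.float64), kernel, mode="constant")
        fillable = mask & (counts > 0)
        for ch in range(img.shape[2]):
            vals = ndimage.convolve(img[..., ch] * known, kernel, mode="constant")
            img[..., ch][fillable] = vals[fillable] / counts[fillable]
        mask = mask & ~fillable
    if mask.any():
        raise RuntimeError("inpainting failed to converge")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class PreprocessResult:
    """Enhanced image plus the intermediate masks and the crop window
    (half-open full-frame bounds) needed to map results back to the input."""

    image: np.ndarray       # enhanced RGB, float in [0,255], cropped frame
    gray: np.ndarray        # NTSC grayscale of the enhanced image
    window: tuple[int, int, int, int]  # (r0, r1, c0, c1) in input coordinates
    frame_mask: np.ndarray  # full-frame
    hair_mask: np.ndarray   # cropped coordinates


def preprocess_pipeline(
    image: np.ndarray, sigma: float = 1.5, selem_diameter: int = 7
) -> PreprocessResult:
    """Full enhancement chain: frame detection and crop, hair detection and
    inpainting, then Gaussian smoothing; returns the enhanced color image and
    its grayscale together with the bookkeeping masks."""
    frame = detect_black_frame(image)
    if frame.any():
        if frame.mean() > 0.5:
            raise ValueError("unusable image: black frame covers more than 50% of pixels")
        r0, r1, c0, c1 = clear_rectangle(frame)
        if r1 <= r0 or c1 <= c0:
            raise ValueError("unusable image: no frame-free rectangle found")
    else:
        r0, r1, c0, c1 = 0, image.shape[0], 0, image.shape[1]
    cropped = image[r0:r1, c0:c1]

    hair = detect_hair(rgb_to_gray(cropped), selem_diameter=selem_diameter)
    if hair.any():
        grown = ndimage.binary_dilation(hair, structure=np.ones((3, 3), dtype=bool))
        cropped = inpaint_hair(cropped, grown)
        hair = grown
    enhanced = smooth(cropped, sigma=sigma)
    return PreprocessResult(
        image=enhanced,
        gray=rgb_to_gray(enhanced),
        window=(r0, r1, c0, c1),
        frame_mask=frame,
        hair_mask=hair,
    )
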