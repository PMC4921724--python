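"""End-to-end glue: image -> enhanced image -> lesion mask -> features.

These helpers chain the stage modules with consistent coordinate
bookkeeping (segmentation runs on the frame-cropped image; masks are mapped
back to full-frame coordinates for comparison with ground truth).
"""

from __future__ import annotations

import numpy as np

from .features import FeatureTable, compute_features
from .preprocess import PreprocessResult, preprocess_pipeline
from .segment import DEFAULT_SEED, extract_contour, segment_lesion
from .synthetic import SyntheticSample

__all__ = ["extract_lesion", "image_features", "dataset_feature_table"]


def extract_lesion(
    image: np.ndarray,
    sigma: float = 1.5,
    tolerance: float | None = None,
    seed: tuple[int, int] = DEFAULT_SEED,
) -> tuple[np.ndarray, PreprocessResult]:
    """Enhance and segment one image; the returned mask lives in the
    full-frame coordinates of the input image."""
    pre = preprocess_pipeline(image, sigma=sigma)
    mask_crop = segment_lesion(pre.gray, seed=seed, tolerance=tolerance)
    r0, r1, c0, c1 = pre.window
    full = np.zeros(image.shape[:2], dtype=bool)
    full[r0:r1, c0:c1] = mask_crop
    return full, pre


def image_features(
    image: np.ndarray,
    sigma: float = 1.5,
    tolerance: float | None = None,
    levels: int = 64,
) -> dict[str, float]:
    """Full per-image feature vector: preprocess, segment, then the 23-entry
    feature bank computed on the enhanced (cropped) image."""
    pre = preprocess_pipeline(image, sigma=sigma)
    mask = segment_lesion(pre.gray, tolerance=tolerance)
    contour = extract_contour(mask)
    return compute_features(pre.image, pre.gray, mask, contour, levels=levels)


def dataset_feature_table(samples: list[SyntheticSample], **kwargs) -> FeatureTable:
    """Feature table + labels for a list of synthetic samples."""
    records = [image_features(s.image, **kwargs) for s in samples]
    labels = [s.label for s in samples]
    return FeatureTable.from_records(records, labels)
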