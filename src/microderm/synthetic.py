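"""Synthetic dermoscopy-image generator with known ground truth.

Every downstream stage (preprocessing, segmentation, feature extraction,
classification) is exercised on images from this module: a roughly
homogeneous skin background carrying a single darker pigmented lesion of
controllable boundary asymmetry, color count and texture contrast, plus the
acquisition artifacts typical of dermoscopes — dark hair strokes, a black
frame at the image border, and bright air-bubble discs.

The benign/malignant generating ranges mirror the clinical cues the feature
bank is designed to capture: melanomas tend to be asymmetric, multicolored
(three or more pigment tones, sometimes five or six) and texturally irregular,
while benign nevi are round-ish, one- or two-toned and smooth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "BENIGN_RANGES",
    "MALIGNANT_RANGES",
    "MALIGNANT_ASYMMETRY_MIN",
    "MALIGNANT_COLOR_MIN",
    "generate_lesion_shape",
    "render_image",
    "generate_sample",
    "generate_dataset",
    "save_dataset",
]

#: Skin background tone (R, G, B) and iid noise standard deviation.
SKIN_TONE = (205.0, 170.0, 150.0)
SKIN_NOISE_SD = 2.0

#: Pigment palette, light to dark; the first ``n_colors`` tones are used.
PIGMENT_PALETTE = (
    (150.0, 110.0, 95.0),
    (128.0, 90.0, 76.0),
    (108.0, 72.0, 60.0),
    (88.0, 56.0, 48.0),
    (68.0, 42.0, 38.0),
    (50.0, 30.0, 28.0),
)

#: A sample is labelled malignant iff both thresholds are met.
MALIGNANT_ASYMMETRY_MIN = 0.2
MALIGNANT_COLOR_MIN = 3

#: Class-conditional parameter ranges used by :func:`generate_dataset`.
BENIGN_RANGES = {
    "asymmetry_amp": (0.0, 0.1),
    "n_colors": (1, 2),
    "texture_contrast": (0.0, 5.0),
}
MALIGNANT_RANGES = {
    "asymmetry_amp": (0.25, 0.6),
    "n_colors": (3, 6),
    "texture_contrast": (15.0, 40.0),
}

_HAIR_TONE = (30.0, 26.0, 22.0)  # lightness well below 60
_FRAME_TONE = 5.0                # all channels below the 15-lightness frame rule
_BUBBLE_OFFSET = 40.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dermoscopy image.

    ``asymmetry_amp`` is the radial-perturbation amplitude of the lesion
    boundary (dimensionless, in [0, 1]); ``n_colors`` the number of pigment
    tones (1..6); ``texture_contrast`` the standard deviation, in gray
    levels, of spatially correlated intensity noise inside the lesion.
    """

    image_height: int = 192
    image_width: int = 192
    lesion_radius: float = 40.0
    asymmetry_amp: float = 0.0
    n_colors: int = 1
    texture_contrast: float = 0.0
    hair_count: int = 3
    frame_width: int = 6
    bubble_count: int = 2
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if not (0.0 <= self.asymmetry_amp <= 1.0):
            raise ValueError(f"asymmetry_amp must lie in [0, 1], got {self.asymmetry_amp}")
        if not (1 <= self.n_colors <= 6):
            raise ValueError(f"n_colors must lie in 1..6, got {self.n_colors}")
        if self.texture_contrast < 0:
            raise ValueError("texture_contrast must be >= 0")
        if self.hair_count < 0 or self.frame_width < 0 or self.bubble_count < 0:
            raise ValueError("hair_count, frame_width and bubble_count must be >= 0")
        limit = min(self.image_height, self.image_width) / 2 - self.frame_width
        if self.lesion_radius * (1.0 + self.asymmetry_amp) >= limit:
            raise ValueError(
                "lesion does not fit inside the image: "
                f"radius*(1+asymmetry_amp) = {self.lesion_radius * (1 + self.asymmetry_amp):.1f} "
                f">= min(H,W)/2 - frame_width = {limit:.1f}"
            )

    @property
    def label(self) -> int:
        """Deterministic class label: 1 (malignant-like) iff the lesion is
        both asymmetric and multicolored."""
        malignant = (
            self.asymmetry_amp >= MALIGNANT_ASYMMETRY_MIN
            and self.n_colors >= MALIGNANT_COLOR_MIN
        )
        return int(malignant)


@dataclass
class SyntheticSample:
    image: np.ndarray              # H x W x 3 uint8
    lesion_mask_truth: np.ndarray  # H x W bool
    label: int                     # 0 benign, 1 malignant
    spec: SyntheticSpec = field(repr=False)


def _streams(spec: SyntheticSpec) -> dict[str, np.random.Generator]:
    """Independent named RNG streams so that, e.g., removing hairs never
    shifts the lesion shape or texture draws."""
    ss = np.random.SeedSequence(spec.rng_seed)
    names = ("shape", "color", "noise", "hair", "bubble")
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


def generate_lesion_shape(spec: SyntheticSpec) -> np.ndarray:
    """Rasterize a star-convex lesion boundary.

    The boundary is the radial function
    ``r(theta) = R * (1 + amp * sum_{k=2..5} a_k sin(k*theta + phi_k))``
    with the harmonic weights ``a_k`` (normalised to sum to one) and phases
    drawn from the sample's seeded generator; ``amp = 0`` yields a disc.
    The result is a single 4-connected component centred in the image.
    """
    spec.validate()
    rng = _streams(spec)["shape"]
    a = rng.uniform(0.2, 1.0, size=4)
    a /= a.sum()
    phi = rng.uniform(0.0, 2.0 * np.pi, size=4)

    h, w = spec.image_height, spec.image_width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dy, dx = rows - cy, cols - cx
    theta = np.arctan2(dy, dx)
    perturb = np.zeros_like(theta)
    for k, (ak, pk) in enumerate(zip(a, phi), start=2):
        perturb += ak * np.sin(k * theta + pk)
    boundary = spec.lesion_radius * (1.0 + spec.asymmetry_amp * perturb)
    mask = np.hypot(dy, dx) <= boundary
    return mask


def _quadratic_bezier(p0, p1, p2, n=200):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _paint_stroke(img: np.ndarray, pts: np.ndarray, width: float, tone) -> None:
    h, w = img.shape[:2]
    rad = max(width / 2.0, 0.5)
    for r, c in pts:
        r0, r1 = int(np.floor(r - rad)), int(np.ceil(r + rad)) + 1
        c0, c1 = int(np.floor(c - rad)), int(np.ceil(c + rad)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, h), min(c1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        hit = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        for ch in range(3):
            img[r0:r1, c0:c1, ch][hit] = tone[ch]


def render_image(mask_truth: np.ndarray, spec: SyntheticSpec) -> SyntheticSample:
    """Render the full synthetic sample on top of a ground-truth lesion mask.

    Background: homogeneous skin tone plus low-amplitude iid noise.
    Lesion: ``n_colors`` pigment tones laid out as nearest-seed cells, plus
    zero-mean spatially correlated noise of sd ``texture_contrast``.
    Artifacts: ``hair_count`` dark quadratic-Bezier strokes (width 1-3 px),
    ``bubble_count`` bright discs away from the lesion, and a black border
    ring of ``frame_width`` px.
    """
    spec.validate()
    streams = _streams(spec)
    h, w = spec.image_height, spec.image_width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = SKIN_TONE
    img += streams["noise"].normal(0.0, SKIN_NOISE_SD, size=(h, w, 3))

    # lesion pigment cells
    rng_c = streams["color"]
    ys, xs = np.nonzero(mask_truth)
    if ys.size:
        idx = rng_c.choice(ys.size, size=spec.n_colors, replace=ys.size < spec.n_colors)
        centers = np.stack([ys[idx], xs[idx]], axis=1).astype(float)
        d2 = (
            (ys[:, None] - centers[None, :, 0]) ** 2
            + (xs[:, None] - centers[None, :, 1]) ** 2
        )
        cell = np.argmin(d2, axis=1)
        palette = np.asarray(PIGMENT_PALETTE[: spec.n_colors])
        img[ys, xs] = palette[cell]

        if spec.texture_contrast > 0:
            raw = streams["noise"].normal(0.0, 1.0, size=(h, w))
            corr = ndimage.gaussian_filter(raw, sigma=2.0)
            sd = corr[mask_truth].std()
            if sd > 0:
                tex = corr * (spec.texture_contrast / sd)
                img[mask_truth] += tex[mask_truth][:, None]

    # air bubbles: bright discs kept clear of the lesion and the frame
    rng_b = streams["bubble"]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_max = spec.lesion_radius * (1.0 + spec.asymmetry_amp)
    rows, cols = np.mgrid[0:h, 0:w]
    for _ in range(spec.bubble_count):
        rad = rng_b.uniform(4.0, 7.0)
        for _attempt in range(50):
            br = rng_b.uniform(spec.frame_width + rad, h - spec.frame_width - rad)
            bc = rng_b.uniform(spec.frame_width + rad, w - spec.frame_width - rad)
            if np.hypot(br - cy, bc - cx) > r_max + rad + 6.0:
                break
        disc = (rows - br) ** 2 + (cols - bc) ** 2 <= rad**2
        img[disc] += _BUBBLE_OFFSET

    # hairs: dark quadratic Bezier strokes spanning the field of view
    rng_h = streams["hair"]
    for _ in range(spec.hair_count):
        p0 = rng_h.uniform([0, 0], [h - 1, w - 1])
        p2 = rng_h.uniform([0, 0], [h - 1, w - 1])
        while np.hypot(*(p2 - p0)) < 0.5 * min(h, w):
            p2 = rng_h.uniform([0, 0], [h - 1, w - 1])
        mid = (p0 + p2) / 2.0
        p1 = mid + rng_h.uniform(-0.25, 0.25, size=2) * np.array([h, w])
        width = rng_h.uniform(1.0, 3.0)
        pts = _quadratic_bezier(p0, p1, p2, n=4 * max(h, w))
        _paint_stroke(img, pts, width, _HAIR_TONE)

    if spec.frame_width > 0:
        fw = spec.frame_width
        img[:fw, :] = _FRAME_TONE
        img[-fw:, :] = _FRAME_TONE
        img[:, :fw] = _FRAME_TONE
        img[:, -fw:] = _FRAME_TONE

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSample(image=image, lesion_mask_truth=mask_truth, label=spec.label, spec=spec)


def generate_sample(spec: SyntheticSpec) -> SyntheticSample:
    """Shape + rendering in one call."""
    return render_image(generate_lesion_shape(spec), spec)


def _draw_class_params(rng: np.random.Generator, malignant: bool) -> dict:
    ranges = MALIGNANT_RANGES if malignant else BENIGN_RANGES
    lo, hi = ranges["asymmetry_amp"]
    asym = rng.uniform(lo, hi)
    lo, hi = ranges["n_colors"]
    ncol = int(rng.integers(lo, hi + 1))
    lo, hi = ranges["texture_contrast"]
    tex = rng.uniform(lo, hi)
    return {"asymmetry_amp": asym, "n_colors": ncol, "texture_contrast": tex}


def sample_spec(base_spec: SyntheticSpec, index: int, malignant: bool) -> SyntheticSpec:
    """Spec of sample ``index`` in a dataset keyed by ``base_spec.rng_seed``.

    Each sample owns one pseudo-random stream keyed by (seed, index), so
    dataset generation is order-independent and any sample can be recreated
    in isolation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([base_spec.rng_seed, index]))
    params = _draw_class_params(rng, malignant)
    sub_seed = int(rng.integers(0, 2**31 - 1))
    return replace(base_spec, rng_seed=sub_seed, **params)


def generate_dataset(
    n: int, malignant_fraction: float, base_spec: SyntheticSpec | None = None
) -> list[SyntheticSample]:
    """Generate ``n`` samples with ``round(n * malignant_fraction)`` malignant
    cases (drawn from the malignant parameter ranges) and the complement
    benign; fully reproducible from ``base_spec.rng_seed``."""
    if n < 2:
        raise ValueError("dataset needs at least 2 samples")
    if not (0.0 < malignant_fraction < 1.0):
        raise ValueError("malignant_fraction must lie strictly between 0 and 1")
    if base_spec is None:
        base_spec = SyntheticSpec()
    n_mal = int(round(n * malignant_fraction))
    samples = []
    for i in range(n):
        malignant = i < n_mal
        samples.append(generate_sample(sample_spec(base_spec, i, malignant)))
    return samples


def save_dataset(samples: list[SyntheticSample], out_dir: str | Path) -> None:
    """Write images/masks as PNG plus a labels CSV and a spec JSON sidecar."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        name = f"sample_{i:04d}"
        Image.fromarray(s.image).save(out / "images" / f"{name}.png")
        Image.fromarray((s.lesion_mask_truth * np.uint8(255))).save(
            out / "masks" / f"{name}.png"
        )
        rows.append({"image_id": name, "label": s.label})
        with open(out / "images" / f"{name}.json", "w") as fh:
            json.dump({k: getattr(s.spec, k) for k in s.spec.__dataclass_fields__}, fh)
    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["image_id", "label"])
        writer.writeheader()
        writer.writerows(rows)
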