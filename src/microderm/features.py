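"""Lesion feature bank: shape, asymmetry, color variegation, GLCM texture.

The feature vector quantifies the visual cues a dermatologist scores —
asymmetry of the border (symmetry distance), color count and spread
(per-channel log coefficient of variation), geometric irregularity
(moment-ellipse, bounding-box and convex-hull ratios) and textural pattern
(orientation-averaged Haralick statistics of the gray-level co-occurrence
matrix restricted to lesion pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from shapely.geometry import Polygon
from skimage.measure import regionprops

__all__ = [
    "FEATURE_NAMES",
    "GlcmMatrix",
    "ScalingParams",
    "FeatureTable",
    "shape_features",
    "resample_contour",
    "symmetry_distance",
    "intensity_channel",
    "color_variegation",
    "compute_glcm",
    "haralick_features",
    "texture_summary",
    "compute_features",
    "fit_scaling",
    "apply_scaling",
]

#: Floor for log(sigma/mu) when a channel is constant (sigma = 0).
CV_FLOOR = -10.0

HARALICK_NAMES = (
    "max_probability",
    "energy",
    "entropy",
    "dissimilarity",
    "contrast",
    "inverse_difference",
    "inverse_difference_moment",
    "correlation",
)

SHAPE_NAMES = (
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "elongation",
    "compactness",
    "rectangularity",
    "convexity",
    "solidity",
)

#: The full feature bank, in fixed order.
FEATURE_NAMES = (
    SHAPE_NAMES
    + ("symmetry_distance",)
    + ("cv_red", "cv_green", "cv_blue", "cv_intensity")
    + HARALICK_NAMES
    + ("entropy_variance", "ellipse_variance")
)

#: Single-pixel offsets (dx=column step, dy=row step) covering the four
#: orientations 0, 90, 45 and 135 degrees.
TEXTURE_OFFSETS = ((1, 0), (0, 1), (1, 1), (1, -1))


# --------------------------------------------------------------------------
# shape


def _contour_polygon(contour: np.ndarray) -> Polygon:
    """Polygon through boundary-pixel centers in (x, y) = (col, row); repaired
    if the raster trace self-touches."""
    poly = Polygon(contour[:, ::-1])
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda p: p.area)
    if poly.is_empty or poly.area <= 0:
        raise ValueError("contour does not enclose positive area")
    return poly


def shape_features(mask: np.ndarray, contour: np.ndarray) -> dict[str, float]:
    """Eight geometric descriptors of the lesion silhouette.

    eccentricity is the major/minor axis-length ratio of the second-moment
    ellipse; elongation is 1 - (short side / long side) of the minimum-area
    rotated bounding box; compactness is 4*pi*area/perimeter^2 (1 for a
    disc); rectangularity, convexity and solidity compare the region with its
    rotated bounding box and convex hull.
    """
    if int(np.count_nonzero(mask)) < 10:
        raise ValueError("degenerate mask: fewer than 10 pixels")
    rp = regionprops(mask.astype(np.uint8))[0]
    major = float(rp.axis_major_length)
    minor = float(rp.axis_minor_length)
    if minor <= 0:
        raise ValueError("degenerate mask: zero minor axis")

    poly = _contour_polygon(contour)
    hull = poly.convex_hull
    mrr = poly.minimum_rotated_rectangle
    xs, ys = mrr.exterior.coords.xy
    sides = np.hypot(np.diff(xs), np.diff(ys))[:2]
    short, long_ = float(min(sides)), float(max(sides))

    perim = float(rp.perimeter_crofton)  # unbiased on smooth digitized shapes
    compactness = min(4.0 * np.pi * rp.area / perim**2, 1.0) if perim > 0 else 0.0
    return {
        "major_axis_length": major,
        "minor_axis_length": minor,
        "eccentricity": major / minor,
        "elongation": 1.0 - short / long_ if long_ > 0 else 0.0,
        "compactness": float(compactness),
        "rectangularity": float(poly.area / mrr.area) if mrr.area > 0 else 0.0,
        "convexity": float(hull.exterior.length / poly.exterior.length),
        "solidity": float(rp.solidity),
    }


def ellipse_variance(mask: np.ndarray, contour: np.ndarray) -> float:
    """Normalized variance of the radial residuals between contour points and
    the second-moment fitted ellipse: Var(r_i - e(psi_i)) / mean(r_i)^2,
    where e(psi) is the ellipse radius along the contour point's direction
    in the ellipse frame. Zero for an exact ellipse."""
    rp = regionprops(mask.astype(np.uint8))[0]
    cy, cx = rp.centroid
    a = rp.axis_major_length / 2.0
    b = rp.axis_minor_length / 2.0
    if a <= 0 or b <= 0:
        raise ValueError("degenerate mask: cannot fit ellipse")
    # regionprops orientation: angle between the major axis and the row axis
    phi = rp.orientation
    dy = contour[:, 0] - cy
    dx = contour[:, 1] - cx
    # rotate into the ellipse frame (major axis -> u)
    u = dx * np.sin(phi) + dy * np.cos(phi)
    v = dx * np.cos(phi) - dy * np.sin(phi)
    r = np.hypot(u, v)
    psi = np.arctan2(v, u)
    e = (a * b) / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)
    mean_r = r.mean()
    if mean_r <= 0:
        raise ValueError("degenerate contour")
    return float(np.var(r - e) / mean_r**2)


# --------------------------------------------------------------------------
# symmetry distance


def resample_contour(contour: np.ndarray, n: int) -> np.ndarray:
    """``n`` points equally spaced by arc length along the closed contour,
    starting at the first vertex."""
    pts = np.asarray(contour, dtype=np.float64)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("contour has zero length")
    targets = np.arange(n) * total / n
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, cum, closed[:, 0])
    out[:, 1] = np.interp(targets, cum, closed[:, 1])
    return out


def _reflection(theta: float) -> np.ndarray:
    c, s = np.cos(2.0 * theta), np.sin(2.0 * theta)
    return np.array([[c, s], [s, -c]])


def _sd_cost(P: np.ndarray, Qrev: np.ndarray, idx: np.ndarray, theta: float) -> tuple[float, int]:
    """Min over cyclic pairings of the mean point-to-mirror distance / 2 for
    a mirror axis at angle ``theta``."""
    Qr = Qrev @ _reflection(theta).T
    d = np.linalg.norm(P[None, :, :] - Qr[idx], axis=2)  # (n_shift, n)
    costs = d.mean(axis=1) / 2.0
    s = int(np.argmin(costs))
    return float(costs[s]), s


def symmetry_distance(contour: np.ndarray, n: int = 64, n_angles: int = 180) -> float:
    """Mean displacement to the nearest mirror-symmetric shape.

    The contour is resampled to ``n`` equally spaced vertices, translated so
    the vertex centroid sits at the origin and scaled to unit mean vertex
    radius, making the value invariant to position, orientation and size.
    For each candidate mirror axis through the origin (coarse grid of
    ``n_angles`` over pi, then a local continuous refinement), the vertices
    are matched with their reflected, order-reversed images over all cyclic
    shifts; the nearest symmetric shape averages each matched pair, so the
    per-vertex displacement is half the pair distance. The reported value is
    the minimum over axes and pairings of the mean displacement.
    """
    if n < 8 or n % 2:
        raise ValueError("n must be an even integer >= 8")
    pts = np.asarray(contour, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError("contour needs at least 3 points")
    ring = Polygon(pts)
    if not ring.is_valid:
        raise ValueError("self-intersecting contour")

    P = resample_contour(pts, n)
    P = P - P.mean(axis=0)
    radii = np.linalg.norm(P, axis=1)
    mean_r = radii.mean()
    if mean_r <= 0:
        raise ValueError("degenerate contour: zero mean radius")
    P = P / mean_r

    Qrev = P[::-1].copy()  # reflection reverses orientation
    shifts = np.arange(n)
    idx = (shifts[:, None] + np.arange(n)[None, :]) % n

    thetas = np.arange(n_angles) * np.pi / n_angles
    best = (np.inf, 0.0, 0)
    for theta in thetas:
        cost, s = _sd_cost(P, Qrev, idx, theta)
        if cost < best[0]:
            best = (cost, theta, s)

    # refine the axis angle continuously around the best grid cell
    step = np.pi / n_angles
    _, theta0, _ = best
    res = minimize_scalar(
        lambda t: _sd_cost(P, Qrev, idx, t)[0],
        bounds=(theta0 - step, theta0 + step),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(min(best[0], res.fun))


# --------------------------------------------------------------------------
# color


def intensity_channel(image: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean norm of the (R, G, B) vector; range [0, 255*sqrt(3)]."""
    img = np.asarray(image, dtype=np.float64)
    return np.sqrt((img**2).sum(axis=2))


def color_variegation(image: np.ndarray, lesion: np.ndarray) -> dict[str, float]:
    """log(sigma/mu) of each of R, G, B and the intensity channel over lesion
    pixels (population standard deviation, natural log); a constant channel
    is floored at ``CV_FLOOR``."""
    if not lesion.any():
        raise ValueError("empty lesion mask")
    img = np.asarray(image, dtype=np.float64)
    channels = {
        "cv_red": img[..., 0][lesion],
        "cv_green": img[..., 1][lesion],
        "cv_blue": img[..., 2][lesion],
        "cv_intensity": intensity_channel(img)[lesion],
    }
    out = {}
    for name, vals in channels.items():
        mu = vals.mean()
        sigma = vals.std()  # population (divisor n)
        if sigma == 0 or mu == 0:
            out[name] = CV_FLOOR
        else:
            out[name] = float(max(np.log(sigma / mu), CV_FLOOR))
    return out


# --------------------------------------------------------------------------
# texture


@dataclass
class GlcmMatrix:
    """Symmetrized gray-level co-occurrence counts for one offset."""

    counts: np.ndarray  # levels x levels, non-negative ints
    levels: int
    offset: tuple[int, int]  # (dx, dy) = (column step, row step)

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of [0, 255] gray values into ``levels`` bins."""
    q = (np.asarray(gray, dtype=np.float64) * levels / 256.0).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    gray: np.ndarray,
    lesion: np.ndarray,
    offset: tuple[int, int],
    levels: int = 64,
) -> GlcmMatrix:
    """Co-occurrence counts of quantized gray levels at ``offset`` restricted
    to pixel pairs whose both endpoints lie inside the lesion mask; the
    matrix is symmetrized (each pair counted in both directions)."""
    if levels not in (64, 256):
        raise ValueError("levels must be 64 or 256")
    dx, dy = offset
    if (dx, dy) == (0, 0):
        raise ValueError("offset must be nonzero")
    q = quantize(gray, levels)
    h, w = q.shape

    r0s, r0e = max(0, -dy), min(h, h - dy)
    c0s, c0e = max(0, -dx), min(w, w - dx)
    a = q[r0s:r0e, c0s:c0e]
    b = q[r0s + dy : r0e + dy, c0s + dx : c0e + dx]
    ma = lesion[r0s:r0e, c0s:c0e]
    mb = lesion[r0s + dy : r0e + dy, c0s + dx : c0e + dx]
    valid = ma & mb
    if not valid.any():
        raise ValueError("lesion too small to contain any pixel pair at this offset")
    i, j = a[valid], b[valid]
    counts = np.bincount(i * levels + j, minlength=levels * levels).reshape(levels, levels)
    counts = counts + counts.T
    return GlcmMatrix(counts=counts, levels=levels, offset=(dx, dy))


def haralick_features(glcm: GlcmMatrix | np.ndarray) -> dict[str, float]:
    """Eight Haralick statistics of a normalized co-occurrence matrix.

    entropy uses base-2 logarithms (bits) with 0*log(0) := 0; correlation is
    defined as 0 when either marginal standard deviation vanishes (constant
    region)."""
    c = glcm.normalized() if isinstance(glcm, GlcmMatrix) else np.asarray(glcm, dtype=float)
    n = c.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    absdiff = np.abs(i - j)
    nz = c > 0

    px = c.sum(axis=1)
    py = c.sum(axis=0)
    mu_x = (np.arange(n) * px).sum()
    mu_y = (np.arange(n) * py).sum()
    sd_x = np.sqrt(((np.arange(n) - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((np.arange(n) - mu_y) ** 2 * py).sum())
    if sd_x > 0 and sd_y > 0:
        corr = float(((i * j * c).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        corr = 0.0
    return {
        "max_probability": float(c.max()),
        "energy": float((c**2).sum()),
        "entropy": float(-(c[nz] * np.log2(c[nz])).sum()),
        "dissimilarity": float((absdiff * c).sum()),
        "contrast": float((absdiff**2 * c).sum()),
        "inverse_difference": float((c / (1.0 + absdiff)).sum()),
        "inverse_difference_moment": float((c / (1.0 + absdiff**2)).sum()),
        "correlation": corr,
    }


def texture_summary(
    gray: np.ndarray, lesion: np.ndarray, levels: int = 64
) -> dict[str, float]:
    """Haralick features at the four single-pixel orientations, averaged, plus
    the variance of entropy across orientations (an anisotropy cue)."""
    per_offset = []
    for off in TEXTURE_OFFSETS:
        glcm = compute_glcm(gray, lesion, off, levels=levels)
        per_offset.append(haralick_features(glcm))
    out = {
        name: float(np.mean([f[name] for f in per_offset])) for name in HARALICK_NAMES
    }
    entropies = np.array([f["entropy"] for f in per_offset])
    out["entropy_variance"] = float(np.var(entropies))
    return out


# --------------------------------------------------------------------------
# assembly and scaling


def compute_features(
    image: np.ndarray,
    gray: np.ndarray,
    lesion: np.ndarray,
    contour: np.ndarray,
    levels: int = 64,
) -> dict[str, float]:
    """The full 23-entry feature vector for one lesion."""
    feats: dict[str, float] = {}
    feats.update(shape_features(lesion, contour))
    # raster traces may self-touch at 1-px spurs; hand SD a repaired ring
    ring = np.asarray(_contour_polygon(contour).exterior.coords)[:-1, ::-1]
    feats["symmetry_distance"] = symmetry_distance(ring)
    feats.update(color_variegation(image, lesion))
    feats.update(texture_summary(gray, lesion, levels=levels))
    feats["ellipse_variance"] = ellipse_variance(lesion, contour)
    return {name: feats[name] for name in FEATURE_NAMES}


@dataclass
class FeatureTable:
    """n_samples x n_features matrix with names and binary labels."""

    data: pd.DataFrame          # columns = feature names
    labels: np.ndarray          # 0 benign / 1 malignant

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.data) != len(self.labels):
            raise ValueError("data and labels disagree in length")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing cells")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_records(cls, records: list[dict[str, float]], labels) -> "FeatureTable":
        return cls(pd.DataFrame.from_records(records), np.asarray(labels))

    def subset(self, names) -> "FeatureTable":
        return FeatureTable(self.data[list(names)].copy(), self.labels.copy())

    def take(self, rows) -> "FeatureTable":
        rows = np.asarray(rows)
        return FeatureTable(
            self.data.iloc[rows].reset_index(drop=True), self.labels[rows]
        )

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        if "image_id" in df.columns:
            df = df.drop(columns=["image_id"])
        return cls(df, labels)


@dataclass
class ScalingParams:
    """Per-feature training min/max for the [-1, 1] affine rescaling."""

    minima: pd.Series
    maxima: pd.Series

    @property
    def constant(self) -> pd.Series:
        """Flags features whose training column was constant (max == min)."""
        return self.maxima == self.minima


def fit_scaling(table: FeatureTable) -> ScalingParams:
    if len(table.data) < 2:
        raise ValueError("need at least 2 samples to fit scaling")
    return ScalingParams(minima=table.data.min(), maxima=table.data.max())


def apply_scaling(
    data: FeatureTable | pd.DataFrame | dict, params: ScalingParams
) -> FeatureTable | pd.DataFrame | pd.Series:
    """x' = 2 (x - min) / (max - min) - 1 per feature.

    Training min maps to -1 and max to +1; out-of-range test values are not
    clipped. Constant training columns map to 0.
    """
    if isinstance(data, FeatureTable):
        return FeatureTable(apply_scaling(data.data, params), data.labels.copy())
    if isinstance(data, dict):
        data = pd.Series(data)
    span = params.maxima - params.minima
    safe = span.replace(0.0, 1.0)
    scaled = 2.0 * (data - params.minima) / safe - 1.0
    if isinstance(scaled, pd.DataFrame):
        scaled.loc[:, params.constant] = 0.0
    else:
        scaled[params.constant[scaled.index]] = 0.0
    return scaled
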