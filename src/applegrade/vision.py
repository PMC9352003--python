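"""Appearance measurement of round fruit from a single top-view RGB image.

The pipeline mirrors a conveyor-belt grading camera: gamma contrast
enhancement, Gaussian denoising, HSV-based separation of the fruit from a
light background, morphological cleanup, boundary extraction, and three
classifiers driven by scalar appearance measurements:

* defect pixel ratio ``t``  — dark-blemish area over total fruit area,
* aspect ratio ``lambda``   — max horizontal extent over max vertical extent,
* cross diameter ``Wp``     — twice the largest centroid-to-hull-vertex radius.

Conventions
-----------
Images are ``(V, U, 3)`` uint8 arrays; masks are boolean ``(V, U)`` arrays.
Pixel coordinates are 0-based with ``x`` = column and ``y`` = row; contour
points are pixel centers.  Physical calibration maps image pixels ``Wp`` to
millimetres ``Wr`` via an ordinary least-squares line, and the size grade
cutoffs (80 / 70 / 65 mm) are expressed in mm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError
from skimage.color import rgb2hsv
from skimage.morphology import disk

from .errors import DegenerateInputError, EmptyMaskError, InvalidParameterError

__all__ = [
    "VisionConfig",
    "ContourPolygon",
    "AppearanceResult",
    "SizeCalibration",
    "gamma_correct",
    "gaussian_smooth",
    "segment_fruit",
    "largest_contour",
    "extract_defects",
    "defect_ratio",
    "critical_defect_ratio",
    "classify_defect",
    "aspect_ratio",
    "classify_shape",
    "raw_moment",
    "contour_centroid",
    "max_cross_diameter",
    "fit_size_calibration",
    "size_thresholds",
    "classify_size",
    "measure_appearance",
]

# Luminance weights (ITU-R BT.601), the classic grey-level transform.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class VisionConfig:
    """Tunable parameters of the appearance pipeline.

    The classifier cutoffs (``defect_ratio_cutoff``, ``round_band``,
    ``size_thresholds_px``) implement the national-standard grade
    definitions; the remaining fields control preprocessing and were tuned
    on the synthetic renderer (a light background, red fruit, dark defects).
    """

    gamma: float = 1.2
    gaussian_sigma: float = 1.5
    #: background = pixels with saturation below / value above these bounds
    background_max_saturation: float = 0.25
    background_min_value: float = 0.55
    morph_radius: int = 3
    defect_grey_threshold: float = 60.0
    defect_ratio_cutoff: float = 0.0018
    round_band: tuple[float, float] = (0.98, 1.05)
    size_thresholds_px: tuple[int, int, int] = (164, 139, 127)

    def __post_init__(self) -> None:
        if self.defect_ratio_cutoff <= 0:
            raise InvalidParameterError("defect_ratio_cutoff must be positive")
        lo, hi = self.round_band
        if not lo < hi:
            raise InvalidParameterError("round_band must satisfy low < high")
        xl, lg, md = self.size_thresholds_px
        if not xl > lg > md:
            raise InvalidParameterError("size thresholds must be strictly decreasing")


@dataclass(frozen=True)
class ContourPolygon:
    """Closed fruit boundary: ordered pixel-center points plus the centroid
    of the enclosed region (sub-pixel, from first-order moments)."""

    points: np.ndarray  # (K, 2) float, columns (x, y)
    centroid: tuple[float, float]


@dataclass(frozen=True)
class AppearanceResult:
    """The three appearance measurements with their grade labels."""

    defect_ratio: float
    aspect_ratio: float
    diameter_px: float
    defect_label: str  # normal | defective
    shape_label: str  # nearly_round | nearly_oval
    size_label: str  # extra_large | large | medium | small

    def to_dict(self) -> dict:
        return {
            "defect_ratio": self.defect_ratio,
            "aspect_ratio": self.aspect_ratio,
            "diameter_px": self.diameter_px,
            "defect_label": self.defect_label,
            "shape_label": self.shape_label,
            "size_label": self.size_label,
        }


@dataclass(frozen=True)
class SizeCalibration:
    """OLS line mapping image diameter (px) to caliper diameter (mm)."""

    slope: float  # mm per pixel
    intercept: float  # mm
    r_squared: float
    residual_variance: float  # mm^2, SSE / (n - 2)
    n_pairs: int


def _as_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError("expected a (V, U, 3) RGB array")
    return img


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law contrast enhancement ``v -> 255 (v/255)^gamma`` per channel."""
    if not gamma > 0:
        raise InvalidParameterError(f"gamma must be positive, got {gamma}")
    img = _as_image(image).astype(np.float64) / 255.0
    out = 255.0 * np.power(img, gamma)
    return np.rint(out).clip(0, 255).astype(np.uint8)


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Per-channel Gaussian filtering with reflective boundary handling."""
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    img = _as_image(image).astype(np.float64)
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(img[..., c], sigma, mode="reflect")
    return np.rint(out).clip(0, 255).astype(np.uint8)


def segment_fruit(image: np.ndarray, config: VisionConfig | None = None) -> np.ndarray:
    """Separate fruit from a light background.

    The image is converted to HSV; low-saturation high-value pixels are
    declared background and the fruit is the complement.  Opening removes
    stray foreground specks, closing bridges boundary nicks, and interior
    holes (specular highlights, the fruit tip) are filled.  An image that is
    all background yields an all-zero mask.
    """
    cfg = config or VisionConfig()
    hsv = rgb2hsv(_as_image(image))
    background = (hsv[..., 1] <= cfg.background_max_saturation) & (
        hsv[..., 2] >= cfg.background_min_value
    )
    fruit = ~background
    if cfg.morph_radius > 0:
        foot = disk(cfg.morph_radius)
        fruit = ndimage.binary_opening(fruit, structure=foot)
        fruit = ndimage.binary_closing(fruit, structure=foot)
    return ndimage.binary_fill_holes(fruit)


_EIGHT = np.ones((3, 3), dtype=bool)

# Moore neighbourhood, clockwise starting east: (dy, dx)
_MOORE = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


def _trace_boundary(component: np.ndarray) -> np.ndarray:
    """Moore boundary following (8-connectivity) around one connected
    component; returns ordered unique boundary pixels as (x, y) rows."""
    padded = np.pad(component, 1)
    ys, xs = np.nonzero(padded)
    order = np.lexsort((xs, ys))  # row-major: topmost, then leftmost
    y0, x0 = int(ys[order[0]]), int(xs[order[0]])

    pts: list[tuple[int, int]] = []
    y, x, d = y0, x0, 0  # d = direction of the move that entered (y, x)
    first_move: tuple[int, int, int] | None = None
    while True:
        if not pts or pts[-1] != (y, x):
            pts.append((y, x))
        moved = False
        for i in range(8):
            nd = (d + 6 + i) % 8  # resume scan just past the backtrack pixel
            ny, nx = y + _MOORE[nd][0], x + _MOORE[nd][1]
            if padded[ny, nx]:
                if first_move is None:
                    first_move = (ny, nx, nd)
                elif (ny, nx, nd) == first_move:
                    if len(pts) > 1 and pts[-1] == pts[0]:
                        pts.pop()
                    xy = np.array([(px - 1, py - 1) for py, px in pts], dtype=float)
                    return xy
                y, x, d = ny, nx, nd
                moved = True
                break
        if not moved:  # isolated single pixel
            return np.array([(x0 - 1, y0 - 1)], dtype=float)


def largest_contour(mask: np.ndarray) -> ContourPolygon:
    """Boundary of the 8-connected component with the largest pixel area.

    Ties are broken by first occurrence in row-major scan order (the label
    numbering of ``scipy.ndimage.label``).
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise EmptyMaskError("mask has no foreground pixels")
    labels, n = ndimage.label(m, structure=_EIGHT)
    counts = np.bincount(labels.ravel())[1:]  # label 1..n
    best = int(np.argmax(counts)) + 1  # argmax keeps the earliest label on ties
    comp = labels == best
    points = _trace_boundary(comp)
    xc, yc = contour_centroid(comp)
    return ContourPolygon(points=points, centroid=(xc, yc))


def extract_defects(
    image: np.ndarray, fruit_mask: np.ndarray, config: VisionConfig | None = None
) -> np.ndarray:
    """Dark-blemish mask: pixels inside the fruit whose grey level falls
    below ``defect_grey_threshold``.  Always a subset of ``fruit_mask``."""
    cfg = config or VisionConfig()
    fm = np.asarray(fruit_mask).astype(bool)
    if not fm.any():
        raise EmptyMaskError("fruit mask is empty")
    grey = _as_image(image).astype(np.float64) @ _LUMA
    return (grey < cfg.defect_grey_threshold) & fm


def defect_ratio(defect_mask: np.ndarray, fruit_mask: np.ndarray) -> float:
    """Defect pixel count over fruit pixel count, ``t`` in [0, 1]."""
    fm = np.asarray(fruit_mask).astype(bool)
    dm = np.asarray(defect_mask).astype(bool)
    n_fruit = int(fm.sum())
    if n_fruit == 0:
        raise EmptyMaskError("fruit mask is empty; defect ratio undefined")
    if (dm & ~fm).any():
        raise InvalidParameterError("defect mask must be a subset of the fruit mask")
    return float(dm.sum()) / n_fruit


def critical_defect_ratio(defect_diameter_mm: float = 3.0, fruit_diameter_mm: float = 70.0) -> float:
    """Critical area ratio ``t0 = (d0/d1)^2`` below which a blemish is
    tolerated: a 3 mm spot on a 70 mm fruit gives 0.18%."""
    if defect_diameter_mm <= 0 or fruit_diameter_mm <= 0:
        raise InvalidParameterError("diameters must be positive")
    return (defect_diameter_mm / fruit_diameter_mm) ** 2


def classify_defect(t: float, config: VisionConfig | None = None) -> str:
    """``normal`` below the critical ratio, ``defective`` at or above it."""
    cfg = config or VisionConfig()
    if not 0.0 <= t <= 1.0:
        raise InvalidParameterError(f"defect ratio must lie in [0, 1], got {t}")
    return "defective" if t >= cfg.defect_ratio_cutoff else "normal"


def aspect_ratio(contour: ContourPolygon) -> float:
    """Max horizontal pixel extent over max vertical pixel extent of the
    boundary points (extent counts pixels, i.e. max - min + 1)."""
    pts = np.asarray(contour.points, dtype=float)
    if pts.ndim != 2 or len(pts) < 1:
        raise InvalidParameterError("contour has no points")
    ext_x = pts[:, 0].max() - pts[:, 0].min() + 1.0
    ext_y = pts[:, 1].max() - pts[:, 1].min() + 1.0
    if ext_y <= 0:
        raise DegenerateInputError("contour has zero vertical extent")
    return float(ext_x / ext_y)


def classify_shape(lam: float, config: VisionConfig | None = None) -> str:
    """``nearly_round`` inside the round band [0.98, 1.05), else ``nearly_oval``."""
    cfg = config or VisionConfig()
    if not lam > 0:
        raise InvalidParameterError(f"aspect ratio must be positive, got {lam}")
    lo, hi = cfg.round_band
    return "nearly_round" if lo <= lam < hi else "nearly_oval"


def raw_moment(mask: np.ndarray, p: int, q: int) -> float:
    """Raw image moment ``m_pq = sum_y sum_x x^p y^q f(x, y)``."""
    if p < 0 or q < 0:
        raise InvalidParameterError("moment orders must be non-negative")
    a = np.asarray(mask, dtype=np.float64)
    ys, xs = np.nonzero(a)
    return float(np.sum(xs**p * ys**q * a[ys, xs]))


def contour_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid ``(m10/m00, m01/m00)`` of a binary region."""
    m00 = raw_moment(mask, 0, 0)
    if m00 == 0:
        raise EmptyMaskError("empty mask has no centroid")
    return raw_moment(mask, 1, 0) / m00, raw_moment(mask, 0, 1) / m00


def max_cross_diameter(contour: ContourPolygon) -> float:
    """Largest cross diameter ``Wp = 2 max_k r_k`` in pixels.

    ``r_k`` is the centroid-to-boundary radius sequence; the maximum is
    attained at a convex-hull vertex, so only hull vertices are scanned
    (falling back to all points for degenerate geometry)."""
    pts = np.asarray(contour.points, dtype=float)
    if len(pts) == 0:
        raise InvalidParameterError("contour has no points")
    if len(pts) == 1:
        return 0.0
    cx, cy = contour.centroid
    candidates = pts
    if len(np.unique(pts, axis=0)) >= 3:
        try:
            hull = ConvexHull(pts)
            candidates = pts[hull.vertices]
        except QhullError:  # collinear points
            pass
    r = np.hypot(candidates[:, 0] - cx, candidates[:, 1] - cy)
    return float(2.0 * r.max())


def fit_size_calibration(pairs) -> SizeCalibration:
    """OLS regression of caliper diameter Wr (mm) on image diameter Wp (px)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise InvalidParameterError("need >= 2 (Wp, Wr) pairs")
    wp, wr = arr[:, 0], arr[:, 1]
    if np.ptp(wp) == 0:
        raise DegenerateInputError("all Wp identical; calibration fit is singular")
    res = stats.linregress(wp, wr)
    fitted = res.slope * wp + res.intercept
    sse = float(np.sum((wr - fitted) ** 2))
    dof = max(len(arr) - 2, 1)
    return SizeCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_variance=sse / dof,
        n_pairs=len(arr),
    )


def size_thresholds(
    cal: SizeCalibration, cutoffs_mm: tuple[float, ...] = (80.0, 70.0, 65.0)
) -> tuple[int, ...]:
    """Invert the calibration line at the mm grade cutoffs, rounding to the
    nearest integer pixel.  The default cutoffs are the national-standard
    8 / 7 / 6.5 cm class boundaries expressed in mm."""
    if cal.slope == 0:
        raise DegenerateInputError("zero slope; cannot invert calibration")
    return tuple(int(round((w - cal.intercept) / cal.slope)) for w in cutoffs_mm)


def classify_size(wp: float, config: VisionConfig | None = None) -> str:
    """Four-way size grade from the image diameter Wp (pixels)."""
    cfg = config or VisionConfig()
    if wp < 0:
        raise InvalidParameterError(f"diameter must be non-negative, got {wp}")
    xl, lg, md = cfg.size_thresholds_px
    if wp >= xl:
        return "extra_large"
    if wp >= lg:
        return "large"
    if wp >= md:
        return "medium"
    return "small"


def measure_appearance(
    image: np.ndarray,
    config: VisionConfig | None = None,
    return_masks: bool = False,
):
    """Full appearance pipeline: preprocess, segment, measure, classify.

    Returns an :class:`AppearanceResult`; with ``return_masks=True`` also
    returns ``(fruit_mask, defect_mask)`` for inspection.
    """
    cfg = config or VisionConfig()
    img = gamma_correct(image, cfg.gamma)
    img = gaussian_smooth(img, cfg.gaussian_sigma)
    fruit = segment_fruit(img, cfg)
    contour = largest_contour(fruit)
    defects = extract_defects(img, fruit, cfg)
    t = defect_ratio(defects, fruit)
    lam = aspect_ratio(contour)
    wp = max_cross_diameter(contour)
    result = AppearanceResult(
        defect_ratio=t,
        aspect_ratio=lam,
        diameter_px=wp,
        defect_label=classify_defect(t, cfg),
        shape_label=classify_shape(lam, cfg),
        size_label=classify_size(wp, cfg),
    )
    if return_masks:
        return result, (fruit, defects)
    return result
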