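"""Synthetic fixtures with known ground truth.

Two generators stand in for the physical acquisition rigs:

* :func:`render_apple` draws a near-round red fruit on a light background —
  an axis-aligned ellipse with mild radial shading, optional dark defect
  blobs and an optional specular highlight — and returns the appearance
  measurements implied by the drawn geometry.

* :func:`simulate_spectra` emits diffuse-reflectance spectra on a 400–1000
  nm grid (1771 points by default) whose absorption-band depths are linear
  in a per-sample Brix value drawn from a truncated normal matching the
  reference population (mean 11.7, SD 1.1, range 8.9–14.6 °Brix), corrupted
  by fixed-shape interferent bands with random per-sample amplitudes,
  multiplicative/additive scatter, and white noise.

Both are pure functions of their spec (the seed included): identical spec
means identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidParameterError, RenderError
from .vision import (
    AppearanceResult,
    VisionConfig,
    classify_defect,
    classify_shape,
    classify_size,
)

__all__ = [
    "ImageSpec",
    "SpectraSpec",
    "render_apple",
    "sample_image_specs",
    "simulate_spectra",
    "make_calibration_pairs",
]


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and blemish parameters of one rendered fruit."""

    diameter_px: float = 150.0  # horizontal axis of the ellipse
    aspect: float = 1.0  # horizontal / vertical extent
    defect_fraction: float = 0.0  # target t
    n_defect_blobs: int = 1
    highlight: bool = False
    background_level: int = 245
    frame: tuple[int, int] | None = None  # (height, width); auto-sized if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_px < 20:
            raise InvalidParameterError("diameter_px must be >= 20")
        if not self.aspect > 0:
            raise InvalidParameterError("aspect must be positive")
        if not 0.0 <= self.defect_fraction <= 0.2:
            raise InvalidParameterError("defect_fraction must lie in [0, 0.2]")
        if self.n_defect_blobs < 1:
            raise InvalidParameterError("need at least one blob slot")


_FRUIT_RGB = np.array([205.0, 60.0, 48.0])
_DEFECT_RGB = _FRUIT_RGB * 0.35  # ~35% of fruit luminance: well below grey threshold
_HIGHLIGHT_RGB = np.array([250.0, 248.0, 244.0])
_MARGIN = 20


def render_apple(
    spec: ImageSpec, config: VisionConfig | None = None
) -> tuple[np.ndarray, AppearanceResult]:
    """Draw one fruit; return the uint8 RGB image and the ground-truth
    appearance (t, lambda, Wp and labels from the drawn raster)."""
    cfg = config or VisionConfig()
    rng = np.random.default_rng(spec.seed)
    a = spec.diameter_px / 2.0
    b = spec.diameter_px / (2.0 * spec.aspect)
    if spec.frame is None:
        height = int(math.ceil(2 * b)) + 2 * _MARGIN
        width = int(math.ceil(2 * a)) + 2 * _MARGIN
    else:
        height, width = spec.frame
        if 2 * a > width - 4 or 2 * b > height - 4:
            raise RenderError("fruit does not fit inside the requested frame")
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0

    yy, xx = np.mgrid[0:height, 0:width]
    rho2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    fruit = rho2 <= 1.0
    if not fruit.any():
        raise RenderError("degenerate geometry: no fruit pixels")

    img = np.empty((height, width, 3), dtype=float)
    img[:] = [spec.background_level, spec.background_level - 2, spec.background_level - 6]
    shade = 1.0 - 0.08 * np.clip(rho2, 0.0, 1.0)
    img[fruit] = _FRUIT_RGB * shade[fruit][:, None]

    if spec.highlight:
        hr = max(2.0, 0.05 * min(a, b))
        hx, hy = cx - 0.35 * a, cy - 0.3 * b
        hl = (xx - hx) ** 2 + (yy - hy) ** 2 <= hr**2
        img[hl & fruit] = _HIGHLIGHT_RGB

    defect_mask = np.zeros((height, width), dtype=bool)
    n_fruit = int(fruit.sum())
    target = spec.defect_fraction * n_fruit
    if target >= 1.0:
        per_blob = target / spec.n_defect_blobs
        for _ in range(spec.n_defect_blobs):
            r = max(1.0, math.sqrt(per_blob / math.pi))
            # uniform position in a shrunken ellipse so the blob stays inside
            theta = rng.uniform(0.0, 2.0 * math.pi)
            u = math.sqrt(rng.uniform())
            px = cx + u * max(a - r - 2.0, 0.0) * math.cos(theta)
            py = cy + u * max(b - r - 2.0, 0.0) * math.sin(theta)
            blob = (xx - px) ** 2 + (yy - py) ** 2 <= r**2
            defect_mask |= blob & fruit
        img[defect_mask] = _DEFECT_RGB

    img += rng.normal(0.0, 2.0, size=img.shape)  # mild sensor noise
    image = np.rint(img).clip(0, 255).astype(np.uint8)

    ys, xs = np.nonzero(fruit)
    ext_x = float(xs.max() - xs.min() + 1)
    ext_y = float(ys.max() - ys.min() + 1)
    t_true = float(defect_mask.sum()) / n_fruit
    lam_true = ext_x / ext_y
    wp_true = max(ext_x, ext_y)
    truth = AppearanceResult(
        defect_ratio=t_true,
        aspect_ratio=lam_true,
        diameter_px=wp_true,
        defect_label=classify_defect(t_true, cfg),
        shape_label=classify_shape(lam_true, cfg),
        size_label=classify_size(wp_true, cfg),
    )
    return image, truth


def sample_image_specs(n: int, seed: int = 0, class_margin: bool = True) -> list[ImageSpec]:
    """Randomized fixture specs spanning all defect/shape/size classes.

    With ``class_margin`` (the default) parameters stay clear of the
    classifier cut points — a few pixels of diameter, ~0.015 of aspect
    ratio, a factor ~2 of defect ratio — emulating a study population of
    unambiguous class members rather than borderline fruit.
    """
    rng = np.random.default_rng(seed)
    cfg = VisionConfig()
    cuts = cfg.size_thresholds_px
    specs = []
    for _ in range(n):
        d = float(rng.uniform(105, 190))
        if class_margin:
            while min(abs(d - c) for c in cuts) < 4.0:
                d = float(rng.uniform(105, 190))
        if rng.uniform() < 0.5:  # nearly round
            aspect = float(rng.uniform(0.995, 1.035))
        elif rng.uniform() < 0.5:  # oval, squat
            aspect = float(rng.uniform(1.065, 1.13))
        else:  # oval, tall
            aspect = float(rng.uniform(0.90, 0.965))
        if rng.uniform() < 0.5:
            frac = 0.0 if rng.uniform() < 0.5 else float(rng.uniform(0.0, 0.0007))
        else:
            frac = float(rng.uniform(0.004, 0.015))
        specs.append(
            ImageSpec(
                diameter_px=d,
                aspect=aspect,
                defect_fraction=frac,
                n_defect_blobs=int(rng.integers(1, 4)),
                highlight=bool(rng.uniform() < 0.5),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return specs


@dataclass(frozen=True)
class SpectraSpec:
    """Population and noise model for simulated apple spectra."""

    n_samples: int = 168
    n_wavelengths: int = 1771
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    brix_mean: float = 11.7  # °Brix
    brix_sd: float = 1.1
    brix_range: tuple[float, float] = (8.9, 14.6)
    #: centers (nm) of the Brix-linked absorption bands (sugar C-H / O-H overtones)
    band_centers: tuple[float, ...] = (680.0, 760.0, 840.0, 912.0, 962.0)
    band_widths: tuple[float, ...] = (8.0, 10.0, 8.0, 12.0, 10.0)  # nm (Gaussian sigma)
    band_gains: tuple[float, ...] = (0.020, 0.030, 0.022, 0.032, 0.026)  # depth per °Brix
    n_interferents: int = 8
    interferent_amp_sd: float = 0.015
    #: interferent absorption centers keep this distance from the sugar bands
    interferent_min_offset_nm: float = 25.0
    interferent_width_range: tuple[float, float] = (10.0, 30.0)  # nm (Gaussian sigma)
    scatter_on: bool = True
    scatter_slope_sd: float = 0.08
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.003
    #: extra detector noise where the lamp/detector energy is low, i.e.
    #: outside [edge_noise_limits]: reflectance = (I-Id)/(Iw-Id) amplifies
    #: counting noise wherever Iw-Id is small
    edge_noise_sd: float = 0.06
    edge_noise_limits: tuple[float, float] = (660.0, 985.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise InvalidParameterError("n_samples must be >= 4")
        lo, hi = self.wavelength_range
        if not all(lo <= c <= hi for c in self.band_centers):
            raise InvalidParameterError("band centers must lie inside the wavelength range")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_gains)):
            raise InvalidParameterError("band centers/widths/gains must have equal length")


def _baseline(wl: np.ndarray) -> np.ndarray:
    s = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.78 - 0.15 * s + 0.06 * np.exp(-(((wl - 560.0) / 130.0) ** 2))


def simulate_spectra(spec: SpectraSpec):
    """Generate a reference-labelled :class:`SpectraSet` plus ground truth.

    Truth dict keys: ``clean`` (noise/scatter-free matrix),
    ``scatter_slope`` / ``scatter_offset`` (per-sample b_i, a_i), and
    ``band_indices`` (wavelength indices within one sigma of a band center).
    """
    from .chemometrics.preprocess import SpectraSet

    rng = np.random.default_rng(spec.seed)
    wl = np.linspace(*spec.wavelength_range, spec.n_wavelengths)
    lo, hi = spec.brix_range
    brix = stats.truncnorm.rvs(
        (lo - spec.brix_mean) / spec.brix_sd,
        (hi - spec.brix_mean) / spec.brix_sd,
        loc=spec.brix_mean,
        scale=spec.brix_sd,
        size=spec.n_samples,
        random_state=rng,
    )

    bands = np.stack(
        [np.exp(-0.5 * ((wl - c) / w) ** 2) for c, w in zip(spec.band_centers, spec.band_widths)]
    )  # (B, W)
    gains = np.asarray(spec.band_gains)
    clean = _baseline(wl)[None, :] - (brix[:, None] * (gains @ bands))

    observed = clean.copy()
    if spec.n_interferents > 0:
        # fixed interferent species, random per-sample concentrations;
        # their absorption centers sit away from the sugar bands
        bc = np.asarray(spec.band_centers)
        centers = np.empty(spec.n_interferents)
        for k in range(spec.n_interferents):
            c = rng.uniform(*spec.wavelength_range)
            while np.min(np.abs(c - bc)) < spec.interferent_min_offset_nm:
                c = rng.uniform(*spec.wavelength_range)
            centers[k] = c
        widths = rng.uniform(*spec.interferent_width_range, size=spec.n_interferents)
        shapes = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / widths[:, None]) ** 2)
        amps = rng.normal(0.0, spec.interferent_amp_sd, size=(spec.n_samples, spec.n_interferents))
        observed = observed + amps @ shapes

    if spec.scatter_on:
        b = rng.normal(1.0, spec.scatter_slope_sd, size=spec.n_samples)
        a = rng.normal(0.0, spec.scatter_offset_sd, size=spec.n_samples)
        observed = b[:, None] * observed + a[:, None]
    else:
        b = np.ones(spec.n_samples)
        a = np.zeros(spec.n_samples)

    if spec.noise_sd > 0:
        observed = observed + rng.normal(0.0, spec.noise_sd, size=observed.shape)
    if spec.edge_noise_sd > 0:
        lo_nm, hi_nm = spec.edge_noise_limits
        edge = (wl < lo_nm) | (wl > hi_nm)
        observed[:, edge] += rng.normal(0.0, spec.edge_noise_sd, size=(spec.n_samples, int(edge.sum())))

    band_indices = np.nonzero(
        np.any(
            np.abs(wl[None, :] - np.asarray(spec.band_centers)[:, None])
            <= np.asarray(spec.band_widths)[:, None],
            axis=0,
        )
    )[0]
    truth = {
        "clean": clean,
        "scatter_slope": b,
        "scatter_offset": a,
        "band_indices": band_indices,
    }
    return SpectraSet(wavelengths=wl, reflectance=observed, brix=brix), truth


def make_calibration_pairs(
    n: int,
    slope: float = 0.4052,
    intercept: float = 13.5015,
    noise_sd: float = 2.0,
    seed: int = 0,
    wp_range: tuple[float, float] = (110.0, 200.0),
) -> np.ndarray:
    """(Wp px, Wr mm) pairs from a linear caliper model with Gaussian
    measurement noise; feeds the size-calibration regression."""
    if n < 2:
        raise InvalidParameterError("need at least 2 pairs")
    rng = np.random.default_rng(seed)
    wp = rng.uniform(*wp_range, size=n)
    wr = slope * wp + intercept + rng.normal(0.0, noise_sd, size=n)
    return np.column_stack([wp, wr])
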