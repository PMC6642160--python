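"""Synthetic fixtures for the whole pipeline.

Real inputs are H&E whole-slide images plus TCGA-style clinical tables.
Everything here emulates just the properties the pipeline depends on:

* slides with a near-white background and textured tissue, where a
  designated "tumor" texture has a known ground-truth pixel mask;
* images of dark elliptical nuclei with analytically known geometry;
* well-separated Gaussian embedding clusters standing in for the
  penultimate-layer representation of a trained network;
* survival cohorts with exponential event times under a known
  proportional-hazards structure and independent censoring.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse
from skimage.filters import gaussian as _gaussian

__all__ = [
    "TextureParams",
    "SyntheticSlideSpec",
    "SyntheticCohortSpec",
    "generate_slide",
    "generate_nuclei_image",
    "generate_embedding_clusters",
    "generate_survival_cohort",
]


@dataclass
class TextureParams:
    """Appearance of one tissue class.

    blob_density is in blobs per 10^4 px^2; blob radii in pixels; base_color
    is the mean RGB of the tissue (kept below the background threshold so
    tissue patches survive background filtering).
    """

    blob_density: float = 8.0
    blob_radius: tuple[float, float] = (3.0, 8.0)
    base_color: tuple[int, int, int] = (180, 140, 170)
    noise_sigma: float = 8.0


@dataclass
class SyntheticSlideSpec:
    width: int = 1024
    height: int = 1024
    tissue_classes: list[str] = field(default_factory=lambda: ["tumor", "normal"])
    background_level: int = 245
    textures: dict[str, TextureParams] | None = None
    tumor_fraction: float = 0.5
    tissue_fraction: float = 0.8
    label: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.background_level <= 210:
            raise ValueError(
                "background_level must exceed 210 so background patches trip the filter"
            )
        if self.textures is None:
            # tumor: purple-ish dense texture; normal: pink sparse texture
            self.textures = {
                "tumor": TextureParams(blob_density=12.0, base_color=(150, 110, 160)),
                "normal": TextureParams(blob_density=5.0, base_color=(200, 160, 180)),
            }
        for cls in self.tissue_classes:
            if cls not in self.textures:
                raise ValueError(f"no texture parameters for class {cls!r}")


def _render_texture(rng: np.random.Generator, shape: tuple[int, int],
                    params: TextureParams) -> np.ndarray:
    """Tissue texture: base color + Gaussian noise + dark elliptical blobs."""
    h, w = shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(params.base_color, dtype=np.float64)
    img += rng.normal(0.0, params.noise_sigma, size=(h, w, 3))
    n_blobs = rng.poisson(params.blob_density * h * w / 1e4)
    rmin, rmax = params.blob_radius
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(rmin, rmax)
        b = rng.uniform(rmin, rmax)
        rr, cc = _draw_ellipse(cy, cx, a, b, shape=(h, w),
                               rotation=rng.uniform(0, np.pi))
        img[rr, cc] *= 0.45  # dark basophilic blob
    return img


def generate_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, np.ndarray, str]:
    """Render a synthetic slide.

    Returns ``(rgb, tumor_mask, label)``: an ``(H, W, 3)`` uint8 image with a
    near-white border and a central textured tissue block, a boolean mask
    marking exactly the pixels rendered with the tumor texture, and the slide
    label (``spec.label`` or the majority texture class).

    The tissue block occupies ``tissue_fraction`` of each dimension; the left
    part of it, sized to ``tumor_fraction`` of the tissue area, carries the
    tumor texture.
    """
    if spec.width < 1 or spec.height < 1:
        raise ValueError("slide dimensions must be positive")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    img = np.empty((h, w, 3), dtype=np.float64)
    bg = rng.normal(spec.background_level, 2.0, size=(h, w, 3))
    img[:] = np.clip(bg, 212, 255)  # strictly above the 210 filter threshold

    # central tissue rectangle
    th = int(round(h * spec.tissue_fraction))
    tw = int(round(w * spec.tissue_fraction))
    y0, x0 = (h - th) // 2, (w - tw) // 2
    tumor_mask = np.zeros((h, w), dtype=bool)

    if th > 0 and tw > 0:
        split = int(round(tw * spec.tumor_fraction))
        if split > 0:
            tex = _render_texture(rng, (th, split), spec.textures["tumor"])
            img[y0:y0 + th, x0:x0 + split] = tex
            tumor_mask[y0:y0 + th, x0:x0 + split] = True
        if split < tw:
            tex = _render_texture(rng, (th, tw - split), spec.textures["normal"])
            img[y0:y0 + th, x0 + split:x0 + tw] = tex

    label = spec.label
    if label is None:
        label = "tumor" if spec.tumor_fraction >= 0.5 else "normal"
    return np.clip(img, 0, 255).astype(np.uint8), tumor_mask, label


def generate_nuclei_image(
    n_nuclei: int,
    axis_range: tuple[float, float] = (5.0, 12.0),
    shape: tuple[int, int] = (512, 512),
    background_level: int = 235,
    nucleus_level: int = 60,
    blur_sigma: float = 0.8,
    max_tries: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render non-overlapping dark ellipses on a light background.

    Returns the RGB image and a ground-truth table with one row per nucleus:
    center, semi-axes ``a >= b``, orientation, analytic ``area = pi*a*b`` and
    axis lengths ``2a``, ``2b``.  Placement uses rejection sampling on
    bounding circles; raises ``RuntimeError`` if ``n_nuclei`` cannot be
    placed within ``max_tries`` attempts.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full((h, w), float(background_level))
    rows: list[dict] = []
    centers: list[tuple[float, float, float]] = []  # (y, x, bounding radius)

    tries = 0
    while len(rows) < n_nuclei:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_nuclei} non-overlapping nuclei "
                f"(placed {len(rows)} after {max_tries} attempts)"
            )
        tries += 1
        a = rng.uniform(*axis_range)
        b = rng.uniform(axis_range[0], a)
        theta = rng.uniform(0, np.pi)
        margin = a + 2.0
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if any((cy - y) ** 2 + (cx - x) ** 2 < (a + r + 2.0) ** 2
               for y, x, r in centers):
            continue
        rr, cc = _draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        img[rr, cc] = nucleus_level
        centers.append((cy, cx, a))
        rows.append({
            "nucleus_id": len(rows),
            "cy": cy, "cx": cx,
            "semi_major": a, "semi_minor": b,
            "orientation": theta,
            "area": np.pi * a * b,
            "major_axis": 2 * a, "minor_axis": 2 * b,
        })

    img += rng.normal(0.0, 2.0, size=img.shape)
    if blur_sigma > 0:
        img = _gaussian(img, sigma=blur_sigma, preserve_range=True)
    img = np.clip(img, 0, 255).astype(np.uint8)
    rgb = np.repeat(img[:, :, None], 3, axis=2)
    table = pd.DataFrame(rows, columns=[
        "nucleus_id", "cy", "cx", "semi_major", "semi_minor",
        "orientation", "area", "major_axis", "minor_axis",
    ])
    return rgb, table


def generate_embedding_clusters(
    n_classes: int,
    n_per_class: int,
    dim: int = 512,
    separation: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spherical unit-variance Gaussian clusters at mutually equidistant centers.

    ``separation`` is the pairwise center distance in units of the
    within-class standard deviation.  Centers sit on scaled standard-basis
    vectors (pairwise distance sqrt(2) before scaling), so every pair of
    classes is exactly ``separation`` apart.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if dim < n_classes:
        raise ValueError("dim must be >= n_classes for equidistant centers")
    rng = np.random.default_rng(seed)
    centers = np.eye(n_classes, dim) * (separation / np.sqrt(2.0))
    X = np.empty((n_classes * n_per_class, dim))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for k in range(n_classes):
        block = slice(k * n_per_class, (k + 1) * n_per_class)
        X[block] = centers[k] + rng.standard_normal((n_per_class, dim))
    return X, y


@dataclass
class SyntheticCohortSpec:
    n_patients: int = 200
    n_features: int = 1
    beta: np.ndarray | list[float] | None = None
    baseline_rate: float = 1.0 / 1000.0  # per day; median ~ 700 days
    censor_rate: float = 0.3
    covariate_betas: dict[str, float] | None = None
    with_covariates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.beta is None:
            self.beta = np.zeros(self.n_features)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.n_features,):
            raise ValueError("beta length must equal n_features")


def generate_survival_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Simulate a right-censored cohort under a proportional-hazards model.

    Features are i.i.d. standard normal; event times are exponential with
    per-patient hazard ``baseline_rate * exp(x . beta [+ covariate terms])``.
    Censoring times are independent exponentials whose rate is calibrated so
    the expected censored fraction equals ``censor_rate``.

    Returns a DataFrame with columns ``patient_id, time, event``, optional
    clinical covariates (age, gender, stage, grade) and features ``f0..``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_patients, spec.n_features
    X = rng.standard_normal((n, p))
    log_hr = X @ spec.beta

    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    if spec.with_covariates:
        df["age"] = np.round(rng.normal(60, 10, n)).clip(30, 90)
        df["gender"] = rng.integers(0, 2, n)
        df["stage"] = rng.integers(1, 5, n)
        df["grade"] = rng.integers(1, 5, n)
        if spec.covariate_betas:
            for name, b in spec.covariate_betas.items():
                col = df[name].to_numpy(dtype=float)
                log_hr = log_hr + b * (col - col.mean())

    hazard = spec.baseline_rate * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)

    if spec.censor_rate > 0:
        # mean hazard of the cohort sets the censoring rate so that the
        # expected censored fraction matches the request
        mean_h = float(hazard.mean())
        c_rate = mean_h * spec.censor_rate / (1.0 - spec.censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)

    df["time"] = np.minimum(event_time, censor_time)
    df["event"] = event_time <= censor_time
    for j in range(p):
        df[f"f{j}"] = X[:, j]
    return df
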