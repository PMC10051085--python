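"""Synthetic endoscopy-like scenes with exact ground-truth lesion masks.

Real capsule-endoscopy and colonoscopy frames show reddish lesions
(bleeding spots, polyps) of widely varying size on a pink-brown mucosal
background. This module emulates those statistics — a smoothly textured
background, one or more red-dominant elliptical blobs with irregular
boundaries, and additive Gaussian pixel noise — so that every other module
(loading, augmentation, training, evaluation) is exercisable without any
external download. It makes no attempt at photorealism: no specular
highlights, vignetting, or instrument artifacts.

Lesion boundaries are radially perturbed ellipses,

    r(theta) = r_base * (1 + irregularity * s(theta)),

where ``s`` is a low-order random trigonometric series normalized to
|s| <= 1, so no lesion pixel ever lies farther than
``(1 + irregularity) * r_max`` from its center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageSample

__all__ = ["SyntheticSceneSpec", "generate_scene", "generate_dataset"]

_N_HARMONICS = 4


@dataclass
class SyntheticSceneSpec:
    """Parameters of one synthetic scene.

    ``radius_range`` bounds the ellipse semi-axes in pixels (a degenerate
    range gives circles); ``boundary_irregularity`` is the relative radial
    perturbation amplitude; ``noise_sigma`` the per-channel Gaussian noise
    standard deviation. Colors are RGB means in [0, 1]; the defaults are a
    red-dominant lesion on a pink-brown mucosa.
    """

    size: tuple[int, int] = (64, 64)
    n_lesions: int = 1
    radius_range: tuple[float, float] = (6.0, 16.0)
    lesion_color_mean: tuple[float, float, float] = (0.72, 0.18, 0.16)
    background_color_mean: tuple[float, float, float] = (0.78, 0.55, 0.48)
    boundary_irregularity: float = 0.25
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        h, w = self.size
        rmin, rmax = self.radius_range
        if h < 1 or w < 1:
            raise ValueError("scene size must be positive")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if rmin <= 0 or rmax < rmin:
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if rmax >= min(h, w) / 2:
            raise ValueError(
                f"max radius {rmax} cannot fit in a {h}x{w} scene (must be < {min(h, w) / 2})"
            )
        for color in (self.lesion_color_mean, self.background_color_mean):
            if any(c < 0 or c > 1 for c in color):
                raise ValueError("color means must lie in [0, 1]^3")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _smooth_angular_noise(rng: np.random.Generator, theta: np.ndarray) -> np.ndarray:
    """Random trigonometric series in theta, normalized so |s| <= 1."""
    a = rng.normal(size=_N_HARMONICS)
    b = rng.normal(size=_N_HARMONICS)
    k = np.arange(1, _N_HARMONICS + 1)
    s = a @ np.cos(np.outer(k, theta)) + b @ np.sin(np.outer(k, theta))
    bound = np.sum(np.hypot(a, b))  # sup over theta of the series
    return s / bound if bound > 0 else np.zeros_like(theta)


def _lesion_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    angle: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask of one radially perturbed, rotated ellipse."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy  # ellipse frame
    v = -sa * dx + ca * dy
    ry, rx = radii
    rho = np.hypot(u / rx, v / ry)  # 1.0 on the unperturbed boundary
    if irregularity > 0:
        theta = np.arctan2(v, u)
        flat = _smooth_angular_noise(rng, theta.ravel()).reshape(theta.shape)
        boundary = 1.0 + irregularity * flat
    else:
        boundary = 1.0
    return rho <= boundary


def _background(rng: np.random.Generator, spec: SyntheticSceneSpec) -> np.ndarray:
    """Smoothly textured mucosa: color mean plus low-frequency color noise."""
    h, w = spec.size
    base = np.asarray(spec.background_color_mean, dtype=np.float64)
    texture = rng.normal(0.0, 1.0, size=(h, w, 3))
    texture = ndimage.gaussian_filter(texture, sigma=(6.0, 6.0, 0.0))
    peak = np.abs(texture).max()
    if peak > 0:
        texture *= 0.06 / peak
    return np.clip(base[None, None, :] + texture, 0.0, 1.0)


def generate_scene(spec: SyntheticSceneSpec, return_geometry: bool = False):
    """Render one scene; deterministic in ``spec.seed``.

    The mask is 1 exactly on lesion pixels. With ``noise_sigma = 0`` and
    ``boundary_irregularity = 0`` a single lesion's foreground is precisely
    the discrete ellipse (a disk for a degenerate radius range). With
    ``return_geometry=True`` also returns the per-lesion centers/radii/angles
    so callers can verify the mask against the analytic boundary.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    image = _background(rng, spec)
    mask = np.zeros((h, w), dtype=bool)
    rmin, rmax = spec.radius_range
    margin = (1.0 + spec.boundary_irregularity) * rmax
    if margin >= min(h, w) / 2:
        raise ValueError(
            "lesion cannot fit: (1 + irregularity) * max radius exceeds half the frame"
        )
    lesion_color = np.asarray(spec.lesion_color_mean, dtype=np.float64)
    geometry = []
    for _ in range(spec.n_lesions):
        ry = rng.uniform(rmin, rmax)
        rx = rng.uniform(rmin, rmax)
        reach = (1.0 + spec.boundary_irregularity) * max(ry, rx)
        cy = rng.uniform(reach, h - 1 - reach)
        cx = rng.uniform(reach, w - 1 - reach)
        angle = rng.uniform(0.0, np.pi)
        blob = _lesion_mask((h, w), (cy, cx), (ry, rx), angle, spec.boundary_irregularity, rng)
        mask |= blob
        geometry.append({"center": (cy, cx), "radii": (ry, rx), "angle": angle})
        # mild radial shading keeps the blob's mean color near the target
        shade = 1.0 - 0.12 * rng.random()
        image[blob] = np.clip(lesion_color * shade, 0.0, 1.0)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    sample = ImageSample(
        image=image.astype(np.float32),
        mask=mask.astype(np.uint8),
        identifier=f"scene-{spec.seed:08d}",
    )
    return (sample, geometry) if return_geometry else sample


def generate_dataset(
    spec: SyntheticSceneSpec, n_samples: int, seed: int | None = None
) -> list[ImageSample]:
    """Generate ``n_samples`` scenes with per-sample seeds spawned from ``seed``.

    Lesion count stays as specified but sizes/positions/shapes vary per
    sample. Deterministic in the master seed (defaults to ``spec.seed``).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    master = spec.seed if seed is None else seed
    # derive well-separated 31-bit per-sample seeds
    child_seeds = np.random.default_rng(master).integers(0, 2**31 - 1, size=n_samples)
    samples = []
    for i, s in enumerate(child_seeds):
        sub = SyntheticSceneSpec(
            size=spec.size,
            n_lesions=spec.n_lesions,
            radius_range=spec.radius_range,
            lesion_color_mean=spec.lesion_color_mean,
            background_color_mean=spec.background_color_mean,
            boundary_irregularity=spec.boundary_irregularity,
            noise_sigma=spec.noise_sigma,
            seed=int(s),
        )
        sample = generate_scene(sub)
        sample.identifier = f"scene-{i:05d}"
        samples.append(sample)
    return samples
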