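"""Paired image/mask augmentation: flips, rotation, zoom.

The same geometric transform is always applied to the image and its mask;
the image is interpolated bilinearly, the mask with nearest-neighbor so it
stays strictly binary. Rotations by exact multiples of 90 degrees on square
frames are performed as index permutations (``np.rot90``), which preserves
the mask's foreground pixel count bit-exactly; arbitrary angles fall back to
resampling with zero fill outside the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageSample

__all__ = ["AugmentationPolicy", "augment_pair", "rotate_pair", "zoom_pair"]


@dataclass
class AugmentationPolicy:
    """Which transform families are enabled, and their ranges.

    Each enabled transform fires independently with probability 1/2 per
    draw. A fully disabled policy is the identity. ``zoom_range`` is the
    maximum relative scale deviation (0.1 means scales in [0.9, 1.1]).
    """

    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_max_degrees: float = 20.0
    zoom_range: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rotation_max_degrees <= 180.0:
            raise ValueError("rotation_max_degrees must lie in [0, 180]")
        if not 0.0 <= self.zoom_range < 1.0:
            raise ValueError("zoom_range must lie in [0, 1)")

    @property
    def enabled(self) -> bool:
        return (
            self.horizontal_flip
            or self.vertical_flip
            or self.rotation_max_degrees > 0
            or self.zoom_range > 0
        )

    def to_dict(self) -> dict:
        return {
            "horizontal_flip": self.horizontal_flip,
            "vertical_flip": self.vertical_flip,
            "rotation_max_degrees": self.rotation_max_degrees,
            "zoom_range": self.zoom_range,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationPolicy":
        return cls(**d)


def rotate_pair(
    image: np.ndarray, mask: np.ndarray, angle_degrees: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image (bilinear) and mask (nearest) about the frame center.

    Output keeps the input shape; pixels rotated in from outside the frame
    are filled with 0 (background). Angles that are exact multiples of 90
    degrees use ``np.rot90`` when the frame is square (or the angle is a
    multiple of 180), making the rotation an exact permutation of pixels.
    """
    h, w = mask.shape
    quarter, rem = divmod(angle_degrees % 360.0, 90.0)
    if rem == 0.0 and (h == w or quarter % 2 == 0):
        k = int(quarter)
        return np.ascontiguousarray(np.rot90(image, k)), np.ascontiguousarray(
            np.rot90(mask, k)
        )
    img = ndimage.rotate(
        image, angle_degrees, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0
    )
    msk = ndimage.rotate(
        mask, angle_degrees, axes=(0, 1), reshape=False, order=0, mode="constant", cval=0
    )
    return np.clip(img, 0.0, 1.0), msk.astype(mask.dtype)


def zoom_pair(
    image: np.ndarray, mask: np.ndarray, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Zoom about the frame center by ``scale`` (>1 enlarges), same output shape."""
    if scale == 1.0:
        return image.copy(), mask.copy()
    h, w = mask.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    matrix = np.diag([1.0 / scale, 1.0 / scale])
    offset = center - matrix @ center
    img = np.stack(
        [
            ndimage.affine_transform(
                image[:, :, c], matrix, offset=offset, order=1, mode="constant", cval=0.0
            )
            for c in range(image.shape[2])
        ],
        axis=2,
    )
    msk = ndimage.affine_transform(
        mask, matrix, offset=offset, order=0, mode="constant", cval=0
    )
    return np.clip(img, 0.0, 1.0), msk.astype(mask.dtype)


def augment_pair(
    sample: ImageSample, policy: AugmentationPolicy, draw_seed: int
) -> ImageSample:
    """Apply one random draw of the policy to an image/mask pair.

    Deterministic in ``(policy.seed, draw_seed)``; the identical geometric
    transform is applied to image and mask, dims are unchanged, and the mask
    stays binary.
    """
    if not policy.enabled:
        return ImageSample(sample.image.copy(), sample.mask.copy(), sample.identifier)
    rng = np.random.default_rng(np.random.SeedSequence([policy.seed, draw_seed]))
    image, mask = sample.image, sample.mask
    if policy.horizontal_flip and rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if policy.vertical_flip and rng.random() < 0.5:
        image, mask = image[::-1], mask[::-1]
    if policy.rotation_max_degrees > 0 and rng.random() < 0.5:
        angle = rng.uniform(-policy.rotation_max_degrees, policy.rotation_max_degrees)
        image, mask = rotate_pair(np.ascontiguousarray(image), np.ascontiguousarray(mask), angle)
    if policy.zoom_range > 0 and rng.random() < 0.5:
        scale = 1.0 + rng.uniform(-policy.zoom_range, policy.zoom_range)
        image, mask = zoom_pair(np.ascontiguousarray(image), np.ascontiguousarray(mask), scale)
    return ImageSample(
        np.ascontiguousarray(image), np.ascontiguousarray(mask), sample.identifier
    )
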