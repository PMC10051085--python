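"""Image/mask pair loading, normalization, resizing and dataset splitting.

Datasets follow the common polyp-segmentation layout (Kvasir-SEG,
CVC-ClinicDB): an ``images/`` directory and a ``masks/`` directory whose
files share filename stems. Masks are stored as 8-bit single-channel PNGs
with values {0, 255} and held in memory as {0, 1} uint8 arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImageSample",
    "DatasetSplit",
    "load_pair",
    "normalize_image",
    "resize_sample",
    "split_dataset",
    "save_mask",
    "save_image",
    "load_dataset",
    "write_dataset",
]


@dataclass
class ImageSample:
    """A normalized RGB image with its binary ground-truth mask.

    ``image`` is (H, W, 3) float in [0, 1]; ``mask`` is (H, W) uint8 in
    {0, 1}; ``identifier`` is the source filename stem (or any opaque id).
    """

    image: np.ndarray
    mask: np.ndarray
    identifier: str

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be (H, W, 3), got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"image/mask dimension mismatch: {self.image.shape[:2]} vs {self.mask.shape}"
            )
        if self.image.min() < 0.0 or self.image.max() > 1.0:
            raise ValueError("image values must lie in [0, 1]")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must lie in {0, 1}")

    @property
    def size(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class DatasetSplit:
    """Train/validation/test fractions plus the shuffling seed."""

    train_fraction: float = 0.6
    validation_fraction: float = 0.2
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        fracs = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")


def normalize_image(raw_image: np.ndarray) -> np.ndarray:
    """Map 8-bit pixel values to [0, 1] by dividing by 255."""
    raw = np.asarray(raw_image)
    if raw.size and (raw.min() < 0 or raw.max() > 255):
        raise ValueError("pixel values must lie in [0, 255]")
    return (raw / 255.0).astype(np.float32)


def _binarize_mask(raw: np.ndarray) -> np.ndarray:
    """Threshold at the midpoint of the source bit depth (e.g. >127 for 8-bit)."""
    if raw.ndim == 3:  # collapse color-coded annotations to one channel
        raw = raw.max(axis=2)
    if np.issubdtype(raw.dtype, np.integer):
        midpoint = np.iinfo(raw.dtype).max / 2
    else:
        midpoint = 0.5
    return (raw > midpoint).astype(np.uint8)


def load_pair(image_path: str | Path, mask_path: str | Path) -> ImageSample:
    """Load and normalize an image/mask pair from disk.

    The image is converted to 3 channels (grayscale replicated, alpha
    dropped) and scaled to [0, 1]; the mask is binarized at the midpoint of
    its bit depth. A spatial-dimension mismatch raises ``ValueError``.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(p)
    img = np.asarray(iio.imread(image_path))
    msk = np.asarray(iio.imread(mask_path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=2)
    elif img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    elif img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"cannot interpret image of shape {img.shape}")
    if np.issubdtype(img.dtype, np.integer) and np.iinfo(img.dtype).max != 255:
        img = (img.astype(np.float64) / np.iinfo(img.dtype).max * 255).round()
    image = normalize_image(img)
    mask = _binarize_mask(msk)
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"image/mask dimension mismatch: image {image.shape[:2]}, mask {mask.shape}"
        )
    return ImageSample(image=image, mask=mask, identifier=image_path.stem)


def resize_sample(sample: ImageSample, target: tuple[int, int]) -> ImageSample:
    """Resize to (H, W): bilinear for the image, nearest for the mask.

    Nearest-neighbor keeps the mask strictly binary; the image is clipped
    back into [0, 1] after interpolation.
    """
    th, tw = int(target[0]), int(target[1])
    if th <= 0 or tw <= 0:
        raise ValueError(f"target dims must be positive, got {target}")
    if (th, tw) == sample.size:
        return ImageSample(sample.image.copy(), sample.mask.copy(), sample.identifier)
    image = _sk_resize(
        sample.image, (th, tw), order=1, preserve_range=True, anti_aliasing=False
    )
    mask = _sk_resize(
        sample.mask, (th, tw), order=0, preserve_range=True, anti_aliasing=False
    )
    return ImageSample(
        image=np.clip(image, 0.0, 1.0).astype(np.float32),
        mask=mask.astype(np.uint8),
        identifier=sample.identifier,
    )


def split_dataset(
    samples: list[ImageSample], split: DatasetSplit
) -> tuple[list[ImageSample], list[ImageSample], list[ImageSample]]:
    """Shuffle and partition into (train, validation, test).

    Validation and test sizes are ``round(n * fraction)``; the remainder
    (including rounding leftovers) goes to train. Deterministic in
    ``split.seed``.
    """
    n = len(samples)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    n_val = round(n * split.validation_fraction)
    n_test = round(n * split.test_fraction)
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("rounded validation/test sizes exceed the dataset")
    order = np.random.default_rng(split.seed).permutation(n)
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train : n_train + n_val]]
    test = [samples[i] for i in order[n_train + n_val :]]
    return train, val, test


# ---------------------------------------------------------------------------
# disk layout helpers


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit single-channel PNG with values {0,255}."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must lie in {0, 1}")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an [0,1] RGB image as an 8-bit PNG/JPEG."""
    arr = np.asarray(image)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def write_dataset(samples: list[ImageSample], root: str | Path) -> None:
    """Write samples to ``root/images`` and ``root/masks`` (PNG)."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        save_image(s.image, root / "images" / f"{s.identifier}.png")
        save_mask(s.mask, root / "masks" / f"{s.identifier}.png")


def load_dataset(root: str | Path) -> list[ImageSample]:
    """Load every image/mask pair under ``root/images`` and ``root/masks``.

    Pairs are matched by filename stem and returned sorted by identifier.
    """
    root = Path(root)
    img_dir, msk_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not msk_dir.is_dir():
        raise FileNotFoundError(f"expected {img_dir} and {msk_dir}")
    masks = {p.stem: p for p in msk_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")}
    samples = []
    for img_path in sorted(img_dir.iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        if img_path.stem not in masks:
            raise FileNotFoundError(f"no mask for image {img_path.name}")
        samples.append(load_pair(img_path, masks[img_path.stem]))
    return samples
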