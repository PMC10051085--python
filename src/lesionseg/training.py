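"""Training protocol: BCE loss, Adam, batching, early stopping, history.

The protocol mirrors common practice for sigmoid-output binary
segmentation: mean binary cross-entropy (a soft-Dice option is available),
Adam with beta1 = 0.9 and beta2 = 0.99, batch size 40, up to 50 epochs, and
early stopping on validation loss with best-weight restoration.
Augmentation is applied on the fly to training batches only; validation
always sees the untouched samples. Every source of randomness (shuffling,
augmentation draws) derives from ``TrainConfig.seed``, so two runs with the
same seed and config produce identical histories on a fixed platform.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentationPolicy, augment_pair
from .io import ImageSample
from .metrics import confusion, dice_coefficient, pixel_accuracy
from .models import ModelConfig, SegmentationModel, build_model

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "EpochRecord",
    "bce_loss",
    "train",
    "checkpoint_save",
    "checkpoint_load",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters and early-stopping policy."""

    batch_size: int = 40
    epochs: int = 50
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.99
    early_stop_patience: int = 10
    seed: int = 0
    loss: str = "bce"  # or "dice"
    augmentation: AugmentationPolicy | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("batch_size, epochs and early_stop_patience must be >= 1")
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ValueError("betas must lie in (0, 1)")
        if self.loss not in ("bce", "dice"):
            raise ValueError("loss must be 'bce' or 'dice'")

    def to_dict(self) -> dict:
        d = {
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "early_stop_patience": self.early_stop_patience,
            "seed": self.seed,
            "loss": self.loss,
        }
        if self.augmentation is not None:
            d["augmentation"] = self.augmentation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        aug = d.pop("augmentation", None)
        if aug is not None:
            aug = AugmentationPolicy.from_dict(aug)
        return cls(augmentation=aug, **d)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    train_acc: float
    val_acc: float
    val_dice: float


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def write_csv(self, path: str | Path) -> None:
        cols = ["epoch", "train_loss", "val_loss", "train_acc", "val_acc", "val_dice"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            for r in self.records:
                writer.writerow(
                    [
                        r.epoch,
                        f"{r.train_loss:.6f}",
                        f"{r.val_loss:.6f}",
                        f"{r.train_acc:.6f}",
                        f"{r.val_acc:.6f}",
                        f"{r.val_dice:.6f}",
                    ]
                )


def bce_loss(probability_map: np.ndarray, true_mask: np.ndarray) -> float:
    """Mean binary cross-entropy of a probability map against a binary mask."""
    p = np.asarray(probability_map, dtype=np.float32)
    y = np.asarray(true_mask, dtype=np.float32)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return float(nn.bce_loss(nn.Tensor(p), y).data)


def _to_batch(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    masks = np.stack([s.mask[None].astype(np.float32) for s in samples])
    return images, masks


def _loss_tensor(pred: nn.Tensor, target: np.ndarray, kind: str) -> nn.Tensor:
    if kind == "dice":
        return nn.soft_dice_loss(pred, target)
    return nn.bce_loss(pred, target)


def _evaluate_epoch(
    model: SegmentationModel,
    samples: list[ImageSample],
    batch_size: int,
    loss_kind: str,
) -> tuple[float, float, float]:
    """(loss, accuracy, mean per-image Dice) in inference mode."""
    model.eval()
    losses, n_pix = [], []
    accs, dices = [], []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        x, y = _to_batch(chunk)
        pred = model.forward(x)
        losses.append(float(_loss_tensor(pred, y, loss_kind).data) * len(chunk))
        n_pix.append(len(chunk))
        binary = (pred.data >= 0.5).astype(np.uint8)
        for i, s in enumerate(chunk):
            c = confusion(binary[i, 0], s.mask)
            accs.append(pixel_accuracy(c))
            dices.append(dice_coefficient(binary[i, 0], s.mask))
    loss = float(np.sum(losses) / np.sum(n_pix))
    return loss, float(np.mean(accs)), float(np.mean(dices))


def train(
    model: SegmentationModel,
    train_samples: list[ImageSample],
    val_samples: list[ImageSample],
    config: TrainConfig,
    progress: bool = False,
) -> tuple[SegmentationModel, TrainingHistory]:
    """Fit ``model`` in place and return it with its per-epoch history.

    Runs at most ``config.epochs`` epochs; stops early once validation loss
    has not improved for ``early_stop_patience`` consecutive epochs, and
    always restores the parameters of the best-validation-loss epoch.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be nonempty")
    h, w = model.config.input_size
    for s in train_samples + val_samples:
        if s.size != (h, w):
            raise ValueError(f"sample {s.identifier} has size {s.size}, model expects {(h, w)}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E5]))
    optimizer = nn.Adam(
        model.parameters(),
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
    )
    history = TrainingHistory()
    best_loss = np.inf
    best_state: dict[str, np.ndarray] | None = None
    stall = 0

    iterator = range(1, config.epochs + 1)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="epochs")

    for epoch in iterator:
        model.train()
        order = rng.permutation(len(train_samples))
        epoch_losses, epoch_sizes, epoch_accs = [], [], []
        for bstart in range(0, len(order), config.batch_size):
            idx = order[bstart : bstart + config.batch_size]
            batch = [train_samples[i] for i in idx]
            if config.augmentation is not None and config.augmentation.enabled:
                draw_base = int(rng.integers(0, 2**31 - 1))
                batch = [
                    augment_pair(s, config.augmentation, draw_base + j)
                    for j, s in enumerate(batch)
                ]
            x, y = _to_batch(batch)
            pred = model.forward(x)
            loss_t = _loss_tensor(pred, y, config.loss)
            optimizer.zero_grad()
            loss_t.backward()
            optimizer.step()
            epoch_losses.append(float(loss_t.data) * len(batch))
            epoch_sizes.append(len(batch))
            epoch_accs.append(float(((pred.data >= 0.5) == (y >= 0.5)).mean()))
        train_loss = float(np.sum(epoch_losses) / np.sum(epoch_sizes))
        train_acc = float(np.mean(epoch_accs))

        val_loss, val_acc, val_dice = _evaluate_epoch(
            model, val_samples, config.batch_size, config.loss
        )
        history.records.append(
            EpochRecord(
                epoch=epoch,
                train_loss=train_loss,
                val_loss=val_loss,
                train_acc=train_acc,
                val_acc=val_acc,
                val_dice=val_dice,
            )
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# checkpointing


def checkpoint_save(model: SegmentationModel, path: str | Path) -> None:
    """Serialize parameters, buffers and the model config to one ``.npz``."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:  # plain handle: keep the exact filename
        np.savez(fh, **state)


def checkpoint_load(path: str | Path, model: SegmentationModel | None = None) -> SegmentationModel:
    """Rebuild (or refill) a model from a checkpoint.

    If ``model`` is given its config must equal the checkpoint's config,
    otherwise a fresh model is built from the embedded config. Forward
    outputs after a save/load round trip are bit-identical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    raw = state.pop("__config__", None)
    if raw is None:
        raise ValueError(f"{path} is not a model checkpoint (missing embedded config)")
    config = ModelConfig.from_dict(json.loads(raw.tobytes().decode()))
    if model is None:
        model = build_model(config)
    elif model.config != config:
        raise ValueError(
            f"checkpoint config {config} does not match the supplied model's {model.config}"
        )
    model.load_state_dict(state)
    model.eval()
    return model
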