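"""U-Net family builders: plain U-Net, attention U-Net, attention residual U-Net.

All three share one encoder--decoder skeleton. Per downsampling stage the
channel width doubles and the spatial size halves (2x2 max pooling); the
decoder mirrors this with 2x nearest-neighbor upsampling followed by a
convolution, merges the skip connection, and refines with a plain conv block
(the residual structure is used only on the encoder side). The variants
differ in two switches:

==============  =================  ==========================
architecture    encoder block      skip merge
==============  =================  ==========================
``unet``        conv block         concatenation
``attunet``     conv block         attention gate, then concat
``attresunet``  residual block     attention gate, then concat
==============  =================  ==========================

The head is a 1x1 convolution plus sigmoid, so the forward pass maps an
(N, 3, H, W) image batch to an (N, 1, H, W) probability map in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import AttentionGate, ConvBlock, ResidualBlock
from .nn import Tensor

ARCHITECTURES = ("unet", "attunet", "attresunet")

__all__ = ["ModelConfig", "SegmentationModel", "build_model", "predict_mask", "ARCHITECTURES"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by ``2**depth`` so every pooling stage
    halves cleanly. ``base_filters`` is the channel width of the first
    encoder stage; each deeper stage doubles it.
    """

    architecture: str = "attresunet"
    input_size: tuple[int, int] = (128, 128)
    input_channels: int = 3
    depth: int = 4
    base_filters: int = 64
    output_channels: int = 1

    def __post_init__(self):
        self.input_size = tuple(int(v) for v in self.input_size)
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        h, w = self.input_size
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2^depth = {1 << self.depth}"
            )

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "input_size": list(self.input_size),
            "input_channels": self.input_channels,
            "depth": self.depth,
            "base_filters": self.base_filters,
            "output_channels": self.output_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            architecture=d["architecture"],
            input_size=tuple(d["input_size"]),
            input_channels=int(d["input_channels"]),
            depth=int(d["depth"]),
            base_filters=int(d["base_filters"]),
            output_channels=int(d.get("output_channels", 1)),
        )


class _UpStage(nn.Module):
    """2x nearest upsampling followed by conv -> BN -> ReLU halving channels."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, 3, rng=rng)
        self.bn = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return nn.relu(self.bn(self.conv(nn.upsample_nearest2x(x))))


class SegmentationModel(nn.Module):
    """Encoder--decoder segmentation network; build via :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        arch = config.architecture
        use_residual = arch == "attresunet"
        use_attention = arch in ("attunet", "attresunet")
        widths = [config.base_filters << i for i in range(config.depth + 1)]

        enc_cls = ResidualBlock if use_residual else ConvBlock
        self.encoders = nn.ModuleList()
        cin = config.input_channels
        for w in widths[:-1]:
            self.encoders.append(enc_cls(cin, w, rng))
            cin = w
        self.bottleneck = enc_cls(widths[-2], widths[-1], rng)

        self.gates = nn.ModuleList()
        if use_attention:
            # gate i re-weights the encoder skip at level i using the decoder
            # feature one level deeper as gating signal
            for i in range(config.depth):
                self.gates.append(AttentionGate(widths[i], widths[i + 1], rng))

        self.up_stages = nn.ModuleList()
        self.decoders = nn.ModuleList()
        for i in reversed(range(config.depth)):
            self.up_stages.append(_UpStage(widths[i + 1], widths[i], rng))
            self.decoders.append(ConvBlock(2 * widths[i], widths[i], rng))

        self.head = nn.Conv2d(widths[0], config.output_channels, 1, pad=0, rng=rng)

    # -- forward ----------------------------------------------------------
    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        n, c, h, w = x.data.shape
        if c != self.config.input_channels or (h, w) != self.config.input_size:
            raise ValueError(
                f"expected input {self.config.input_channels}x{self.config.input_size[0]}"
                f"x{self.config.input_size[1]}, got {c}x{h}x{w}"
            )
        skips: list[Tensor] = []
        h_t = x
        for enc in self.encoders:
            h_t = enc(h_t)
            skips.append(h_t)
            h_t = nn.max_pool2x2(h_t)
        h_t = self.bottleneck(h_t)
        for stage, (up, dec) in enumerate(zip(self.up_stages, self.decoders)):
            level = self.config.depth - 1 - stage
            skip = skips[level]
            if self.gates:
                skip = self.gates[level](skip, h_t).gated
            h_t = up(h_t)
            h_t = dec(nn.concat_channels([h_t, skip]))
        return nn.sigmoid(self.head(h_t))

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Inference-mode probability maps for an (N, 3, H, W) batch."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(images).data
        finally:
            if was_training:
                self.train()
        return out

    # -- introspection -----------------------------------------------------
    def count_blocks(self, block_type: type) -> int:
        return sum(1 for m in self.modules() if isinstance(m, block_type))


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationModel:
    """Construct a segmentation network with reproducible initialization."""
    return SegmentationModel(config, seed=seed)


def predict_mask(model: SegmentationModel, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize the model's probability map: mask = (p >= threshold).

    ``image`` may be a single (3, H, W) image or an (H, W, 3) array in [0, 1].
    Returns a uint8 (H, W) mask.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] == model.config.input_channels:
        img = img.transpose(2, 0, 1)
    probs = model.predict(img[None])[0, 0]
    return (probs >= threshold).astype(np.uint8)
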