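"""Building blocks of the segmentation networks.

Three units compose every architecture in this package:

* :class:`ConvBlock` — two [3x3 conv -> batch norm -> ReLU] stages.
* :class:`ResidualBlock` — ``y = F(x) + shortcut(x)`` where ``F`` is a
  :class:`ConvBlock` and the shortcut is the identity when channel counts
  match, else a 1x1 projection. With ``F``'s final stage zeroed the block is
  the exact identity, which is what makes deep encoders trainable.
* :class:`AttentionGate` — additive soft attention on a skip connection.
  The encoder feature ``x_l`` is downsampled by a strided 1x1 convolution to
  the gating signal's resolution, the gating signal ``g`` (one level deeper,
  semantically richer) passes a 1x1 convolution, the two are summed, and a
  ReLU -> 1x1 conv -> sigmoid pipeline yields per-location coefficients
  ``alpha`` in [0, 1]. ``alpha`` is upsampled bilinearly back to ``x_l``'s
  resolution and multiplies ``x_l`` channelwise, so the decoder receives a
  re-weighted skip that emphasizes lesion-relevant locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ConvBlock", "ResidualBlock", "AttentionGate", "AttentionOutput"]


class ConvBlock(nn.Module):
    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        h = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(h)))

    def zero_final_stage(self) -> None:
        """Zero the second stage so the block maps everything to zero."""
        self.conv2.weight.data[...] = 0.0
        if self.conv2.bias is not None:
            self.conv2.bias.data[...] = 0.0
        self.bn2.beta.data[...] = 0.0


class ResidualBlock(nn.Module):
    """Residual unit: two-stage convolutional transform plus shortcut."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.body = ConvBlock(in_channels, out_channels, rng)
        if in_channels != out_channels:
            self.shortcut = nn.Conv2d(in_channels, out_channels, 1, pad=0, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        fx = self.body(x)
        sx = self.shortcut(x) if self.shortcut is not None else x
        return nn.add(fx, sx)


@dataclass
class AttentionOutput:
    """Gated skip feature and the attention coefficients that produced it."""

    gated: Tensor
    coefficients: Tensor


class AttentionGate(nn.Module):
    """Additive attention gate for a skip connection.

    Parameters
    ----------
    x_channels : channels of the encoder (skip) feature ``x_l``.
    g_channels : channels of the gating signal ``g`` from one level deeper.
    inter_channels : width of the shared additive space; defaults to
        ``g_channels // 2`` (at least 1).
    """

    def __init__(
        self,
        x_channels: int,
        g_channels: int,
        rng: np.random.Generator,
        inter_channels: int | None = None,
    ):
        super().__init__()
        if inter_channels is None:
            inter_channels = max(g_channels // 2, 1)
        self.theta = nn.Conv2d(x_channels, inter_channels, 1, pad=0, rng=rng)
        self.bn_theta = nn.BatchNorm2d(inter_channels)
        self.phi = nn.Conv2d(g_channels, inter_channels, 1, pad=0, rng=rng)
        self.bn_phi = nn.BatchNorm2d(inter_channels)
        self.psi = nn.Conv2d(inter_channels, 1, 1, pad=0, rng=rng)
        self.bn_psi = nn.BatchNorm2d(1)

    def forward(self, x_l: Tensor, g: Tensor) -> AttentionOutput:
        hx, wx = x_l.data.shape[2:]
        hg, wg = g.data.shape[2:]
        if hx % hg or wx % wg:
            raise ValueError(
                f"skip dims {hx}x{wx} must be integer multiples of gating dims {hg}x{wg}"
            )
        stride = hx // hg
        if wx // wg != stride:
            raise ValueError("anisotropic skip/gating spatial ratio is not supported")
        self.theta.stride = stride  # ratio between x_l and g fixes the stride
        tx = self.bn_theta(self.theta(x_l))
        tg = self.bn_phi(self.phi(g))
        a = nn.relu(nn.add(tx, tg))
        alpha = nn.sigmoid(self.bn_psi(self.psi(a)))
        if (hg, wg) != (hx, wx):
            alpha = nn.resize_bilinear(alpha, (hx, wx))
        gated = nn.mul(alpha, x_l)
        return AttentionOutput(gated=gated, coefficients=alpha)

    def zero_weights(self) -> None:
        """Zero every convolution and shift so alpha = sigmoid(0) = 0.5."""
        for conv in (self.theta, self.phi, self.psi):
            conv.weight.data[...] = 0.0
            if conv.bias is not None:
                conv.bias.data[...] = 0.0
        for bn in (self.bn_theta, self.bn_phi, self.bn_psi):
            bn.beta.data[...] = 0.0
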