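"""U-Net regressor on the structured axial x circumferential grid.

Encoder blocks double the channel count (base -> 2*base -> 4*base ...) with
two 3x3 convolutions + batch norm + ReLU per block and 2x2 max pooling;
a bottleneck block at ``base * 2^depth`` channels; a symmetric decoder with
2x2 stride-2 transpose-convolution upsampling and skip concatenation; and a
1x1 linear output head.  Padding is cyclic circumferentially (the wall is a
closed tube) and reflective axially.  Dropout deepens from 0.1 to 0.3.

The full-scale configuration is ``base=64, depth=3`` (64 -> 128 -> 256 with
a 512-channel bottleneck) on the 560 x 40 grid; the grid must be divisible
by ``2^depth`` in both directions.

Composite loss: ``L = L_MSE + lambda1 L_relative + lambda2 L_smoothness``
where ``L_relative`` normalizes errors by the target magnitude and
``L_smoothness`` penalizes squared prediction gradients in both grid
directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ShapeError, ValidationError
from ..nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    Linear,
    MaxPool2d,
    Module,
    Tensor,
)


@dataclass
class UNetLossConfig:
    lambda1: float = 0.1
    lambda2: float = 0.05
    eps_rel: float = 1e-3

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("loss weights must be >= 0")


def unet_loss(pred, target, config: UNetLossConfig | None = None):
    """Composite U-Net loss on (.., H, W) grids.

    Returns ``(total, components)``; smoothness differences wrap
    circumferentially (axis -1) and stay one-sided axially (axis -2).
    """
    config = config or UNetLossConfig()
    pred_t = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, float))
    targ = target.data if isinstance(target, Tensor) else np.asarray(target, float)
    if pred_t.data.shape != targ.shape:
        raise ShapeError("pred/target shape mismatch")
    diff = pred_t - Tensor(targ)
    l_mse = (diff ** 2).mean()
    l_rel = (diff.abs() / Tensor(np.abs(targ) + config.eps_rel)).mean()
    gx = pred_t[..., 1:, :] - pred_t[..., :-1, :]
    # circumferential neighbor with wrap: roll the grid by one sector
    n_th = pred_t.data.shape[-1]
    roll = np.arange(1, n_th + 1) % n_th
    gy = pred_t[..., roll] - pred_t
    l_smooth = (gx ** 2).mean() + (gy ** 2).mean()
    total = l_mse + config.lambda1 * l_rel + config.lambda2 * l_smooth
    return total, {
        "L_mse": float(l_mse.data),
        "L_relative": float(l_rel.data),
        "L_smoothness": float(l_smooth.data),
    }


class _ConvBlock(Module):
    def __init__(self, in_ch, out_ch, rng, dropout_rate, drop_rng):
        super().__init__()
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.b1 = BatchNorm2d(out_ch)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)
        self.b2 = BatchNorm2d(out_ch)
        self.drop = Dropout(dropout_rate, drop_rng)

    def forward(self, x):
        x = self.b1(self.c1(x)).relu()
        x = self.b2(self.c2(x)).relu()
        return self.drop(x)


class UNet(Module):
    """Symmetric encoder-decoder with skip connections; input (B, C, H, W),
    output (B, 1, H, W)."""

    def __init__(self, in_ch: int = 8, base: int = 64, depth: int = 3,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 1)
        self.depth = depth
        rates = np.linspace(0.1, 0.3, depth + 1)
        self.enc = []
        ch = in_ch
        for d in range(depth):
            out = base * 2 ** d
            self.enc.append(_ConvBlock(ch, out, rng, rates[d], drop_rng))
            ch = out
        self.pool = MaxPool2d()
        self.bottleneck = _ConvBlock(ch, base * 2 ** depth, rng,
                                     rates[depth], drop_rng)
        self.up = []
        self.dec = []
        ch = base * 2 ** depth
        for d in reversed(range(depth)):
            out = base * 2 ** d
            self.up.append(ConvTranspose2d(ch, out, rng))
            self.dec.append(_ConvBlock(2 * out, out, rng, rates[d], drop_rng))
            ch = out
        self.head = Linear(ch, 1, rng)  # 1x1 convolution as a linear map

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ShapeError("input must be (B, C, H, W)")
        h, w = x.shape[2], x.shape[3]
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ShapeError(
                f"grid {h}x{w} not divisible by 2^{self.depth}"
            )
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up(x)
            x = Tensor.concat([skip, x], axis=1)
            x = dec(x)
        b, c, hh, ww = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(b * hh * ww, c)
        out = self.head(flat).reshape(b, hh, ww, 1).transpose(0, 3, 1, 2)
        return out
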