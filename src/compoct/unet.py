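"""A U-Net for single-channel binary segmentation, in pure numpy.

Standard encoder/decoder with skip connections: each resolution level
applies two 3x3 convolutions with ReLU; levels are linked by 2x2 max
pooling on the way down and nearest-neighbour upsampling followed by a
3x3 convolution on the way up, with the encoder feature map of the same
resolution concatenated before the decoder convolutions.  A final 1x1
convolution and sigmoid produce per-pixel foreground probabilities.

"Depth" counts resolution levels, so a depth-6 network pools five times
and requires the input side length to be divisible by 32.
"""

from __future__ import annotations

import numpy as np

from compoct.nn import Adam, Conv2D, GroupNorm, MaxPool2, Upsample2, sigmoid

__all__ = ["UNet"]


class _ConvBlock:
    """3x3 convolution -> group norm -> ReLU."""

    def __init__(self, c_in: int, c_out: int,
                 rng: np.random.Generator) -> None:
        self.conv = Conv2D(c_in, c_out, relu=False, rng=rng)
        self.norm = GroupNorm(c_out)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.norm.forward(self.conv.forward(x, train), train)
        mask = h > 0
        if train:
            self._mask = mask
        return np.where(mask, h, 0.0).astype(np.float32)

    def backward(self, d: np.ndarray) -> np.ndarray:
        d = np.where(self._mask, d, 0.0).astype(np.float32)
        return self.conv.backward(self.norm.backward(d))

    def backward_params_only(self, d: np.ndarray) -> None:
        d = np.where(self._mask, d, 0.0).astype(np.float32)
        self.conv.backward_params_only(self.norm.backward(d))

    def params(self):
        return self.conv.params() + self.norm.params()

    def grads(self):
        return self.conv.grads() + self.norm.grads()


class UNet:
    """See module docstring.  ``channels[i]`` is the width of level ``i``."""

    def __init__(self, depth: int = 6, base_channels: int = 4,
                 max_channels: int = 32, in_channels: int = 1,
                 coord_features: bool = True, seed: int = 0) -> None:
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.coord_features = coord_features
        if coord_features:
            # two constant coordinate planes give the first convolution
            # direct access to absolute position; several of the target
            # ROIs (muscle-band sectors, psoas) are defined by where they
            # sit in the torso, not only by local texture
            in_channels += 2
        ch = [min(base_channels * 2 ** i, max_channels) for i in range(depth)]
        self.channels = ch

        self.enc: list[tuple[_ConvBlock, _ConvBlock]] = []
        c_prev = in_channels
        for i in range(depth):
            a = _ConvBlock(c_prev, ch[i], rng)
            b = _ConvBlock(ch[i], ch[i], rng)
            self.enc.append((a, b))
            c_prev = ch[i]
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups = [Upsample2() for _ in range(depth - 1)]
        self.upconv = [_ConvBlock(ch[i + 1], ch[i], rng) for i in range(depth - 1)]
        self.dec = [
            (_ConvBlock(2 * ch[i], ch[i], rng), _ConvBlock(ch[i], ch[i], rng))
            for i in range(depth - 1)
        ]
        self.head = Conv2D(ch[0], 1, k=1, relu=False, rng=rng)
        # start the output near the background prior: foreground is a few
        # percent of pixels for every ROI, and a neutral 0.5 start lets the
        # initial cross-entropy shock saturate small networks (seed-dependent
        # failure to ever leave the empty prediction)
        self.head.b[:] = -2.0

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, 1, H, W) float32 in [0,1] -> (N, 1, H, W) probabilities."""
        h = x.shape[2]
        if h % 2 ** (self.depth - 1) or x.shape[3] % 2 ** (self.depth - 1):
            raise ValueError(
                f"input size {x.shape[2:]} not divisible by "
                f"2**(depth-1) = {2 ** (self.depth - 1)}"
            )
        if self.coord_features:
            n, _, hh, ww = x.shape
            rr = np.linspace(-1.0, 1.0, hh, dtype=np.float32)
            cc = np.linspace(-1.0, 1.0, ww, dtype=np.float32)
            rows = np.broadcast_to(rr[None, None, :, None], (n, 1, hh, ww))
            cols = np.broadcast_to(cc[None, None, None, :], (n, 1, hh, ww))
            x = np.concatenate([x, rows, cols], axis=1)
        skips = []
        for i in range(self.depth):
            a, b = self.enc[i]
            x = b.forward(a.forward(x, train), train)
            if i < self.depth - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        for i in range(self.depth - 2, -1, -1):
            x = self.upconv[i].forward(self.ups[i].forward(x, train), train)
            x = np.concatenate([skips[i], x], axis=1)
            a, b = self.dec[i]
            x = b.forward(a.forward(x, train), train)
        self._z = self.head.forward(x, train)
        self._p = sigmoid(self._z)
        return self._p

    def backward(self, dldp: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        dz = (dldp * self._p * (1.0 - self._p)).astype(np.float32)
        self.backward_from_logits(dz)

    def backward_from_logits(self, dz: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the pre-sigmoid logits."""
        d = self.head.backward(dz.astype(np.float32))
        dskips: dict[int, np.ndarray] = {}
        for i in range(self.depth - 1):
            a, b = self.dec[i]
            d = a.backward(b.backward(d))
            c = self.channels[i]
            dskip, dup = d[:, :c], d[:, c:]
            dskips[i] = dskip
            d = self.ups[i].backward(self.upconv[i].backward(dup))
        # d now flows into the bottleneck encoder output; walk back up
        for i in range(self.depth - 1, -1, -1):
            a, b = self.enc[i]
            if i < self.depth - 1:
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = b.backward(d)
            if i == 0:
                a.backward_params_only(d)  # input gradient is never used
            else:
                d = a.backward(d)

    # ------------------------------------------------------------------
    def _layers(self) -> list:
        out: list = []
        for a, b in self.enc:
            out += [a, b]
        out += list(self.upconv)
        for a, b in self.dec:
            out += [a, b]
        out.append(self.head)
        return out

    def params(self) -> list[np.ndarray]:
        return [p for lyr in self._layers() for p in lyr.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for lyr in self._layers() for g in lyr.grads()]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params(), lr=lr)
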