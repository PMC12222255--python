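"""Attention-gated 2D U-Net for residual PET denoising.

The network consumes three consecutive image slices as input channels and
predicts the middle slice.  Architecture: an encoder/decoder with max
pooling and bilinear upsampling, batch normalization and PReLU
activations, additive attention gates on the skip connections, and a
residual connection from the input middle slice to the output so the
network learns the noise correction rather than the image itself.

The repository default is a deliberately small configuration (depth 3,
16 base channels, ~0.2 M parameters) that trains in minutes on one CPU;
larger configurations are expressible through :class:`NetConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["NetConfig", "AttentionUNet"]


@dataclass(frozen=True)
class NetConfig:
    depth: int = 3  # pooling stages
    base_channels: int = 16
    conv_per_stage: int = 1
    attention_gates: bool = True
    residual: bool = True
    in_slices: int = 3

    def __post_init__(self) -> None:
        if self.in_slices != 3:
            raise ValueError("the denoiser consumes exactly 3 consecutive slices")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def min_size(self) -> int:
        return 2**self.depth


class _Conv:
    def __init__(self, rng, c_in, c_out, k=3, zero_init=False):
        if zero_init:
            w = np.zeros((c_out, c_in, k, k))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / (c_in * k * k)), (c_out, c_in, k, k))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = k // 2

    def __call__(self, x):
        return ag.conv2d(x, self.w, self.b, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class _BatchNorm:
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones((1, c, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, c, 1, 1), dtype=ag.DTYPE)
        self.running_var = np.ones((1, c, 1, 1), dtype=ag.DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training: bool):
        if training:
            mu = ag.mean(x, axis=(0, 2, 3), keepdims=True)
            xc = ag.sub(x, mu)
            var = ag.mean(ag.mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = ag.div(xc, ag.sqrt(ag.add(var, self.eps)))
        else:
            xhat = ag.div(ag.sub(x, self.running_mean),
                          np.sqrt(self.running_var + self.eps))
        return ag.add(ag.mul(xhat, self.gamma), self.beta)

    def params(self):
        return [self.gamma, self.beta]


class _PReLU:
    def __init__(self, c, init=0.25):
        self.slope = Tensor(np.full(c, init), requires_grad=True)

    def __call__(self, x):
        return ag.prelu(x, self.slope)

    def params(self):
        return [self.slope]


class _ConvBlock:
    def __init__(self, rng, c_in, c_out, n_convs):
        self.layers = []
        c = c_in
        for _ in range(n_convs):
            self.layers.append((_Conv(rng, c, c_out), _BatchNorm(c_out), _PReLU(c_out)))
            c = c_out

    def __call__(self, x, training):
        for conv, bn, act in self.layers:
            x = act(bn(conv(x), training))
        return x

    def params(self):
        out = []
        for conv, bn, act in self.layers:
            out += conv.params() + bn.params() + act.params()
        return out

    @property
    def n_convs(self):
        return len(self.layers)


class _AttentionGate:
    """Additive attention on a skip connection (single 1x1 projections).

    q = relu(Wg g + Wx x); psi = sigmoid(Wpsi q); out = x * psi.
    """

    def __init__(self, rng, c_skip, c_gate):
        c_int = max(c_skip // 2, 1)
        self.wg = _Conv(rng, c_gate, c_int, k=1)
        self.wx = _Conv(rng, c_skip, c_int, k=1)
        self.psi = _Conv(rng, c_int, 1, k=1)

    def __call__(self, x, g):
        q = ag.relu(ag.add(self.wg(g), self.wx(x)))
        att = ag.sigmoid(self.psi(q))
        return ag.mul(x, att)

    def params(self):
        return self.wg.params() + self.wx.params() + self.psi.params()


class AttentionUNet:
    """Residual attention U-Net over (N, 3, H, W) slice windows."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        d = config.depth
        k = config.conv_per_stage
        enc_ch = [c * 2**i for i in range(d)]
        self.encoders = []
        c_in = config.in_slices
        for co in enc_ch:
            self.encoders.append(_ConvBlock(rng, c_in, co, k))
            c_in = co
        self.bottleneck = _ConvBlock(rng, enc_ch[-1], enc_ch[-1] * 2, k)
        self.decoders = []
        self.gates = []
        c_up = enc_ch[-1] * 2
        for co in reversed(enc_ch):
            if config.attention_gates:
                self.gates.append(_AttentionGate(rng, co, c_up))
            else:
                self.gates.append(None)
            self.decoders.append(_ConvBlock(rng, c_up + co, co, k))
            c_up = co
        self.final = _Conv(rng, enc_ch[0], 1, k=1, zero_init=True)

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor, training: bool = False) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(x)
        skips = []
        h = t
        for enc in self.encoders:
            h = enc(h, training)
            skips.append(h)
            h = ag.maxpool2(h)
        h = self.bottleneck(h, training)
        for dec, gate, skip in zip(self.decoders, self.gates, reversed(skips)):
            h = ag.upsample_bilinear2(h)
            s = gate(skip, h) if gate is not None else skip
            h = dec(ag.concat(h, s, axis=1), training)
        out = self.final(h)
        if self.config.residual:
            mid = ag.narrow_channels(t, 1, 2)
            out = ag.add(out, mid)
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode forward pass returning (N, H, W)."""
        return self.forward(x, training=False).data[:, 0]

    # ------------------------------------------------------------------
    def params(self) -> list[Tensor]:
        out = []
        for enc in self.encoders:
            out += enc.params()
        out += self.bottleneck.params()
        for dec, gate in zip(self.decoders, self.gates):
            if gate is not None:
                out += gate.params()
            out += dec.params()
        out += self.final.params()
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    @property
    def n_conv_layers(self) -> int:
        n = sum(b.n_convs for b in self.encoders) + self.bottleneck.n_convs
        n += sum(b.n_convs for b in self.decoders) + 1  # final 1x1
        if self.config.attention_gates:
            n += 3 * len([g for g in self.gates if g is not None])
        return n

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data for i, p in enumerate(self.params())}
        j = 0
        for bn in self._batchnorms():
            state[f"rm{j}"] = bn.running_mean
            state[f"rv{j}"] = bn.running_var
            j += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.data = np.array(state[f"p{i}"], dtype=ag.DTYPE)
        for j, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.array(state[f"rm{j}"], dtype=ag.DTYPE)
            bn.running_var = np.array(state[f"rv{j}"], dtype=ag.DTYPE)

    def _batchnorms(self):
        for block in [*self.encoders, self.bottleneck, *self.decoders]:
            for _, bn, _ in block.layers:
                yield bn
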