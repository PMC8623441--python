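"""Encoder-decoder segmentation architectures with configurable kernels.

Four fully convolutional networks share a uniform forward contract
(``(N, C_in, H, W)`` float32 in, ``(N, 4, H, W)`` logits out, any H/W):

UNet
    five levels of double conv (conv -> ReLU), 2x2 max-pool, channel
    doubling, up-convolutions and skip concatenation.
AttentionUNet
    UNet plus additive attention gates applied to each skip connection
    before concatenation.
ReLayNet
    single conv + batch-norm + ReLU blocks of constant feature width, three
    pool/unpool stages with max-pool index passing, default 7x3 kernel.
LFUNet
    UNet encoder with dual decoders (a concatenation path and an addition
    path), their outputs concatenated and passed through three parallel
    dilated convolutions (rates 1, 2, 4) before the final projection.

Kernels may be rectangular (e.g. 9x3 or 3x9) but must have odd dims so that
same padding preserves the spatial size.  Inputs of arbitrary size are
reflection-padded to the network's pooling granularity and cropped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

ARCHS = ("UNet", "AttentionUNet", "ReLayNet", "LFUNet")
KERNEL_CHOICES = ((3, 3), (5, 5), (7, 7), (5, 3), (7, 3), (9, 3),
                  (3, 5), (3, 7), (3, 9))

__all__ = ["ARCHS", "KERNEL_CHOICES", "NetSpec", "build_network", "predict",
           "parameter_count"]


@dataclass
class NetSpec:
    """Architecture + hyperparameters of one model."""

    arch: str = "UNet"
    kernel: tuple = (3, 3)
    init_features: int = 32
    in_channels: int = 1
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unsupported arch {self.arch!r}; choose from {ARCHS}")
        kh, kw = self.kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd")
        if self.init_features < 4:
            raise ValueError("init_features must be >= 4")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")

    def to_dict(self) -> dict:
        return {"arch": self.arch, "kernel": list(self.kernel),
                "init_features": self.init_features,
                "in_channels": self.in_channels,
                "n_classes": self.n_classes, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "NetSpec":
        d = dict(d)
        d["kernel"] = tuple(d["kernel"])
        return cls(**d)


# ---------------------------------------------------------------------------
# building blocks


class _Module:
    def __init__(self):
        self._params: list[nn.Parameter] = []
        self._mods: list[_Module] = []
        self._bn_states: list[dict] = []

    def _register(self, mod):
        self._mods.append(mod)
        return mod

    def parameters(self):
        out = list(self._params)
        for m in self._mods:
            out.extend(m.parameters())
        return out

    def bn_states(self):
        out = list(self._bn_states)
        for m in self._mods:
            out.extend(m.bn_states())
        return out

    def get_state(self):
        return {
            "params": [p.data.copy() for p in self.parameters()],
            "bn": [{k: v.copy() for k, v in s.items()} for s in self.bn_states()],
        }

    def set_state(self, state):
        for p, d in zip(self.parameters(), state["params"], strict=True):
            p.data = np.array(d, dtype=np.float32)
        for s, d in zip(self.bn_states(), state["bn"], strict=True):
            s.update({k: np.array(v) for k, v in d.items()})


class Conv(_Module):
    """Same-padded conv with He-uniform init; optional dilation."""

    def __init__(self, rng, cin, cout, kernel, dilation=1):
        super().__init__()
        kh, kw = kernel
        bound = np.sqrt(6.0 / (cin * kh * kw))
        self.w = nn.Parameter(rng.uniform(-bound, bound, (cout, cin, kh, kw)))
        self.b = nn.Parameter(np.zeros(cout))
        self._params += [self.w, self.b]
        self.dilation = dilation

    def __call__(self, x, training=False):
        return nn.conv2d(x, self.w, self.b, self.dilation)


class UpConv(_Module):
    """2x2 stride-2 transposed convolution."""

    def __init__(self, rng, cin, cout):
        super().__init__()
        bound = np.sqrt(6.0 / (cin * 4))
        self.w = nn.Parameter(rng.uniform(-bound, bound, (cin, cout, 2, 2)))
        self.b = nn.Parameter(np.zeros(cout))
        self._params += [self.w, self.b]

    def __call__(self, x, training=False):
        return nn.conv_transpose2x2(x, self.w, self.b)


class BatchNorm(_Module):
    def __init__(self, channels):
        super().__init__()
        self.gamma = nn.Parameter(np.ones(channels))
        self.beta = nn.Parameter(np.zeros(channels))
        self._params += [self.gamma, self.beta]
        self.state = {"mean": np.zeros(channels, dtype=np.float32),
                      "var": np.ones(channels, dtype=np.float32)}
        self._bn_states.append(self.state)

    def __call__(self, x, training=False):
        return nn.batchnorm2d(x, self.gamma, self.beta, self.state, training)


class DoubleConv(_Module):
    """conv -> ReLU -> conv -> ReLU (the UNet block)."""

    def __init__(self, rng, cin, cout, kernel):
        super().__init__()
        self.c1 = self._register(Conv(rng, cin, cout, kernel))
        self.c2 = self._register(Conv(rng, cout, cout, kernel))

    def __call__(self, x, training=False):
        return nn.relu(self.c2(nn.relu(self.c1(x))))


class BNConv(_Module):
    """conv -> batch norm -> ReLU (the ReLayNet block)."""

    def __init__(self, rng, cin, cout, kernel):
        super().__init__()
        self.conv = self._register(Conv(rng, cin, cout, kernel))
        self.bn = self._register(BatchNorm(cout))

    def __call__(self, x, training=False):
        return nn.relu(self.bn(self.conv(x), training))


class AttentionGate(_Module):
    """Additive attention on a skip connection.

    The gating signal g (decoder, already upsampled to the skip resolution)
    and the skip features x are projected to an intermediate width by 1x1
    convs, summed, passed through ReLU and a 1x1 conv + sigmoid to produce a
    single-channel attention map that rescales x.
    """

    def __init__(self, rng, channels):
        super().__init__()
        inter = max(channels // 2, 1)
        k = (1, 1)
        self.wg = self._register(Conv(rng, channels, inter, k))
        self.wx = self._register(Conv(rng, channels, inter, k))
        self.psi = self._register(Conv(rng, inter, 1, k))

    def __call__(self, x, g, training=False):
        att = nn.sigmoid(self.psi(nn.relu(nn.add(self.wg(g), self.wx(x)))))
        return nn.mul(x, att)


def _pad_input(x: nn.Tensor, multiple: int):
    h, w = x.data.shape[2], x.data.shape[3]
    ph = (-h) % multiple
    pw = (-w) % multiple
    return nn.pad_reflect(x, (0, ph, 0, pw)), h, w


# ---------------------------------------------------------------------------
# architectures


class UNet(_Module):
    pad_multiple = 16

    def __init__(self, spec: NetSpec, attention: bool = False):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng((int(spec.seed), 0x9E))
        f, k = spec.init_features, spec.kernel
        widths = [f, 2 * f, 4 * f, 8 * f]
        self.enc = [self._register(DoubleConv(rng, c_in, c_out, k))
                    for c_in, c_out in zip([spec.in_channels] + widths[:-1], widths)]
        self.bottleneck = self._register(DoubleConv(rng, 8 * f, 16 * f, k))
        self.ups, self.dec, self.gates = [], [], []
        cur = 16 * f
        for skip_c in reversed(widths):
            self.ups.append(self._register(UpConv(rng, cur, skip_c)))
            if attention:
                self.gates.append(self._register(AttentionGate(rng, skip_c)))
            self.dec.append(self._register(DoubleConv(rng, 2 * skip_c, skip_c, k)))
            cur = skip_c
        self.head = self._register(Conv(rng, f, spec.n_classes, (1, 1)))
        self.attention = attention

    def forward(self, x: nn.Tensor, training: bool = False) -> nn.Tensor:
        x, h, w = _pad_input(x, self.pad_multiple)
        skips = []
        for block in self.enc:
            x = block(x, training)
            skips.append(x)
            x, _ = nn.maxpool2x2(x)
        x = self.bottleneck(x, training)
        for i, skip in enumerate(reversed(skips)):
            x = self.ups[i](x)
            if self.attention:
                skip = self.gates[i](skip, x, training)
            x = self.dec[i](nn.concat([skip, x]), training)
        return nn.crop(self.head(x), h, w)


class ReLayNet(_Module):
    """Constant-width encoder-decoder with max-unpooling via stored indices."""

    pad_multiple = 8

    def __init__(self, spec: NetSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng((int(spec.seed), 0x9E))
        f, k = spec.init_features, spec.kernel
        self.enc = [self._register(BNConv(rng, spec.in_channels if i == 0 else f, f, k))
                    for i in range(3)]
        self.bottleneck = self._register(BNConv(rng, f, f, k))
        self.dec = [self._register(BNConv(rng, 2 * f, f, k)) for _ in range(3)]
        self.head = self._register(Conv(rng, f, spec.n_classes, (1, 1)))

    def forward(self, x: nn.Tensor, training: bool = False) -> nn.Tensor:
        x, h, w = _pad_input(x, self.pad_multiple)
        skips, indices = [], []
        for block in self.enc:
            x = block(x, training)
            skips.append(x)
            x, idx = nn.maxpool2x2(x)
            indices.append(idx)
        x = self.bottleneck(x, training)
        for i in range(3):
            x = nn.maxunpool2x2(x, indices[2 - i])
            x = self.dec[i](nn.concat([skips[2 - i], x]), training)
        return nn.crop(self.head(x), h, w)


class LFUNet(_Module):
    """UNet encoder with dual (concat + add) decoders and dilated fusion."""

    pad_multiple = 16
    dilations = (1, 2, 4)

    def __init__(self, spec: NetSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng((int(spec.seed), 0x9E))
        f, k = spec.init_features, spec.kernel
        widths = [f, 2 * f, 4 * f, 8 * f]
        self.enc = [self._register(DoubleConv(rng, c_in, c_out, k))
                    for c_in, c_out in zip([spec.in_channels] + widths[:-1], widths)]
        self.bottleneck = self._register(DoubleConv(rng, 8 * f, 16 * f, k))
        # concatenation path (standard UNet decoder)
        self.cat_ups, self.cat_dec = [], []
        cur = 16 * f
        for skip_c in reversed(widths):
            self.cat_ups.append(self._register(UpConv(rng, cur, skip_c)))
            self.cat_dec.append(self._register(DoubleConv(rng, 2 * skip_c, skip_c, k)))
            cur = skip_c
        # addition path: halve features after each fusion, end at f
        self.add_ups, self.add_dec = [], []
        cur = 16 * f
        for skip_c, out_c in zip(reversed(widths), [4 * f, 2 * f, f, f]):
            self.add_ups.append(self._register(UpConv(rng, cur, skip_c)))
            self.add_dec.append(self._register(DoubleConv(rng, skip_c, out_c, k)))
            cur = out_c
        self.dilated = [self._register(Conv(rng, 2 * f, f, (3, 3), dilation=d))
                        for d in self.dilations]
        self.head = self._register(Conv(rng, len(self.dilations) * f,
                                        spec.n_classes, (1, 1)))

    def forward(self, x: nn.Tensor, training: bool = False) -> nn.Tensor:
        x, h, w = _pad_input(x, self.pad_multiple)
        skips = []
        for block in self.enc:
            x = block(x, training)
            skips.append(x)
            x, _ = nn.maxpool2x2(x)
        bott = self.bottleneck(x, training)
        xc = bott
        xa = bott
        for i, skip in enumerate(reversed(skips)):
            xc = self.cat_dec[i](nn.concat([skip, self.cat_ups[i](xc)]), training)
            xa = self.add_dec[i](nn.add(self.add_ups[i](xa), skip), training)
        fused = nn.concat([xc, xa])
        branches = [nn.relu(conv(fused)) for conv in self.dilated]
        return nn.crop(self.head(nn.concat(branches)), h, w)


def build_network(spec: NetSpec):
    """Instantiate the architecture named by ``spec.arch``."""
    if spec.arch == "UNet":
        return UNet(spec)
    if spec.arch == "AttentionUNet":
        return UNet(spec, attention=True)
    if spec.arch == "ReLayNet":
        return ReLayNet(spec)
    if spec.arch == "LFUNet":
        return LFUNet(spec)
    raise ValueError(f"unsupported arch {spec.arch!r}")


def parameter_count(model) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def forward_probs(model, inp: np.ndarray, training: bool = False):
    """Run the model on a (C, H, W) input; returns the softmax prob Tensor."""
    inp = np.asarray(inp, dtype=np.float32)
    if inp.ndim == 2:
        inp = inp[None]
    if inp.shape[0] != model.spec.in_channels:
        raise ValueError(f"expected {model.spec.in_channels} input channels, "
                         f"got {inp.shape[0]}")
    x = nn.Tensor(inp[None])
    if training:
        x.requires_grad = False  # input itself never needs gradients
    logits = model.forward(x, training)
    return nn.softmax_channels(logits)


def predict(model, inp: np.ndarray):
    """Probability map + hard class mask for one (C, H, W) or (H, W) input.

    The probability map has one channel per class and sums to 1 per pixel;
    the mask is the per-pixel argmax with ties toward the smaller class
    index.  Output spatial size always equals the input size.
    """
    probs = forward_probs(model, inp, training=False).data[0]
    return probs, probs.argmax(axis=0).astype(np.int8)
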