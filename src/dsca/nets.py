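"""Encoder–decoder segmentation networks for dural-sac delineation.

Three variants are provided, all mapping a normalized axial slice to a
per-pixel foreground probability map through a terminal sigmoid:

``unet``
    The plain symmetric encoder–decoder: two 3x3 ReLU convolutions per
    level, 2x2 max-pool downsampling, 2x2 stride-2 transposed-convolution
    upsampling, and skip concatenation between matching levels.

``attention_unet``
    As above, but every skip connection is modulated by an additive
    attention gate: a per-location coefficient
    ``alpha = sigmoid(psi(relu(W_g g + W_x x)))`` computed from the decoder
    (gating) signal ``g`` and the encoder skip tensor ``x``; the skip
    contribution becomes ``alpha * x``.

``multires_unet``
    Each conv block is a MultiRes block — three chained 3x3 convolutions
    whose concatenated outputs are summed with a 1x1 residual shortcut —
    and each skip connection is a ResPath of residual conv units, with the
    shallowest (highest-resolution) skip carrying the most units.

Networks are built on the in-package autodiff (:mod:`dsca._autograd`);
parameter initialization is fully determined by ``NetSpec.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = [
    "NetSpec",
    "NetworkGraph",
    "build_unet",
    "build_attention_unet",
    "build_multires_unet",
    "build_network",
    "predict_mask",
    "multires_channel_split",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("unet", "attention_unet", "multires_unet")


@dataclass
class NetSpec:
    """Architecture configuration shared by the three variants.

    Parameters
    ----------
    variant:
        One of ``unet``, ``attention_unet``, ``multires_unet``.
    depth:
        Number of encoder levels (pooling steps); the input side must be
        divisible by ``2**depth``.
    base_filters:
        Channel count at the highest-resolution level; doubles per level.
    alpha:
        MultiRes channel-scaling factor (``multires_unet`` only).
    seed:
        Parameter-initialization seed.
    """

    variant: str = "unet"
    depth: int = 4
    base_filters: int = 16
    alpha: float = 1.67
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def multires_channel_split(w_budget: int) -> tuple[int, int, int]:
    """Split a MultiRes block's channel budget W across its three convs.

    The split is ``floor(W/6), floor(W/3)`` and the remainder, so the three
    branch widths always sum to ``W`` exactly.
    """
    a = w_budget // 6
    b = w_budget // 3
    return a, b, w_budget - a - b


# ---------------------------------------------------------------------------
# layer building blocks


class _Conv:
    """3x3 or 1x1 'same' convolution with He/Xavier init."""

    def __init__(self, rng, c_in, c_out, k=3, gain="relu"):
        fan_in = c_in * k * k
        if gain == "relu":
            std = math.sqrt(2.0 / fan_in)
        else:  # linear / sigmoid head
            std = math.sqrt(1.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, size=(k, k, c_in, c_out)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return ag.conv2d(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _ConvT:
    """2x2 stride-2 transposed convolution."""

    def __init__(self, rng, c_in, c_out):
        std = math.sqrt(1.0 / (c_in * 4))
        self.w = Tensor(rng.normal(0.0, std, size=(2, 2, c_in, c_out)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return ag.conv_transpose2x2(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _DoubleConv:
    def __init__(self, rng, c_in, c_out):
        self.c1 = _Conv(rng, c_in, c_out)
        self.c2 = _Conv(rng, c_out, c_out)

    def __call__(self, x):
        return ag.relu(self.c2(ag.relu(self.c1(x))))

    def params(self):
        return self.c1.params() + self.c2.params()


class _AttentionGate:
    """Additive attention gate producing a single-channel coefficient map."""

    def __init__(self, rng, c_skip, c_gate):
        c_int = max(c_skip // 2, 1)
        self.wx = _Conv(rng, c_skip, c_int, k=1, gain="linear")
        self.wg = _Conv(rng, c_gate, c_int, k=1, gain="linear")
        self.psi = _Conv(rng, c_int, 1, k=1, gain="linear")

    def coefficients(self, x, g):
        return ag.sigmoid(self.psi(ag.relu(ag.add(self.wx(x), self.wg(g)))))

    def params(self):
        return self.wx.params() + self.wg.params() + self.psi.params()


class _MultiResBlock:
    """Three chained 3x3 convs, concatenated and summed with a 1x1 shortcut."""

    def __init__(self, rng, c_in, u_filters, alpha):
        w_budget = int(round(alpha * u_filters))
        self.widths = multires_channel_split(w_budget)
        w1, w2, w3 = self.widths
        self.out_channels = w_budget
        self.c1 = _Conv(rng, c_in, w1)
        self.c2 = _Conv(rng, w1, w2)
        self.c3 = _Conv(rng, w2, w3)
        self.shortcut = _Conv(rng, c_in, w_budget, k=1, gain="linear")

    def __call__(self, x):
        a = ag.relu(self.c1(x))
        b = ag.relu(self.c2(a))
        c = ag.relu(self.c3(b))
        return ag.relu(ag.add(ag.concat([a, b, c], axis=-1), self.shortcut(x)))

    def params(self):
        return self.c1.params() + self.c2.params() + self.c3.params() + self.shortcut.params()


class _ResPath:
    """Chain of residual conv units carried along a skip connection."""

    def __init__(self, rng, channels, n_units):
        self.n_units = n_units
        self.units = [(_Conv(rng, channels, channels),
                       _Conv(rng, channels, channels, k=1, gain="linear"))
                      for _ in range(n_units)]

    def __call__(self, x):
        for conv3, conv1 in self.units:
            x = ag.relu(ag.add(conv3(x), conv1(x)))
        return x

    def params(self):
        out = []
        for conv3, conv1 in self.units:
            out += conv3.params() + conv1.params()
        return out


# ---------------------------------------------------------------------------
# full architectures


class _UNet:
    def __init__(self, spec: NetSpec, attention: bool = False):
        rng = np.random.default_rng(spec.seed)
        self.depth = spec.depth
        self.attention = attention
        self.force_alpha_one = False  # debugging hook: bypass gates
        filters = [spec.base_filters * 2 ** i for i in range(spec.depth + 1)]
        self.enc = []
        c = 1
        for f in filters[:-1]:
            self.enc.append(_DoubleConv(rng, c, f))
            c = f
        self.bottleneck = _DoubleConv(rng, c, filters[-1])
        self.up = []
        self.dec = []
        self.gates = []
        c = filters[-1]
        for f in reversed(filters[:-1]):
            self.up.append(_ConvT(rng, c, f))
            if attention:
                self.gates.append(_AttentionGate(rng, f, f))
            self.dec.append(_DoubleConv(rng, 2 * f, f))
            c = f
        self.head = _Conv(rng, c, 1, k=1, gain="linear")
        self.last_attention: list[np.ndarray] = []

    def forward_logits(self, x: Tensor) -> Tensor:
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = ag.maxpool2x2(x)
        x = self.bottleneck(x)
        self.last_attention = []
        for i, (upc, block) in enumerate(zip(self.up, self.dec)):
            g = upc(x)
            skip = skips[-(i + 1)]
            if self.attention and not self.force_alpha_one:
                alpha = self.gates[i].coefficients(skip, g)
                self.last_attention.append(alpha.data)
                skip = ag.mul(skip, alpha)
            x = block(ag.concat([skip, g], axis=-1))
        return self.head(x)

    def params(self):
        out = []
        for block in self.enc:
            out += block.params()
        out += self.bottleneck.params()
        for upc, block in zip(self.up, self.dec):
            out += upc.params() + block.params()
        for gate in self.gates:
            out += gate.params()
        out += self.head.params()
        return out


class _MultiResUNet:
    def __init__(self, spec: NetSpec):
        rng = np.random.default_rng(spec.seed)
        self.depth = spec.depth
        u_filters = [spec.base_filters * 2 ** i for i in range(spec.depth + 1)]
        self.enc = []
        self.respaths = []
        c = 1
        for level, u in enumerate(u_filters[:-1]):
            block = _MultiResBlock(rng, c, u, spec.alpha)
            self.enc.append(block)
            # highest-resolution skip travels furthest -> most units
            self.respaths.append(_ResPath(rng, block.out_channels, spec.depth - level))
            c = block.out_channels
        self.bottleneck = _MultiResBlock(rng, c, u_filters[-1], spec.alpha)
        c = self.bottleneck.out_channels
        self.up = []
        self.dec = []
        for level in reversed(range(spec.depth)):
            skip_c = self.enc[level].out_channels
            self.up.append(_ConvT(rng, c, skip_c))
            block = _MultiResBlock(rng, 2 * skip_c, u_filters[level], spec.alpha)
            self.dec.append(block)
            c = block.out_channels
        self.head = _Conv(rng, c, 1, k=1, gain="linear")

    def forward_logits(self, x: Tensor) -> Tensor:
        skips = []
        for block, respath in zip(self.enc, self.respaths):
            x = block(x)
            skips.append(respath(x))
            x = ag.maxpool2x2(x)
        x = self.bottleneck(x)
        for i, (upc, block) in enumerate(zip(self.up, self.dec)):
            g = upc(x)
            skip = skips[-(i + 1)]
            x = block(ag.concat([skip, g], axis=-1))
        return self.head(x)

    def params(self):
        out = []
        for block, respath in zip(self.enc, self.respaths):
            out += block.params() + respath.params()
        out += self.bottleneck.params()
        for upc, block in zip(self.up, self.dec):
            out += upc.params() + block.params()
        out += self.head.params()
        return out


@dataclass
class NetworkGraph:
    """A built segmentation network: differentiable slice -> probability map."""

    variant: str
    spec: NetSpec
    model: object = field(repr=False)
    param_count: int = 0

    def __post_init__(self):
        if not self.param_count:
            self.param_count = int(sum(p.data.size for p in self.model.params()))

    def parameters(self) -> list[Tensor]:
        return self.model.params()

    def _check_input(self, batch: np.ndarray):
        h, w = batch.shape[-2:]
        div = 2 ** self.spec.depth
        if h % div or w % div:
            raise ValueError(
                f"input side {h}x{w} not divisible by 2^depth = {div}")

    def forward_logits(self, batch: np.ndarray) -> Tensor:
        """Forward pass on a (N, H, W) or (H, W) array; returns logits tensor."""
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 2:
            batch = batch[None]
        self._check_input(batch)
        return self.model.forward_logits(ag.tensor(batch[:, :, :, None]))

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probabilities, shape matching the input."""
        squeeze = np.asarray(batch).ndim == 2
        out = ag.sigmoid(self.forward_logits(batch)).data[..., 0]
        return out[0] if squeeze else out

    def summary(self) -> dict:
        return {
            "variant": self.variant,
            "depth": self.spec.depth,
            "base_filters": self.spec.base_filters,
            "alpha": self.spec.alpha,
            "seed": self.spec.seed,
            "param_count": self.param_count,
        }


def build_unet(spec: NetSpec) -> NetworkGraph:
    """Plain U-Net (see module docstring)."""
    if spec.variant != "unet":
        raise ValueError("spec.variant must be 'unet'")
    return NetworkGraph(variant="unet", spec=spec, model=_UNet(spec, attention=False))


def build_attention_unet(spec: NetSpec) -> NetworkGraph:
    """U-Net with additive attention gates on the skip connections."""
    if spec.variant != "attention_unet":
        raise ValueError("spec.variant must be 'attention_unet'")
    return NetworkGraph(variant="attention_unet", spec=spec, model=_UNet(spec, attention=True))


def build_multires_unet(spec: NetSpec) -> NetworkGraph:
    """MultiResUNet with MultiRes blocks and ResPath skip connections."""
    if spec.variant != "multires_unet":
        raise ValueError("spec.variant must be 'multires_unet'")
    return NetworkGraph(variant="multires_unet", spec=spec, model=_MultiResUNet(spec))


_BUILDERS: dict[str, Callable[[NetSpec], NetworkGraph]] = {
    "unet": build_unet,
    "attention_unet": build_attention_unet,
    "multires_unet": build_multires_unet,
}


def build_network(spec: NetSpec) -> NetworkGraph:
    """Dispatch to the builder matching ``spec.variant``."""
    return _BUILDERS[spec.variant](spec)


def predict_mask(net: NetworkGraph, slice_image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold the network's probability map into a binary mask.

    Foreground iff ``p >= threshold``; returns a float32 {0, 1} grid with
    the same shape as the input slice.
    """
    image = np.asarray(getattr(slice_image, "image", slice_image), dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("predict_mask expects a single 2-D slice")
    p = net.predict_proba(image)
    return (p >= threshold).astype(np.float32)


def save_checkpoint(net: NetworkGraph, path) -> None:
    """Serialize parameters and architecture config to a single .npz file."""
    arrays = {f"p{i:04d}": p.data for i, p in enumerate(net.parameters())}
    arrays["_spec_json"] = np.frombuffer(
        json.dumps(net.summary()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> NetworkGraph:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["_spec_json"].tobytes()).decode())
        spec = NetSpec(variant=meta["variant"], depth=meta["depth"],
                       base_filters=meta["base_filters"], alpha=meta["alpha"],
                       seed=meta["seed"])
        net = build_network(spec)
        for i, p in enumerate(net.parameters()):
            p.data = data[f"p{i:04d}"].astype(np.float32)
    return net
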