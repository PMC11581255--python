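"""Densely connected convolutional feature extractor with channel
squeeze-and-excitation (SE) recalibration.

The network follows the classic densely-connected layout: a 7x7 stride-2
convolution stem with 3x3 max pooling, four dense blocks (each layer a
1x1 bottleneck followed by a 3x3 convolution, every layer receiving the
channel concatenation of all previous outputs), 1x1-conv + 2x2
average-pool transitions between blocks, an SE block after each dense
block, and a global-average-pool head that yields the fixed-length
feature vector.  An L-layer dense block therefore contains exactly
L(L+1)/2 direct layer-to-layer feeds.

Epochs are mapped to single-channel "images" of shape
``1 x n_channels x n_samples`` so 2-D kernels slide over the
channel x time plane.  The extractor is forward-only with seeded
He-style initialization: downstream classification is delegated to the
convolutional autoencoder, and the hyperparameter search varies the
architecture rather than training it, so reproducible random features
are the contract here.  A softmax head is retained for standalone use.

Implementation is plain NumPy (im2col convolutions); desk-scale inputs
keep this fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .epochs import EEGEpoch


class ConfigurationError(ValueError):
    """Raised when the input is too small for the stem/pool stack."""


#: named presets: block layout approximating total depths of 72/96/121
#: (depth = 2*sum(block_layers) + stem + 3 transitions + classifier),
#: plus a deliberately small layout for desk-scale runs.
PRESETS: dict[str, dict] = {
    "tiny": {"block_layers": [2, 2, 2, 2], "growth_rate": 8, "stem_channels": 8},
    "d72": {"block_layers": [4, 8, 12, 9], "growth_rate": 12, "stem_channels": 16},
    "d96": {"block_layers": [5, 10, 18, 13], "growth_rate": 12, "stem_channels": 16},
    "d121": {"block_layers": [6, 12, 24, 16], "growth_rate": 32, "stem_channels": 64},
}


@dataclass
class DenseNetConfig:
    growth_rate: int = 8
    block_layers: list[int] = field(default_factory=lambda: [2, 2, 2, 2])
    stem_channels: int = 8
    se_reduction: int = 4
    num_classes: int = 2
    input_shape: tuple[int, int, int] = (1, 3, 500)  # (channels, height, width)

    def __post_init__(self) -> None:
        ints = [self.growth_rate, self.stem_channels, self.se_reduction,
                self.num_classes, *self.block_layers]
        if any(int(v) <= 0 for v in ints):
            raise ValueError("all size parameters must be positive integers")

    @property
    def total_depth(self) -> int:
        """Counted layers: 2 convs per dense layer + stem + 3 transition
        convs + classifier."""
        return 2 * sum(self.block_layers) + 5

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "DenseNetConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        kw = dict(PRESETS[name])
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# primitive layers (im2col convolutions)


def _he_init(rng, c_out, c_in, kh, kw):
    fan_in = c_in * kh * kw
    return rng.standard_normal((c_out, c_in * kh * kw)) * np.sqrt(2.0 / fan_in)


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
           kh: int, kw: int, stride: int = 1, pad: tuple[int, int] = (0, 0)
           ) -> np.ndarray:
    """2-D convolution of a (C,H,W) tensor; weight is (Cout, C*kh*kw)."""
    c, h, w = x.shape
    x = np.pad(x, ((0, 0), (pad[0], pad[0]), (pad[1], pad[1])))
    if x.shape[1] < kh or x.shape[2] < kw:
        raise ConfigurationError(
            f"spatial size {x.shape[1:]} smaller than kernel ({kh},{kw})")
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    ho, wo = win.shape[1], win.shape[2]
    cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * kh * kw)
    out = cols @ weight.T + bias
    return out.reshape(ho, wo, -1).transpose(2, 0, 1)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def max_pool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1
             ) -> np.ndarray:
    x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)),
               constant_values=-np.inf)
    kh = min(k, x.shape[1])
    kw = min(k, x.shape[2])
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    return win.max(axis=(-1, -2))


def avg_pool(x: np.ndarray, k: int = 2, stride: int = 2) -> np.ndarray:
    kh = min(k, x.shape[1])
    kw = min(k, x.shape[2])
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    return win.mean(axis=(-1, -2))


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# SE recalibration


@dataclass
class SEBlock:
    """Channel attention: squeeze (global average pool per channel),
    excite through a reduce/expand bottleneck, sigmoid gate, rescale."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    @classmethod
    def init(cls, channels: int, reduction: int, rng) -> "SEBlock":
        if channels < 1:
            raise ValueError("need at least one channel")
        hidden = max(1, channels // reduction)
        return cls(
            w1=rng.standard_normal((hidden, channels)) * np.sqrt(2.0 / channels),
            b1=np.zeros(hidden),
            w2=rng.standard_normal((channels, hidden)) * np.sqrt(2.0 / hidden),
            b2=np.zeros(channels))

    def gate(self, x: np.ndarray) -> np.ndarray:
        squeeze = x.mean(axis=(1, 2))                      # (C,)
        hidden = relu(self.w1 @ squeeze + self.b1)
        return sigmoid(self.w2 @ hidden + self.b2)         # in (0,1)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x * self.gate(x)[:, None, None]


def se_recalibrate(x: np.ndarray, reduction: int, rng=None) -> np.ndarray:
    """Standalone SE pass with freshly initialized gate weights."""
    rng = np.random.default_rng(rng)
    return SEBlock.init(x.shape[0], reduction, rng)(x)


# ---------------------------------------------------------------------------
# dense blocks


@dataclass
class _ConvLayer:
    weight: np.ndarray
    bias: np.ndarray
    kh: int
    kw: int
    stride: int = 1
    pad: tuple[int, int] = (0, 0)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return conv2d(x, self.weight, self.bias, self.kh, self.kw,
                      self.stride, self.pad)


@dataclass
class DenseBlock:
    """L composite layers; layer i consumes the concatenation of the
    block input and all previous layer outputs."""

    layers: list[tuple[_ConvLayer, _ConvLayer]]
    growth_rate: int
    in_channels: int

    @classmethod
    def init(cls, in_channels: int, n_layers: int, growth: int, rng
             ) -> "DenseBlock":
        layers = []
        c = in_channels
        for _ in range(n_layers):
            bottleneck = 4 * growth
            l1 = _ConvLayer(_he_init(rng, bottleneck, c, 1, 1),
                            np.zeros(bottleneck), 1, 1)
            l2 = _ConvLayer(_he_init(rng, growth, bottleneck, 3, 3),
                            np.zeros(growth), 3, 3, pad=(1, 1))
            layers.append((l1, l2))
            c += growth
        return cls(layers=layers, growth_rate=growth, in_channels=in_channels)

    @property
    def out_channels(self) -> int:
        return self.in_channels + len(self.layers) * self.growth_rate

    def n_direct_connections(self) -> int:
        """Count direct feeds by traversing the concatenation graph:
        layer i receives i tensors, so an L-layer block has L(L+1)/2."""
        return sum(i + 1 for i in range(len(self.layers)))

    def forward(self, x0: np.ndarray,
                ablate: tuple[int, int] | None = None) -> np.ndarray:
        """Run the block.  ``ablate=(layer, input_index)`` zeroes one
        concatenation input of one layer (diagnostic for verifying the
        dense connectivity is load-bearing)."""
        feats = [x0]
        for i, (l1, l2) in enumerate(self.layers):
            inputs = list(feats)
            if ablate is not None and ablate[0] == i:
                j = ablate[1]
                inputs[j] = np.zeros_like(inputs[j])
            cat = np.concatenate(inputs, axis=0)
            feats.append(l2(relu(l1(relu(cat)))))
        return np.concatenate(feats, axis=0)

    __call__ = forward


def dense_block_forward(block: DenseBlock, x0: np.ndarray,
                        ablate=None) -> np.ndarray:
    if x0.shape[0] != block.in_channels:
        raise ValueError(f"expected {block.in_channels} input channels, "
                         f"got {x0.shape[0]}")
    return block.forward(x0, ablate=ablate)


# ---------------------------------------------------------------------------
# full network


@dataclass
class DenseNet:
    config: DenseNetConfig
    stem: _ConvLayer
    blocks: list[DenseBlock]
    se_blocks: list[SEBlock]
    transitions: list[_ConvLayer]
    fc_w: np.ndarray
    fc_b: np.ndarray

    @property
    def feature_dim(self) -> int:
        return self.blocks[-1].out_channels

    def n_direct_connections(self) -> list[int]:
        return [b.n_direct_connections() for b in self.blocks]

    def features(self, x: np.ndarray) -> np.ndarray:
        """(C,H,W) image -> global-average-pooled feature vector."""
        if x.shape != self.config.input_shape:
            raise ValueError(f"expected input shape {self.config.input_shape}, "
                             f"got {x.shape}")
        h = relu(self.stem(x))
        h = max_pool(h, 3, 2, 1)
        for i, block in enumerate(self.blocks):
            h = block(h)
            h = self.se_blocks[i](h)
            if i < len(self.transitions):
                h = relu(self.transitions[i](h))
                h = avg_pool(h, 2, 2)
        return h.mean(axis=(1, 2))  # global average pool

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.fc_w @ self.features(x) + self.fc_b

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.logits(x)
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()


def build_densenet(config: DenseNetConfig, seed: int = 0) -> DenseNet:
    """Construct the network with seeded He-style initialization."""
    rng = np.random.default_rng(seed)
    cin, h_in, w_in = config.input_shape
    if h_in < 1 or w_in < 8:  # narrower than the 7-tap stem is meaningless
        raise ConfigurationError(
            f"input spatial size {(h_in, w_in)} too small for the 7x7 "
            "stride-2 stem")
    stem = _ConvLayer(_he_init(rng, config.stem_channels, cin, 7, 7),
                      np.zeros(config.stem_channels), 7, 7, stride=2,
                      pad=(3, 3))
    blocks, se_blocks, transitions = [], [], []
    c = config.stem_channels
    for i, n_layers in enumerate(config.block_layers):
        block = DenseBlock.init(c, n_layers, config.growth_rate, rng)
        blocks.append(block)
        c = block.out_channels
        se_blocks.append(SEBlock.init(c, config.se_reduction, rng))
        if i < len(config.block_layers) - 1:
            c_half = max(1, c // 2)
            transitions.append(_ConvLayer(_he_init(rng, c_half, c, 1, 1),
                                          np.zeros(c_half), 1, 1))
            c = c_half
    fc_w = rng.standard_normal((config.num_classes, c)) * np.sqrt(2.0 / c)
    model = DenseNet(config=config, stem=stem, blocks=blocks,
                     se_blocks=se_blocks, transitions=transitions,
                     fc_w=fc_w, fc_b=np.zeros(config.num_classes))
    # fail fast if the spatial stack collapses below one pixel
    model.features(np.zeros(config.input_shape))
    return model


def epoch_to_image(epoch: EEGEpoch) -> np.ndarray:
    """Map an epoch to a single-channel channels x time image."""
    return epoch.data[None, :, :]


def extract_features(model: DenseNet, epochs: list[EEGEpoch]) -> np.ndarray:
    """One fixed-length feature vector per epoch (rows follow input
    order; deterministic for fixed weights)."""
    return np.stack([model.features(epoch_to_image(ep)) for ep in epochs])
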