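"""The lesion classification network (LCNet): an 11-block CNN.

The network is built from small convolutional blocks, each a run of
conv -> batch-norm -> LeakyReLU(0.3) layers, wired so that parallel
blocks see the same input and their feature maps are concatenated
channel-wise — feature information flows through the network along
multiple paths of different receptive field.

Canonical wiring for 128x128x3 input::

    stem   conv 8@3x3 stride 2 (BN+LReLU) -> max-pool 2x2    = 32x32x8  (P)
    junction  concat[ block1(P), block2(P), P ]              = 32x32x72
    block3 36@1x1 -> avg-pool                                = 16x16x36
    group A (x2)  concat[ block4, block5 ]  (r,m)=(32,64)    -> 128 ch
    block6 32@1x1 -> avg-pool                                = 8x8x32
    group B (x4)  concat[ block7, block8 ]  (r,m)=(64,128)   -> 256 ch
    block9 64@1x1 -> avg-pool                                = 4x4x64
    group C (x2)  concat[ block10, block11 ] (r,m)=(128,256) -> 512 ch
    head   global average pool -> FC 512 -> n_classes -> softmax

where block1/4/7/10 are r@1x1 -> m@3x3 and block2/5/8/11 are a single
m@3x3, all on the unit's input.  The three repeat groups run 2, 4 and
2 times; only the first unit of a group sees the preceding reduction
block's channel count, subsequent units see the unit output (2m).

This wiring has exactly 31 convolutional layers and 3,100 kernels; the
structural parameter count (conv weights+biases, 2 batch-norm
learnables per channel, FC weights+biases) is 3,435,598, about 4%
above the 3.3 M headline figure the architecture is known by — no
rewiring consistent with the written description closes that gap, so
it is documented rather than guessed away (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import layers as L

__all__ = [
    "ConvSpec",
    "BlockSpec",
    "LCNetConfig",
    "NetworkStats",
    "build_config",
    "build_network",
    "network_stats",
    "leaky_relu",
    "LCNetModel",
]

LEAKY_SLOPE = 0.3


def leaky_relu(x: float, slope: float = LEAKY_SLOPE) -> float:
    """Scalar LeakyReLU: x for x >= 0, slope * x otherwise."""
    return x if x >= 0 else slope * x


@dataclass(frozen=True)
class ConvSpec:
    """One convolutional layer: kernel count, size, stride, padding."""

    n_kernels: int
    kernel_size: int
    stride: int = 1
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        if self.kernel_size not in (1, 3):
            raise ValueError(f"kernel_size must be 1 or 3, got {self.kernel_size}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")


@dataclass(frozen=True)
class BlockSpec:
    """A block: conv layers (each followed by BN + LeakyReLU), optional pool."""

    block_id: int
    convs: tuple[ConvSpec, ...]
    pool: str = "none"  # "none" | "avg2x2"

    def __post_init__(self) -> None:
        if not 1 <= self.block_id <= 11:
            raise ValueError("block_id must be 1..11")
        if self.pool not in ("none", "avg2x2"):
            raise ValueError(f"unknown pool {self.pool!r}")


@dataclass(frozen=True)
class LCNetConfig:
    """Immutable structural description of the canonical architecture."""

    n_classes: int = 2
    input_size: int = 128
    input_channels: int = 3
    stem: ConvSpec = ConvSpec(8, 3, stride=2)
    blocks: tuple[BlockSpec, ...] = field(default=())
    repeats: tuple[int, int, int] = (2, 4, 2)
    leaky_slope: float = LEAKY_SLOPE


def build_config(n_classes: int = 2) -> LCNetConfig:
    """The canonical 11-block configuration (only the head width varies)."""
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    blocks = (
        BlockSpec(1, (ConvSpec(16, 1), ConvSpec(32, 3))),
        BlockSpec(2, (ConvSpec(32, 3),)),
        BlockSpec(3, (ConvSpec(36, 1),), pool="avg2x2"),
        BlockSpec(4, (ConvSpec(32, 1), ConvSpec(64, 3))),
        BlockSpec(5, (ConvSpec(64, 3),)),
        BlockSpec(6, (ConvSpec(32, 1),), pool="avg2x2"),
        BlockSpec(7, (ConvSpec(64, 1), ConvSpec(128, 3))),
        BlockSpec(8, (ConvSpec(128, 3),)),
        BlockSpec(9, (ConvSpec(64, 1),), pool="avg2x2"),
        BlockSpec(10, (ConvSpec(128, 1), ConvSpec(256, 3))),
        BlockSpec(11, (ConvSpec(256, 3),)),
    )
    return LCNetConfig(n_classes=n_classes, blocks=blocks)


@dataclass(frozen=True)
class NetworkStats:
    n_conv_layers: int
    n_kernels: int
    n_learnable_params: int


def _expanded_conv_layers(config: LCNetConfig) -> tuple[list[tuple[int, ConvSpec]], int]:
    """(in_ch, spec) for every conv layer in network order, plus head width.

    Walks the wiring without instantiating weights, tracking the channel
    count entering each layer; the concatenation arithmetic lives here.
    """
    by_id = {b.block_id: b for b in config.blocks}

    def block_convs(block: BlockSpec, in_ch: int):
        out = []
        for spec in block.convs:
            out.append((in_ch, spec))
            in_ch = spec.n_kernels
        return out, in_ch

    result: list[tuple[int, ConvSpec]] = [(config.input_channels, config.stem)]
    p_ch = config.stem.n_kernels  # after max-pool, channels unchanged
    # stem junction: blocks 1 and 2 in parallel on P, concat with P
    convs1, out1 = block_convs(by_id[1], p_ch)
    convs2, out2 = block_convs(by_id[2], p_ch)
    result += convs1 + convs2
    ch = out1 + out2 + p_ch
    # three (reduction block, repeated unit) stages
    stages = [(3, (4, 5)), (6, (7, 8)), (9, (10, 11))]
    for repeat, (red_id, (a_id, b_id)) in zip(config.repeats, stages):
        red_convs, ch = block_convs(by_id[red_id], ch)
        result += red_convs
        for _ in range(repeat):
            convs_a, out_a = block_convs(by_id[a_id], ch)
            convs_b, out_b = block_convs(by_id[b_id], ch)
            result += convs_a + convs_b
            ch = out_a + out_b
    return result, ch


def network_stats(config: LCNetConfig) -> NetworkStats:
    """Structural counts: conv layers, kernels, learnable parameters.

    Parameters = conv weights+biases + 2 batch-norm learnables per conv
    output channel (running statistics excluded) + FC weights+biases.
    """
    conv_layers, final_ch = _expanded_conv_layers(config)
    n_layers = len(conv_layers)
    n_kernels = 0
    n_params = 0
    for in_ch, spec in conv_layers:
        n_kernels += spec.n_kernels
        n_params += spec.n_kernels * (in_ch * spec.kernel_size**2 + 1)  # w + b
        n_params += 2 * spec.n_kernels  # BN scale + offset
    n_params += final_ch * config.n_classes + config.n_classes  # FC w + b
    return NetworkStats(n_layers, n_kernels, n_params)


class LCNetModel:
    """Instantiated network: (B, 3, 128, 128) batches -> class probabilities."""

    def __init__(self, config: LCNetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        slope = config.leaky_slope
        by_id = {b.block_id: b for b in config.blocks}

        def conv_bn_act(in_ch: int, spec: ConvSpec) -> tuple[L.Sequential, int]:
            return (
                L.Sequential(
                    L.Conv2d(
                        in_ch,
                        spec.n_kernels,
                        spec.kernel_size,
                        stride=spec.stride,
                        padding=spec.padding,
                        rng=rng,
                        dtype=dtype,
                        init_slope=slope,
                    ),
                    L.BatchNorm2d(spec.n_kernels, dtype=dtype),
                    L.LeakyReLU(slope),
                ),
                spec.n_kernels,
            )

        def build_block(block: BlockSpec, in_ch: int) -> tuple[L.Sequential, int]:
            mods = []
            for spec in block.convs:
                m, in_ch = conv_bn_act(in_ch, spec)
                mods.append(m)
            if block.pool == "avg2x2":
                mods.append(L.AvgPool2())
            return L.Sequential(*mods), in_ch

        seq: list[L.Module] = []
        stem, p_ch = conv_bn_act(config.input_channels, config.stem)
        seq.append(stem)
        seq.append(L.MaxPool2())
        b1, out1 = build_block(by_id[1], p_ch)
        b2, out2 = build_block(by_id[2], p_ch)
        seq.append(L.ConcatUnit([b1, b2], include_input=True))
        ch = out1 + out2 + p_ch
        for repeat, (red_id, (a_id, b_id)) in zip(
            config.repeats, [(3, (4, 5)), (6, (7, 8)), (9, (10, 11))]
        ):
            red, ch = build_block(by_id[red_id], ch)
            seq.append(red)
            for _ in range(repeat):
                br_a, out_a = build_block(by_id[a_id], ch)
                br_b, out_b = build_block(by_id[b_id], ch)
                seq.append(L.ConcatUnit([br_a, br_b]))
                ch = out_a + out_b
        seq.append(L.GlobalAvgPool())
        seq.append(L.Linear(ch, config.n_classes, rng=rng, dtype=dtype))
        self.body = L.Sequential(*seq)
        self.final_channels = ch

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        s = self.config.input_size
        if x.ndim != 4 or x.shape[1] != self.config.input_channels or x.shape[2:] != (s, s):
            raise ValueError(
                f"expected input of shape (B, {self.config.input_channels}, {s}, {s}), "
                f"got {x.shape}"
            )
        return x.astype(self.dtype, copy=False)

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.body.forward(self._check_input(x), training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities (softmax over the head logits)."""
        return L.softmax(self.forward_logits(x, training))

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        return self.body.backward(grad_logits)

    def params(self) -> list[tuple[str, L.Param]]:
        return self.body.params()

    def zero_grad(self) -> None:
        for _, p in self.params():
            p.grad[...] = 0

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value.copy() for name, p in self.params()}
        for name, mod in self._bn_modules():
            state[f"{name}.running_mean"] = mod.running_mean.copy()
            state[f"{name}.running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.params():
            p.value = state[name].astype(self.dtype).copy()
        for name, mod in self._bn_modules():
            mod.running_mean = state[f"{name}.running_mean"].astype(self.dtype).copy()
            mod.running_var = state[f"{name}.running_var"].astype(self.dtype).copy()

    def _bn_modules(self):
        out = []

        def walk(mod, prefix):
            if isinstance(mod, L.BatchNorm2d):
                out.append((prefix, mod))
            elif isinstance(mod, L.Sequential):
                for i, m in enumerate(mod.modules):
                    walk(m, f"{prefix}.{i}" if prefix else str(i))
            elif isinstance(mod, L.ConcatUnit):
                for i, m in enumerate(mod.branches):
                    walk(m, f"{prefix}.b{i}")

        walk(self.body, "")
        return out


def build_network(config: LCNetConfig, seed: int = 0) -> LCNetModel:
    """Instantiate the network with seed-deterministic initial weights."""
    return LCNetModel(config, seed=seed)
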