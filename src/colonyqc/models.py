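"""The five VGG-family colony classifiers, built declaratively from a registry.

The registry maps each architecture name to its conv-block layout.  VGG13
follows the canonical configuration-B stack (2x64, 2x128, 2x256, 2x512,
2x512 convs with 3x3 kernels and 2x2 max-pools) with a reduced two-layer
head ending in a single sigmoid unit for the binary good/bad decision.

* ``VGG13-FirstPool4`` — first max-pool has kernel/stride 4, shrinking every
  downstream feature map (and the head) fourfold in area.
* ``VGG12`` — VGG13 with the second conv of the last block removed.
* ``Res+VGG13`` — VGG13 with a learnable 1x1 projection skip around each
  block's conv stack (added before the block's final ReLU + pool).  Zeroing
  every skip projection makes the forward pass exactly VGG13's.

A ``width_multiplier`` scales all channel widths, giving the reduced
variants used for desk-scale training; the layout is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import RegistryError, ValidationError

__all__ = ["ArchitectureSpec", "ModelHandle", "REGISTRY", "registry_names",
           "architecture_spec", "build_model", "forward", "parameter_count_from_spec"]

_VGG13_BLOCKS = ((2, 64), (2, 128), (2, 256), (2, 512), (2, 512))
_VGG12_BLOCKS = ((2, 64), (2, 128), (2, 256), (2, 512), (1, 512))

#: name -> (conv_blocks, first_pool_size, residual)
REGISTRY = {
    "VGG13": (_VGG13_BLOCKS, 2, False),
    "VGG13-FirstPool4": (_VGG13_BLOCKS, 4, False),
    "VGG12": (_VGG12_BLOCKS, 2, False),
    "VGG12-FirstPool4": (_VGG12_BLOCKS, 4, False),
    "Res+VGG13": (_VGG13_BLOCKS, 2, True),
}

_HEAD_HIDDEN = 256  # hidden width of the 2-layer head at width_multiplier=1


def registry_names() -> list[str]:
    return list(REGISTRY)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Resolved description of one network variant."""

    name: str
    conv_blocks: tuple[tuple[int, int], ...]   # (n_convs, channels) per block
    first_pool_size: int
    residual: bool
    input_side: int
    width_multiplier: float = 1.0
    in_channels: int = 1

    def channels(self) -> list[int]:
        """Width-scaled channel count per block (floor of 4)."""
        return [max(4, int(round(c * self.width_multiplier)))
                for _, c in self.conv_blocks]

    def head_hidden(self) -> int:
        return max(8, int(round(_HEAD_HIDDEN * self.width_multiplier)))

    def pool_sizes(self) -> list[int]:
        return [self.first_pool_size] + [2] * (len(self.conv_blocks) - 1)

    def feature_map_sides(self) -> list[int]:
        """Spatial side after each block's pool."""
        sides = []
        s = self.input_side
        for k in self.pool_sizes():
            if s % k:
                raise ValidationError(
                    f"input_side {self.input_side} not divisible by the "
                    f"pooling cascade of {self.name} (stuck at {s} / pool {k})")
            s //= k
            sides.append(s)
        return sides

    def total_downsample(self) -> int:
        return int(np.prod(self.pool_sizes()))


def architecture_spec(name: str, input_side: int = 256,
                      width_multiplier: float = 1.0,
                      in_channels: int = 1) -> ArchitectureSpec:
    if name not in REGISTRY:
        raise RegistryError(
            f"unknown architecture {name!r}; valid names: {registry_names()}")
    blocks, first_pool, residual = REGISTRY[name]
    spec = ArchitectureSpec(name=name, conv_blocks=blocks,
                            first_pool_size=first_pool, residual=residual,
                            input_side=input_side,
                            width_multiplier=width_multiplier,
                            in_channels=in_channels)
    spec.feature_map_sides()   # validates divisibility
    return spec


def parameter_count_from_spec(spec: ArchitectureSpec) -> int:
    """Parameter count by layer-by-layer arithmetic on the spec alone."""
    total = 0
    in_ch = spec.in_channels
    for (n_convs, _), ch in zip(spec.conv_blocks, spec.channels()):
        for _ in range(n_convs):
            total += ch * in_ch * 9 + ch
            in_ch = ch
    if spec.residual:
        # one 1x1 projection skip per block, block input -> block output
        prev = spec.in_channels
        for ch in spec.channels():
            total += ch * prev * 1 + ch
            prev = ch
    feat_side = spec.feature_map_sides()[-1]
    feat = spec.channels()[-1] * feat_side * feat_side
    hidden = spec.head_hidden()
    total += hidden * feat + hidden
    total += 1 * hidden + 1
    return total


def _build_network(spec: ArchitectureSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Module] = []
    in_ch = spec.in_channels
    for b, ((n_convs, _), ch, pool) in enumerate(
            zip(spec.conv_blocks, spec.channels(), spec.pool_sizes())):
        convs: list[nn.Module] = []
        block_in = in_ch
        for i in range(n_convs):
            convs.append(nn.Conv2d(block_in if i == 0 else ch, ch, 3, rng,
                                   name=f"b{b}c{i}"))
            if i < n_convs - 1:
                convs.append(nn.ReLU())
        main = nn.Sequential(convs)
        if spec.residual:
            skip = nn.Conv2d(in_ch, ch, 1, rng, name=f"b{b}skip")
            layers.append(nn.ResidualWrap(main, skip))
        else:
            layers.append(main)
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2d(pool))
        in_ch = ch
    layers.append(nn.Flatten())
    feat_side = spec.feature_map_sides()[-1]
    feat = spec.channels()[-1] * feat_side * feat_side
    hidden = spec.head_hidden()
    layers.append(nn.Linear(feat, hidden, rng, name="head0"))
    layers.append(nn.ReLU())
    layers.append(nn.Linear(hidden, 1, rng, name="head1"))
    return nn.Sequential(layers)


@dataclass
class ModelHandle:
    """An initialized network plus the spec it was built from."""

    architecture: ArchitectureSpec
    network: nn.Sequential
    init_seed: int

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.network.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.network.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.network.parameters(), weights):
            p.value[...] = w

    def logits(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        batch = _check_batch(batch, self.architecture)
        return self.network.forward(batch, train=train).ravel()

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Predicted probability that each image shows a good colony."""
        return nn.sigmoid(self.logits(batch, train=False))


def _check_batch(batch: np.ndarray, spec: ArchitectureSpec) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.float64)
    s = spec.input_side
    if batch.ndim == 3:
        batch = batch[:, None, :, :]
    if batch.ndim != 4 or batch.shape[1:] != (spec.in_channels, s, s):
        raise ValidationError(
            f"expected batch of shape (N, {spec.in_channels}, {s}, {s}), "
            f"got {batch.shape}")
    return batch


def build_model(name: str, input_side: int = 256, seed: int = 0,
                width_multiplier: float = 1.0) -> ModelHandle:
    """Build an initialized model; weights are deterministic given the seed."""
    spec = architecture_spec(name, input_side, width_multiplier)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x11F7)))
    net = _build_network(spec, rng)
    return ModelHandle(architecture=spec, network=net, init_seed=int(seed))


def forward(model: ModelHandle, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward pass; probabilities strictly inside (0, 1)."""
    return model.predict_proba(batch)


def save_model(model: ModelHandle, path) -> None:
    """Serialize spec + weights to a single .npz checkpoint."""
    import json

    spec = model.architecture
    meta = {"name": spec.name, "input_side": spec.input_side,
            "width_multiplier": spec.width_multiplier,
            "in_channels": spec.in_channels, "init_seed": model.init_seed}
    arrays = {f"w{i}": p.value for i, p in enumerate(model.network.parameters())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> ModelHandle:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = build_model(meta["name"], meta["input_side"],
                            seed=meta["init_seed"],
                            width_multiplier=meta["width_multiplier"])
        model.set_weights([data[f"w{i}"]
                           for i in range(len(model.network.parameters()))])
    return model
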