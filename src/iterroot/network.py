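"""The iterative residual U-Net architecture.

One full-depth "input" U-Net (4 encoder levels) is followed by a chain of
smaller refinement U-Nets (3 encoder levels).  Every sub-network is built
from residual units (conv3x3 -> batch-norm -> ReLU -> conv3x3 ->
batch-norm -> add input -> ReLU) and owns a sigmoid output head, so a
forward pass yields ``iterations + 1`` probability maps; the last map is
the final segmentation.

Refinement network k receives, concatenated channel-wise before its
first downsampling, the last-hidden-layer features of network k-1 plus
the first-layer features of the previous two networks (network 0's first
layer being the input network's stem).  These inter-network skips carry
high-level image detail forward while each refinement re-processes the
learned representation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor

INPUT_NET_DEPTH = 4
SECONDARY_NET_DEPTH = 3


@dataclass(frozen=True)
class IterRootConfig:
    in_channels: int = 3
    base_features: int = 32
    iterations: int = 3
    input_net_depth: int = INPUT_NET_DEPTH
    secondary_net_depth: int = SECONDARY_NET_DEPTH
    binarize_threshold: float = 0.5
    pre_concat: bool = True            # concat skip before the transpose (figure wiring)
    skip_mode: str = "previous_two"    # or "all": first layers of every previous net

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be positive")
        if self.base_features < 1:
            raise ValueError("base_features must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be nonnegative")
        if self.input_net_depth != INPUT_NET_DEPTH:
            raise ValueError(f"input_net_depth is fixed at {INPUT_NET_DEPTH}")
        if self.secondary_net_depth != SECONDARY_NET_DEPTH:
            raise ValueError(f"secondary_net_depth is fixed at {SECONDARY_NET_DEPTH}")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.skip_mode not in ("previous_two", "all"):
            raise ValueError("skip_mode must be 'previous_two' or 'all'")

    @property
    def divisibility(self) -> int:
        return 2 ** self.input_net_depth


@dataclass
class ForwardResult:
    """Probability maps of one sample, in network order (last = final)."""

    probability_maps: list[np.ndarray]

    @property
    def final(self) -> np.ndarray:
        return self.probability_maps[-1]


# ----------------------------------------------------------------------
# blocks
# ----------------------------------------------------------------------

class ResidualUnit(nn.Module):
    """conv-BN-ReLU-conv-BN + input skip (1x1 projection on width change)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if in_ch != out_ch:
            self.project = nn.Conv2d(in_ch, out_ch, 1, rng)
        else:
            self.project = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        return nn.relu(h + self.project(x))


class DownBlock(nn.Module):
    """Residual unit followed by 2x2 max pooling (halves spatial dims)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.unit = ResidualUnit(in_ch, out_ch, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (pre-pool features, pooled features)."""
        pre = self.unit(x)
        return pre, nn.max_pool2d(pre)


class UpBlock(nn.Module):
    """Transpose-convolution upsampling with an encoder skip.

    Default wiring concatenates the skip (at the *pre-upsampled*
    resolution) before the transpose convolution; ``pre_concat=False``
    gives the standard U-Net order (upsample, then concatenate a skip at
    the target resolution).
    """

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int,
                 rng: np.random.Generator, pre_concat: bool = True):
        super().__init__()
        self.pre_concat = pre_concat
        if pre_concat:
            self.upsample = nn.ConvTranspose2d(in_ch + skip_ch, out_ch, rng)
            self.unit = ResidualUnit(out_ch, out_ch, rng)
        else:
            self.upsample = nn.ConvTranspose2d(in_ch, out_ch, rng)
            self.unit = ResidualUnit(out_ch + skip_ch, out_ch, rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        if self.pre_concat:
            if x.shape[2:] != skip.shape[2:]:
                raise ValueError(
                    f"up_block skip spatial dims {skip.shape[2:]} do not match "
                    f"input {x.shape[2:]}")
            return self.unit(self.upsample(nn.concat([x, skip], axis=1)))
        up = self.upsample(x)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"up_block skip spatial dims {skip.shape[2:]} do not match "
                f"upsampled input {up.shape[2:]}")
        return self.unit(nn.concat([up, skip], axis=1))


class OutputBlock(nn.Module):
    """3x3 convolution to one channel followed by a sigmoid.

    The head is initialized at a tenth of the usual scale so an untrained
    model emits near-0.5 probabilities instead of saturated ones.
    """

    def __init__(self, in_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, 1, 3, rng, init_scale=0.1)

    def forward(self, x: Tensor) -> Tensor:
        return nn.sigmoid(self.conv(x))


class UNet(nn.Module):
    """Residual U-Net returning (probability map, last hidden, stem features)."""

    def __init__(self, in_ch: int, base: int, depth: int,
                 rng: np.random.Generator, pre_concat: bool = True):
        super().__init__()
        self.depth = depth
        self.pre_concat = pre_concat
        self.stem = ResidualUnit(in_ch, base, rng)
        chans = [base * 2 ** i for i in range(depth + 1)]
        self.downs = [DownBlock(chans[i], chans[i + 1], rng) for i in range(depth)]
        self.bottleneck = ResidualUnit(chans[depth], chans[depth], rng)
        ups = []
        for i in range(depth, 0, -1):
            # skip = pooled encoder features (pre_concat) or pre-pool (standard)
            ups.append(UpBlock(chans[i], chans[i], chans[i - 1], rng,
                               pre_concat=pre_concat))
        self.ups = ups
        self.head = OutputBlock(base, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.depth
        if h % div or w % div:
            raise ValueError(
                f"spatial dims {h}x{w} must be divisible by {div} "
                f"for a depth-{self.depth} network")
        stem = self.stem(x)
        feats = stem
        pre_pool, post_pool = [], []
        for down in self.downs:
            pre, feats = down(feats)
            pre_pool.append(pre)
            post_pool.append(feats)
        feats = self.bottleneck(feats)
        for level, up in zip(range(self.depth, 0, -1), self.ups):
            skip = post_pool[level - 1] if self.pre_concat else pre_pool[level - 1]
            feats = up(feats, skip)
        return self.head(feats), feats, stem


class IterRoot(nn.Module):
    """Input U-Net plus ``iterations`` refinement U-Nets with skip wiring."""

    def __init__(self, config: IterRootConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        base = config.base_features
        self.input_net = UNet(config.in_channels, base, config.input_net_depth,
                              rng, pre_concat=config.pre_concat)
        nets = []
        for k in range(1, config.iterations + 1):
            if config.skip_mode == "previous_two":
                n_first = min(2, k)
            else:
                n_first = k
            nets.append(UNet(base * (1 + n_first), base,
                             config.secondary_net_depth, rng,
                             pre_concat=config.pre_concat))
        self.refine_nets = nets

    def forward(self, x: Tensor) -> list[Tensor]:
        out, hidden, stem = self.input_net(x)
        maps = [out]
        first_layers = [stem]
        for net in self.refine_nets:
            if self.config.skip_mode == "previous_two":
                skips = first_layers[-2:][::-1]
            else:
                skips = first_layers[::-1]
            inp = nn.concat([hidden] + skips, axis=1)
            out, hidden, stem_k = net(inp)
            maps.append(out)
            first_layers.append(stem_k)
        return maps

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


# ----------------------------------------------------------------------
# module surface
# ----------------------------------------------------------------------

def build_model(config: IterRootConfig | None = None,
                seed: int = 0) -> IterRoot:
    """Assemble a model with deterministic, seeded initialization."""
    if config is None:
        config = IterRootConfig()
    rng = np.random.default_rng(seed)
    return IterRoot(config, rng)


def forward(model: IterRoot, images: np.ndarray) -> list[ForwardResult]:
    """Run a batch of (N, H, W, 3) images in evaluation mode.

    Returns one :class:`ForwardResult` per batch item, each holding
    ``iterations + 1`` probability maps of the input's spatial size.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    x = Tensor(images.transpose(0, 3, 1, 2))
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            maps = model(x)
    finally:
        if was_training:
            model.train()
    stacked = [m.data[:, 0] for m in maps]     # each (N, H, W)
    return [ForwardResult([s[i] for s in stacked])
            for i in range(images.shape[0])]


# ----------------------------------------------------------------------
# checkpointing
# ----------------------------------------------------------------------

def save_checkpoint(model: IterRoot, path, extra: dict | None = None) -> None:
    state = model.state_arrays()
    meta = {"config": asdict(model.config), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> IterRoot:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = IterRootConfig(**meta["config"])   # re-validates
    model = build_model(config, seed=0)
    model.load_state_arrays(state)
    return model
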