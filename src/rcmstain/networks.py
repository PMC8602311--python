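"""Network architectures for virtual staining and learned registration.

The acetic-acid staining generator is an attention U-Net whose first
encoder block runs three 3x3x3 convolutions without depth padding, so a
seven-slice input collapses 7 -> 5 -> 3 -> 1 and the rest of the network
is 2D.  The discriminator is a plain conv stack with spectral
normalization scoring an image into (0, 1).  The bridge networks used for
registration and the pseudo-H&E renderer reuse the same U-Net backbone in
2D with fewer levels/channels, and the DVF-predicting network is the same
backbone with a zero-initialized linear head emitting a 2-channel
displacement field (identity warp at initialization).
"""

from __future__ import annotations

import dataclasses
import numpy as np

from . import nn
from .nn import Tensor, ops


@dataclasses.dataclass
class GeneratorConfig:
    input_depth: int = 7
    in_channels: int = 1
    out_channels: int = 1
    n_levels: int = 5
    base_channels: int = 48
    channel_cap: int = 768
    attention_gates: bool = True
    leaky_slope: float = 0.2
    final_activation: str = "sigmoid"     # "sigmoid" | "none"
    zero_init_final: bool = False
    seed: int = 0

    def validate(self):
        if self.input_depth < 1 or self.input_depth % 2 == 0:
            raise ValueError("input_depth must be odd and >= 1")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.final_activation not in ("sigmoid", "none"):
            raise ValueError("final_activation must be 'sigmoid' or 'none'")


@dataclasses.dataclass
class DiscriminatorConfig:
    n_blocks: int = 5
    base_channels: int = 32
    fc_width: int = 1024
    spectral_norm: bool = True
    leaky_slope: float = 0.2
    seed: int = 0


@dataclasses.dataclass
class GanLossConfig:
    """Loss weights: alpha scales total variation, lam the adversarial
    term, delta_fraction sets the BerHu threshold as a fraction of the
    target image's standard deviation."""

    alpha: float = 0.02
    lam: float = 15.0
    delta_fraction: float = 0.2

    def validate(self):
        if min(self.alpha, self.lam, self.delta_fraction) < 0:
            raise ValueError("loss coefficients must be nonnegative")


class _AttentionGate(nn.Module):
    """Additive soft attention on a skip connection.

    1x1 convs project the gating (decoder) and skip (encoder) signals to an
    intermediate width, their sum passes ReLU, and a final 1x1 conv +
    sigmoid yields a pixel-wise multiplicative weight map for the skip.
    """

    def __init__(self, ch_skip: int, ch_gate: int, rng):
        super().__init__()
        inter = max(ch_skip // 2, 1)
        self.wx = nn.Conv2d(ch_skip, inter, 1, rng)
        self.wg = nn.Conv2d(ch_gate, inter, 1, rng)
        self.psi = nn.Conv2d(inter, 1, 1, rng)

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        a = (self.wx(skip) + self.wg(gate)).relu()
        weights = self.psi(a).sigmoid()
        return skip * weights


class _ConvBlock2d(nn.Module):
    """Three 3x3 convs with batch norm + leaky ReLU, optional residual add
    from the block input (1x1-projected when channels differ)."""

    def __init__(self, in_ch: int, out_ch: int, rng, slope: float,
                 residual: bool):
        super().__init__()
        self.slope = slope
        self.residual = residual
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.b1 = nn.BatchNorm(out_ch)
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.b2 = nn.BatchNorm(out_ch)
        self.c3 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.b3 = nn.BatchNorm(out_ch)
        if residual and in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.b1(self.c1(x)).leaky_relu(self.slope)
        h = self.b2(self.c2(h)).leaky_relu(self.slope)
        h = self.b3(self.c3(h)).leaky_relu(self.slope)
        if self.residual:
            h = h + (self.proj(x) if self.proj is not None else x)
        return h


class _EntryBlock3d(nn.Module):
    """First encoder block: three 3D convs, depth-valid, collapsing the
    input depth to 1; residual from the central input slice."""

    def __init__(self, in_ch: int, out_ch: int, input_depth: int, rng,
                 slope: float):
        super().__init__()
        self.slope = slope
        self.input_depth = input_depth
        depth = input_depth
        self.convs, self.bns, self.kds = [], [], []
        ch = in_ch
        for i in range(3):
            kd = 3 if depth >= 3 else 1
            conv = nn.Conv3dDepthValid(ch, out_ch, rng, kernel=3) if kd == 3 \
                else None
            if kd == 1:
                conv = nn.Conv2d(ch, out_ch, 3, rng)
            self._modules[f"c{i}"] = conv
            bn = nn.BatchNorm(out_ch)
            self._modules[f"b{i}"] = bn
            self.convs.append(conv)
            self.bns.append(bn)
            self.kds.append(kd)
            depth = depth - kd + 1
            ch = out_ch
        if depth != 1:
            raise ValueError(
                f"input_depth {input_depth} does not collapse to one slice "
                "within three depth-valid convolutions (supported: 1, 3, 5, 7)")
        self.proj = nn.Conv2d(in_ch, out_ch, 1, rng)
        self.depth_trace = self._trace()

    def _trace(self) -> list[int]:
        d = [self.input_depth]
        for kd in self.kds:
            d.append(d[-1] - kd + 1)
        return d

    def forward(self, x: Tensor) -> Tensor:
        # x: (N, C, D, H, W); central slice kept for the residual add
        center = x[:, :, self.input_depth // 2]
        h = x
        depth = self.input_depth
        for conv, bn, kd in zip(self.convs, self.bns, self.kds):
            if kd == 3:
                h = conv(h)
            else:
                if h.ndim == 5:      # depth already 1: drop the axis
                    h = h[:, :, 0]
                h = conv(h)
            h = bn(h).leaky_relu(self.slope)
            depth = depth - kd + 1
        if h.ndim == 5:
            h = h[:, :, 0]
        return h + self.proj(center)


class Generator(nn.Module):
    """Attention U-Net mapping a depth-window of RCM slices to one stained
    slice (or, in 2D mode, image(s) to image(s))."""

    def __init__(self, config: GeneratorConfig | None = None, **kw):
        super().__init__()
        config = config or GeneratorConfig(**kw)
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = [min(config.base_channels * 2 ** i, config.channel_cap)
                 for i in range(config.n_levels)]
        self.chans = chans
        s = config.leaky_slope
        # encoder
        if config.input_depth > 1:
            self.entry = _EntryBlock3d(config.in_channels, chans[0],
                                       config.input_depth, rng, s)
        else:
            self.entry = _ConvBlock2d(config.in_channels, chans[0], rng, s,
                                      residual=True)
        for i in range(1, config.n_levels):
            self._modules[f"down{i}"] = _ConvBlock2d(chans[i - 1], chans[i],
                                                     rng, s, residual=True)
        # bottleneck operates below the deepest skip
        self.bottom = _ConvBlock2d(chans[-1], chans[-1], rng, s, residual=True)
        # decoder
        for i in range(config.n_levels - 1, -1, -1):
            gate_ch = chans[min(i + 1, config.n_levels - 1)] \
                if i < config.n_levels - 1 else chans[-1]
            if config.attention_gates:
                self._modules[f"att{i}"] = _AttentionGate(chans[i], gate_ch,
                                                          rng)
            self._modules[f"up{i}"] = _ConvBlock2d(chans[i] + gate_ch,
                                                   chans[i], rng, s,
                                                   residual=False)
        self.head = nn.Conv2d(chans[0], config.out_channels, 1, rng,
                              zero_init=config.zero_init_final)

    # -- shape handling ----------------------------------------------------
    def _check_spatial(self, h: int, w: int):
        f = 2 ** self.config.n_levels
        if h % f or w % f:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by {f}; pad or crop "
                f"the input to a multiple of 2^{self.config.n_levels}")

    def depth_trace(self) -> list[int]:
        """Depth of the activation after each conv of the entry block."""
        if isinstance(self.entry, _EntryBlock3d):
            return self.entry.depth_trace
        return [1, 1, 1, 1]

    def forward(self, x) -> Tensor:
        cfg = self.config
        x = nn.as_tensor(x)
        if cfg.input_depth > 1:
            if x.ndim == 3:                      # (D, H, W)
                x = x.reshape(1, 1, *x.shape)
            elif x.ndim == 4:                    # (N, D, H, W)
                x = x.reshape(x.shape[0], 1, *x.shape[1:])
            if x.data.shape[2] != cfg.input_depth:
                raise ValueError(
                    f"expected {cfg.input_depth} input slices, got "
                    f"{x.data.shape[2]}")
            self._check_spatial(*x.data.shape[3:])
        else:
            if x.ndim == 2:
                x = x.reshape(1, 1, *x.shape)
            elif x.ndim == 3:
                if cfg.in_channels > 1 and x.shape[0] == cfg.in_channels:
                    x = x.reshape(1, *x.shape)   # (C, H, W) single sample
                else:
                    x = x.reshape(x.shape[0], 1, *x.shape[1:])
            if x.data.shape[1] != cfg.in_channels:
                raise ValueError(
                    f"expected {cfg.in_channels} input channels, got "
                    f"{x.data.shape[1]}")
            self._check_spatial(*x.data.shape[2:])

        skips = []
        h = self.entry(x)
        skips.append(h)
        h = ops.avg_pool2d(h)
        for i in range(1, cfg.n_levels):
            h = self._modules[f"down{i}"](h)
            skips.append(h)
            h = ops.avg_pool2d(h)
        h = self.bottom(h)
        for i in range(cfg.n_levels - 1, -1, -1):
            h = ops.upsample_bilinear2x(h)
            skip = skips[i]
            if cfg.attention_gates:
                skip = self._modules[f"att{i}"](skip, h)
            h = self._modules[f"up{i}"](nn.concat([skip, h], axis=1))
        out = self.head(h)
        if cfg.final_activation == "sigmoid":
            out = out.sigmoid()
        if cfg.out_channels == 1:
            out = out[:, 0]
        return out

    def infer(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode forward returning a plain array."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(x).data
        finally:
            self.train(was_training)
        if out.shape[0] == 1 and np.asarray(x).ndim in (2, 3):
            out = out[0]
        return out


class Discriminator(nn.Module):
    """Conv stack + FC head scoring an image into (0, 1)."""

    def __init__(self, config: DiscriminatorConfig | None = None, **kw):
        super().__init__()
        config = config or DiscriminatorConfig(**kw)
        self.config = config
        rng = np.random.default_rng(config.seed + 1)
        ch = 1
        for i in range(config.n_blocks):
            out_ch = min(config.base_channels * 2 ** i, config.fc_width)
            self._modules[f"c{i}a"] = nn.Conv2d(
                ch, out_ch, 3, rng, stride=1,
                spectral_norm=config.spectral_norm)
            self._modules[f"c{i}b"] = nn.Conv2d(
                out_ch, out_ch, 2, rng, stride=2, padding=0,
                spectral_norm=config.spectral_norm)
            ch = out_ch
        self.fc1 = nn.Linear(ch, config.fc_width, rng)
        self.fc2 = nn.Linear(config.fc_width, 1, rng)

    def forward(self, x) -> Tensor:
        x = nn.as_tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        h_, w_ = x.data.shape[2:]
        if min(h_, w_) < 2 ** self.config.n_blocks:
            raise ValueError(
                f"discriminator input {h_}x{w_} too small for "
                f"{self.config.n_blocks} downsamplings (needs >= "
                f"{2 ** self.config.n_blocks} px)")
        s = self.config.leaky_slope
        h = x
        for i in range(self.config.n_blocks):
            h = self._modules[f"c{i}a"](h).leaky_relu(s)
            h = self._modules[f"c{i}b"](h).leaky_relu(s)
        h = h.mean(axis=(2, 3))              # global average pool -> (N, C)
        h = self.fc1(h).leaky_relu(s)
        return self.fc2(h).sigmoid()[:, 0]   # (N,) scores in (0, 1)


def build_generator(config: GeneratorConfig | None = None, **kw) -> Generator:
    return Generator(config, **kw)


def build_discriminator(config: DiscriminatorConfig | None = None,
                        **kw) -> Discriminator:
    return Discriminator(config, **kw)


def build_vshe_network(base_channels: int = 16, n_levels: int = 3,
                       seed: int = 0) -> Generator:
    """Pseudo-H&E renderer: (stained, unstained) 2-channel input -> RGB.

    Same U-Net backbone as the registration bridge networks, with two
    input and three output channels and a sigmoid head keeping the RGB
    output in (0, 1).
    """
    return Generator(GeneratorConfig(
        input_depth=1, in_channels=2, out_channels=3, n_levels=n_levels,
        base_channels=base_channels, attention_gates=False, seed=seed))


def architecture_summary(model: nn.Module) -> dict:
    """JSON-serializable parameter/shape audit of a model."""
    state = model.state_dict()
    return {"n_parameters": int(sum(v.size for v in state.values())),
            "tensors": {k: list(v.shape) for k, v in state.items()}}


def save_checkpoint(model: nn.Module, path):
    np.savez(path, **model.state_dict())


def load_checkpoint(model: nn.Module, path):
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
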