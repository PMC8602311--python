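"""Network building blocks: modules with parameters, serialization, modes."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor
from . import ops

__all__ = ["Module", "Conv2d", "Conv3dDepthValid", "Linear", "BatchNorm",
           "Sequential"]


class Module:
    """Minimal module: tracks parameters and sub-modules, train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, t: Tensor) -> Tensor:
        t.requires_grad = True
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat state dict for checkpointing ---------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data.copy() for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        for k, v in getattr(self, "_buffers", {}).items():
            for stat, arr in v.items():
                out[f"{prefix}{k}.{stat}"] = np.asarray(arr).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, v in self._params.items():
            v.data = np.array(state[prefix + k], dtype=np.float64)
        for k, buf in getattr(self, "_buffers", {}).items():
            for stat in list(buf.keys()) or ("mean", "var"):
                key = f"{prefix}{k}.{stat}"
                if key in state:
                    buf[stat] = np.array(state[key])
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """3x3/2x2/1x1 2D convolution with optional spectral normalization.

    Spectral normalization divides the weight by its leading singular value
    (one power iteration per forward pass, estimate carried between calls);
    the scale is treated as a constant in the backward pass.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, padding: int | None = None,
                 spectral_norm: bool = False, zero_init: bool = False):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        w = np.zeros((out_ch, in_ch, kernel, kernel)) if zero_init else \
            _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.w = self.register("w", Tensor(w))
        self.b = self.register("b", Tensor(np.zeros(out_ch)))
        self.spectral_norm = spectral_norm
        self._u = rng.normal(size=out_ch) if spectral_norm else None

    def _normalized_weight(self) -> Tensor:
        wmat = self.w.data.reshape(self.w.data.shape[0], -1)
        v = wmat.T @ self._u
        v /= (np.linalg.norm(v) + 1e-12)
        u = wmat @ v
        sigma = np.linalg.norm(u) + 1e-12
        self._u = u / sigma
        return self.w * (1.0 / sigma)

    def forward(self, x: Tensor) -> Tensor:
        w = self._normalized_weight() if self.spectral_norm else self.w
        return ops.conv2d(x, w, self.b, stride=self.stride,
                          padding=self.padding)


class Conv3dDepthValid(Module):
    """3x3x3 convolution, valid along depth, same-padded laterally."""

    def __init__(self, in_ch: int, out_ch: int, rng, kernel: int = 3):
        super().__init__()
        fan_in = in_ch * kernel ** 3
        self.w = self.register(
            "w", Tensor(_he_init(rng, (out_ch, in_ch, kernel, kernel, kernel),
                                 fan_in)))
        self.b = self.register("b", Tensor(np.zeros(out_ch)))

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv3d_depth_valid(x, self.w, self.b)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng):
        super().__init__()
        self.w = self.register("w", Tensor(_he_init(rng, (in_f, out_f), in_f)))
        self.b = self.register("b", Tensor(np.zeros(out_f)))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class BatchNorm(Module):
    """Batch normalization over every axis but channel; tracks running stats."""

    def __init__(self, n_ch: int):
        super().__init__()
        self.gamma = self.register("gamma", Tensor(np.ones(n_ch)))
        self.beta = self.register("beta", Tensor(np.zeros(n_ch)))
        self._buffers = {"running": {}}

    def forward(self, x: Tensor) -> Tensor:
        return ops.batch_norm(x, self.gamma, self.beta,
                              running=self._buffers["running"],
                              training=self.training)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            if isinstance(layer, Module):
                self._modules[f"l{i}"] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x
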