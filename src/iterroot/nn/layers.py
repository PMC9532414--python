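"""Layer abstractions on top of the autodiff engine.

Modules hold :class:`Parameter` tensors and a shared training-mode flag;
initialization draws from a caller-supplied ``numpy.random.Generator`` so
model construction is fully deterministic under a seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters are trainable even under no_grad


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            mod = stack.pop()
            for value in vars(mod).values():
                if isinstance(value, Parameter) and id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        stack = [self]
        while stack:
            mod = stack.pop()
            for value in vars(mod).values():
                children = []
                if isinstance(value, Module):
                    children = [value]
                elif isinstance(value, (list, tuple)):
                    children = [v for v in value if isinstance(v, Module)]
                for child in children:
                    mods.append(child)
                    stack.append(child)
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- flat state dict of numpy arrays (parameters + buffers) ---------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(mod: Module, prefix: str):
            for name, value in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    out[key] = value.data
                elif isinstance(value, np.ndarray):
                    out[key] = value
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, v in enumerate(value):
                        if isinstance(v, Module):
                            walk(v, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"checkpoint missing arrays: {sorted(missing)[:5]}")
        for key, arr in own.items():
            src = np.asarray(state[key])
            if src.shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {key}: checkpoint {src.shape}, model {arr.shape}")
            arr[...] = src


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1 convolution with zero padding (``same`` for odd kernels)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None,
                 init_scale: float = 1.0):
        super().__init__()
        if padding is None:
            padding = kernel_size // 2
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(init_scale * _he_normal(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2d(Module):
    """Kernel-2, stride-2 transpose convolution (exact x2 upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_normal(
            rng, (in_channels, out_channels, 2, 2), in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm(x, self.gamma, self.beta,
                             self.running_mean, self.running_var,
                             training=self.training,
                             momentum=self.momentum, eps=self.eps)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
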