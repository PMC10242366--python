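"""Parameter containers: Module base class and layer primitives."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import DEFAULT_DTYPE, Tensor


class Module:
    """Base class; discovers parameters/submodules from instance attributes."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameter_count(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def named_buffers(self, prefix: str = ""):
        """Non-trainable state (e.g. batch-norm running statistics)."""
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        if set(params) | set(buffers) != set(state):
            raise KeyError("state dict does not match module parameters/buffers")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for parameter {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for name, b in buffers.items():
            b[:] = state[name]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype=DEFAULT_DTYPE):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv2D(Module):
    """Same-padding stride-1 convolution with He-uniform init."""

    def __init__(self, c_in, c_out, kernel, rng, dtype=DEFAULT_DTYPE):
        if c_out < 1:
            raise ValueError("channels must be >= 1")
        fan_in = kernel * kernel * c_in
        self.weight = Tensor(
            he_uniform(rng, (kernel, kernel, c_in, c_out), fan_in, dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def forward(self, x, training=False):
        return F.conv2d(x, self.weight, self.bias)


class ConvTranspose2D(Module):
    """2x2 stride-2 transposed convolution (learned x2 upsampling)."""

    def __init__(self, c_in, c_out, rng, dtype=DEFAULT_DTYPE):
        fan_in = 4 * c_in
        self.weight = Tensor(
            he_uniform(rng, (2, 2, c_in, c_out), fan_in, dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def forward(self, x, training=False):
        return F.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2D(Module):
    def __init__(self, channels, dtype=DEFAULT_DTYPE):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, training=False):
        return F.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, training
        )


class PReLU(Module):
    """Channel-wise parametric ReLU; slopes initialised to 0.25."""

    def __init__(self, channels, dtype=DEFAULT_DTYPE):
        self.alpha = Tensor(
            np.full(channels, 0.25, dtype=dtype), requires_grad=True
        )

    def forward(self, x, training=False):
        return F.prelu(x, self.alpha)
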