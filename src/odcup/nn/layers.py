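"""Layer abstractions over the autograd engine: modules, parameters, init.

Weights are initialised from an explicit :class:`numpy.random.Generator`, so a
model built twice from the same seed is bit-identical.  ``state_dict`` /
``load_state_dict`` round-trip through plain dictionaries of numpy arrays and
serialise to ``.npz`` checkpoints.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module base: parameter discovery, state dicts, grad clearing."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as f:
            self.load_state_dict({k: f[k] for k in f.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 dilation=1, bias=True, *, rng: np.random.Generator):
        k = int(kernel_size)
        self.stride, self.padding, self.dilation = int(stride), int(padding), int(dilation)
        fan_in = in_channels * k * k
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 bias=True, *, rng: np.random.Generator):
        k = int(kernel_size)
        self.stride, self.padding = int(stride), int(padding)
        fan_in = in_channels * k * k
        self.weight = Parameter(_he_init(rng, (in_channels, out_channels, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = float(slope)

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *modules):
        self.layers = list(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
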