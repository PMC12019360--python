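"""Neural-network layers on top of the autodiff tensor.

Modules register parameters, buffers and sub-modules by attribute assignment
(torch-like), which gives deterministic, named state dictionaries for
checkpointing.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array: np.ndarray):
        self._buffers[name] = name
        object.__setattr__(self, name, np.asarray(array, dtype=np.float64))

    # -- traversal -----------------------------------------------------------
    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self):
        for m in self.modules():
            yield from m._params.values()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state ---------------------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name in self._buffers:
            out[prefix + name] = getattr(self, name)
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = np.asarray(state[prefix + name], dtype=np.float64).reshape(p.data.shape)
        for name in self._buffers:
            object.__setattr__(self, name, np.asarray(state[prefix + name], dtype=np.float64))
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.n_layers = len(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for i in range(self.n_layers):
            x = getattr(self, f"layer{i}")(x)
        return x


def _init_conv(rng: np.random.Generator, shape, std: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = _init_conv(rng, (out_ch, in_ch, kernel, kernel))
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = _init_conv(rng, (in_ch, out_ch, kernel, kernel))
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _init_conv(rng, (in_features, out_features))
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalization with running statistics for evaluation mode."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            object.__setattr__(self, "running_mean",
                               (1 - m) * self.running_mean + m * mu.data.reshape(c))
            object.__setattr__(self, "running_var",
                               (1 - m) * self.running_var + m * var.data.reshape(c))
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x):
        c = x.shape[1]
        if x.shape[2] * x.shape[3] < 2:
            # a single spatial element has no meaningful statistics;
            # normalizing it would erase the signal entirely
            return x * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=(2, 3), keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Dropout(Module):
    """Inverted dropout.

    When ``frozen`` is set, the mask of the previous call is reused as long as
    the input shape matches; the gradient-penalty computation relies on this to
    evaluate the critic at perturbed inputs under identical masks.
    """

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng
        self.frozen = False
        self._mask: np.ndarray | None = None

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        if not (self.frozen and self._mask is not None and self._mask.shape == x.shape):
            keep = 1.0 - self.p
            mask = (self.rng.random(x.shape) < keep) / keep
            object.__setattr__(self, "_mask", mask)
        return x * Tensor(self._mask)


def freeze_dropout(module: Module, flag: bool) -> None:
    for m in module.modules():
        if isinstance(m, Dropout):
            object.__setattr__(m, "frozen", flag)
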