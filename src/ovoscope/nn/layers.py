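"""Neural-network modules on top of the autodiff engine.

The Module protocol mirrors the conventions of the major frameworks:
`parameters()` walks the attribute tree, `train()`/`eval()` toggle
batch-norm statistics, and calling a module runs its forward pass.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, maxpool2d

__all__ = [
    "Module",
    "Sequential",
    "Identity",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
]


class Module:
    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params = [
            v for v in self.__dict__.values()
            if isinstance(v, Tensor) and v.requires_grad
        ]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                state[key] = value.data
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                state[key] = value
            elif isinstance(value, Module):
                state.update(value.state_dict(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{key}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                value.data = np.asarray(state[key], dtype=np.float32).reshape(value.shape)
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                value[...] = state[key]
            elif isinstance(value, Module):
                value.load_state_dict(state, f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{key}.{i}.")


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Conv2d(Module):
    """2-D convolution with Kaiming-normal (fan-out) initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = padding
        fan_out = out_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_out))
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel_size, self.stride, self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(num_features), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        gamma = self.weight.reshape(1, c, 1, 1)
        beta = self.bias.reshape(1, c, 1, 1)
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            xhat = centred * ((var + self.eps) ** -0.5)
        else:
            rm = self.running_mean.reshape(1, c, 1, 1)
            rstd = 1.0 / np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
            xhat = (x - rm) * rstd
        return xhat * gamma + beta


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, std: float | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = std if std is not None else float(np.sqrt(2.0 / in_features))
        self.weight = Tensor(rng.normal(0.0, std, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
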