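"""Parameterized layers built on the autograd core."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batchnorm2d, conv3x3, maxpool2x2

__all__ = ["Module", "Conv3x3", "BatchNorm2d", "Linear", "MaxPool2x2"]


class Module:
    """Base class: named parameter traversal and train/eval mode."""

    training: bool = True

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                params[key] = value
            elif isinstance(value, Module):
                params.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{key}.{i}."))
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def _submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                yield from (v for v in value if isinstance(v, Module))

    def train(self) -> None:
        self.training = True
        for m in self._submodules():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._submodules():
            m.eval()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv3x3(Module):
    """3x3 same-padding convolution, He-normal initialization."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        std = np.sqrt(2.0 / (in_channels * 9))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_channels, in_channels, 3, 3)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3x3(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int):
        self.channels = channels
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var, self.training
        )


class MaxPool2x2(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class Linear(Module):
    """Affine layer; weight stored as (in_features, out_features)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        std = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(in_features, out_features)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
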