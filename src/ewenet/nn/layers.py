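"""Layer/module abstractions over the autograd primitives."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, add, batch_norm, conv2d, leaky_relu, upsample2x

__all__ = ["Module", "ConvBNLeaky", "ConvLinear", "Residual", "Upsample2x", "Sequential"]


class Module:
    """Base class: parameter/buffer registry, train/eval mode, state dict."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        return arr

    def parameters(self) -> Iterator[Tensor]:
        yield from self._params.values()
        for child in self._children.values():
            yield from child.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield f"{prefix}{name}", b
        for cname, child in self._children.items():
            yield from child.named_buffers(prefix=f"{prefix}{cname}.")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"param.{k}": v.data for k, v in self.named_parameters()}
        out.update({f"buffer.{k}": v for k, v in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                params[name].data = np.asarray(value, dtype=np.float32).copy()
            elif kind == "buffer":
                buffers[name][...] = value
            else:  # pragma: no cover - corrupted checkpoint
                raise KeyError(f"unknown state entry {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], slope: float = 0.1) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    std = np.sqrt(2.0 / ((1 + slope**2) * fan_in))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class ConvBNLeaky(Module):
    """3x3/1x1 convolution + batch norm + leaky ReLU(0.1) — the basic unit."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.pad = k // 2
        self.weight = self.register_parameter("weight", _he_init(rng, (c_out, c_in, k, k)))
        self.gamma = self.register_parameter("gamma", np.ones(c_out, dtype=np.float32))
        self.beta = self.register_parameter("beta", np.zeros(c_out, dtype=np.float32))
        self.running_mean = self.register_buffer("running_mean", np.zeros(c_out))
        self.running_var = self.register_buffer("running_var", np.ones(c_out))

    def forward(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.weight, stride=self.stride, pad=self.pad)
        y = batch_norm(
            y, self.gamma, self.beta, self.running_mean, self.running_var, self.training
        )
        return leaky_relu(y)


class ConvLinear(Module):
    """1x1 convolution with bias and no activation — the prediction head."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        bias_init: np.ndarray | None = None,
    ):
        super().__init__()
        self.weight = self.register_parameter("weight", _he_init(rng, (c_out, c_in, 1, 1)))
        bias = np.zeros(c_out, dtype=np.float32) if bias_init is None else bias_init
        self.bias = self.register_parameter("bias", bias.astype(np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, bias=self.bias, stride=1, pad=0)


class Residual(Module):
    """Bottleneck residual unit: 1x1 halving conv, 3x3 conv, additive skip."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        mid = max(1, channels // 2)
        self.conv1 = ConvBNLeaky(channels, mid, 1, 1, rng)
        self.conv2 = ConvBNLeaky(mid, channels, 3, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return add(x, self.conv2(self.conv1(x)))


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample2x(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.mods = list(modules)
        for i, m in enumerate(modules):
            self._children[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
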