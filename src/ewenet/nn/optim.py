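"""Stochastic gradient descent with momentum and weight decay."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["SGD"]


class SGD:
    """Classic momentum SGD: ``v = mu*v + (g + wd*w); w -= lr*v``.

    Weight decay is applied only to parameters flagged as decayable
    (convolution kernels); batch-norm scales/offsets and biases are
    exempt, the usual convention.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        momentum: float = 0.9,
        weight_decay: float = 5e-4,
        decay_mask: list[bool] | None = None,
    ):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.decay_mask = decay_mask if decay_mask is not None else [True] * len(self.params)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v, decay in zip(self.params, self._velocity, self.decay_mask):
            if p.grad is None:
                continue
            g = p.grad
            if decay and self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"velocity.{i}": v for i, v in enumerate(self._velocity)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i in range(len(self._velocity)):
            self._velocity[i][...] = state[f"velocity.{i}"]
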