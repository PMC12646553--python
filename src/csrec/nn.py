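"""Parameterised layers and the Adam optimiser used by the recommender.

All parameters are `autodiff.Tensor`s with `requires_grad=True`, registered
on a flat per-module dict so checkpoints serialise to plain ``.npz`` blobs.
Initialisation is Xavier-uniform from an explicit `numpy.random.Generator`,
so every model build is reproducible from a single integer seed.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .autodiff import Tensor


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Base class: recursive parameter registry."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def parameters(self) -> Iterable[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield name, p
        for mname, m in self._modules.items():
            for name, p in m.parameters():
                yield f"{mname}.{name}", p

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(np.float64).copy()


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int,
                 bias: bool = True):
        super().__init__()
        self.W = self.register("W", xavier_uniform(rng, in_dim, out_dim))
        self.b = self.register("b", np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class GRUCell(Module):
    """Standard gated recurrent unit.

    r = sigmoid(x Wxr + h Whr + br);  z = sigmoid(x Wxz + h Whz + bz)
    n = tanh(x Wxn + r * (h Whn) + bn);  h' = (1 - z) * n + z * h
    """

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden: int):
        super().__init__()
        self.hidden = hidden
        self.Wx = self.register("Wx", xavier_uniform(rng, in_dim, 3 * hidden,
                                                     (in_dim, 3 * hidden)))
        self.Wh = self.register("Wh", xavier_uniform(rng, hidden, 3 * hidden,
                                                     (hidden, 3 * hidden)))
        self.b = self.register("b", np.zeros(3 * hidden))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        d = self.hidden
        gx = x @ self.Wx + self.b
        gh = h @ self.Wh
        r = (gx[0:d] + gh[0:d]).sigmoid()
        z = (gx[d:2 * d] + gh[d:2 * d]).sigmoid()
        n = (gx[2 * d:3 * d] + r * gh[2 * d:3 * d]).tanh()
        return (1.0 - z) * n + z * h

    def run(self, xs: list[Tensor]) -> list[Tensor]:
        """Unroll over a sequence of 1D inputs from a zero initial state."""
        h = Tensor(np.zeros(self.hidden))
        states = []
        for x in xs:
            h = self(x, h)
            states.append(h)
        return states


class Adam:
    """Adam with decoupled-from-nothing classic L2 via `weight_decay`
    added to the gradient (the common coupled form)."""

    def __init__(self, params: Iterable[tuple[str, Tensor]], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = {name: np.zeros_like(p.data) for name, p in self.params}
        self.v = {name: np.zeros_like(p.data) for name, p in self.params}

    def step(self) -> None:
        self.t += 1
        for name, p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad = None
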