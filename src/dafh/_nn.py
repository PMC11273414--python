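"""Layers and optimizer on top of the autodiff engine.

Initialization follows the usual fan-based schemes (He for ReLU layers,
Glorot for linear maps) drawn from an explicit ``numpy.random.Generator``
so that a single seed fully determines the weights.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, conv2d

__all__ = ["Parameter", "Module", "Linear", "Conv2d", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny container: children and parameters discovered via attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for v in vars(self).values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Parameter) and id(item) not in seen:
                    seen.add(id(item))
                    params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(mod, prefix):
            for name, v in vars(mod).items():
                if isinstance(v, Parameter):
                    out[prefix + name] = v.data
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{name}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{name}.{i}.")
                        elif isinstance(item, Parameter):
                            out[f"{prefix}{name}.{i}"] = item.data

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        mine = self._named_parameters()
        missing = set(mine) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in mine.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def _named_parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def walk(mod, prefix):
            for name, v in vars(mod).items():
                if isinstance(v, Parameter):
                    out[prefix + name] = v
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{name}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{name}.{i}.")
                        elif isinstance(item, Parameter):
                            out[f"{prefix}{name}.{i}"] = item

        walk(self, "")
        return out


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 pad: int | None = None, bias: bool = True):
        fan_in = c_in * k * k
        sd = np.sqrt(2.0 / fan_in)  # He normal
        self.weight = Parameter(rng.normal(0.0, sd, size=(c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.pad = k // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class Adam:
    """Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
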