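"""Trainable layers built on the autodiff tensor.

Modules hold named parameters (Tensors with ``requires_grad=True``) and can
be toggled between training and inference mode (dropout / batch-norm).
Initialisation is Glorot-uniform and fully determined by the RNG handed in,
so two models built from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Linear", "Dropout", "BatchNorm1d", "LayerNorm", "Sequential"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Base class: parameter registry + train/eval mode propagation."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def register(self, name: str, value) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All persistent arrays (parameters + buffers) for checkpointing."""
        out = {k: v.data for k, v in self.named_parameters().items()}
        out.update(self.named_buffers())
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in getattr(self, "_buffers", {}).items()}
        for name, child in self._children.items():
            out.update(child.named_buffers(prefix + name + "."))
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self._buffer_refs()
        for key, value in arrays.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = np.asarray(value, dtype=np.float64)
            elif key in buffers:
                owner, name = buffers[key]
                owner._buffers[name] = np.asarray(value, dtype=np.float64)
            else:
                raise KeyError(f"unknown state entry {key!r}")

    def _buffer_refs(self, prefix: str = "") -> dict[str, tuple["Module", str]]:
        out = {prefix + k: (self, k) for k in getattr(self, "_buffers", {})}
        for name, child in self._children.items():
            out.update(child._buffer_refs(prefix + name + "."))
        return out

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


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.W = self.register("W", glorot(rng, in_dim, out_dim))
        self.b = self.register("b", np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Dropout(Module):
    """Inverted dropout; active only in training mode, seeded per forward."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class BatchNorm1d(Module):
    """Feature-wise batch normalisation over the row axis.

    Uses biased batch statistics in training (running stats tracked with
    momentum 0.1) and the running statistics at inference.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(dim))
        self.beta = self.register("beta", np.zeros(dim))
        self.eps = eps
        self.momentum = momentum
        self._buffers = {
            "running_mean": np.zeros(dim),
            "running_var": np.ones(dim),
        }

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel()
            )
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel()
            )
            xhat = centered * (var + self.eps) ** -0.5
        else:
            xhat = (x - self._buffers["running_mean"]) * (
                self._buffers["running_var"] + self.eps
            ) ** -0.5
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(dim))
        self.beta = self.register("beta", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = []
        for i, m in enumerate(modules):
            self.add_child(str(i), m)
            self.steps.append(m)

    def __call__(self, x: Tensor) -> Tensor:
        for m in self.steps:
            x = m(x)
        return x
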