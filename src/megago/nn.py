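"""Small neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "BatchNorm", "FeatureConv1d"]


class Module:
    """Base class: recursively collects parameter tensors and a train flag."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def set_training(self, flag: bool) -> None:
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flatten parameters (and buffers) into a name → array dict."""
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item.data
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and key in state:
                if v.data.shape != state[key].shape:
                    raise ValueError(
                        f"shape mismatch for '{key}': checkpoint "
                        f"{state[key].shape} vs model {v.data.shape}")
                v.data = np.array(state[key], dtype=np.float64)
            elif isinstance(v, np.ndarray) and key in state:
                setattr(self, name, np.array(state[key]))
            elif isinstance(v, Module):
                v.load_state_arrays(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        k = f"{key}.{i}"
                        if k in state:
                            item.data = np.array(state[k], dtype=np.float64)


class Linear(Module):
    """Affine map x @ W + b with Glorot-uniform init from a seeded RNG."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Tensor(rng.uniform(-limit, limit, (d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Per-row normalization with learned affine parameters."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta

    def normalize_only(self, x: Tensor) -> Tensor:
        """Normalization without the affine part (used in invariance tests)."""
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt()


class BatchNorm(Module):
    """Per-feature batch normalization over the node axis.

    Batch statistics are used in training mode; exponential running
    statistics at inference, so predictions are deterministic functions of
    the input.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.eps, self.momentum = eps, momentum
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class FeatureConv1d(Module):
    """Depthwise 1-D convolution along the feature axis of an N×d tensor.

    The kernel slides over feature positions, identically for every node, so
    the operation is permutation-equivariant over nodes.  Same-padding keeps
    the output shape N×d.
    """

    def __init__(self, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for same-padding")
        self.kernel = Tensor(rng.normal(0.0, 1.0 / kernel_size, kernel_size),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(1), requires_grad=True)
        self.kernel_size = kernel_size

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel_size
        half = k // 2
        padded = x.pad_axis1(half, half)
        d = x.shape[1]
        out = None
        for o in range(k):
            term = padded[:, o:o + d] * self.kernel[o]
            out = term if out is None else out + term
        return out + self.bias
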