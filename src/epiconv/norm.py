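"""Normalization layers for the 3 x dim HLA layer matrix.

Three interchangeable schemes, selectable per configuration:

* ``hlan`` — per-sample statistics pooled over *all* layers and embedding
  dimensions (C x H = 3 x dim entries), then a learnable affine.  This is
  the scheme built for the hierarchical encoding: it standardizes each
  sample using the joint spread of its three nomenclature layers, so
  between-layer offsets carry through while remaining batch-independent.
* ``batch`` — classic batch normalization with per-dimension statistics
  across the batch and running statistics for inference.
* ``layer`` — per-sample, per-row standardization (each 1 x dim layer row
  independently).

All three end with the same ``x * alpha + beta`` affine.  ``alpha`` and
``beta`` are scalars by default; a per-dimension variant is available via
``affine_shape="per-dim"``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["HlanParams", "Hlan", "BatchNorm", "LayerNormRows", "make_normalizer"]


class HlanParams:
    """Learnable scale/shift plus the stability constant for HLAN."""

    def __init__(
        self,
        dim: int = 128,
        epsilon: float = 1e-5,
        affine_shape: str = "scalar",
        per_layer_stats: bool = False,
    ):
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if affine_shape not in ("scalar", "per-dim"):
            raise ValueError(f"unknown affine shape {affine_shape!r}")
        self.C = 3
        self.H = dim
        self.epsilon = epsilon
        self.per_layer_stats = per_layer_stats
        shape = () if affine_shape == "scalar" else (dim,)
        self.alpha = Tensor(np.ones(shape), requires_grad=True)
        self.beta = Tensor(np.zeros(shape), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.alpha, self.beta]


def _standardize(x: Tensor, axes: tuple[int, ...], eps: float) -> Tensor:
    mu = x.mean(axis=axes, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=axes, keepdims=True)
    return centred / ((var + eps) ** 0.5)


class Hlan:
    """Per-sample normalization pooling statistics over layers and dims."""

    def __init__(self, params: HlanParams | None = None, dim: int = 128, **kw):
        self.p = params if params is not None else HlanParams(dim=dim, **kw)

    def __call__(self, x: Tensor) -> Tensor:
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite input to HLAN")
        if x.shape[-2] != self.p.C:
            raise ValueError(f"expected {self.p.C} layer rows, got {x.shape[-2]}")
        axes = (-1,) if self.p.per_layer_stats else (-2, -1)
        z = _standardize(x, axes, self.p.epsilon)
        return z * self.p.alpha + self.p.beta

    def params(self) -> list[Tensor]:
        return self.p.params()


class LayerNormRows:
    """Each 1 x dim row standardized independently, then shared affine."""

    def __init__(self, params: HlanParams | None = None, dim: int = 128, **kw):
        self.p = params if params is not None else HlanParams(dim=dim, **kw)

    def __call__(self, x: Tensor) -> Tensor:
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite input to layer norm")
        z = _standardize(x, (-1,), self.p.epsilon)
        return z * self.p.alpha + self.p.beta

    def params(self) -> list[Tensor]:
        return self.p.params()


class BatchNorm:
    """Per-dimension statistics across the batch (axis 0).

    Training mode requires batch size >= 2; inference uses running
    statistics accumulated with momentum.  Unlike HLAN/layer norm, a
    sample's output depends on its batch companions during training.
    """

    def __init__(
        self,
        params: HlanParams | None = None,
        dim: int = 128,
        momentum: float = 0.1,
        **kw,
    ):
        self.p = params if params is not None else HlanParams(dim=dim, **kw)
        self.momentum = momentum
        self.running_mean = np.zeros((self.p.C, self.p.H))
        self.running_var = np.ones((self.p.C, self.p.H))
        self.training = True
        self._initialized = False

    def __call__(self, x: Tensor) -> Tensor:
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite input to batch norm")
        if x.ndim < 3:
            raise ValueError("batch norm expects a batched (B, 3, dim) input")
        if self.training:
            if x.shape[0] < 2:
                raise ValueError("batch of 1 in training mode")
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True)
            m = self.momentum if self._initialized else 1.0
            self.running_mean = (1 - m) * self.running_mean + m * mu.data[0]
            self.running_var = (1 - m) * self.running_var + m * var.data[0]
            self._initialized = True
            z = centred / ((var + self.p.epsilon) ** 0.5)
        else:
            z = (x - self.running_mean) * (
                1.0 / np.sqrt(self.running_var + self.p.epsilon)
            )
        return z * self.p.alpha + self.p.beta

    def params(self) -> list[Tensor]:
        return self.p.params()


def make_normalizer(kind: str, dim: int = 128, **kw):
    """Factory for the config enum {hlan, batch, layer, none}."""
    if kind == "hlan":
        return Hlan(dim=dim, **kw)
    if kind == "batch":
        return BatchNorm(dim=dim, **kw)
    if kind == "layer":
        return LayerNormRows(dim=dim, **kw)
    if kind in ("none", None):
        return None
    raise ValueError(f"unknown normalization kind {kind!r}")


def integrate_head(x: Tensor, kernel: Tensor, bias: Tensor) -> Tensor:
    """Learned convolution over the layer axis: (..., 3, dim) -> (..., dim).

    ``kernel`` has shape (3, dim) (a depthwise kernel spanning the three
    layer rows); with a row-summing kernel and zero bias the output is the
    column sums of the layer matrix.
    """
    if x.shape[-2] != 3:
        raise ValueError(f"expected 3 layer rows, got {x.shape[-2]}")
    if kernel.shape != (3, x.shape[-1]):
        raise ValueError("kernel/input shape mismatch")
    acc = None
    for i in range(3):
        term = x[..., i, :] * kernel[i]
        acc = term if acc is None else acc + term
    return acc + bias


# ---- functional numpy forms (convenient for direct checks) -----------------

def hlan(x: np.ndarray, alpha: float = 1.0, beta: float = 0.0,
         epsilon: float = 1e-5) -> np.ndarray:
    """Functional HLAN on a single 3 x dim array."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    mu = x.mean()
    var = x.var()
    return (x - mu) / np.sqrt(var + epsilon) * alpha + beta


def layer_norm(x: np.ndarray, alpha: float = 1.0, beta: float = 0.0,
               epsilon: float = 1e-5) -> np.ndarray:
    """Functional per-row layer norm on a single 3 x dim array."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + epsilon) * alpha + beta


def batch_norm(batch: np.ndarray, alpha: float = 1.0, beta: float = 0.0,
               epsilon: float = 1e-5) -> np.ndarray:
    """Functional training-mode batch norm on a (B, 3, dim) array."""
    batch = np.asarray(batch, dtype=float)
    if batch.shape[0] < 2:
        raise ValueError("batch of 1 in training mode")
    mu = batch.mean(axis=0, keepdims=True)
    var = batch.var(axis=0, keepdims=True)
    return (batch - mu) / np.sqrt(var + epsilon) * alpha + beta
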