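"""Training objective: per-channel similarity plus field-smoothness losses.

Two similarity metrics are provided.  ``mse`` is the mean squared intensity
difference between the fixed and warped-moving channel; it is the default on
[0,1] intensities.  ``lncc`` is the negated mean of the local normalized
cross-correlation over square windows (default 9 px), robust to the
illumination changes the acetowhitening reaction produces; its denominator
is epsilon-stabilized so constant windows do not divide by zero.

The smoothness (local spatial variation) loss is the mean of squared
forward-difference spatial gradients of the displacement field, over both
components and both axes; it is zero iff the field is constant, i.e. a pure
translation is not penalized.

Losses are differentiable graph nodes (``cervreg.nn.Tensor``); the module
also exposes plain-number wrappers matching the array-in/scalar-out
signature the rest of the package uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LossConfig",
    "similarity_loss",
    "smoothness_loss",
    "total_loss",
    "similarity_term",
    "smoothness_term",
]


@dataclass(frozen=True)
class LossConfig:
    similarity: str = "mse"  # "mse" | "lncc"
    lncc_window: int = 9
    lncc_eps: float = 1e-5
    lambda_smooth: float = 0.1

    def validate(self) -> None:
        if self.similarity not in ("mse", "lncc"):
            raise ValueError(f"unknown similarity {self.similarity!r}")
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be non-negative")
        if self.lncc_window < 3 or self.lncc_window % 2 == 0:
            raise ValueError("lncc_window must be odd and >= 3")


# -- graph-building terms (Tensors in, scalar Tensor out) ----------------


def similarity_term(fixed: Tensor, warped: Tensor, config: LossConfig) -> Tensor:
    """Similarity loss between a fixed channel and the warped moving channel."""
    config.validate()
    if fixed.shape != warped.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {warped.shape}")
    if config.similarity == "mse":
        return (fixed - warped).square().mean()
    return _lncc_term(fixed, warped, config)


def _lncc_term(f: Tensor, m: Tensor, config: LossConfig) -> Tensor:
    win = config.lncc_window
    margin = win // 2
    H, W = f.shape[-2], f.shape[-1]
    if H <= 2 * margin or W <= 2 * margin:
        raise ValueError(f"image {H}x{W} smaller than lncc window {win}")
    mu_f = nn.box_filter(f, win)
    mu_m = nn.box_filter(m, win)
    cov = nn.box_filter(f * m, win) - mu_f * mu_m
    var_f = nn.box_filter(f * f, win) - mu_f.square()
    var_m = nn.box_filter(m * m, win) - mu_m.square()
    denom = (var_f * var_m + config.lncc_eps).sqrt()
    cc = cov / denom
    # only windows fully inside the image contribute
    return -(nn.crop2d(cc, margin).mean())


def smoothness_term(field: Tensor) -> Tensor:
    """Mean squared forward-difference gradient of a (2, H, W) field."""
    dy = nn.spatial_diff(field, axis=-2)
    dx = nn.spatial_diff(field, axis=-1)
    n = dy.data.size + dx.data.size
    return (dy.square().sum() + dx.square().sum()) * (1.0 / n)


# -- plain-number wrappers ----------------------------------------------


def similarity_loss(fixed, warped, config: LossConfig = LossConfig()) -> float:
    """Scalar similarity loss between two (H, W) arrays."""
    f = Tensor(np.asarray(fixed, dtype=np.float64))
    m = Tensor(np.asarray(warped, dtype=np.float64))
    return float(similarity_term(f, m, config).data)


def smoothness_loss(field) -> float:
    """Scalar smoothness loss of a (H, W, 2) displacement field."""
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 3 or field.shape[2] != 2:
        raise ValueError(f"field must be (H, W, 2), got {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    return float(smoothness_term(Tensor(field.transpose(2, 0, 1))).data)


def total_loss(pairs, fields, config: LossConfig = LossConfig()) -> float:
    """Aggregate loss over channels.

    ``pairs`` is a sequence of ``(fixed, moving)`` (H, W) array pairs and
    ``fields`` the matching (H, W, 2) displacement fields (three of each in
    RGB mode, one in single-channel mode).  Each channel contributes
    ``similarity(fixed, warp(moving, field)) + lambda_smooth * smoothness``.
    """
    from .transform import warp

    pairs, fields = list(pairs), list(fields)
    if len(pairs) != len(fields) or len(pairs) not in (1, 3):
        raise ValueError(
            f"expected 1 or 3 channel pairs with matching fields, "
            f"got {len(pairs)} pairs and {len(fields)} fields"
        )
    config.validate()
    total = 0.0
    for (fixed, moving), field in zip(pairs, fields):
        warped = warp(np.asarray(moving, dtype=np.float64), field)
        total += similarity_loss(fixed, warped, config)
        total += config.lambda_smooth * smoothness_loss(field)
    return float(total)
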