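"""Feature extraction: images/volumes and clinical scalars to token sequences.

Raw images go through a small residual CNN backbone whose spatial output map
is unrolled super-pixel by super-pixel (row-major) into N tokens and linearly
projected to a common imaging width CX.  Scalar clinical variables are
one-hot encoded (continuous ones quantized into equal-width bins, with an
extra slot for MISSING), then mapped through a per-variable feed-forward
encoder (linear, GELU, layer norm) to a common non-imaging width CM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .synthetic import (
    CATEGORICAL_LEVELS,
    CONTINUOUS_RANGES,
    COVARIATE_NAMES,
    PatientRecord,
    is_missing,
)

__all__ = [
    "TokenSequence",
    "quantize_continuous",
    "CovariateSchema",
    "ScalarEncoder",
    "ImageEncoder",
    "unfold_grid",
    "fold_grid",
]


@dataclass
class TokenSequence:
    """Ordered fixed-width feature vectors for a transformer block.

    ``tokens`` has shape (batch, n_tokens, C).  ``grid_shape`` records the
    spatial layout of imaging tokens so attention maps can be folded back.
    """

    tokens: object  # nn.Tensor or ndarray, (B, n, C)
    modality_tag: str = "imaging"
    grid_shape: tuple | None = None

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[1]

    @property
    def width(self) -> int:
        return self.tokens.shape[2]


def quantize_continuous(value: float, vmin: float, vmax: float, bins: int = 4) -> np.ndarray:
    """Equal-width one-hot quantization of a continuous value.

    Bins are half-open except the last (closed at ``vmax``); out-of-range
    values are clipped into [vmin, vmax].
    """
    if vmin >= vmax:
        raise ValueError(f"vmin must be < vmax, got [{vmin}, {vmax}]")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    v = min(max(float(value), vmin), vmax)
    idx = min(int((v - vmin) / (vmax - vmin) * bins), bins - 1)
    out = np.zeros(bins)
    out[idx] = 1.0
    return out


@dataclass
class CovariateSchema:
    """Encoding plan for the clinical variables of a cohort.

    Continuous variables use per-variable min/max learned from the training
    split; every variable gets one extra one-hot slot for MISSING, so no
    imputation is needed.
    """

    bins: int = 4
    categorical_levels: dict = field(default_factory=dict)
    continuous_ranges: dict = field(default_factory=dict)

    @property
    def names(self) -> list:
        return list(self.categorical_levels) + list(self.continuous_ranges)

    def input_dim(self, name: str) -> int:
        if name in self.categorical_levels:
            return self.categorical_levels[name] + 1
        return self.bins + 1

    def fit(self, records: Sequence[PatientRecord]) -> "CovariateSchema":
        names = records[0].covariates.keys()
        for name in names:
            values = [r.covariates[name] for r in records if not is_missing(r.covariates[name])]
            if name in CATEGORICAL_LEVELS or all(
                isinstance(v, (int, np.integer)) for v in values
            ):
                levels = CATEGORICAL_LEVELS.get(name, int(max(values)) + 1 if values else 2)
                self.categorical_levels[name] = levels
            else:
                if not values:
                    lo, hi = CONTINUOUS_RANGES.get(name, (0.0, 1.0))
                else:
                    lo, hi = float(min(values)), float(max(values))
                    if lo == hi:
                        hi = lo + 1.0
                self.continuous_ranges[name] = (lo, hi)
        return self

    def encode_value(self, name: str, value) -> np.ndarray:
        d = self.input_dim(name)
        out = np.zeros(d)
        if is_missing(value):
            out[-1] = 1.0
        elif name in self.categorical_levels:
            idx = int(value)
            if not 0 <= idx < self.categorical_levels[name]:
                raise ValueError(f"category {value} out of range for {name}")
            out[idx] = 1.0
        else:
            lo, hi = self.continuous_ranges[name]
            out[:-1] = quantize_continuous(value, lo, hi, self.bins)
        return out

    def encode_records(self, records: Sequence[PatientRecord]) -> list:
        """One (B, d_name) array per covariate, ordered as :attr:`names`."""
        return [
            np.stack([self.encode_value(name, r.covariates[name]) for r in records])
            for name in self.names
        ]


class ScalarEncoder(nn.Module):
    """Linear -> GELU -> LayerNorm mapping a one-hot variable to width C."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc = nn.Linear(in_dim, out_dim, rng)
        self.norm = nn.LayerNorm(out_dim)
        self.in_dim, self.out_dim = in_dim, out_dim

    def __call__(self, x) -> nn.Tensor:
        x = nn.astensor(x)
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected input width {self.in_dim}, got {x.shape[-1]}")
        return self.norm(nn.gelu(self.fc(x)))


def unfold_grid(feature_map: nn.Tensor) -> tuple:
    """(B, C, *grid) feature map -> ((B, prod(grid), C) tokens, grid shape).

    Row-major order; :func:`fold_grid` inverts it.
    """
    shape = feature_map.shape
    B, C = shape[0], shape[1]
    grid = tuple(shape[2:])
    n = int(np.prod(grid))
    x = nn.astensor(feature_map).reshape(B, C, n).swapaxes(1, 2)
    return x, grid


def fold_grid(tokens, grid_shape: tuple):
    """(B, n, C) tokens -> (B, C, *grid); inverse of :func:`unfold_grid`."""
    B, n, C = tokens.shape
    if int(np.prod(grid_shape)) != n:
        raise ValueError(f"cannot fold {n} tokens onto grid {grid_shape}")
    if isinstance(tokens, nn.Tensor):
        return tokens.swapaxes(1, 2).reshape(B, C, *grid_shape)
    return np.swapaxes(tokens, 1, 2).reshape(B, C, *grid_shape)


class _ResidualBlock(nn.Module):
    def __init__(self, conv_cls, channels, rng):
        super().__init__()
        self.conv1 = conv_cls(channels, channels, 3, 1, 1, rng)
        self.conv2 = conv_cls(channels, channels, 3, 1, 1, rng)

    def __call__(self, x):
        return x + self.conv2(nn.gelu(self.conv1(x)))


class ImageEncoder(nn.Module):
    """Residual CNN backbone + linear projection to CX-wide tokens.

    2D: a stride-4 stem followed by ``stages`` stride-2 downsampling stages,
    total stride 4 * 2**stages (default 32).  3D: stride-2 stem, total
    stride 2 * 2**stages (default 16).  Each stage carries one residual
    block.  Randomly initialized; depth/width are configuration knobs.
    """

    def __init__(
        self,
        cx: int,
        rng: np.random.Generator,
        ndim: int = 2,
        width: int = 16,
        stages: int = 3,
        blocks_per_stage: int = 1,
    ):
        super().__init__()
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        conv_cls = nn.Conv2d if ndim == 2 else nn.Conv3d
        stem_stride = 4 if ndim == 2 else 2
        self.ndim = ndim
        self.total_stride = stem_stride * 2**stages
        layers = [conv_cls(1, width, stem_stride, stem_stride, 0, rng)]
        for _ in range(stages):
            layers.append(conv_cls(width, width, 2, 2, 0, rng))
            for _ in range(blocks_per_stage):
                layers.append(_ResidualBlock(conv_cls, width, rng))
        self.backbone = nn.Sequential(*layers)
        self.proj = nn.Linear(width, cx, rng)
        self.cx = cx

    def grid_shape(self, image_shape: Sequence[int]) -> tuple:
        spatial = tuple(image_shape[-self.ndim :])
        if any(d % self.total_stride or d < self.total_stride for d in spatial):
            raise ValueError(
                f"image shape {spatial} not divisible by total stride {self.total_stride}"
            )
        return tuple(d // self.total_stride for d in spatial)

    def __call__(self, images) -> TokenSequence:
        """``images``: (B, H, W) or (B, D, H, W) arrays in [0, 1]."""
        x = nn.astensor(images)
        self.grid_shape(x.shape[1:])  # validate divisibility early
        x = x.reshape(x.shape[0], 1, *x.shape[1:])
        fmap = self.backbone(x)
        tokens, grid = unfold_grid(fmap)
        tokens = self.proj(tokens)
        return TokenSequence(tokens=tokens, modality_tag="imaging", grid_shape=grid)
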