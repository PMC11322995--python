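"""Reference grouped 2-D convolution and exact parameter accounting.

A grouped convolution partitions the input channels into ``groups``
contiguous blocks and the output channels likewise; output block *g* sees
only input block *g*.  With *g* groups the weight tensor shrinks by a
factor *g* relative to a full convolution at equal widths — the parameter
economy that motivates the architecture in this package.

This module is the slow, transparent correctness oracle: plain channel
slicing and shifted-window accumulation, cross-correlation convention
(no kernel flip), channels-last layout.  The trainable, vectorized layer
lives in :mod:`cropgcnn.nn.layers` and is checked against this one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConvSpec", "WeightSet", "SpecError", "grouped_conv_forward", "param_count"]


class SpecError(ValueError):
    """Invalid convolution specification (divisibility or shape)."""


@dataclass(frozen=True)
class ConvSpec:
    """Declarative description of one grouped convolution layer.

    ``groups`` must divide both channel counts; the implied weight-tensor
    shape is ``out_channels x (in_channels // groups) x kh x kw``.
    """

    in_channels: int
    out_channels: int
    kernel: tuple[int, int] = (3, 3)
    groups: int = 1
    padding: str = "same"
    bias: bool = True

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1 or self.groups < 1:
            raise SpecError("channel and group counts must be positive")
        if self.kernel[0] < 1 or self.kernel[1] < 1:
            raise SpecError("kernel dimensions must be positive")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise SpecError(
                f"groups={self.groups} must divide in_channels="
                f"{self.in_channels} and out_channels={self.out_channels}"
            )
        if self.padding not in ("same", "valid"):
            raise SpecError(f"padding must be 'same' or 'valid', got {self.padding!r}")

    @property
    def weight_shape(self) -> tuple[int, int, int, int]:
        return (
            self.out_channels,
            self.in_channels // self.groups,
            self.kernel[0],
            self.kernel[1],
        )


@dataclass(frozen=True)
class WeightSet:
    """Weights (and optional bias) matching a :class:`ConvSpec`."""

    weights: np.ndarray
    bias: np.ndarray | None = None

    @classmethod
    def random(cls, spec: ConvSpec, rng: np.random.Generator, scale: float = 0.1):
        w = rng.normal(0.0, scale, size=spec.weight_shape)
        b = rng.normal(0.0, scale, size=spec.out_channels) if spec.bias else None
        return cls(w, b)

    def validate(self, spec: ConvSpec) -> None:
        if tuple(self.weights.shape) != spec.weight_shape:
            raise SpecError(
                f"weight shape {self.weights.shape} does not match spec "
                f"{spec.weight_shape}"
            )
        if spec.bias:
            if self.bias is None or self.bias.shape != (spec.out_channels,):
                raise SpecError("bias vector missing or wrong length")


def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # 'same': symmetric zero padding, extra pixel on the bottom/right for
    # even kernels (framework convention).
    top, left = (kh - 1) // 2, (kw - 1) // 2
    bottom, right = kh - 1 - top, kw - 1 - left
    return np.pad(x, ((0, 0), (top, bottom), (left, right), (0, 0)))


def grouped_conv_forward(
    x: np.ndarray, spec: ConvSpec, w: WeightSet
) -> np.ndarray:
    """Grouped cross-correlation of a channels-last batch.

    Parameters
    ----------
    x : ndarray, shape (n, h, w, in_channels)
    spec : ConvSpec
    w : WeightSet

    Returns
    -------
    ndarray, shape (n, oh, ow, out_channels); spatial size preserved for
    ``same`` padding, reduced by ``kernel - 1`` for ``valid``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise SpecError(f"input must be rank 4 (n, h, w, c); got shape {x.shape}")
    if x.shape[-1] != spec.in_channels:
        raise SpecError(
            f"input has {x.shape[-1]} channels, spec expects {spec.in_channels}"
        )
    w.validate(spec)

    kh, kw = spec.kernel
    if spec.padding == "same":
        xp = _pad_same(x, kh, kw)
    else:
        xp = x
    n, hp, wp, _ = xp.shape
    oh, ow = hp - kh + 1, wp - kw + 1
    if oh < 1 or ow < 1:
        raise SpecError("kernel larger than (padded) input")

    cg = spec.in_channels // spec.groups
    og = spec.out_channels // spec.groups
    out = np.zeros((n, oh, ow, spec.out_channels))
    for g in range(spec.groups):
        in_lo = g * cg
        for j in range(og):
            oc = g * og + j
            acc = np.zeros((n, oh, ow))
            for ci in range(cg):
                for dy in range(kh):
                    for dx in range(kw):
                        acc += (
                            w.weights[oc, ci, dy, dx]
                            * xp[:, dy : dy + oh, dx : dx + ow, in_lo + ci]
                        )
            if spec.bias:
                acc += w.bias[oc]
            out[..., oc] = acc
    return out


def param_count(spec: ConvSpec) -> int:
    """Exact trainable-parameter count of a grouped convolution layer.

    ``out_channels * kh * kw * (in_channels / groups)`` weights, plus one
    bias per output channel when enabled; weight parameters scale as
    ``1 / groups`` at fixed widths.
    """
    o, cg, kh, kw = spec.weight_shape
    n = o * cg * kh * kw
    if spec.bias:
        n += spec.out_channels
    return n
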