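"""Independent scalar/brute-force oracles used by the test suite.

Everything here is deliberately written per pixel / per element from the
published closed-form definitions, independent of the vectorized package
code paths it is used to check.
"""

from __future__ import annotations

import colorsys

import numpy as np

# sRGB -> XYZ matrix (ITU sRGB primaries, D65 white), published values.
_M = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
_WHITE = _M.sum(axis=1)  # XYZ of RGB (1,1,1)


def _linearize(c: float) -> float:
    return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4


def xyz_pixel(r, g, b):
    lin = np.array([_linearize(r), _linearize(g), _linearize(b)])
    return _M @ lin


def _lab_f(t: float) -> float:
    return t ** (1.0 / 3.0) if t > 0.008856 else 7.787 * t + 16.0 / 116.0


def lab_pixel(r, g, b):
    x, y, z = xyz_pixel(r, g, b) / _WHITE
    fx, fy, fz = _lab_f(x), _lab_f(y), _lab_f(z)
    return np.array([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)])


def luv_pixel(r, g, b):
    x, y, z = xyz_pixel(r, g, b)
    yr = y / _WHITE[1]
    L = 116.0 * _lab_f(yr) - 16.0
    denom = x + 15.0 * y + 3.0 * z
    if denom <= 0:
        return np.array([L, 0.0, 0.0])
    up = 4.0 * x / denom
    vp = 9.0 * y / denom
    dn = _WHITE[0] + 15.0 * _WHITE[1] + 3.0 * _WHITE[2]
    upn = 4.0 * _WHITE[0] / dn
    vpn = 9.0 * _WHITE[1] / dn
    return np.array([L, 13.0 * L * (up - upn), 13.0 * L * (vp - vpn)])


def yuv_pixel(r, g, b):
    # BT.601 analog: U/V scale factors as published for the analog system
    y = 0.299 * r + 0.587 * g + 0.114 * b
    return np.array([y, 0.492111 * (b - y), 0.877283 * (r - y)])


def ycrcb_pixel(r, g, b):
    # BT.601 full-range float with +0.5 chroma offset
    y = 0.299 * r + 0.587 * g + 0.114 * b
    return np.array([y, (r - y) * 0.713 + 0.5, (b - y) * 0.564 + 0.5])


def hsv_pixel(r, g, b):
    return np.array(colorsys.rgb_to_hsv(r, g, b))


def hls_pixel(r, g, b):
    # colorsys returns (h, l, s), matching the package's channel order
    return np.array(colorsys.rgb_to_hls(r, g, b))


SCALAR_CONVERTERS = {
    "HSV": hsv_pixel,
    "HLS": hls_pixel,
    "XYZ": xyz_pixel,
    "LAB": lab_pixel,
    "LUV": luv_pixel,
    "YUV": yuv_pixel,
    "YCrCb": ycrcb_pixel,
    "RGB": lambda r, g, b: np.array([r, g, b]),
}


def convert_batch_scalar(pixels: np.ndarray, space: str) -> np.ndarray:
    """Apply the scalar converter pixel by pixel over a rank-4 batch."""
    out = np.empty_like(pixels, dtype=np.float64)
    f = SCALAR_CONVERTERS[space]
    it = np.ndindex(pixels.shape[:-1])
    for idx in it:
        out[idx] = f(*pixels[idx])
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def f1_per_class_bruteforce(true_labels, pred_labels, n_classes):
    """Per-class precision/recall/F1 by direct counting."""
    out = []
    for c in range(n_classes):
        tp = sum(1 for t, p in zip(true_labels, pred_labels) if t == c and p == c)
        fp = sum(1 for t, p in zip(true_labels, pred_labels) if t != c and p == c)
        fn = sum(1 for t, p in zip(true_labels, pred_labels) if t == c and p != c)
        if tp == 0 and fp == 0 and fn == 0:
            out.append(0.0)
            continue
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        out.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return np.array(out)


# ---------------------------------------------------------------------------
# grouped convolution
# ---------------------------------------------------------------------------


def blockdiag_embed(weights: np.ndarray, groups: int) -> np.ndarray:
    """Embed grouped weights (o, c/g, kh, kw) into full weights (o, c, kh, kw).

    Output-group g's filters see only input block g; all cross-group
    entries are zero, so a full convolution with the embedded tensor must
    reproduce the grouped convolution exactly.
    """
    o, cg, kh, kw = weights.shape
    og = o // groups
    full = np.zeros((o, cg * groups, kh, kw))
    for g in range(groups):
        full[g * og : (g + 1) * og, g * cg : (g + 1) * cg] = weights[
            g * og : (g + 1) * og
        ]
    return full
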