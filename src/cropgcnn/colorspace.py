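"""Color-space expansion of RGB image batches.

An RGB leaf photograph carries its class signal partly in chroma (hue and
saturation of lesions) and partly in luminance.  Re-expressing the same
pixels in an alternative color space (HSV, CIELAB, YCrCb, ...) rotates that
signal into different channels, which is the input-representation variable
the classifier experiments in this package manipulate.

Conventions (fixed so that every consumer and every test oracle agree):

* RGB enters as floating point in ``[0, 1]`` (8-bit files divided by 255).
* HSV and HLS follow the hexcone model with hue stored as a fraction of a
  turn in ``[0, 1)``; hue of an achromatic pixel is defined as 0.
* XYZ is computed from linear sRGB (gamma decoded) with the D65 white
  point; CIELAB and CIELUV (CIE 1976) derive from that XYZ.
* YCrCb is ITU-R BT.601 full-range float with a ``+0.5`` chroma offset.
* YUV is the BT.601 analog matrix with no offset.

Channels are brought onto a common ``[0, 1]`` scale by an affine map from
each channel's theoretical native range (``CHANNEL_RANGES``) before they
enter a network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "COLOR_SPACES",
    "EXPANSION_SPACES",
    "CHANNEL_RANGES",
    "ImageBatch",
    "ColorSpaceError",
    "InvalidSourceError",
    "RangeError",
    "UnknownSpaceError",
    "DoubleNormalizationError",
    "convert_color",
    "convert_to_rgb",
    "normalize_channels",
    "denormalize_channels",
    "expand_all",
    "luminance_ablation",
    "load_channel_ranges",
]

#: The eight recognized color-space identifiers.  RGB is the source space;
#: the remaining seven form the expansion set.  "HSL" in some writeups is
#: the same hexcone space as HLS; a single HLS identifier is exposed.
COLOR_SPACES = ("RGB", "HSV", "LAB", "YCrCb", "XYZ", "HLS", "LUV", "YUV")

#: The seven non-RGB spaces produced by :func:`expand_all`.
EXPANSION_SPACES = tuple(s for s in COLOR_SPACES if s != "RGB")

# Index of the luminance-like channel (V, L*, Y, L) in each space.
LUMINANCE_CHANNEL = {
    "RGB": None,
    "HSV": 2,
    "LAB": 0,
    "YCrCb": 0,
    "XYZ": 1,
    "HLS": 1,
    "LUV": 0,
    "YUV": 0,
}


class ColorSpaceError(ValueError):
    """Base class for color-space conversion errors."""


class InvalidSourceError(ColorSpaceError):
    """Conversion requested from a batch that is not unnormalized RGB."""


class RangeError(ColorSpaceError):
    """Input values outside the space's expected range beyond tolerance."""


class UnknownSpaceError(ColorSpaceError):
    """Color-space identifier not among the eight recognized ones."""


class DoubleNormalizationError(ColorSpaceError):
    """normalize_channels applied to an already-normalized batch."""


@dataclass(frozen=True)
class ImageBatch:
    """A rank-4 batch of images tagged with its color space.

    Parameters
    ----------
    pixels : ndarray of shape (n_images, height, width, 3)
        Floating-point pixel data, channels last.
    space : str
        One of :data:`COLOR_SPACES`.
    normalized : bool
        True once every channel has been affinely mapped to ``[0, 1]``.
    """

    pixels: np.ndarray
    space: str = "RGB"
    normalized: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 4 or px.shape[-1] != 3:
            raise ValueError(
                f"pixels must have shape (n, h, w, 3); got {px.shape}"
            )
        if self.space not in COLOR_SPACES:
            raise UnknownSpaceError(f"unknown color space {self.space!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def __len__(self) -> int:
        return self.pixels.shape[0]


# Theoretical native (min, max) per channel, used by normalize_channels.
# LAB / LUV chroma bounds are the sRGB-gamut extrema (attained at the cube
# corners: green/magenta for a*, blue/yellow for b*, green/red for u*,
# blue for v*), padded to one decimal so gamut-boundary pixels stay inside.
_YUV_U_MAX = 0.43601035
_YUV_V_MAX = 0.61497538
CHANNEL_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "RGB": ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)),
    "HSV": ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)),
    "HLS": ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)),
    "XYZ": ((0.0, 0.950456), (0.0, 1.0), (0.0, 1.088754)),
    "LAB": ((0.0, 100.0), (-86.2, 98.3), (-107.9, 94.5)),
    "LUV": ((0.0, 100.0), (-83.1, 175.1), (-134.2, 107.4)),
    "YCrCb": ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)),
    "YUV": ((0.0, 1.0), (-_YUV_U_MAX, _YUV_U_MAX), (-_YUV_V_MAX, _YUV_V_MAX)),
}


def load_channel_ranges() -> dict:
    """Load the channel-range table shipped with the package (JSON)."""
    text = resources.files(__package__).joinpath("channel_ranges.json").read_text()
    raw = json.loads(text)
    return {k: tuple(tuple(pair) for pair in v) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# forward conversions (vectorized, on (..., 3) arrays of [0, 1] RGB)
# ---------------------------------------------------------------------------

def _rgb_to_hls(rgb: np.ndarray) -> np.ndarray:
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    delta = mx - mn
    lightness = (mx + mn) / 2.0
    denom = 1.0 - np.abs(2.0 * lightness - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(delta > 0, delta / np.where(denom > 0, denom, 1.0), 0.0)
    # hue is shared with HSV (hexcone); reuse skimage's and zero it where
    # saturation vanishes
    hue = _skcolor.rgb2hsv(rgb)[..., 0]
    hue = np.where(delta > 0, hue, 0.0)
    return np.stack([hue, lightness, sat], axis=-1)


def _hls_to_rgb(hls: np.ndarray) -> np.ndarray:
    h, lightness, s = hls[..., 0], hls[..., 1], hls[..., 2]
    c = (1.0 - np.abs(2.0 * lightness - 1.0)) * s
    hp = (h % 1.0) * 6.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    m = lightness - c / 2.0
    z = np.zeros_like(c)
    seg = np.floor(hp).astype(int) % 6
    r = np.choose(seg, [c, x, z, z, x, c])
    g = np.choose(seg, [x, c, c, x, z, z])
    b = np.choose(seg, [z, z, x, c, c, x])
    return np.stack([r + m, g + m, b + m], axis=-1)


# CIE XYZ from linear sRGB (D65), and CIELAB / CIELUV (CIE 1976) from XYZ.
# The reference white is the XYZ of RGB (1,1,1) under the same matrix, so
# grays sit exactly on the achromatic line (a*=b*=u*=v*=0) by construction.
_XYZ_FROM_LINRGB = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
_WHITE_XYZ = _XYZ_FROM_LINRGB.sum(axis=1)
_LAB_DELTA3 = (6.0 / 29.0) ** 3


def _srgb_linearize(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_delinearize(c: np.ndarray) -> np.ndarray:
    return np.where(
        c <= 0.0031308, 12.92 * c, 1.055 * np.maximum(c, 0.0) ** (1 / 2.4) - 0.055
    )


def _rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    return _srgb_linearize(rgb) @ _XYZ_FROM_LINRGB.T


def _xyz_to_rgb(xyz: np.ndarray) -> np.ndarray:
    lin = xyz @ np.linalg.inv(_XYZ_FROM_LINRGB).T
    return _srgb_delinearize(lin)


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(
        t > _LAB_DELTA3, np.cbrt(t), t / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0
    )


def _rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    f = _lab_f(_rgb_to_xyz(rgb) / _WHITE_XYZ)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack(
        [116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1
    )


def _rgb_to_luv(rgb: np.ndarray) -> np.ndarray:
    xyz = _rgb_to_xyz(rgb)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    L = 116.0 * _lab_f(y / _WHITE_XYZ[1]) - 16.0
    denom = x + 15.0 * y + 3.0 * z
    safe = np.where(denom > 0, denom, 1.0)
    up = np.where(denom > 0, 4.0 * x / safe, 0.0)
    vp = np.where(denom > 0, 9.0 * y / safe, 0.0)
    dn = _WHITE_XYZ[0] + 15.0 * _WHITE_XYZ[1] + 3.0 * _WHITE_XYZ[2]
    upn, vpn = 4.0 * _WHITE_XYZ[0] / dn, 9.0 * _WHITE_XYZ[1] / dn
    u = np.where(denom > 0, 13.0 * L * (up - upn), 0.0)
    v = np.where(denom > 0, 13.0 * L * (vp - vpn), 0.0)
    return np.stack([L, u, v], axis=-1)


# BT.601 full-range float YCrCb: Y in [0,1], chroma offset +0.5.
_KR, _KG, _KB = 0.299, 0.587, 0.114
_CR_SCALE = 0.713  # = 0.5 / (1 - Kr)
_CB_SCALE = 0.564  # = 0.5 / (1 - Kb)


def _rgb_to_ycrcb(rgb: np.ndarray) -> np.ndarray:
    y = _KR * rgb[..., 0] + _KG * rgb[..., 1] + _KB * rgb[..., 2]
    cr = (rgb[..., 0] - y) * _CR_SCALE + 0.5
    cb = (rgb[..., 2] - y) * _CB_SCALE + 0.5
    return np.stack([y, cr, cb], axis=-1)


def _ycrcb_to_rgb(ycc: np.ndarray) -> np.ndarray:
    y, cr, cb = ycc[..., 0], ycc[..., 1], ycc[..., 2]
    r = y + (cr - 0.5) / _CR_SCALE
    b = y + (cb - 0.5) / _CB_SCALE
    g = (y - _KR * r - _KB * b) / _KG
    return np.stack([r, g, b], axis=-1)


_FORWARD = {
    "RGB": lambda rgb: rgb.copy(),
    "HSV": _skcolor.rgb2hsv,
    "LAB": _rgb_to_lab,
    "LUV": _rgb_to_luv,
    "XYZ": _rgb_to_xyz,
    "YUV": _skcolor.rgb2yuv,
    "HLS": _rgb_to_hls,
    "YCrCb": _rgb_to_ycrcb,
}

# Spaces with an implemented inverse (used by round-trip tests and the
# synthetic generator; LAB/LUV are one-way here).
_INVERSE = {
    "RGB": lambda a: a.copy(),
    "HSV": _skcolor.hsv2rgb,
    "XYZ": _xyz_to_rgb,
    "YUV": _skcolor.yuv2rgb,
    "HLS": _hls_to_rgb,
    "YCrCb": _ycrcb_to_rgb,
}

INVERTIBLE_SPACES = tuple(s for s in _INVERSE if s != "RGB")

_RANGE_TOL = 1e-6


def convert_color(batch: ImageBatch, target: str) -> ImageBatch:
    """Convert an unnormalized RGB batch to ``target``'s native units.

    The result keeps each channel in the target space's theoretical range
    (e.g. hue as a fraction of a turn in ``[0, 1)``, L* in ``[0, 100]``);
    use :func:`normalize_channels` to rescale to ``[0, 1]``.
    ``target="RGB"`` returns the input unchanged.
    """
    if target not in COLOR_SPACES:
        raise UnknownSpaceError(f"unknown target color space {target!r}")
    if batch.space != "RGB" or batch.normalized:
        raise InvalidSourceError(
            "convert_color requires an unnormalized RGB batch; got "
            f"space={batch.space!r}, normalized={batch.normalized}"
        )
    px = batch.pixels
    if px.min() < -_RANGE_TOL or px.max() > 1.0 + _RANGE_TOL:
        raise RangeError(
            f"RGB values must lie in [0, 1]; got [{px.min():.4g}, {px.max():.4g}]"
        )
    if target == "RGB":
        return batch
    out = _FORWARD[target](np.clip(px, 0.0, 1.0))
    return ImageBatch(out, space=target, normalized=False)


def convert_to_rgb(batch: ImageBatch) -> ImageBatch:
    """Inverse conversion back to RGB for spaces that support it."""
    if batch.normalized:
        raise InvalidSourceError("inverse conversion expects native units")
    if batch.space not in _INVERSE:
        raise UnknownSpaceError(
            f"no inverse implemented for {batch.space!r} (one-way space)"
        )
    rgb = _INVERSE[batch.space](batch.pixels)
    return ImageBatch(np.clip(rgb, 0.0, 1.0), space="RGB", normalized=False)


def normalize_channels(
    batch: ImageBatch, ranges: dict | None = None
) -> ImageBatch:
    """Affinely map each channel from its native range onto ``[0, 1]``.

    Small float excursions are clipped; calling this twice is an error
    (the affine map is keyed to native units).
    """
    if batch.normalized:
        raise DoubleNormalizationError(
            f"batch in space {batch.space!r} is already normalized"
        )
    ranges = CHANNEL_RANGES if ranges is None else ranges
    if batch.space not in ranges:
        raise UnknownSpaceError(f"no channel ranges recorded for {batch.space!r}")
    lo = np.array([r[0] for r in ranges[batch.space]])
    hi = np.array([r[1] for r in ranges[batch.space]])
    out = (batch.pixels - lo) / (hi - lo)
    return ImageBatch(np.clip(out, 0.0, 1.0), space=batch.space, normalized=True)


def denormalize_channels(
    batch: ImageBatch, ranges: dict | None = None
) -> ImageBatch:
    """Inverse of :func:`normalize_channels` (back to native units)."""
    if not batch.normalized:
        raise ColorSpaceError("batch is not normalized")
    ranges = CHANNEL_RANGES if ranges is None else ranges
    lo = np.array([r[0] for r in ranges[batch.space]])
    hi = np.array([r[1] for r in ranges[batch.space]])
    return ImageBatch(
        batch.pixels * (hi - lo) + lo, space=batch.space, normalized=False
    )


def expand_all(
    batch: ImageBatch, include_rgb: bool = False
) -> dict[str, ImageBatch]:
    """Expand one RGB batch into all seven alternative color spaces at once.

    Returns a mapping from color-space id to a converted *and normalized*
    batch — exactly the seven non-RGB spaces, plus RGB itself when
    ``include_rgb`` is set (for comparison runs that include the native
    representation as a baseline row).
    """
    spaces = (("RGB",) if include_rgb else ()) + EXPANSION_SPACES
    return {
        s: normalize_channels(convert_color(batch, s)) for s in spaces
    }


def luminance_ablation(batch: ImageBatch) -> ImageBatch:
    """Replace an RGB batch by its BT.601 luma replicated over 3 channels.

    Serves as the luminance-only control when measuring how much of a
    model's accuracy is carried by chroma.
    """
    ycc = convert_color(batch, "YCrCb")
    y = ycc.pixels[..., :1]
    return ImageBatch(
        np.repeat(y, 3, axis=-1), space="RGB", normalized=True
    )
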