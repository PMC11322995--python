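"""Datasets: class-per-folder image I/O, splitting, synthetic leaf imagery.

The on-disk convention is the PlantVillage layout — one subdirectory per
class, PNG/JPEG files inside.  Class labels are assigned by sorting the
subdirectory names lexicographically.

The synthetic generator stands in for field photographs of single leaves
on a dark background: an elliptical "leaf" filled with a class-specific
hue/saturation, dotted with brown circular "lesions" at a class-specific
rate, with luminance jitter.  Classes declared as *chroma-only pairs*
share lesion rate and luminance statistics exactly and differ only in
hue/saturation — the probe used to show that a chroma-separating color
space carries information a luminance-only representation cannot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .colorspace import ImageBatch

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledImageSet",
    "SplitConfig",
    "SyntheticSpec",
    "EmptyDatasetError",
    "load_image_folder",
    "write_image_folder",
    "split",
    "generate_synthetic",
]


class EmptyDatasetError(ValueError):
    """No readable images found under the dataset root."""


@dataclass
class LabeledImageSet:
    """RGB images with integer labels and class names."""

    images: ImageBatch
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.images):
            raise ValueError("labels length must equal image count")
        if len(self.labels) and self.labels.max() >= len(self.class_names):
            raise ValueError("label index outside class_names")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(
            ImageBatch(
                self.images.pixels[idx],
                space=self.images.space,
                normalized=self.images.normalized,
            ),
            self.labels[idx],
            list(self.class_names),
        )


@dataclass(frozen=True)
class SplitConfig:
    """Train/validation/test fractions (default 70/10/20), seeded."""

    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        f = tuple(self.fractions)
        if len(f) != 3 or any(not 0.0 < x < 1.0 for x in f):
            raise ValueError("fractions must be three values in (0, 1)")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(f)}")
        object.__setattr__(self, "fractions", f)


def load_image_folder(path, image_size: int = 32) -> LabeledImageSet:
    """Read a class-per-subdirectory tree of PNG/JPEG images.

    Classes are the subdirectory names in lexicographic order.  Images are
    decoded as RGB, resized to ``image_size`` square with bilinear
    resampling, and scaled to [0, 1].  Unreadable files are skipped with a
    warning; a class left empty raises.
    """
    root = Path(path)
    if not root.is_dir():
        raise EmptyDatasetError(f"{root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise EmptyDatasetError(f"no class subdirectories under {root}")
    images, labels, skipped = [], [], 0
    class_names = [d.name for d in class_dirs]
    for label, cdir in enumerate(class_dirs):
        count = 0
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            try:
                with Image.open(f) as im:
                    im = im.convert("RGB").resize(
                        (image_size, image_size), Image.BILINEAR
                    )
                    arr = np.asarray(im, dtype=np.float64) / 255.0
            except Exception:  # decoding failure: skip, warn once at the end
                skipped += 1
                logger.warning("skipping unreadable image %s", f)
                continue
            images.append(arr)
            labels.append(label)
            count += 1
        if count == 0:
            raise EmptyDatasetError(f"class directory {cdir} has no readable images")
    if skipped:
        warnings.warn(f"skipped {skipped} unreadable image file(s)", stacklevel=2)
    return LabeledImageSet(
        ImageBatch(np.stack(images), space="RGB", normalized=False),
        np.array(labels),
        class_names,
    )


def write_image_folder(ds: LabeledImageSet, path, overwrite: bool = False) -> None:
    """Write a dataset as a class-per-subdirectory PNG tree.

    Files are named ``<class>_<index>.png`` with a per-class running
    index, so a re-load reproduces the labels.  Refuses a non-empty
    target unless ``overwrite`` is set.
    """
    root = Path(path)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"{root} is not empty (pass overwrite=True)")
    root.mkdir(parents=True, exist_ok=True)
    counters = {name: 0 for name in ds.class_names}
    for img, label in zip(ds.images.pixels, ds.labels):
        cname = ds.class_names[label]
        cdir = root / cname
        cdir.mkdir(exist_ok=True)
        i = counters[cname]
        counters[cname] += 1
        arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(cdir / f"{cname}_{i:05d}.png")


def _split_sizes(n: int, fractions) -> tuple[int, int, int]:
    # round per set; remainder (positive or negative) absorbed by train
    n_val = round(n * fractions[1])
    n_test = round(n * fractions[2])
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def split(
    ds: LabeledImageSet, cfg: SplitConfig | None = None
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Partition a dataset into train/validation/test sets.

    Sizes are ``round(n * fraction)`` per set with the remainder assigned
    to train; stratification applies the same rule within each class.
    Classes with fewer than 3 members cannot be stratified and fall back
    to the pooled (non-stratified) assignment with a warning.  The
    partition is disjoint, exhaustive and deterministic under the seed.
    """
    cfg = cfg or SplitConfig()
    if len(ds) == 0:
        raise EmptyDatasetError("cannot split an empty dataset")
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx, test_idx = [], [], []
    if cfg.stratified:
        pooled = []
        for c in range(ds.n_classes):
            members = np.flatnonzero(ds.labels == c)
            if len(members) == 0:
                continue
            if len(members) < 3:
                warnings.warn(
                    f"class {ds.class_names[c]!r} has {len(members)} member(s); "
                    "falling back to non-stratified assignment for it",
                    stacklevel=2,
                )
                pooled.append(members)
                continue
            members = rng.permutation(members)
            n_train, n_val, n_test = _split_sizes(len(members), cfg.fractions)
            train_idx.append(members[:n_train])
            val_idx.append(members[n_train : n_train + n_val])
            test_idx.append(members[n_train + n_val :])
        if pooled:
            members = rng.permutation(np.concatenate(pooled))
            n_train, n_val, n_test = _split_sizes(len(members), cfg.fractions)
            train_idx.append(members[:n_train])
            val_idx.append(members[n_train : n_train + n_val])
            test_idx.append(members[n_train + n_val :])
    else:
        members = rng.permutation(len(ds))
        n_train, n_val, n_test = _split_sizes(len(members), cfg.fractions)
        train_idx.append(members[:n_train])
        val_idx.append(members[n_train : n_train + n_val])
        test_idx.append(members[n_train + n_val :])
    cat = lambda parts: (
        np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int)
    )
    return (
        ds.subset(cat(train_idx)),
        ds.subset(cat(val_idx)),
        ds.subset(cat(test_idx)),
    )


# ---------------------------------------------------------------------------
# synthetic leaf imagery
# ---------------------------------------------------------------------------

# Hexcone hues 0.1138 (orange-yellow) and 0.4985 (cyan-green) both have a
# BT.601 chroma-pattern luma of 0.70, so classes 0 and 1 — the default
# chroma-only pair — carry identical luminance at equal saturation/value
# and are separable by hue alone.
_DEFAULT_HUES = (0.1138, 0.4985, 0.06, 0.17, 0.25, 0.33, 0.41, 0.57, 0.66, 0.80)
_DEFAULT_SATS = (0.85, 0.85, 0.55, 0.65, 0.75, 0.85, 0.60, 0.70, 0.80, 0.50)
_DEFAULT_LESION_RATES = (0.15, 0.15, 0.0, 0.05, 0.10, 0.20, 0.25, 0.30, 0.08, 0.12)

_LEAF_VALUE = 0.62  # base HSV value of leaf tissue
_BACKGROUND = 0.12  # dark-gray sheet behind the leaf
_LESION_SAT = 0.80
_LESION_VALUE = 0.35


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic leaf-image generator.

    Per-class hue/saturation encode identity in chroma; per-class lesion
    rates encode it in luminance/texture.  ``chroma_only_pairs`` lists
    class pairs constrained to identical lesion-rate and luminance
    statistics (hue/saturation being their only difference).
    """

    n_classes: int = 10
    n_per_class: int = 100
    image_size: int = 32
    leaf_hue_by_class: tuple[float, ...] | None = None
    lesion_hue: float = 0.08  # brown
    lesion_rate_by_class: tuple[float, ...] | None = None
    saturation_by_class: tuple[float, ...] | None = None
    luminance_jitter: float = 0.03
    chroma_only_pairs: tuple[tuple[int, int], ...] = ((0, 1),)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        K = self.n_classes
        def cycle(vals):
            return tuple(vals[i % len(vals)] for i in range(K))
        hues = self.leaf_hue_by_class or cycle(_DEFAULT_HUES)
        sats = self.saturation_by_class or cycle(_DEFAULT_SATS)
        rates = self.lesion_rate_by_class or cycle(_DEFAULT_LESION_RATES)
        for name, vals in (
            ("leaf_hue_by_class", hues),
            ("saturation_by_class", sats),
            ("lesion_rate_by_class", rates),
        ):
            if len(vals) != K:
                raise ValueError(f"{name} must have {K} entries")
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        for a, b in self.chroma_only_pairs:
            if not (0 <= a < K and 0 <= b < K):
                raise ValueError(f"chroma_only_pairs reference invalid class ({a},{b})")
            if rates[a] != rates[b] or sats[a] != sats[b]:
                raise ValueError(
                    "chroma-only pair classes must share lesion rate and saturation"
                )
        object.__setattr__(self, "leaf_hue_by_class", tuple(hues))
        object.__setattr__(self, "saturation_by_class", tuple(sats))
        object.__setattr__(self, "lesion_rate_by_class", tuple(rates))
        object.__setattr__(
            self, "chroma_only_pairs", tuple(tuple(p) for p in self.chroma_only_pairs)
        )


def _hsv_pixel_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    c = v * s
    hp = (h % 1.0) * 6.0
    x = c * (1.0 - abs(hp % 2.0 - 1.0))
    seg = int(hp) % 6
    r, g, b = [
        (c, x, 0.0), (x, c, 0.0), (0.0, c, x),
        (0.0, x, c), (x, 0.0, c), (c, 0.0, x),
    ][seg]
    m = v - c
    return np.array([r + m, g + m, b + m])


def generate_synthetic(spec: SyntheticSpec | None = None) -> LabeledImageSet:
    """Render a deterministic synthetic leaf-image dataset.

    For each image: an elliptical leaf mask with randomized center, axes
    and rotation on a dark-gray background; leaf fill from the class hue
    and saturation with per-image value jitter and light per-pixel value
    noise; circular lesions placed inside the leaf so that their expected
    area fraction equals the class lesion rate.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    images = np.empty((spec.n_classes * spec.n_per_class, size, size, 3))
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)

    # geometry scaled to the image; leaf covers roughly 55-60% of the frame
    cxy_jit = 0.04 * size
    ax_lo, ax_hi = 0.42 * size, 0.48 * size
    bx_lo, bx_hi = 0.37 * size, 0.43 * size
    lesion_r = max(1.5, 0.07 * size)

    i = 0
    for c in range(spec.n_classes):
        hue = spec.leaf_hue_by_class[c]
        sat = spec.saturation_by_class[c]
        rate = spec.lesion_rate_by_class[c]
        for _ in range(spec.n_per_class):
            cx = size / 2 + rng.uniform(-cxy_jit, cxy_jit)
            cy = size / 2 + rng.uniform(-cxy_jit, cxy_jit)
            a = rng.uniform(ax_lo, ax_hi)
            b = rng.uniform(bx_lo, bx_hi)
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            w = -(xx - cx) * st + (yy - cy) * ct
            leaf = (u / a) ** 2 + (w / b) ** 2 <= 1.0

            img = np.empty((size, size, 3))
            img[...] = _BACKGROUND + rng.normal(0.0, 0.01, (size, size, 1))
            value = np.clip(
                _LEAF_VALUE
                + rng.normal(0.0, spec.luminance_jitter)
                + rng.normal(0.0, 0.01, (size, size)),
                0.05,
                1.0,
            )
            leaf_rgb = _hsv_pixel_to_rgb(hue, sat, 1.0)
            img[leaf] = value[leaf, None] * leaf_rgb

            leaf_area = leaf.sum()
            if rate > 0 and leaf_area:
                n_lesions = int(round(rate * leaf_area / (np.pi * lesion_r**2)))
                lesion_rgb = _hsv_pixel_to_rgb(
                    spec.lesion_hue, _LESION_SAT, _LESION_VALUE
                )
                ys, xs = np.nonzero(leaf)
                for _k in range(n_lesions):
                    j = rng.integers(len(ys))
                    d2 = (xx - xs[j]) ** 2 + (yy - ys[j]) ** 2
                    spot = (d2 <= lesion_r**2) & leaf
                    img[spot] = lesion_rgb * (1.0 + rng.normal(0.0, 0.03))
            images[i] = np.clip(img, 0.0, 1.0)
            i += 1

    class_names = [f"class_{c:02d}" for c in range(spec.n_classes)]
    return LabeledImageSet(
        ImageBatch(images, space="RGB", normalized=False), labels, class_names
    )
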