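"""Assembly of the grouped-convolution CNN (GCNN) and its fused variant.

The network has three kinds of blocks:

* **processing block** — GroupedConv(stage1_filters, 3x3) -> ReLU ->
  BatchNorm -> PReLU -> AvgPool 2x2.  The double activation (ReLU before
  the normalization, PReLU after) is part of the published design and is
  reproduced verbatim; ``lead_relu=False`` drops the leading ReLU for
  ablation.
* **residual blocks** — GroupedConv(stage2_filters, 3x3) -> BatchNorm ->
  PReLU, with the block input added to the output (1x1 grouped projection
  when the channel counts differ).  The number of residual blocks N is a
  multiple of 2; the default N=2 gives the simple GCNN.
* **classification block** — MaxPool 2x2 -> GroupedConv(stage2_filters,
  1x1) -> ReLU -> Flatten -> Dense(128) -> ReLU -> Dropout(0.5) ->
  Dense(64) -> ReLU -> Dense(n_classes) -> softmax.

The multi-branch variant runs one independent GCNN per color space on an
internally expanded RGB batch and fuses the branches, either by
concatenating the 64-unit feature layers under a fresh softmax head
(``concat_features``) or by averaging the branch class probabilities
(``average_probs``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import colorspace
from .nn import (
    AvgPool2D,
    BatchNorm2D,
    Dense,
    Dropout,
    Flatten,
    GroupedConv2D,
    MaxPool2D,
    PReLU,
    ReLU,
    ResidualBlock,
    Sequential,
    Softmax,
    fit_network,
    predict_proba,
)

__all__ = [
    "GCNNConfig",
    "ConfigError",
    "GCNNModel",
    "MultiBranchModel",
    "LayerSummary",
    "build_processing_block",
    "build_residual_block",
    "build_classification_block",
    "build_gcnn",
    "build_multibranch",
    "summarize",
]


class ConfigError(ValueError):
    """Invalid GCNN configuration (divisibility, ranges, block count)."""


@dataclass(frozen=True)
class GCNNConfig:
    """Hyperparameters of the GCNN.

    Defaults reproduce the published architecture: 32x32x3 input, a 54-filter
    grouped stem, two 108-filter residual blocks, a 128 -> 64 dense head with
    dropout 0.5, and a 10-way softmax, all grouped convolutions using 3 groups.
    """

    input_size: tuple[int, int] = (32, 32)
    in_channels: int = 3
    stage1_filters: int = 54
    stage2_filters: int = 108
    kernel: tuple[int, int] = (3, 3)
    groups: int = 3
    n_residual_blocks: int = 2
    dense_units: tuple[int, ...] = (128, 64)
    dropout_rate: float = 0.5
    n_classes: int = 10
    skip_mode: str = "identity_or_project"
    lead_relu: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("in_channels", "stage1_filters", "stage2_filters"):
            v = getattr(self, name)
            if v % self.groups:
                raise ConfigError(
                    f"groups={self.groups} must divide {name}={v}"
                )
        if self.n_residual_blocks < 2 or self.n_residual_blocks % 2:
            raise ConfigError(
                f"n_residual_blocks must be a positive multiple of 2, "
                f"got {self.n_residual_blocks}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"dropout_rate must be in [0, 1): {self.dropout_rate}")
        if self.skip_mode not in ("identity_or_project", "off"):
            raise ConfigError(f"unknown skip_mode {self.skip_mode!r}")
        if self.input_size[0] % 4 or self.input_size[1] % 4:
            raise ConfigError(
                "input_size must be divisible by 4 (two 2x2 pooling stages)"
            )
        if self.n_classes < 2 or not self.dense_units:
            raise ConfigError("need n_classes >= 2 and at least one dense layer")
        # normalize possible list inputs (e.g. from YAML) to tuples
        object.__setattr__(self, "input_size", tuple(self.input_size))
        object.__setattr__(self, "kernel", tuple(self.kernel))
        object.__setattr__(self, "dense_units", tuple(self.dense_units))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GCNNConfig":
        return cls(**json.loads(text))


@dataclass
class LayerSummary:
    """Ordered (layer name, output shape, parameter count) rows."""

    rows: list[tuple[str, tuple, int]] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(r[2] for r in self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["layer", "output_shape", "params"])

    def __str__(self) -> str:
        lines = [f"{'layer':<28}{'output shape':<22}params"]
        for name, shape, p in self.rows:
            lines.append(f"{name:<28}{str(shape):<22}{p}")
        lines.append(f"total params: {self.total_params}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# block builders
# ---------------------------------------------------------------------------


def build_processing_block(
    cfg: GCNNConfig, rng: np.random.Generator | None = None
) -> Sequential:
    """Stem: grouped 3x3 conv -> ReLU -> BatchNorm -> PReLU -> AvgPool 2x2.

    Halves the spatial size and raises the channel count to
    ``cfg.stage1_filters``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    layers = [
        GroupedConv2D(
            cfg.in_channels,
            cfg.stage1_filters,
            kernel=cfg.kernel,
            groups=cfg.groups,
            padding="same",
            rng=rng,
            name="proc_conv",
        )
    ]
    if cfg.lead_relu:
        layers.append(ReLU(name="proc_relu"))
    layers += [
        BatchNorm2D(cfg.stage1_filters, name="proc_bn"),
        PReLU(cfg.stage1_filters, name="proc_prelu"),
        AvgPool2D(name="proc_avgpool"),
    ]
    return Sequential(layers, name="processing_block")


def build_residual_block(
    cfg: GCNNConfig,
    in_channels: int,
    rng: np.random.Generator | None = None,
    name: str = "residual_block",
) -> ResidualBlock:
    """One residual unit: grouped 3x3 conv -> BatchNorm -> PReLU (+ skip).

    The skip path is the identity when ``in_channels`` equals
    ``cfg.stage2_filters``, otherwise a 1x1 grouped projection; it is
    removed entirely under ``skip_mode='off'``.
    """
    if in_channels % cfg.groups:
        raise ConfigError(
            f"groups={cfg.groups} must divide residual in_channels={in_channels}"
        )
    rng = rng or np.random.default_rng(cfg.seed)
    main = Sequential(
        [
            GroupedConv2D(
                in_channels,
                cfg.stage2_filters,
                kernel=cfg.kernel,
                groups=cfg.groups,
                padding="same",
                rng=rng,
                name=f"{name}_conv",
            ),
            BatchNorm2D(cfg.stage2_filters, name=f"{name}_bn"),
            PReLU(cfg.stage2_filters, name=f"{name}_prelu"),
        ],
        name=f"{name}_main",
    )
    projection = None
    skip = cfg.skip_mode != "off"
    if skip and in_channels != cfg.stage2_filters:
        projection = GroupedConv2D(
            in_channels,
            cfg.stage2_filters,
            kernel=(1, 1),
            groups=cfg.groups,
            padding="same",
            rng=rng,
            name=f"{name}_proj",
        )
    return ResidualBlock(main, projection=projection, skip=skip, name=name)


def build_classification_block(
    cfg: GCNNConfig, rng: np.random.Generator | None = None
) -> Sequential:
    """Head: MaxPool -> 1x1 grouped conv -> dense stack -> softmax."""
    rng = rng or np.random.default_rng(cfg.seed)
    h, w = cfg.input_size[0] // 4, cfg.input_size[1] // 4
    flat = h * w * cfg.stage2_filters
    layers: list = [
        MaxPool2D(name="cls_maxpool"),
        GroupedConv2D(
            cfg.stage2_filters,
            cfg.stage2_filters,
            kernel=(1, 1),
            groups=cfg.groups,
            padding="same",
            rng=rng,
            name="cls_conv1x1",
        ),
        ReLU(name="cls_relu"),
        Flatten(name="cls_flatten"),
    ]
    prev = flat
    for i, units in enumerate(cfg.dense_units):
        layers.append(Dense(prev, units, rng=rng, name=f"cls_dense{i}"))
        layers.append(ReLU(name=f"cls_dense{i}_relu"))
        if i == 0 and cfg.dropout_rate > 0:
            layers.append(Dropout(cfg.dropout_rate, name="cls_dropout"))
        prev = units
    layers.append(Dense(prev, cfg.n_classes, rng=rng, name="cls_logits"))
    layers.append(Softmax(name="cls_softmax"))
    return Sequential(layers, name="classification_block")


class GCNNModel:
    """Trainable GCNN: forward, fit, predict and layer introspection."""

    def __init__(self, cfg: GCNNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        blocks: list = [build_processing_block(cfg, rng)]
        in_ch = cfg.stage1_filters
        for i in range(cfg.n_residual_blocks):
            blocks.append(
                build_residual_block(cfg, in_ch, rng, name=f"res{i}")
            )
            in_ch = cfg.stage2_filters
        blocks.append(build_classification_block(cfg, rng))
        self.net = Sequential(blocks, name="gcnn")

    # -- ModelHandle surface -------------------------------------------------
    @property
    def params(self):
        return self.net.params

    @property
    def grads(self):
        return self.net.grads

    def set_dropout_rng(self, rng):
        self.net.set_dropout_rng(rng)

    def forward(self, x, training: bool = False) -> np.ndarray:
        return self.net.forward(x, training=training)

    def backward(self, dy):
        return self.net.backward(dy)

    def fit(self, X, y, X_val=None, y_val=None, **train_kwargs):
        return fit_network(self, X, y, X_val, y_val, **train_kwargs)

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        return predict_proba(self, X, batch_size=batch_size)

    def predict(self, X, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(X, batch_size=batch_size).argmax(axis=1)

    @property
    def layers(self):
        return list(self.net.iter_layers())

    def feature_trunk(self) -> Sequential:
        """The network truncated after the last hidden dense ReLU.

        Used by the feature-concatenation fusion: everything up to and
        including the 64-unit dense layer and its activation, i.e. the
        final logits layer and softmax are dropped.
        """
        head: Sequential = self.net.layers[-1]
        return Sequential(
            self.net.layers[:-1] + [Sequential(head.layers[:-2], name="cls_trunk")],
            name="gcnn_trunk",
        )

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Save weights (.npz) alongside a backend-neutral config JSON."""
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        bn_state = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2D):
                bn_state[f"rm{i}"] = layer.running_mean
                bn_state[f"rv{i}"] = layer.running_var
        np.savez(path, **arrays, **bn_state)
        cfg_path = str(path)
        cfg_path = cfg_path[: -len(".npz")] if cfg_path.endswith(".npz") else cfg_path
        with open(cfg_path + ".config.json", "w") as fh:
            fh.write(self.cfg.to_json())

    @classmethod
    def load(cls, path) -> "GCNNModel":
        cfg_path = str(path)
        cfg_path = cfg_path[: -len(".npz")] if cfg_path.endswith(".npz") else cfg_path
        with open(cfg_path + ".config.json") as fh:
            cfg = GCNNConfig.from_json(fh.read())
        model = cls(cfg)
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        for i, p in enumerate(model.params):
            p[...] = data[f"p{i}"]
        for i, layer in enumerate(model.layers):
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = data[f"rm{i}"]
                layer.running_var = data[f"rv{i}"]
        return model


class MultiBranchModel:
    """One independent GCNN branch per color space, fused at the top.

    Takes a plain RGB batch (values in [0, 1]); the color-space expansion
    happens inside the forward pass.  ``concat_features`` concatenates
    each branch's 64-unit feature layer and trains a fresh softmax head
    over the fused vector; ``average_probs`` averages the branch
    probability outputs (a convex combination of simplex points, so rows
    still sum to one).
    """

    def __init__(
        self,
        cfg: GCNNConfig,
        spaces: tuple[str, ...] = colorspace.EXPANSION_SPACES,
        fusion: str = "concat_features",
    ):
        spaces = tuple(spaces)
        if not spaces:
            raise ConfigError("spaces must be a non-empty sequence")
        if len(set(spaces)) != len(spaces):
            raise ConfigError(f"duplicate color spaces in {spaces}")
        unknown = set(spaces) - set(colorspace.COLOR_SPACES)
        if unknown:
            raise ConfigError(f"unknown color spaces: {sorted(unknown)}")
        if fusion not in ("concat_features", "average_probs"):
            raise ConfigError(f"unknown fusion mode {fusion!r}")
        self.cfg = cfg
        self.spaces = spaces
        self.fusion = fusion
        # independent branches, deterministically seeded per position
        self.branches = [
            GCNNModel(
                GCNNConfig(**{**asdict(cfg), "seed": (cfg.seed + i) % 2**31})
            )
            for i in range(len(spaces))
        ]
        self.head: Sequential | None = None
        if fusion == "concat_features":
            self._trunks = [b.feature_trunk() for b in self.branches]
            rng = np.random.default_rng((cfg.seed + len(spaces)) % 2**31)
            fused = len(spaces) * cfg.dense_units[-1]
            self.head = Sequential(
                [
                    Dense(fused, cfg.n_classes, rng=rng, name="fuse_logits"),
                    Softmax(name="fuse_softmax"),
                ],
                name="fusion_head",
            )

    @property
    def params(self):
        ps = []
        if self.fusion == "concat_features":
            for t in self._trunks:
                ps += t.params
            ps += self.head.params
        else:
            for b in self.branches:
                ps += b.params
        return ps

    @property
    def grads(self):
        gs = []
        if self.fusion == "concat_features":
            for t in self._trunks:
                gs += t.grads
            gs += self.head.grads
        else:
            for b in self.branches:
                gs += b.grads
        return gs

    def set_dropout_rng(self, rng):
        nets = self._trunks if self.fusion == "concat_features" else [
            b.net for b in self.branches
        ]
        for net in nets:
            net.set_dropout_rng(rng)

    def _expand(self, x: np.ndarray) -> list[np.ndarray]:
        batch = colorspace.ImageBatch(np.asarray(x, dtype=np.float64))
        expanded = colorspace.expand_all(batch, include_rgb="RGB" in self.spaces)
        return [expanded[s].pixels.astype(np.float32) for s in self.spaces]

    def forward(self, x, training: bool = False) -> np.ndarray:
        inputs = self._expand(x)
        if self.fusion == "concat_features":
            feats = [
                t.forward(xi, training=training)
                for t, xi in zip(self._trunks, inputs)
            ]
            self._feat_widths = [f.shape[1] for f in feats]
            return self.head.forward(np.concatenate(feats, axis=1), training=training)
        probs = [
            b.forward(xi, training=training)
            for b, xi in zip(self.branches, inputs)
        ]
        return np.mean(probs, axis=0)

    def backward(self, dy):
        if self.fusion == "concat_features":
            dfused = self.head.backward(dy)
            offset = 0
            for t, width in zip(self._trunks, self._feat_widths):
                t.backward(dfused[:, offset : offset + width])
                offset += width
            return None
        share = dy / len(self.branches)
        for b in self.branches:
            b.backward(share)
        return None

    def fit(self, X, y, X_val=None, y_val=None, **train_kwargs):
        return fit_network(self, X, y, X_val, y_val, **train_kwargs)

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        return predict_proba(self, X, batch_size=batch_size)

    def predict(self, X, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(X, batch_size=batch_size).argmax(axis=1)

    @property
    def layers(self):
        out = []
        for b in self.branches:
            out += b.layers
        if self.head is not None:
            out += list(self.head.iter_layers())
        return out


def build_gcnn(cfg: GCNNConfig | None = None) -> GCNNModel:
    """Build the seeded GCNN: processing -> N residual -> classification."""
    return GCNNModel(cfg or GCNNConfig())


def build_multibranch(
    cfg: GCNNConfig | None = None,
    spaces: tuple[str, ...] = colorspace.EXPANSION_SPACES,
    fusion: str = "concat_features",
) -> MultiBranchModel:
    """Build the fused multi-color-space model (one GCNN per space)."""
    return MultiBranchModel(cfg or GCNNConfig(), spaces=spaces, fusion=fusion)


def summarize(model, input_shape: tuple | None = None) -> LayerSummary:
    """Trace a dummy batch through the model, recording shapes and counts.

    For a :class:`MultiBranchModel` the branch layers are listed per
    branch, followed by the fusion head.
    """
    if isinstance(model, MultiBranchModel):
        summary = LayerSummary()
        for space, branch in zip(model.spaces, model.branches):
            sub = summarize(branch)
            summary.rows += [(f"{space}:{n}", s, p) for n, s, p in sub.rows]
        if model.head is not None:
            width = len(model.spaces) * model.cfg.dense_units[-1]
            x = np.zeros((1, width), dtype=np.float32)
            for layer in model.head.iter_layers():
                x = layer.forward(x, training=False)
                summary.rows.append((layer.name, tuple(x.shape[1:]), layer.param_count()))
        return summary

    cfg = model.cfg
    if input_shape is None:
        input_shape = (cfg.input_size[0], cfg.input_size[1], cfg.in_channels)
    x = np.zeros((1, *input_shape), dtype=np.float32)
    summary = LayerSummary()

    def trace(component, x):
        if isinstance(component, Sequential):
            for sub in component.layers:
                x = trace(sub, x)
            return x
        if isinstance(component, ResidualBlock):
            x_in = x
            x = trace(component.main, x)
            if component.skip and component.projection is not None:
                xs = component.projection.forward(x_in, training=False)
                summary.rows.append(
                    (
                        component.projection.name,
                        tuple(xs.shape[1:]),
                        component.projection.param_count(),
                    )
                )
                x = x + xs
            elif component.skip:
                x = x + x_in
            return x
        y = component.forward(x, training=False)
        summary.rows.append((component.name, tuple(y.shape[1:]), component.param_count()))
        return y

    trace(model.net, x)
    return summary
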