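"""Model specifications, builders and cost auditing.

Two families are provided, each as a single-branch baseline and as a
multibranch variant in which three parallel branches with different
temporal kernel sizes share one softmax head:

* **EEGNet-style branch** — temporal convolution (1 x KE, F1 filters,
  same padding, bias-free) learning frequency filters; batch-norm;
  depthwise spatial convolution (E x 1, depth multiplier D) learning
  frequency-specific spatial filters; batch-norm + ELU + average pool +
  dropout; separable convolution (depthwise 1 x 16 + pointwise to F2);
  batch-norm + ELU + average pool + dropout; flatten.
* **ShallowConvNet-style branch** — temporal convolution (valid);
  full spatial convolution; batch-norm; squaring nonlinearity; overlapping
  average pool (75, stride 15); log; dropout; flatten — the band-power
  pipeline expressed as a network.

The canonical multibranch configurations use kernel sizes 16/32/64 with
4/8/16 temporal filters and dropout 0/0.1/0.2 (EEGNet family) and kernel
sizes 5/15/20 with 40 filters (shallow family).

``count_trainable_parameters`` audits convolution/dense weights, the dense
bias and batch-norm scale/shift pairs; ``conv_multiplication_count`` is
the flattened-filter multiplication cost used to compare 1-D temporal +
spatial filter pairs against full 3-D filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from scipy import fft as sfft

from .errors import SpecError, ValidationError
from .nn import (
    AvgPool,
    BatchNorm,
    Dense,
    Dropout,
    ELU,
    Flatten,
    FusedEntry,
    LogActivation,
    MultibranchClassifier,
    SeparableConv,
    Sequential,
    SpatialConv,
    Square,
    TemporalConv,
)

__all__ = [
    "EEGNetBranchConfig",
    "ShallowBranchConfig",
    "MultibranchModelSpec",
    "ParamAudit",
    "spec_to_config",
    "spec_from_config",
    "mbeegnet_spec",
    "eegnet_spec",
    "mbshallow_spec",
    "shallow_spec",
    "build_model",
    "count_trainable_parameters",
    "conv_multiplication_count",
    "describe_model",
]


@dataclass(frozen=True)
class EEGNetBranchConfig:
    """Hyperparameters of one EEGNet-style branch.

    ``n_filters`` (F1), ``kernel`` (KE) and ``dropout_rate`` vary across
    branches; the remaining values are the compact-EEGNet conventions:
    depth multiplier D = 2, pointwise filters F2 = 2*F1, separable kernel
    16, two temporal average pools of length 8.
    """

    n_filters: int
    kernel: int
    dropout_rate: float
    depth_multiplier: int = 2
    pointwise_filters: int | None = None  # default 2 * n_filters
    separable_kernel: int = 16
    pool_lengths: tuple[int, int] = (8, 8)
    max_norm: float | None = None

    @property
    def f2(self) -> int:
        return self.pointwise_filters if self.pointwise_filters is not None else 2 * self.n_filters

    def validate(self) -> None:
        for name in ("n_filters", "kernel", "depth_multiplier", "separable_kernel"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.f2 < 1 or any(p < 1 for p in self.pool_lengths):
            raise ValidationError("pointwise_filters and pool lengths must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


@dataclass(frozen=True)
class ShallowBranchConfig:
    """Hyperparameters of one ShallowConvNet-style branch."""

    kernel: int
    n_filters: int = 40
    pool_length: int = 75
    pool_stride: int = 15
    dropout_rate: float = 0.5

    def validate(self) -> None:
        for name in ("n_filters", "kernel", "pool_length", "pool_stride"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


@dataclass(frozen=True)
class MultibranchModelSpec:
    """Branches + input dimensions + class count, compiled by :func:`build_model`."""

    family: str  # "eegnet" | "shallow"
    branches: tuple
    n_channels: int
    n_samples: int
    n_classes: int

    def validate(self) -> None:
        if self.family not in ("eegnet", "shallow"):
            raise SpecError(f"family must be 'eegnet' or 'shallow', got {self.family!r}")
        if not self.branches:
            raise SpecError("at least one branch is required")
        expected = EEGNetBranchConfig if self.family == "eegnet" else ShallowBranchConfig
        for b in self.branches:
            if not isinstance(b, expected):
                raise SpecError(f"{self.family} model requires {expected.__name__} branches")
            b.validate()
            if b.kernel > self.n_samples:
                raise SpecError(f"kernel {b.kernel} exceeds {self.n_samples} samples")
        if self.n_channels < 1 or self.n_samples < 1 or self.n_classes < 2:
            raise SpecError("n_channels, n_samples must be >= 1 and n_classes >= 2")


# -- canonical configurations -----------------------------------------

_MBEEGNET_BRANCHES = (
    EEGNetBranchConfig(n_filters=4, kernel=16, dropout_rate=0.0),
    EEGNetBranchConfig(n_filters=8, kernel=32, dropout_rate=0.1),
    EEGNetBranchConfig(n_filters=16, kernel=64, dropout_rate=0.2),
)

_MBSHALLOW_BRANCHES = (
    ShallowBranchConfig(kernel=5),
    ShallowBranchConfig(kernel=15),
    ShallowBranchConfig(kernel=20),
)


def mbeegnet_spec(n_channels: int = 22, n_samples: int = 1125, n_classes: int = 4,
                  branches: tuple = _MBEEGNET_BRANCHES) -> MultibranchModelSpec:
    """Three-branch EEGNet-style model (kernels 16/32/64, filters 4/8/16)."""
    return MultibranchModelSpec("eegnet", tuple(branches), n_channels, n_samples, n_classes)


def eegnet_spec(n_channels: int = 22, n_samples: int = 1125, n_classes: int = 4,
                n_filters: int = 8, kernel: int = 32, dropout_rate: float = 0.1) -> MultibranchModelSpec:
    """Single-branch EEGNet baseline (defaults match the middle branch)."""
    cfg = EEGNetBranchConfig(n_filters=n_filters, kernel=kernel, dropout_rate=dropout_rate)
    return MultibranchModelSpec("eegnet", (cfg,), n_channels, n_samples, n_classes)


def mbshallow_spec(n_channels: int = 22, n_samples: int = 1125, n_classes: int = 4,
                   branches: tuple = _MBSHALLOW_BRANCHES) -> MultibranchModelSpec:
    """Three-branch shallow band-power model (kernels 5/15/20)."""
    return MultibranchModelSpec("shallow", tuple(branches), n_channels, n_samples, n_classes)


def shallow_spec(n_channels: int = 22, n_samples: int = 1125, n_classes: int = 4,
                 kernel: int = 25, n_filters: int = 40) -> MultibranchModelSpec:
    """Single-branch ShallowConvNet baseline."""
    cfg = ShallowBranchConfig(kernel=kernel, n_filters=n_filters)
    return MultibranchModelSpec("shallow", (cfg,), n_channels, n_samples, n_classes)


# -- builders ----------------------------------------------------------


def _eegnet_branch(cfg: EEGNetBranchConfig, spec: MultibranchModelSpec, i: int,
                   fft_length: int, rng, dtype) -> tuple[Sequential, int]:
    e, t = spec.n_channels, spec.n_samples
    p1, p2 = cfg.pool_lengths
    t1 = t // p1
    t2 = t1 // p2
    if t1 < 1 or t2 < 1:
        raise SpecError(f"branch {i}: pools {cfg.pool_lengths} collapse {t} samples to zero")
    name = f"branch{i}"
    fd = cfg.n_filters * cfg.depth_multiplier
    layers = [
        FusedEntry(e, t, cfg.n_filters, cfg.kernel, cfg.depth_multiplier,
                   fft_length=fft_length, max_norm=cfg.max_norm, name=f"{name}/entry",
                   rng=rng, dtype=dtype),
        BatchNorm(fd, name=f"{name}/bn2", dtype=dtype),
        ELU(),
        AvgPool(p1),
        Dropout(cfg.dropout_rate),
        SeparableConv(fd, cfg.f2, cfg.separable_kernel, name=f"{name}/separable", rng=rng, dtype=dtype),
        BatchNorm(cfg.f2, name=f"{name}/bn3", dtype=dtype),
        ELU(),
        AvgPool(p2),
        Dropout(cfg.dropout_rate),
        Flatten(),
    ]
    return Sequential(layers, name=name), cfg.f2 * t2


def _shallow_branch(cfg: ShallowBranchConfig, spec: MultibranchModelSpec, i: int,
                    rng, dtype) -> tuple[Sequential, int]:
    e, t = spec.n_channels, spec.n_samples
    tv = t - cfg.kernel + 1
    tp = (tv - cfg.pool_length) // cfg.pool_stride + 1
    if tp < 1:
        raise SpecError(f"branch {i}: pool {cfg.pool_length}/{cfg.pool_stride} collapses {tv} samples")
    name = f"branch{i}"
    layers = [
        TemporalConv(cfg.n_filters, cfg.kernel, padding="valid", name=f"{name}/temporal", rng=rng, dtype=dtype),
        SpatialConv(e, cfg.n_filters, cfg.n_filters, name=f"{name}/spatial", rng=rng, dtype=dtype),
        BatchNorm(cfg.n_filters, name=f"{name}/bn", dtype=dtype),
        Square(),
        AvgPool(cfg.pool_length, cfg.pool_stride),
        LogActivation(),
        Dropout(cfg.dropout_rate),
        Flatten(),
    ]
    return Sequential(layers, name=name), cfg.n_filters * tp


def build_model(spec: MultibranchModelSpec, seed: int = 0, dtype=np.float32) -> MultibranchClassifier:
    """Compile a spec into a trainable network (deterministic given ``seed``)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    branches, widths = [], []
    if spec.family == "eegnet":
        kmax = max(b.kernel for b in spec.branches)
        fft_length = sfft.next_fast_len(spec.n_samples + kmax - 1, real=True)
        for i, cfg in enumerate(spec.branches):
            br, w = _eegnet_branch(cfg, spec, i, fft_length, rng, dtype)
            branches.append(br)
            widths.append(w)
    else:
        for i, cfg in enumerate(spec.branches):
            br, w = _shallow_branch(cfg, spec, i, rng, dtype)
            branches.append(br)
            widths.append(w)
    head = Dense(int(sum(widths)), spec.n_classes, name="head/dense", rng=rng, dtype=dtype)
    return MultibranchClassifier(branches, head, spec.n_classes,
                                 input_shape=(spec.n_channels, spec.n_samples))


# -- serialization -----------------------------------------------------


def spec_to_config(spec: MultibranchModelSpec) -> dict:
    """Plain-dict form of a model spec (JSON/YAML-serializable)."""
    from dataclasses import asdict

    spec.validate()
    return {
        "family": spec.family,
        "n_channels": spec.n_channels,
        "n_samples": spec.n_samples,
        "n_classes": spec.n_classes,
        "branches": [asdict(b) for b in spec.branches],
    }


def spec_from_config(config: dict) -> MultibranchModelSpec:
    """Inverse of :func:`spec_to_config`; validates the result."""
    family = config.get("family")
    cls = {"eegnet": EEGNetBranchConfig, "shallow": ShallowBranchConfig}.get(family)
    if cls is None:
        raise SpecError(f"family must be 'eegnet' or 'shallow', got {family!r}")
    branches = tuple(cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in b.items()})
                     for b in config["branches"])
    spec = MultibranchModelSpec(family, branches, int(config["n_channels"]),
                                int(config["n_samples"]), int(config["n_classes"]))
    spec.validate()
    return spec


# -- auditing ----------------------------------------------------------


@dataclass
class ParamAudit:
    """Per-layer trainable-parameter breakdown."""

    entries: list[tuple[str, tuple[int, ...], int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(sum(count for _, _, count in self.entries))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.entries, columns=["layer", "shape", "parameters"])
        df["shape"] = df["shape"].map(lambda s: "x".join(map(str, s)))
        return df


def count_trainable_parameters(model: MultibranchClassifier | MultibranchModelSpec) -> ParamAudit:
    """Enumerate every trainable variable of a (built) model.

    Counts convolution weights, dense weights and bias, and batch-norm
    scale/shift; running statistics are non-trainable and excluded.
    """
    if isinstance(model, MultibranchModelSpec):
        model = build_model(model)
    entries = [(p.name, tuple(p.value.shape), int(p.size)) for p in model.params()]
    return ParamAudit(entries)


def conv_multiplication_count(n_filters: int, kernel_dims: tuple[int, int, int], n_positions: int) -> int:
    """Multiplications of a filter bank: ``n_filters * kh * kw * kd * n_positions``.

    With 1-D factorized filters (e.g. a temporal 1 x 8 bank plus a spatial
    22 x 1 bank) this is far below the cost of one dense 3-D filter bank,
    which is the computational argument for flattened convolutions.
    """
    dims = tuple(int(k) for k in kernel_dims)
    if len(dims) != 3:
        raise ValidationError(f"kernel_dims must have three entries, got {kernel_dims!r}")
    if n_filters < 1 or n_positions < 1 or any(k < 1 for k in dims):
        raise ValidationError("all arguments must be positive integers")
    return int(n_filters) * dims[0] * dims[1] * dims[2] * int(n_positions)


def describe_model(spec: MultibranchModelSpec) -> str:
    """Deterministic human-readable layer table with parameter counts."""
    spec.validate()
    model = build_model(spec)
    audit = count_trainable_parameters(model)
    buf = StringIO()
    fam = "MBEEGNet-style" if spec.family == "eegnet" else "MBShallowConvNet-style"
    kind = fam if len(spec.branches) > 1 else fam.replace("MB", "").replace("-style", " (single branch)")
    buf.write(f"{kind}: {spec.n_channels} channels x {spec.n_samples} samples -> {spec.n_classes} classes\n")
    buf.write(f"branches: {len(spec.branches)}")
    if len(spec.branches) > 1:
        buf.write(" (concatenated into the softmax head)")
    buf.write("\n\n")
    buf.write(f"{'layer':<28}{'shape':<16}{'parameters':>12}\n")
    for name, shape, count in audit.entries:
        buf.write(f"{name:<28}{'x'.join(map(str, shape)):<16}{count:>12}\n")
    buf.write(f"{'total':<44}{audit.total:>12}\n")
    return buf.getvalue()
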