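"""The six model families and their closed-form unit/parameter accounting.

All six classifiers share one convolutional recipe: two stride-1 valid
convolutions (16 then 32 kernels of size 3 per spatial dim), each followed
by leaky-ReLU, non-overlapping max pooling of size 2 (floor division of
the extent) and batch normalization; then flatten, dropout (50%), a dense
layer of 128 units with leaky-ReLU and batch normalization, and a dense
softmax output over the 5 movement classes.  They differ only in the
input representation and dimensionality of the convolution:

========== ========================================================
kind       input representation (channels last)
========== ========================================================
m2d        three planar stacks, one 2D conv branch per anatomical
           axis, branch flattens concatenated before the dense head
s2d        the single axis-2 stack: (dimX, dimY) image, dimZ channels
mv2d       the axis-2 mean image: (dimX, dimY), 1 channel
conv1d     the (dimY*dimZ, dimX) vector sequence, 1D conv
conv3d     the raw volume, 1 channel, 3D conv
conv3d_sep conv3d with the SECOND conv factorized into a depthwise
           3x3x3 stage (no bias) and a pointwise 1x1x1 stage (bias)
========== ========================================================

Normalization placement, fixed by fitting the layer-by-layer arithmetic to
the published totals: after each pool in every model; additionally after
the flatten/merge in the 1D/2D/multi-branch models but NOT in the two 3D
models; and after the dense 128 layer in every model.  Each batch-norm
contributes 4 numbers per feature (scale, shift, running mean, running
variance) and all four are included in parameter totals.

Unit/parameter counts are available two ways that must agree: the
closed-form walk over the configuration
(:func:`count_parameters_closed_form`) and the literal sum of array sizes
of a built model (:func:`build_model` + ``model.n_parameters``);
:func:`verify_counts` asserts the equality and reports any per-layer diff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn, slicing
from .nn import softmax  # noqa: F401  (re-exported: the output-layer map)

MODEL_KINDS = ("m2d", "s2d", "mv2d", "conv1d", "conv3d", "conv3d_sep")

#: Kinds whose published totals include a post-flatten/merge normalization.
_FLATTEN_NORM_KINDS = frozenset({"m2d", "s2d", "mv2d", "conv1d"})


@dataclass(frozen=True)
class ArchitectureConfig:
    """Declarative description of one model; counts and builders derive from it."""

    model_kind: str
    volume_shape: tuple[int, int, int] = (91, 109, 91)
    conv_kernels: tuple[int, int] = (16, 32)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: int = 128
    n_classes: int = 5
    dropout: float = 0.5
    leaky_slope: float = 0.3
    norm_after_pool: bool = True
    norm_after_flatten: bool | None = None  # None: resolved by model kind
    norm_after_dense: bool = True

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}; choose from {MODEL_KINDS}")
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 1:
            raise ValueError(f"volume_shape must be 3 positive dims, got {self.volume_shape}")

    @property
    def flatten_norm(self) -> bool:
        if self.norm_after_flatten is None:
            return self.model_kind in _FLATTEN_NORM_KINDS
        return self.norm_after_flatten

    def branch_specs(self) -> list[tuple[int, tuple[int, ...], int]]:
        """Per branch: (conv dimensionality, spatial dims, input channels)."""
        dx, dy, dz = self.volume_shape
        kind = self.model_kind
        if kind == "m2d":
            return [(2, (dy, dz), dx), (2, (dx, dz), dy), (2, (dx, dy), dz)]
        if kind == "s2d":
            return [(2, (dx, dy), dz)]
        if kind == "mv2d":
            return [(2, (dx, dy), 1)]
        if kind == "conv1d":
            return [(1, (dy * dz,), dx)]
        return [(3, (dx, dy, dz), 1)]  # conv3d, conv3d_sep


@dataclass
class CountReport:
    """Unit and parameter accounting for one configuration."""

    model_kind: str
    flatten_units: int
    total_parameters: int
    per_layer: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        assert self.total_parameters == sum(c for _, c in self.per_layer)


def reference_config(model_kind: str, volume_shape=(91, 109, 91)) -> ArchitectureConfig:
    """The published experimental configuration for one model kind."""
    return ArchitectureConfig(model_kind=model_kind, volume_shape=tuple(volume_shape))


def conv_stack_units(
    spatial_dims,
    n_convs: int = 2,
    kernel: int = 3,
    pool: int = 2,
    out_channels: int = 32,
) -> int:
    """Units left after the conv/pool stack: apply d -> floor((d-k+1)/p) per
    stage to every spatial dim, then multiply by the final channel count."""
    dims = list(spatial_dims)
    for stage in range(n_convs):
        dims = [(d - kernel + 1) // pool for d in dims]
        if min(dims) < 1:
            raise ValueError(
                f"spatial dims {tuple(spatial_dims)} collapse below 1 at conv stage {stage + 1}"
            )
    return int(np.prod(dims)) * out_channels


def _stack_out_dims(spatial_dims, n_convs=2, kernel=3, pool=2):
    dims = list(spatial_dims)
    for _ in range(n_convs):
        dims = [(d - kernel + 1) // pool for d in dims]
    return tuple(dims)


def count_parameters_closed_form(config: ArchitectureConfig) -> CountReport:
    """Layer-by-layer arithmetic, independent of any built model.

    conv: (prod kernel)*C_in*C_out + C_out; depthwise: (prod kernel)*C_in
    (no bias); pointwise: C_in*C_out + C_out; batch-norm: 4 per feature;
    dense: in*out + out.
    """
    k = config.kernel_size
    c1, c2 = config.conv_kernels
    per_layer: list[tuple[str, int]] = []
    flatten_total = 0
    for b, (nd, spatial, cin) in enumerate(config.branch_specs()):
        tag = f"branch{b}." if config.model_kind == "m2d" else ""
        kk = k**nd
        per_layer.append((f"{tag}conv1", kk * cin * c1 + c1))
        if config.norm_after_pool:
            per_layer.append((f"{tag}bn1", 4 * c1))
        if config.model_kind == "conv3d_sep":
            per_layer.append((f"{tag}conv2_depthwise", kk * c1))
            per_layer.append((f"{tag}conv2_pointwise", c1 * c2 + c2))
        else:
            per_layer.append((f"{tag}conv2", kk * c1 * c2 + c2))
        if config.norm_after_pool:
            per_layer.append((f"{tag}bn2", 4 * c2))
        flatten_total += conv_stack_units(
            spatial, kernel=k, pool=config.pool_size, out_channels=c2
        )
    if config.flatten_norm:
        per_layer.append(("bn_merge" if config.model_kind == "m2d" else "bn_flatten", 4 * flatten_total))
    per_layer.append(("dense1", flatten_total * config.dense_units + config.dense_units))
    if config.norm_after_dense:
        per_layer.append(("bn_dense", 4 * config.dense_units))
    per_layer.append(("dense2", config.dense_units * config.n_classes + config.n_classes))
    return CountReport(
        model_kind=config.model_kind,
        flatten_units=flatten_total,
        total_parameters=sum(c for _, c in per_layer),
        per_layer=per_layer,
    )


def _conv_block(nd, cin, cout, config, rng, idx, separable=False):
    """conv -> leaky-ReLU -> max-pool -> (batch-norm), as one layer list."""
    layers: list[nn.Layer] = []
    if separable:
        layers.append(nn.DepthwiseConv3D(cin, config.kernel_size, rng, name=f"conv{idx}_depthwise"))
        layers.append(nn.ConvND(nd, cin, cout, 1, rng, name=f"conv{idx}_pointwise"))
    else:
        layers.append(nn.ConvND(nd, cin, cout, config.kernel_size, rng, name=f"conv{idx}"))
    layers.append(nn.LeakyReLU(config.leaky_slope, name=f"lrelu{idx}"))
    layers.append(nn.MaxPoolND(nd, config.pool_size, name=f"pool{idx}"))
    if config.norm_after_pool:
        layers.append(nn.BatchNorm(cout, name=f"bn{idx}"))
    return layers


def build_model(config: ArchitectureConfig, rng: np.random.Generator | int | None = 0):
    """Instantiate a trainable model for the configuration.

    The forward pass maps a batch of the config's input representation
    (a tuple of three planar-stack batches for ``m2d``) to a length-
    ``n_classes`` probability vector per sample.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c1, c2 = config.conv_kernels
    specs = config.branch_specs()
    branches = []
    flatten_total = 0
    for nd, spatial, cin in specs:
        sep2 = config.model_kind == "conv3d_sep"
        layers = _conv_block(nd, cin, c1, config, rng, 1)
        layers += _conv_block(nd, c1, c2, config, rng, 2, separable=sep2)
        layers.append(nn.Flatten(name="flatten"))
        branches.append(nn.Sequential(layers))
        flatten_total += conv_stack_units(
            spatial, kernel=config.kernel_size, pool=config.pool_size, out_channels=c2
        )
    head_layers: list[nn.Layer] = []
    if config.flatten_norm:
        head_layers.append(nn.BatchNorm(flatten_total, name="bn_merge"))
    head_layers.append(nn.Dropout(config.dropout, rng, name="dropout"))
    head_layers.append(nn.Dense(flatten_total, config.dense_units, rng, name="dense1"))
    head_layers.append(nn.LeakyReLU(config.leaky_slope, name="lrelu_dense"))
    if config.norm_after_dense:
        head_layers.append(nn.BatchNorm(config.dense_units, name="bn_dense"))
    head_layers.append(nn.Dense(config.dense_units, config.n_classes, rng, name="dense2"))
    head_layers.append(nn.Softmax(name="softmax"))
    head = nn.Sequential(head_layers, name="head")
    if len(branches) > 1:
        return nn.MultiBranch(branches, head, name=config.model_kind)
    model = nn.Sequential(branches[0].layers + head.layers, name=config.model_kind)
    return model


def built_model_count(config: ArchitectureConfig, rng=0) -> CountReport:
    """Parameter count of an actually instantiated model (array sizes)."""
    model = build_model(config, rng)
    per_layer = [(n, c) for n, c in model.per_layer_counts()]
    flatten_units = count_parameters_closed_form(config).flatten_units
    return CountReport(
        model_kind=config.model_kind,
        flatten_units=flatten_units,
        total_parameters=model.n_parameters,
        per_layer=per_layer,
    )


def verify_counts(config: ArchitectureConfig, rng=0):
    """Build the model and check closed-form vs built parameter totals.

    Returns ``(ok, closed_form_report, built_report)``; on mismatch the
    built report's per-layer list localizes the difference.
    """
    closed = count_parameters_closed_form(config)
    built = built_model_count(config, rng)
    return closed.total_parameters == built.total_parameters, closed, built


# ---------------------------------------------------------------------------
# Input transforms (batched), matching branch_specs ordering
# ---------------------------------------------------------------------------

def transform_volume(config: ArchitectureConfig, volume: np.ndarray):
    """One sample volume -> the model-kind input (no batch axis)."""
    kind = config.model_kind
    if kind == "m2d":
        return tuple(st.data for st in slicing.to_triplanar(volume))
    if kind == "s2d":
        return slicing.to_axial_stack(volume).data
    if kind == "mv2d":
        return slicing.to_mean_value_2d(volume)[..., None]
    if kind == "conv1d":
        return slicing.to_sequence_1d(volume)
    return np.asarray(volume)[..., None]  # conv3d / conv3d_sep


def transform_batch(config: ArchitectureConfig, volumes: np.ndarray):
    """Batch of volumes (N, dimX, dimY, dimZ) -> batched model input."""
    volumes = np.asarray(volumes)
    kind = config.model_kind
    if kind == "m2d":
        return tuple(
            np.ascontiguousarray(np.moveaxis(volumes, axis, -1)) for axis in (1, 2, 3)
        )
    if kind == "s2d":
        return np.ascontiguousarray(np.moveaxis(volumes, 3, -1))
    if kind == "mv2d":
        return volumes.mean(axis=3)[..., None]
    if kind == "conv1d":
        n, dx, dy, dz = volumes.shape
        return np.ascontiguousarray(
            np.transpose(volumes, (0, 3, 2, 1)).reshape(n, dz * dy, dx)
        )
    return volumes[..., None]


def scaled_config(config: ArchitectureConfig, volume_shape) -> ArchitectureConfig:
    """Same architecture on a different volume size (for desk-scale runs)."""
    return replace(config, volume_shape=tuple(volume_shape))
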