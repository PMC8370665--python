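"""Declarative CNN architectures and parameter accounting.

Two families are described here as layer lists (:class:`CnnSpec`):

* the compact five-convolution-layer screening CNN (5x5 kernels with
  doubling filter banks 64-128-256-512-512, each followed by 2x2 max
  pooling and ReLU, then dropout 0.5, a 64-unit dense layer, and a binary
  sigmoid head).  At the reference 224 px input the spatial chain is
  224 -> 112 -> 56 -> 28 -> 14 -> 7, flattening to 25,088 features;
* the ImageNet transfer bases VGG16, Xception and DenseNet-121, built from
  their published topologies with exact per-layer parameter counts
  (including batch-norm statistics), plus feature-extraction / fine-tuning
  customization that freezes or unfreezes trailing layers.

Specs are data, not weights: they drive parameter accounting, shape
verification, and the numpy execution engine in :mod:`dedscreen.nn`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

_PARAM_KINDS = ("conv", "sepconv", "bn", "dense", "output")


@dataclass(frozen=True)
class LayerSpec:
    """One layer: only the fields meaningful for its kind are set.

    ``kernel`` is (h, w, in_channels) for conv-like layers and
    (1, 1, fan_in) for dense layers; ``filters`` doubles as the channel
    count for batch-norm layers.
    """

    kind: str
    name: str = ""
    kernel: tuple[int, int, int] | None = None
    filters: int | None = None
    units: int | None = None
    stride: tuple[int, int] = (1, 1)
    padding: str = "same"
    rate: float | None = None
    use_bias: bool = True
    activation: str | None = None
    trainable: bool = True

    def __post_init__(self) -> None:
        if self.rate is not None and not (0 <= self.rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        for attr in ("filters", "units"):
            v = getattr(self, attr)
            if v is not None and v < 1:
                raise ValueError(f"{attr} must be positive")

    @property
    def n_params(self) -> int:
        """Weight + bias element count (batch norm: gamma, beta, and the
        two moving statistics, i.e. 4 per channel)."""
        if self.kind == "conv":
            h, w, cin = self.kernel
            return h * w * cin * self.filters + (self.filters if self.use_bias else 0)
        if self.kind == "sepconv":
            h, w, cin = self.kernel
            depthwise = h * w * cin
            pointwise = cin * self.filters
            return depthwise + pointwise + (self.filters if self.use_bias else 0)
        if self.kind == "bn":
            return 4 * self.filters
        if self.kind in ("dense", "output"):
            fan_in = self.kernel[2]
            return fan_in * self.units + (self.units if self.use_bias else 0)
        return 0


@dataclass(frozen=True)
class CnnSpec:
    """An ordered layer sequence with resolved per-layer output shapes.

    ``shapes[i]`` is the output shape of ``layers[i]`` — an (H, W, C) tuple,
    an (n,) tuple after flattening, or ``None`` for branching architectures
    where a linear shape chain is not defined.
    """

    input_size: tuple[int, int, int]
    layers: tuple[LayerSpec, ...]
    n_classes: int
    shapes: tuple[tuple[int, ...] | None, ...] = ()
    name: str = ""


def count_parameters(spec: CnnSpec) -> int:
    """Total weight and bias elements across all layers."""
    return sum(layer.n_params for layer in spec.layers)


def count_trainable_parameters(spec: CnnSpec) -> int:
    return sum(layer.n_params for layer in spec.layers if layer.trainable)


def infer_shapes(input_size: tuple[int, int, int],
                 layers: tuple[LayerSpec, ...]) -> tuple[tuple[int, ...], ...]:
    """Resolve the output shape after each layer of a linear (unbranched)
    architecture; raises if pooling would produce a non-integral size."""
    shape: tuple[int, ...] = input_size
    out = []
    for layer in layers:
        if layer.kind == "conv":
            h, w, c = shape
            if layer.padding != "same":
                raise ValueError("linear chain inference supports same-padding only")
            if layer.kernel[2] != c:
                raise ValueError(f"layer {layer.name}: kernel expects "
                                 f"{layer.kernel[2]} channels, got {c}")
            shape = (h // layer.stride[0], w // layer.stride[1], layer.filters)
        elif layer.kind == "maxpool":
            h, w, c = shape
            sh, sw = layer.stride
            if h % sh or w % sw:
                raise ValueError(f"non-integral shape chain: {h}x{w} not divisible "
                                 f"by pool stride {sh}x{sw}")
            shape = (h // sh, w // sw, c)
        elif layer.kind == "flatten":
            n = 1
            for d in shape:
                n *= d
            shape = (n,)
        elif layer.kind in ("dense", "output"):
            if layer.kernel[2] != shape[0]:
                raise ValueError(f"layer {layer.name}: fan-in mismatch")
            shape = (layer.units,)
        elif layer.kind in ("relu", "dropout", "bn"):
            pass
        else:
            raise ValueError(f"cannot infer shape through layer kind {layer.kind!r}")
        out.append(shape)
    return tuple(out)


# --------------------------------------------------------------------------
# The proposed screening CNN
# --------------------------------------------------------------------------


def build_proposed_cnn(
    input_side: int = 224,
    n_classes: int = 2,
    base_filters: int = 64,
    dense_units: int = 64,
    dropout_rate: float = 0.5,
) -> CnnSpec:
    """The five-convolution-layer screening CNN.

    ``base_filters`` scales the filter banks (64-128-256-512-512 at the
    reference width); reduced variants (e.g. ``input_side=64,
    base_filters=8``) keep the topology while fitting CPU budgets.  The
    binary head is a single sigmoid unit trained with binary cross-entropy;
    ``n_classes > 2`` switches to a softmax head.
    """
    if input_side % 32 != 0:
        raise ValueError("input_side must be divisible by 32 for the 5-pool chain")
    widths = [base_filters, 2 * base_filters, 4 * base_filters,
              8 * base_filters, 8 * base_filters]
    layers: list[LayerSpec] = []
    cin = 3
    for i, cout in enumerate(widths, start=1):
        layers.append(LayerSpec("conv", name=f"conv{i}", kernel=(5, 5, cin),
                                filters=cout, padding="same"))
        layers.append(LayerSpec("maxpool", name=f"pool{i}", stride=(2, 2)))
        layers.append(LayerSpec("relu", name=f"relu{i}"))
        cin = cout
    flat = (input_side // 32) ** 2 * widths[-1]
    layers.append(LayerSpec("flatten", name="flatten"))
    layers.append(LayerSpec("dropout", name="dropout", rate=dropout_rate))
    layers.append(LayerSpec("dense", name="fc1", kernel=(1, 1, flat),
                            units=dense_units, activation="relu"))
    head_units = 1 if n_classes == 2 else n_classes
    layers.append(LayerSpec("output", name="head", kernel=(1, 1, dense_units),
                            units=head_units,
                            activation="sigmoid" if n_classes == 2 else "softmax"))
    layers_t = tuple(layers)
    return CnnSpec(
        input_size=(input_side, input_side, 3),
        layers=layers_t,
        n_classes=n_classes,
        shapes=infer_shapes((input_side, input_side, 3), layers_t),
        name="proposed_cnn",
    )


# --------------------------------------------------------------------------
# ImageNet transfer bases
# --------------------------------------------------------------------------


def _vgg16_layers() -> list[LayerSpec]:
    cfg = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]
    layers: list[LayerSpec] = []
    cin = 3
    for b, (cout, reps) in enumerate(cfg, start=1):
        for r in range(1, reps + 1):
            layers.append(LayerSpec("conv", name=f"block{b}_conv{r}",
                                    kernel=(3, 3, cin), filters=cout))
            cin = cout
        layers.append(LayerSpec("maxpool", name=f"block{b}_pool", stride=(2, 2)))
    layers.append(LayerSpec("flatten", name="flatten"))
    layers.append(LayerSpec("dense", name="fc1", kernel=(1, 1, 7 * 7 * 512), units=4096))
    layers.append(LayerSpec("dense", name="fc2", kernel=(1, 1, 4096), units=4096))
    layers.append(LayerSpec("output", name="predictions", kernel=(1, 1, 4096),
                            units=1000, activation="softmax"))
    return layers


def _xception_layers() -> list[LayerSpec]:
    L: list[LayerSpec] = []

    def sep_bn(name: str, cin: int, cout: int) -> None:
        L.append(LayerSpec("sepconv", name=name, kernel=(3, 3, cin),
                           filters=cout, use_bias=False))
        L.append(LayerSpec("bn", name=f"{name}_bn", filters=cout))

    L.append(LayerSpec("conv", name="block1_conv1", kernel=(3, 3, 3), filters=32,
                       stride=(2, 2), use_bias=False))
    L.append(LayerSpec("bn", name="block1_conv1_bn", filters=32))
    L.append(LayerSpec("conv", name="block1_conv2", kernel=(3, 3, 32), filters=64,
                       use_bias=False))
    L.append(LayerSpec("bn", name="block1_conv2_bn", filters=64))
    # Entry-flow blocks with strided 1x1 residual projections.
    cin = 64
    for b, cout in enumerate((128, 256, 728), start=2):
        sep_bn(f"block{b}_sepconv1", cin, cout)
        sep_bn(f"block{b}_sepconv2", cout, cout)
        L.append(LayerSpec("maxpool", name=f"block{b}_pool", stride=(2, 2)))
        L.append(LayerSpec("conv", name=f"block{b}_residual", kernel=(1, 1, cin),
                           filters=cout, stride=(2, 2), use_bias=False))
        L.append(LayerSpec("bn", name=f"block{b}_residual_bn", filters=cout))
        cin = cout
    # Middle flow: eight identity blocks of three separable convolutions.
    for b in range(5, 13):
        for s in range(1, 4):
            sep_bn(f"block{b}_sepconv{s}", 728, 728)
    # Exit flow.
    sep_bn("block13_sepconv1", 728, 728)
    sep_bn("block13_sepconv2", 728, 1024)
    L.append(LayerSpec("maxpool", name="block13_pool", stride=(2, 2)))
    L.append(LayerSpec("conv", name="block13_residual", kernel=(1, 1, 728),
                       filters=1024, stride=(2, 2), use_bias=False))
    L.append(LayerSpec("bn", name="block13_residual_bn", filters=1024))
    sep_bn("block14_sepconv1", 1024, 1536)
    sep_bn("block14_sepconv2", 1536, 2048)
    L.append(LayerSpec("gap", name="avg_pool"))
    L.append(LayerSpec("output", name="predictions", kernel=(1, 1, 2048),
                       units=1000, activation="softmax"))
    return L


def _densenet121_layers() -> list[LayerSpec]:
    growth = 32
    L: list[LayerSpec] = []
    L.append(LayerSpec("conv", name="conv1", kernel=(7, 7, 3), filters=64,
                       stride=(2, 2), use_bias=False))
    L.append(LayerSpec("bn", name="conv1_bn", filters=64))
    L.append(LayerSpec("maxpool", name="pool1", stride=(2, 2)))
    ch = 64
    for b, n_layers in enumerate((6, 12, 24, 16), start=2):
        for i in range(1, n_layers + 1):
            # bottleneck: BN -> 1x1 conv to 4k -> BN -> 3x3 conv to k, concat
            L.append(LayerSpec("bn", name=f"conv{b}_block{i}_0_bn", filters=ch))
            L.append(LayerSpec("conv", name=f"conv{b}_block{i}_1_conv",
                               kernel=(1, 1, ch), filters=4 * growth, use_bias=False))
            L.append(LayerSpec("bn", name=f"conv{b}_block{i}_1_bn", filters=4 * growth))
            L.append(LayerSpec("conv", name=f"conv{b}_block{i}_2_conv",
                               kernel=(3, 3, 4 * growth), filters=growth, use_bias=False))
            ch += growth
        if b < 5:
            L.append(LayerSpec("bn", name=f"pool{b}_bn", filters=ch))
            L.append(LayerSpec("conv", name=f"pool{b}_conv", kernel=(1, 1, ch),
                               filters=ch // 2, use_bias=False))
            L.append(LayerSpec("avgpool", name=f"pool{b}_pool", stride=(2, 2)))
            ch //= 2
    L.append(LayerSpec("bn", name="final_bn", filters=ch))
    L.append(LayerSpec("gap", name="avg_pool"))
    L.append(LayerSpec("output", name="predictions", kernel=(1, 1, ch),
                       units=1000, activation="softmax"))
    return L


_BASES = {
    "vgg16": _vgg16_layers,
    "xception": _xception_layers,
    "densenet121": _densenet121_layers,
}


def build_base(tag: str) -> CnnSpec:
    """A transfer base with its standard 1000-class ImageNet head.

    Weights are not loaded; the spec carries topology and parameter counts
    only (loading published weight files is a network-dependent extra).
    """
    if tag not in _BASES:
        raise ValueError(f"unknown base architecture {tag!r}; "
                         f"choose from {sorted(_BASES)}")
    layers = tuple(_BASES[tag]())
    shapes = None
    if tag == "vgg16":
        shapes = infer_shapes((224, 224, 3), layers)
    return CnnSpec(input_size=(224, 224, 3) if tag != "xception" else (299, 299, 3),
                   layers=layers, n_classes=1000,
                   shapes=shapes or (None,) * len(layers), name=tag)


@dataclass(frozen=True)
class TransferSpec:
    """How to customize a pre-trained base for the screening task."""

    base: str = "vgg16"
    mode: str = "feature_extraction"
    n_unfrozen: int = 0
    head: tuple[LayerSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("feature_extraction", "fine_tune"):
            raise ValueError("mode must be feature_extraction or fine_tune")
        if self.n_unfrozen < 0:
            raise ValueError("n_unfrozen must be >= 0")
        if self.mode == "feature_extraction" and self.n_unfrozen:
            raise ValueError("feature_extraction freezes the whole base")


def build_transfer_model(spec: TransferSpec, n_classes: int = 2) -> CnnSpec:
    """Base network with its ImageNet head replaced by a new classifier.

    In feature-extraction mode every base layer is frozen; in fine-tune mode
    the trailing ``n_unfrozen`` parameter-bearing base layers stay
    trainable.  The default head is global pooling / flattening into a
    64-unit ReLU dense layer and a sigmoid (or softmax) output.
    """
    full = build_base(spec.base)
    # Drop the ImageNet classifier: the final dense stack (and the flatten /
    # global-pool feeding it) is replaced by the new head.
    body = [l for l in full.layers if l.kind not in ("dense", "output", "flatten", "gap")]
    n_param_layers = sum(1 for l in body if l.n_params > 0)
    if spec.n_unfrozen > n_param_layers:
        raise ValueError(f"n_unfrozen={spec.n_unfrozen} exceeds the base's "
                         f"{n_param_layers} parameter-bearing layers")
    if spec.mode == "feature_extraction":
        n_unfrozen = 0
    else:
        n_unfrozen = spec.n_unfrozen
    frozen_body: list[LayerSpec] = []
    remaining = n_unfrozen
    for layer in reversed(body):
        if layer.n_params > 0 and remaining > 0:
            frozen_body.append(replace(layer, trainable=True))
            remaining -= 1
        else:
            frozen_body.append(replace(layer, trainable=False))
    frozen_body.reverse()

    feat = {"vgg16": 512, "xception": 2048, "densenet121": 1024}[spec.base]
    if spec.head:
        head = list(spec.head)
    else:
        head_units = 1 if n_classes == 2 else n_classes
        head = [
            LayerSpec("gap", name="head_pool"),
            LayerSpec("dense", name="head_fc", kernel=(1, 1, feat), units=64,
                      activation="relu"),
            LayerSpec("dropout", name="head_dropout", rate=0.5),
            LayerSpec("output", name="head_out", kernel=(1, 1, 64), units=head_units,
                      activation="sigmoid" if n_classes == 2 else "softmax"),
        ]
    layers = tuple(frozen_body + head)
    return CnnSpec(input_size=full.input_size, layers=layers, n_classes=n_classes,
                   shapes=(None,) * len(layers), name=f"{spec.base}_{spec.mode}")
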