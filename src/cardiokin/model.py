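"""The 3D convolutional cardiac-kinematics classifier.

Architecture
------------
Five same-padded 3D convolutions (kernel 3x3x3, batch-normalized, ReLU)
progressively collapse a (12, 128, 128, C) kinematic stack along time and
space, followed by two 1024-unit dense layers (dropout 0.4 before each)
and a softmax classification head:

    ========  ===================  ==========
    layer     output shape         parameters
    ========  ===================  ==========
    conv3d    (12, 128, 128, 64)   27*C*64+64
    conv3d_1  (6, 64, 64, 128)     221,312
    conv3d_2  (3, 32, 32, 256)     884,992
    conv3d_3  (2, 16, 16, 256)     1,769,728
    conv3d_4  (1, 4, 4, 256)       1,769,728
    dense     1024
    dense_1   1024                 1,049,600
    dense_2   n_classes
    ========  ===================  ==========

Downsampling is realized by strided convolutions with ceil-mode output
sizing (stride schedule 1, 2, 2, 2, (2, 4, 4)).  Training follows the
reference recipe: Adam at learning rate 0.001, batch size 1, 20 epochs,
cross-entropy, dropout 0.4, batch normalization.  The 1024-dimensional
activation of ``dense_1`` (the last hidden dense layer) serves as the
learned cardiac embedding descriptor.

Width/size overrides (``filters``, ``dense_units``, ``input_shape``)
exist so the same code runs desk-scale experiments on small phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import KinematicStack
from .nn import (Adam, BatchNorm, Conv3D, Dense, Dropout, Flatten, Network,
                 ReLU, conv_output_size, softmax, softmax_cross_entropy)

__all__ = ["LayerSpec", "ModelSpec", "TrainConfig", "TrainedModel",
           "EmbeddingVector", "build_architecture", "count_parameters",
           "total_parameters", "build_network", "train_binary", "predict",
           "extract_embedding"]

_STRIDES = ((1, 1, 1), (2, 2, 2), (2, 2, 2), (2, 2, 2), (2, 4, 4))


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one layer."""

    kind: str                      # conv3d | flatten | dense
    name: str
    units: int = 0                 # conv filters or dense units
    kernel: tuple[int, int, int] = (3, 3, 3)
    stride: tuple[int, int, int] = (1, 1, 1)
    batch_norm: bool = False
    dropout_rate: float = 0.0      # applied before the layer
    activation: str = "relu"       # relu | softmax | none


@dataclass(frozen=True)
class ModelSpec:
    """Full declarative architecture plus input geometry."""

    layers: tuple[LayerSpec, ...]
    in_channels: int
    n_classes: int
    input_shape: tuple[int, int, int] = (12, 128, 128)

    def layer(self, name: str) -> LayerSpec:
        for spec in self.layers:
            if spec.name == name:
                return spec
        raise KeyError(f"no layer named {name!r}")

    def output_shapes(self) -> dict[str, tuple]:
        """Per-layer output shapes for the configured input geometry."""
        t, h, w = self.input_shape
        c = self.in_channels
        shapes: dict[str, tuple] = {}
        flat = None
        for spec in self.layers:
            if spec.kind == "conv3d":
                t = conv_output_size(t, spec.stride[0])
                h = conv_output_size(h, spec.stride[1])
                w = conv_output_size(w, spec.stride[2])
                c = spec.units
                shapes[spec.name] = (t, h, w, c)
            elif spec.kind == "flatten":
                flat = t * h * w * c
                shapes[spec.name] = (flat,)
            elif spec.kind == "dense":
                shapes[spec.name] = (spec.units,)
        return shapes

    def layer_in_features(self, name: str) -> int:
        """Input channel/feature count seen by the named layer."""
        t, h, w = self.input_shape
        c = self.in_channels
        flat = None
        for spec in self.layers:
            if spec.kind == "conv3d":
                if spec.name == name:
                    return c
                t = conv_output_size(t, spec.stride[0])
                h = conv_output_size(h, spec.stride[1])
                w = conv_output_size(w, spec.stride[2])
                c = spec.units
            elif spec.kind == "flatten":
                flat = t * h * w * c
                if spec.name == name:
                    return flat
            elif spec.kind == "dense":
                if spec.name == name:
                    return flat if flat is not None else c
                flat = spec.units
        raise KeyError(f"no layer named {name!r}")


def build_architecture(in_channels: int, n_classes: int = 2,
                       input_shape: tuple[int, int, int] = (12, 128, 128),
                       filters: tuple[int, ...] = (64, 128, 256, 256, 256),
                       dense_units: int = 1024,
                       dropout: float = 0.4) -> ModelSpec:
    """Declarative layer stack of the cardiac 3D convolutional network.

    Defaults reproduce the reference geometry for a (12, 128, 128, C)
    input; ``filters`` / ``dense_units`` / ``input_shape`` scale the same
    architecture down for small phantom experiments.
    """
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if len(filters) != len(_STRIDES):
        raise ValueError(f"expected {len(_STRIDES)} filter counts")
    names = ["conv3d", "conv3d_1", "conv3d_2", "conv3d_3", "conv3d_4"]
    layers = [
        LayerSpec(kind="conv3d", name=n, units=f, stride=s, batch_norm=True)
        for n, f, s in zip(names, filters, _STRIDES)
    ]
    layers.append(LayerSpec(kind="flatten", name="flatten", activation="none"))
    layers.append(LayerSpec(kind="dense", name="dense", units=dense_units,
                            dropout_rate=dropout))
    layers.append(LayerSpec(kind="dense", name="dense_1", units=dense_units,
                            dropout_rate=dropout))
    layers.append(LayerSpec(kind="dense", name="dense_2", units=n_classes,
                            activation="softmax"))
    return ModelSpec(layers=tuple(layers), in_channels=in_channels,
                     n_classes=n_classes, input_shape=input_shape)


def count_parameters(spec: ModelSpec, layer_name: str) -> int:
    """Trainable parameters of one layer (weights + bias; batch-norm
    scale/shift counted separately from the convolution)."""
    layer = spec.layer(layer_name)
    fan_in = spec.layer_in_features(layer_name)
    if layer.kind == "conv3d":
        kt, kh, kw = layer.kernel
        return kt * kh * kw * fan_in * layer.units + layer.units
    if layer.kind == "dense":
        return fan_in * layer.units + layer.units
    return 0


def total_parameters(spec: ModelSpec) -> int:
    return sum(count_parameters(spec, l.name) for l in spec.layers)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (reference recipe by default)."""

    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 1            # the recipe trains sample-by-sample
    shuffle: bool = True


@dataclass
class TrainedModel:
    spec: ModelSpec
    network: Network
    classes: tuple[str, ...]
    train_config: TrainConfig
    seed: int
    loss_history: list[float] = field(default_factory=list)
    kinematic_channels: tuple[str, ...] = ()


@dataclass
class EmbeddingVector:
    """Penultimate dense-layer activation used as a learned descriptor."""

    values: np.ndarray
    source_layer: str
    kinematic_channels: tuple[str, ...]
    patient_id: str
    slice_index: int
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite values")


def build_network(spec: ModelSpec, seed: int = 0) -> Network:
    """Instantiate layers (He init) from a spec with a single seeded RNG."""
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, object]] = []
    c = spec.in_channels
    for lspec in spec.layers:
        if lspec.kind == "conv3d":
            layers.append((lspec.name, Conv3D(c, lspec.units, lspec.kernel,
                                              lspec.stride, rng=rng)))
            if lspec.batch_norm:
                layers.append((lspec.name + "_bn", BatchNorm(lspec.units)))
            layers.append((lspec.name + "_relu", ReLU()))
            c = lspec.units
        elif lspec.kind == "flatten":
            layers.append((lspec.name, Flatten()))
        elif lspec.kind == "dense":
            if lspec.dropout_rate > 0:
                layers.append((lspec.name + "_dropout",
                               Dropout(lspec.dropout_rate, rng)))
            fan_in = spec.layer_in_features(lspec.name)
            layers.append((lspec.name, Dense(fan_in, lspec.units, rng=rng)))
            if lspec.activation == "relu":
                layers.append((lspec.name + "_relu", ReLU()))
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {lspec.kind!r}")
    return Network(layers)  # final layer emits logits; softmax applied in predict


def _stack_array(stack: KinematicStack | np.ndarray) -> np.ndarray:
    return stack.data if isinstance(stack, KinematicStack) else np.asarray(stack)


def train_binary(stacks: list[KinematicStack], labels: list[str] | None = None,
                 config: TrainConfig | None = None, seed: int = 0,
                 spec: ModelSpec | None = None) -> TrainedModel:
    """Train the classifier on kinematic stacks (binary or multi-class).

    Classes are the sorted distinct labels; at least two must be present.
    Deterministic given ``seed`` (weight init, shuffling, and dropout all
    draw from one seeded stream).  When ``spec`` is omitted the reference
    architecture is built for the stacks' geometry.
    """
    config = config or TrainConfig()
    if labels is None:
        labels = [s.label for s in stacks]
    if len(labels) != len(stacks):
        raise ValueError("labels and stacks must align")
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError(
            f"need at least 2 classes to train, got {classes}"
        )
    arrays = [_stack_array(s) for s in stacks]
    shape0 = arrays[0].shape
    if any(a.shape != shape0 for a in arrays):
        raise ValueError("all stacks must share one shape")
    if spec is None:
        spec = build_architecture(in_channels=shape0[-1],
                                  n_classes=len(classes),
                                  input_shape=shape0[:3])
    net = build_network(spec, seed=seed)
    shuffler = np.random.default_rng(seed + 1)
    opt = Adam(net.parameters, lr=config.lr)
    targets = np.array([classes.index(l) for l in labels])
    history: list[float] = []
    order = np.arange(len(arrays))
    for _ in range(config.epochs):
        if config.shuffle:
            shuffler.shuffle(order)
        epoch_loss = 0.0
        for i in order:
            logits = net.forward(arrays[i], train=True)
            loss, dlogits = softmax_cross_entropy(logits, targets[i])
            net.backward(dlogits)
            opt.step(net.gradients)
            epoch_loss += loss
        history.append(epoch_loss / len(arrays))
    channels = tuple(stacks[0].channel_names) \
        if isinstance(stacks[0], KinematicStack) else ()
    return TrainedModel(spec=spec, network=net, classes=classes,
                        train_config=config, seed=seed, loss_history=history,
                        kinematic_channels=channels)


def predict(model: TrainedModel, stack: KinematicStack | np.ndarray) -> np.ndarray:
    """Class-probability vector (ordered like ``model.classes``)."""
    x = _stack_array(stack)
    t, h, w = model.spec.input_shape
    if x.shape != (t, h, w, model.spec.in_channels):
        raise ValueError(
            f"stack shape {x.shape} does not match model input "
            f"{(t, h, w, model.spec.in_channels)}"
        )
    return softmax(model.network.forward(x, train=False))


def extract_embedding(model: TrainedModel, stack: KinematicStack,
                      layer: str = "dense_1") -> EmbeddingVector:
    """Post-ReLU activation of a hidden dense layer, inference mode.

    ``layer`` must be ``"dense"`` or ``"dense_1"`` (default: the last
    hidden dense layer).
    """
    if layer not in ("dense", "dense_1"):
        raise ValueError(f"embedding layer must be 'dense' or 'dense_1', "
                         f"got {layer!r}")
    x = _stack_array(stack)
    values = model.network.forward(x, train=False, upto=layer + "_relu")
    return EmbeddingVector(values=values, source_layer=layer,
                           kinematic_channels=model.kinematic_channels,
                           patient_id=getattr(stack, "patient_id", "unknown"),
                           slice_index=getattr(stack, "slice_index", 0),
                           label=getattr(stack, "label", "unknown"))
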