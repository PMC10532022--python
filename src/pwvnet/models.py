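"""The two classifier architectures and their parameter accounting.

CNN1 is a pure fully connected head on the flattened 180x180 image
(FC 512 -> FC 256 -> softmax 4); CNN2 prepends two 3x3 'same' convolution +
4x4/stride-4 max-pooling blocks (32 then 64 filters), giving the feature-map
trace 180x180x32 -> 45x45x32 -> 45x45x64 -> 11x11x64 before the dense head
(FC 128 -> FC 256 -> softmax 4).  ReLU follows every convolution and hidden
dense layer; there is no dropout or batch normalization.

The class order [Normal, Other, VT, VF] is fixed throughout serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _nn
from .preprocess import CLASS_ORDER, RhythmClass
from .tfr import CNN_INPUT_SIDE

N_CLASSES = 4


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor: kind in {conv, maxpool, flatten, dense, softmax}."""

    name: str
    kind: str
    units: int = 0          # filters for conv, units for dense/softmax
    kernel: int = 0         # spatial kernel / pool size
    stride: int = 1
    padding: str = "same"


@dataclass(frozen=True)
class CnnSpec:
    """Named architecture with an ordered layer list."""

    name: str
    layers: tuple[LayerSpec, ...]
    input_side: int = CNN_INPUT_SIDE
    n_classes: int = N_CLASSES


def cnn1_spec() -> CnnSpec:
    return CnnSpec("CNN1", (
        LayerSpec("Flatten", "flatten"),
        LayerSpec("FC1", "dense", units=512),
        LayerSpec("FC2", "dense", units=256),
        LayerSpec("Softmax", "softmax", units=N_CLASSES),
    ))


def cnn2_spec() -> CnnSpec:
    return CnnSpec("CNN2", (
        LayerSpec("Conv1", "conv", units=32, kernel=3),
        LayerSpec("MaxPooling1", "maxpool", kernel=4, stride=4),
        LayerSpec("Conv2", "conv", units=64, kernel=3),
        LayerSpec("MaxPooling2", "maxpool", kernel=4, stride=4),
        LayerSpec("Flatten", "flatten"),
        LayerSpec("FC1", "dense", units=128),
        LayerSpec("FC2", "dense", units=256),
        LayerSpec("Softmax", "softmax", units=N_CLASSES),
    ))


def get_spec(name: str) -> CnnSpec:
    specs = {"CNN1": cnn1_spec, "CNN2": cnn2_spec}
    if name not in specs:
        raise ValueError(f"unknown model spec {name!r}; expected one of {sorted(specs)}")
    return specs[name]()


def feature_map_trace(spec: CnnSpec) -> list[tuple[int, int, int]]:
    """(side, side, channels) after each conv/pool layer, input included."""
    side, ch = spec.input_side, 1
    trace = [(side, side, ch)]
    for layer in spec.layers:
        if layer.kind == "conv":
            ch = layer.units  # 'same' padding, stride 1 keeps the side
            trace.append((side, side, ch))
        elif layer.kind == "maxpool":
            side = side // layer.stride
            trace.append((side, side, ch))
    return trace


@dataclass
class TrainedModel:
    """A (possibly still untrained) classifier bound to its spec."""

    spec: CnnSpec
    net: _nn.Network
    class_order: tuple[RhythmClass, ...] = CLASS_ORDER

    def predict_proba(self, images: np.ndarray, batch: int = 32) -> np.ndarray:
        """Per-class probabilities, rows summing to 1.

        ``images`` is (n, side, side) or (n, side, side, 1) in [0, 1];
        evaluated in chunks to bound the activation memory.
        """
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if self.spec.layers[0].kind not in ("conv", "maxpool"):
            x = x.reshape(x.shape[0], -1)
        chunks = [self.net.predict_proba(x[i:i + batch])
                  for i in range(0, x.shape[0], batch)]
        return np.concatenate(chunks)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def save(self, path: str | Path) -> None:
        """Checkpoint weights plus an echo of the spec for reproducibility."""
        meta = {
            "spec_name": self.spec.name,
            "input_side": self.spec.input_side,
            "class_order": ",".join(c.name for c in self.class_order),
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez(path, **arrays, **{f"meta_{k}": np.array(v) for k, v in meta.items()})

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        model = build_model(get_spec(str(data["meta_spec_name"])), seed=0)
        n = len(model.net.params)
        model.net.set_weights([data[f"w{i}"] for i in range(n)])
        return model


def build_model(spec: CnnSpec, seed: int) -> TrainedModel:
    """Instantiate a network with deterministic Glorot initialization."""
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    side, ch = spec.input_side, 1
    first_conv = True
    n_in = side * side * ch
    for layer in spec.layers:
        if layer.kind == "conv":
            layers.append(_nn.Conv2D(layer.name, rng, ch, layer.units,
                                     ksize=layer.kernel, relu=True,
                                     input_grad=not first_conv))
            first_conv = False
            ch = layer.units
        elif layer.kind == "maxpool":
            layers.append(_nn.MaxPool2D(layer.name, size=layer.kernel))
            side = side // layer.stride
        elif layer.kind == "flatten":
            layers.append(_nn.Flatten(layer.name))
            n_in = side * side * ch
        elif layer.kind == "dense":
            layers.append(_nn.Dense(layer.name, rng, n_in, layer.units, relu=True))
            n_in = layer.units
        elif layer.kind == "softmax":
            layers.append(_nn.Dense(layer.name, rng, n_in, layer.units, relu=False))
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {layer.kind!r}")
    return TrainedModel(spec, _nn.Network(layers))


def layer_param_count(model: TrainedModel, layer_name: str) -> int:
    """Trainable weight + bias count of one named layer."""
    for layer in model.net.layers:
        if layer.name == layer_name:
            return layer.n_params
    known = [layer.name for layer in model.net.layers]
    raise ValueError(f"unknown layer {layer_name!r}; expected one of {known}")
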