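"""Connectogram classifiers.

Two architectures, both taking a pairs x windows connectogram:

* ``custom_cnn`` — a 2-D stack over the image with a trailing channel
  axis: three valid (unpadded) 3x3 convolutions (32/64/128 filters),
  each followed by 2x2 max pooling, then Flatten, Dense(128, ReLU) and a
  softmax output.  On a 171 x 149 input the intermediate shapes are
  (169,147,32) -> (84,73,32) -> (82,71,64) -> (41,35,64) -> (39,33,128)
  -> (19,16,128) -> 38912 -> 128 -> n_classes.

* ``shallow_resnet`` — a 1-D residual stack that treats the *pair* axis
  (length 171) as the sequence dimension and the window axis as input
  features: Conv1D(64, k3, stride 2, same padding) + BN + ReLU, MaxPool(2),
  then three basic residual blocks at 64/128/256 filters (the latter two
  downsampling by stride 2 with 1-tap projection shortcuts), global
  average pooling and a softmax output.  On a 171 x 149 input:
  (86,64) -> (43,64) -> (43,64) -> (22,128) -> (11,256) -> 256 -> n_classes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConfigurationError
from .nn import (
    BatchNorm,
    Conv1D,
    Conv2D,
    Dense,
    Flatten,
    GlobalAvgPool1D,
    MaxPool1D,
    MaxPool2D,
    ReLU,
    ResidualBlock1D,
    Sequential,
)

ARCHITECTURES = ("custom_cnn", "shallow_resnet")


@dataclasses.dataclass
class ModelSpec:
    """Which architecture to build, for which image shape and label count."""

    architecture: str = "shallow_resnet"
    input_shape: tuple[int, int] = (171, 149)
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}"
            )
        shape = tuple(int(s) for s in self.input_shape)
        if len(shape) == 3 and shape[2] == 1:
            shape = shape[:2]
        if len(shape) != 2:
            raise ConfigurationError(
                f"input_shape must be (height, width[, 1]), got {self.input_shape}"
            )
        self.input_shape = shape
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")


def build_model(spec: ModelSpec, seed: int = 0) -> Sequential:
    """Instantiate the requested architecture with seeded He-normal init."""
    rng = np.random.default_rng(seed)
    if spec.architecture == "custom_cnn":
        return _custom_cnn(spec, rng)
    return _shallow_resnet(spec, rng)


def _custom_cnn(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    h, w = spec.input_shape
    layers: list = []
    ch_in = 1
    for filters in (32, 64, 128):
        if h < 3 or w < 3:
            raise ConfigurationError(
                f"custom_cnn: input too small at Conv({filters}) "
                f"(feature map {h}x{w} < 3x3)"
            )
        layers += [Conv2D(ch_in, filters, 3, rng), ReLU(), MaxPool2D(2)]
        h, w = (h - 2) // 2, (w - 2) // 2
        if h < 1 or w < 1:
            raise ConfigurationError(
                f"custom_cnn: pooling after Conv({filters}) empties the map"
            )
        ch_in = filters
    layers += [
        Flatten(),
        Dense(h * w * 128, 128, rng),
        ReLU(),
        Dense(128, spec.n_classes, rng),
    ]
    return Sequential(layers)


def _shallow_resnet(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    length, features = spec.input_shape
    if length < 4:
        raise ConfigurationError("shallow_resnet: sequence axis too short")
    return Sequential([
        Conv1D(features, 64, 3, 2, rng),
        BatchNorm(64),
        ReLU(),
        MaxPool1D(2),
        ResidualBlock1D(64, 64, 1, rng),
        ResidualBlock1D(64, 128, 2, rng),
        ResidualBlock1D(128, 256, 2, rng),
        GlobalAvgPool1D(),
        Dense(256, spec.n_classes, rng),
    ])


def prepare_batch(images: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Shape a (N, pairs, windows) image stack for the architecture:
    trailing channel axis for the 2-D CNN, (N, pairs, windows) as
    sequence x features for the 1-D ResNet."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if spec.architecture == "custom_cnn":
        return images[..., None]
    return images
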