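"""In-memory container for layerwise feature banks.

A feature bank holds, for one model, an ordered list of layers.  Each layer
is an ``images x dimensions`` activation matrix tagged with a relative depth
in [0, 1] (0 = shallowest layer, 1 = deepest).  Multi-axis activation
tensors are flattened row-wise so that every layer represents each image as
a single feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LayerFeatures", "FeatureBank", "flatten_features"]


def flatten_features(array: np.ndarray) -> np.ndarray:
    """Flatten an ``(n, ...)`` activation tensor to an ``(n, D)`` matrix."""
    arr = np.asarray(array)
    if arr.ndim < 2:
        raise ValueError("layer array must have at least 2 axes (images x features)")
    if arr.ndim == 2:
        return arr
    return arr.reshape(arr.shape[0], -1)


@dataclass
class LayerFeatures:
    """One layer: an ``n_images x D`` matrix at a relative depth."""

    layer_id: str
    depth: float
    array: np.ndarray

    def __post_init__(self) -> None:
        self.array = flatten_features(self.array)
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError(f"layer {self.layer_id!r}: depth {self.depth} outside [0, 1]")

    @property
    def width(self) -> int:
        return self.array.shape[1]


@dataclass
class FeatureBank:
    """Ordered layerwise feature matrices for one model."""

    model_id: str
    image_ids: list[str]
    layers: list[LayerFeatures] = field(default_factory=list)
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.image_ids)
        for layer in self.layers:
            if layer.array.shape[0] != n:
                raise ValueError(
                    f"layer {layer.layer_id!r} has {layer.array.shape[0]} rows "
                    f"but the bank lists {n} images"
                )
        depths = [layer.depth for layer in self.layers]
        if any(b < a for a, b in zip(depths, depths[1:])):
            raise ValueError("layer order must match depth order (nondecreasing)")

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def depths(self) -> np.ndarray:
        return np.array([layer.depth for layer in self.layers])

    def deepest(self) -> LayerFeatures:
        if not self.layers:
            raise ValueError("empty feature bank")
        return self.layers[-1]
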