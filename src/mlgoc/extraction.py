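"""Turn a converged multi-layer field into discrete object instances."""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from skimage.measure import label, regionprops

__all__ = ["InstanceSet", "binarize_layers", "extract_objects"]


@dataclass
class InstanceSet:
    """Possibly overlapping binary object masks with layer provenance.

    Masks within one layer are pairwise disjoint (connected components
    of that layer's binary foreground); masks from different layers may
    overlap — that is how stacked nuclei are represented.
    """

    masks: list = dataclass_field(default_factory=list)  # list of (H, W) bool
    layer_of: list = dataclass_field(default_factory=list)
    grid_shape: tuple = (0, 0)

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def n_layers(self) -> int:
        return max(self.layer_of, default=-1) + 1

    def areas(self) -> np.ndarray:
        return np.array([int(m.sum()) for m in self.masks], dtype=int)


def binarize_layers(field, threshold: float = 0.0) -> np.ndarray:
    """Foreground where phi >= threshold (0 is the phase midpoint)."""
    layers = np.asarray(getattr(field, "layers", field), dtype=float)
    if layers.ndim == 2:
        layers = layers[None]
    return layers >= threshold


def extract_objects(binary_layers: np.ndarray, min_area: int = 0) -> InstanceSet:
    """Connected components (8-connectivity) per layer, area-filtered.

    8-connectivity keeps diagonally touching pixels of one nucleus
    together; components below min_area are treated as model artifacts
    and discarded.
    """
    binary_layers = np.asarray(binary_layers, dtype=bool)
    if binary_layers.ndim == 2:
        binary_layers = binary_layers[None]
    out = InstanceSet(grid_shape=binary_layers.shape[1:])
    for li, layer in enumerate(binary_layers):
        labels = label(layer, connectivity=2)
        for rp in regionprops(labels):
            if rp.area < min_area:
                continue
            out.masks.append(labels == rp.label)
            out.layer_of.append(li)
    return out
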