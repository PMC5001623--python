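"""Image, label-stack, and configuration I/O.

Conventions: coordinates are 0-based with x = column, y = row, origin at
the top-left; intensities are never rescaled on read — the intensity
model works in the image's native units.  Instance sets are stored as
multi-page 16-bit label TIFFs (one page per layer, background 0,
objects numbered from 1 within each page) so overlapping objects in
different layers survive round trips without merging.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml
from imageio.v3 import imread as _imread

from .engine import SegmentationConfig
from .extraction import InstanceSet
from .goc import GOCParams
from .intensity import ImageFormationParams

__all__ = [
    "read_image",
    "write_image",
    "write_label_stack",
    "read_label_stack",
    "read_config",
    "write_config",
    "read_seeds_csv",
    "FormatError",
]


class FormatError(ValueError):
    pass


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit single-channel TIFF or PNG as float64, unscaled."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = _imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16, np.int16, np.float32, np.float64):
        raise FormatError(f"{path}: unsupported bit depth {arr.dtype}")
    return arr.astype(float)


def write_image(path, image: np.ndarray) -> None:
    """Write a grayscale image as 16-bit TIFF (values clipped to uint16)."""
    path = Path(path)
    arr = np.clip(np.round(np.asarray(image, dtype=float)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def write_label_stack(instances: InstanceSet, path) -> None:
    """One 16-bit page per layer; objects numbered from 1 within a page."""
    n_layers = max(instances.n_layers, 1)
    h, w = instances.grid_shape if instances.masks else instances.grid_shape
    pages = np.zeros((n_layers, h, w), dtype=np.uint16)
    counters = [0] * n_layers
    for mask, layer in zip(instances.masks, instances.layer_of):
        counters[layer] += 1
        if counters[layer] > 65535:
            raise ValueError(f"more than 65535 objects in layer {layer}")
        pages[layer][mask] = counters[layer]
    tifffile.imwrite(path, pages)


def read_label_stack(path) -> InstanceSet:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    out = InstanceSet(grid_shape=pages.shape[1:])
    for li, page in enumerate(pages):
        for lab in np.unique(page):
            if lab == 0:
                continue
            out.masks.append(page == lab)
            out.layer_of.append(li)
    return out


# ---------------------------------------------------------------------------
# configuration

_SECTIONS = {
    "goc": GOCParams,
    "imaging": ImageFormationParams,
    "segmentation": SegmentationConfig,
}


def write_config(path, goc: GOCParams | None = None,
                 imaging: ImageFormationParams | None = None,
                 segmentation: SegmentationConfig | None = None) -> None:
    doc = {}
    for key, obj in (("goc", goc), ("imaging", imaging), ("segmentation", segmentation)):
        if obj is not None:
            doc[key] = asdict(obj)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> dict:
    """Read a YAML/JSON config into typed parameter objects.

    Unknown sections or fields are rejected rather than ignored.
    Returns a dict with any of the keys 'goc', 'imaging', 'segmentation'.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    unknown = set(doc) - set(_SECTIONS)
    if unknown:
        raise FormatError(f"{path}: unknown config sections {sorted(unknown)}")
    out = {}
    for key, cls in _SECTIONS.items():
        if key not in doc:
            continue
        fields = {f for f in cls.__dataclass_fields__}
        extra = set(doc[key]) - fields
        if extra:
            raise FormatError(f"{path}: unknown keys in '{key}': {sorted(extra)}")
        out[key] = cls(**doc[key])
    return out


def read_seeds_csv(path) -> list[tuple[float, float]]:
    """Seed list: CSV with header 'x,y', 0-based, x = column."""
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames[:2]] != ["x", "y"]:
            raise FormatError(f"{path}: expected header 'x,y'")
        return [(float(row["x"]), float(row["y"])) for row in reader]
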