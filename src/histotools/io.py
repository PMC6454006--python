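"""Readers and writers for tiles, labeled masks, manifests, feature tables,
checkpoints and run configuration.

Conventions: pixel grids are 0-based row-major; labeled masks are stored as
single-channel TIFF, 16-bit by default and 32-bit when ids exceed 65535 so
slide-scale reuse cannot silently overflow; patch-grid coordinates are
(row, col) of a non-overlapping tiling.  Default microns-per-pixel follows
standard scanner conventions: 0.25 at 40x and 0.5 at 20x.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "TileRecord",
    "RunConfig",
    "MPP_BY_MAGNIFICATION",
    "read_image",
    "write_image",
    "read_labeled_mask",
    "write_labeled_mask",
    "write_features_csv",
    "read_features_csv",
    "save_checkpoint",
    "load_checkpoint",
    "write_patch_manifest",
    "read_patch_manifest",
]

MPP_BY_MAGNIFICATION = {"40x": 0.25, "20x": 0.5}


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the declared format."""


@dataclass
class TileRecord:
    """An RGB tissue tile with optional instance ground truth."""

    image: np.ndarray
    mask: np.ndarray | None = None
    magnification: str = "40x"
    mpp: float | None = None
    id: str = ""

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise FormatError("tile image must be HxWx3 RGB")
        if self.mask is not None and self.mask.shape != self.image.shape[:2]:
            raise FormatError("mask dimensions must match the image")
        if self.mpp is None:
            self.mpp = MPP_BY_MAGNIFICATION.get(self.magnification)
        if self.mpp is None or self.mpp <= 0:
            raise FormatError("mpp must be positive")


@dataclass
class RunConfig:
    """All tunable parameters with their package defaults.

    Unknown keys are rejected so a typo in a config file cannot silently fall
    back to a default; the config round-trips losslessly through YAML/JSON.
    """

    seed: int = 0
    mpp_default: float = 0.25
    device: str = "cpu"
    # segmentation dataset geometry
    patch_side: int = 200
    nbl_step: int = 54
    nbl_random_crops: int = 30
    sn_center_side: int = 54
    sn_max_fraction: float = 0.5
    sn_copies: int = 3
    border_thickness: int = 2
    augment_repeats: int = 3
    # network input geometry
    seg_input_side: int = 102
    seg_output_side: int = 54
    # training
    batch_size: int = 32
    l2_factor: float = 1.0e-5
    # inference / post-processing
    blob_threshold: float = 0.5
    border_threshold: float = 0.5
    min_area_um2: float = 13.0
    # classification
    cls_patch_side: int = 256
    cls_crop_side: int = 224
    rf_threshold: float = 0.5

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data or {})

    def save(self, path):
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


# --------------------------------------------------------------------------
# images and masks

def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return img


def write_image(path, image: np.ndarray):
    iio.imwrite(path, image)


def read_labeled_mask(path) -> np.ndarray:
    """Read an instance mask; ids are preserved exactly (no relabeling)."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"labeled mask must be single-channel, got {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"labeled mask must be integer-valued, got {arr.dtype}")
    return arr.astype(np.int64)


def write_labeled_mask(path, mask: np.ndarray):
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise FormatError("labeled mask must be integer-valued")
    if mask.min() < 0:
        raise FormatError("labeled mask ids must be non-negative")
    dtype = np.uint16 if mask.max() <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(path, mask.astype(dtype))


# --------------------------------------------------------------------------
# feature tables

def write_features_csv(features: dict[str, dict[str, float]], path,
                       feature_names: list[str]):
    """Write one row per slide with a fixed, deterministic feature header.

    ``features`` maps slide id to {feature name: value}.  All rows must carry
    exactly the declared feature names and finite values.
    """
    rows = {}
    for slide, vec in features.items():
        if set(vec) != set(feature_names):
            raise FormatError(f"slide {slide!r}: feature names do not match schema")
        vals = [vec[name] for name in feature_names]
        if not np.all(np.isfinite(vals)):
            raise FormatError(f"slide {slide!r}: non-finite feature value")
        rows[slide] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=feature_names)
    df.index.name = "slide"
    df.to_csv(path, float_format="%.12g")


def read_features_csv(path):
    df = pd.read_csv(path, index_col="slide")
    return {slide: row.to_dict() for slide, row in df.iterrows()}, list(df.columns)


# --------------------------------------------------------------------------
# checkpoints and manifests

def save_checkpoint(path, state: dict[str, np.ndarray], meta: dict | None = None):
    """Weight archive: flat state dict plus an embedded JSON metadata blob."""
    payload = dict(state)
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta or {}).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path):
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode()) if "__meta__" in npz else {}
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    return state, meta


def write_patch_manifest(path, entries: list[dict]):
    """JSON manifest rows: slide id, grid row/col, patch path, label."""
    for e in entries:
        missing = {"slide", "row", "col", "path"} - set(e)
        if missing:
            raise FormatError(f"manifest entry missing keys {sorted(missing)}")
    Path(path).write_text(json.dumps(entries, indent=1))


def read_patch_manifest(path) -> list[dict]:
    return json.loads(Path(path).read_text())
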