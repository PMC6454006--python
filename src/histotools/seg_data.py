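"""Training-patch construction for the segmentation networks.

Three datasets are built from annotated 200x200 tile patches:

* **NBL** (nuclei blob): window-slide cropping with a 54 px step plus random
  crops; used to learn the blob (all-nuclear-pixels) mask.
* **NBD** (nuclei boundary): one patch per nucleus, centered on its centroid;
  nuclei whose centroid lies within 100 px of a tile edge are skipped so the
  patch fits without padding.
* **SN** (small nuclei): NBL patches whose centered 54x54 window holds at
  most 50% nuclear pixels, duplicated 3 times; used to counter the bias
  against sparse patches when refining blob detection.

Patches are 200x200 so that augmentation can sample outside the network's
eventual 102x102 input without zero padding; the 102 center crop feeds the
network and the aligned 54 center crop is the training target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, warp

from .io import TileRecord

__all__ = [
    "SegPatch",
    "AugmentParams",
    "extract_nbl",
    "extract_nbd",
    "extract_sn",
    "make_border_target",
    "augment",
    "center_crop",
    "target_crop",
    "blob_target_from_mask",
]

PATCH_SIDE = 200
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SegPatch:
    image: np.ndarray          # 200x200x3 uint8
    blob_target: np.ndarray    # 200x200 {0,1}
    border_target: np.ndarray  # 200x200 {0,1}
    tag: str                   # NBL | NBD | SN
    tile_id: str = ""
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.image.shape[:2] != (PATCH_SIDE, PATCH_SIDE):
            raise ValueError("segmentation patches are 200x200")
        if (self.blob_target.shape != self.image.shape[:2]
                or self.border_target.shape != self.image.shape[:2]):
            raise ValueError("targets must align with the image")


@dataclass(frozen=True)
class AugmentParams:
    """Geometric augmentation ranges (fractions, degrees, radians, ratio)."""

    shift_range: tuple[float, float] = (-0.05, 0.05)
    rotation_range: tuple[float, float] = (-45.0, 45.0)
    flip_probability: float = 0.5
    shear_range: tuple[float, float] = (-0.4 * np.pi, 0.4 * np.pi)
    resize_range: tuple[float, float] = (0.6, 2.0)
    repeats: int = 3


def blob_target_from_mask(mask: np.ndarray) -> np.ndarray:
    return (np.asarray(mask) > 0).astype(np.uint8)


def make_border_target(mask: np.ndarray, thickness: int = 2) -> np.ndarray:
    """Binary border ground truth from a labeled mask.

    A pixel is on the 1 px boundary when it is foreground and 8-adjacent to
    background or to a different instance id (so the interface between
    touching nuclei is boundary for both).  The boundary is then thickened
    inward to ``thickness`` px by repeated 8-connected dilation restricted to
    the foreground.
    """
    mask = np.asarray(mask)
    fg = mask > 0
    if not fg.any():
        return np.zeros(mask.shape, dtype=np.uint8)
    mx = ndi.maximum_filter(mask, footprint=_EIGHT, mode="constant", cval=0)
    mn = ndi.minimum_filter(mask, footprint=_EIGHT, mode="constant", cval=0)
    border = fg & ((mx != mask) | (mn != mask))
    for _ in range(max(0, thickness - 1)):
        border = fg & (ndi.binary_dilation(border, _EIGHT) | border)
    return border.astype(np.uint8)


def _patch_at(tile: TileRecord, r0: int, c0: int, tag: str,
              border_thickness: int) -> SegPatch:
    sl = (slice(r0, r0 + PATCH_SIDE), slice(c0, c0 + PATCH_SIDE))
    mask = tile.mask[sl] if tile.mask is not None else np.zeros(
        (PATCH_SIDE, PATCH_SIDE), dtype=np.int32)
    return SegPatch(
        image=tile.image[sl].copy(),
        blob_target=blob_target_from_mask(mask),
        border_target=make_border_target(mask, border_thickness),
        tag=tag, tile_id=tile.id, offset=(r0, c0))


def extract_nbl(tile: TileRecord, step: int = 54, n_random: int = 30,
                rng: np.random.Generator | None = None,
                border_thickness: int = 2) -> list[SegPatch]:
    """Window-slide crops at multiples of ``step`` plus uniform random crops."""
    h, w = tile.image.shape[:2]
    if h < PATCH_SIDE or w < PATCH_SIDE:
        raise ValueError(f"tile {h}x{w} smaller than {PATCH_SIDE}")
    rng = np.random.default_rng(0) if rng is None else rng
    rows = range(0, h - PATCH_SIDE + 1, step)
    cols = range(0, w - PATCH_SIDE + 1, step)
    patches = [_patch_at(tile, r, c, "NBL", border_thickness)
               for r in rows for c in cols]
    for _ in range(n_random):
        r = int(rng.integers(0, h - PATCH_SIDE + 1))
        c = int(rng.integers(0, w - PATCH_SIDE + 1))
        patches.append(_patch_at(tile, r, c, "NBL", border_thickness))
    return patches


def extract_nbd(tile: TileRecord, border_thickness: int = 2) -> list[SegPatch]:
    """One patch per nucleus, centered on its centroid.

    Nuclei whose (floored) centroid lies closer than half a patch (100 px) to
    any tile edge are ignored, so every returned patch fits without padding.
    """
    if tile.mask is None:
        raise ValueError("NBD extraction requires a labeled mask")
    h, w = tile.image.shape[:2]
    half = PATCH_SIDE // 2
    ids = np.unique(tile.mask)
    ids = ids[ids > 0]
    if ids.size == 0:
        return []
    centroids = ndi.center_of_mass(tile.mask > 0, tile.mask, ids)
    patches = []
    for (cr, cc) in centroids:
        r, c = int(np.floor(cr)), int(np.floor(cc))
        if half <= r <= h - half and half <= c <= w - half:
            patches.append(_patch_at(tile, r - half, c - half, "NBD",
                                     border_thickness))
    return patches


def extract_sn(nbl_patches: list[SegPatch], center_side: int = 54,
               max_fraction: float = 0.5, copies: int = 3) -> list[SegPatch]:
    """SN dataset: sparse NBL patches duplicated ``copies`` times.

    A patch qualifies when the fraction of nuclear pixels inside its centered
    ``center_side`` window is at most ``max_fraction`` (inclusive).
    """
    out = []
    o = (PATCH_SIDE - center_side) // 2
    for patch in nbl_patches:
        if patch.tag != "NBL":
            raise ValueError("extract_sn expects NBL-tagged patches")
        window = patch.blob_target[o:o + center_side, o:o + center_side]
        if window.mean() <= max_fraction:
            out.extend(replace(patch, tag="SN") for _ in range(copies))
    return out


def _sample_transform(params: AugmentParams, rng: np.random.Generator):
    shift = rng.uniform(*params.shift_range, size=2) * PATCH_SIDE
    angle = np.deg2rad(rng.uniform(*params.rotation_range))
    flip_v = rng.random() < params.flip_probability
    flip_h = rng.random() < params.flip_probability
    shear = rng.uniform(*params.shear_range)
    scale = rng.uniform(*params.resize_range)
    return shift, angle, flip_v, flip_h, shear, scale


def _build_affine(shift, angle, flip_v, flip_h, shear, scale):
    """Affine map about the patch center, in (x, y) convention."""
    c = (PATCH_SIDE - 1) / 2.0
    center = AffineTransform(translation=(-c, -c))
    flip = AffineTransform(scale=((-1 if flip_h else 1), (-1 if flip_v else 1)))
    core = AffineTransform(rotation=angle, shear=shear,
                           scale=(scale, scale))
    back = AffineTransform(translation=(c + shift[1], c + shift[0]))
    return center + flip + core + back


def augment(patch: SegPatch, params: AugmentParams,
            rng: np.random.Generator) -> SegPatch:
    """Random shift/rotation/flip/shear/resize applied jointly to image and
    targets (nearest-neighbor for targets, reflection fill outside)."""
    shift, angle, flip_v, flip_h, shear, scale = _sample_transform(params, rng)
    tform = _build_affine(shift, angle, flip_v, flip_h, shear, scale)
    inv = tform.inverse

    def warp_img(arr, order):
        out = warp(arr.astype(np.float64), inv, order=order, mode="reflect",
                   output_shape=arr.shape, preserve_range=True)
        return out

    image = np.clip(np.rint(warp_img(patch.image, 1)), 0, 255).astype(np.uint8)
    blob = warp_img(patch.blob_target, 0).astype(np.uint8)
    border = warp_img(patch.border_target, 0).astype(np.uint8)
    return replace(patch, image=image, blob_target=blob, border_target=border)


def center_crop(arr: np.ndarray, side: int = 102) -> np.ndarray:
    """Centered window at offset floor((size - side) / 2)."""
    h, w = arr.shape[:2]
    if h < side or w < side:
        raise ValueError(f"cannot crop {side} from {h}x{w}")
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return arr[r0:r0 + side, c0:c0 + side].copy()


def target_crop(arr: np.ndarray, side: int = 54) -> np.ndarray:
    """Centered target window aligned with the center of the network input."""
    return center_crop(arr, side)
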