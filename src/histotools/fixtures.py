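"""Synthetic H&E-like test data with exact ground truth.

Real benchmark data (TCGA-derived tiles with hand-segmented nuclei, lung WSIs)
cannot be redistributed, so every other module in this package is exercised
against synthetic material generated here: tissue tiles containing elliptical
hematoxylin-dark nuclei on an eosin-pink background with exact labeled
instance masks, canonical split/merge mask pairs for metric tests, per-slide
class probability maps, and class-conditional 256x256 patch sets.

All generators are pure functions of their specification and seed; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SyntheticTileSpec",
    "PlacementError",
    "generate_nuclei_tile",
    "generate_split_merge_case",
    "generate_probability_maps",
    "generate_classification_patches",
    "CLASS_NAMES",
]

#: Class order used throughout the classification half of the package.
CLASS_NAMES = ("ND", "LUAD", "LUSC")

_EIGHT = np.ones((3, 3), dtype=bool)


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be packed into the tile."""


@dataclass(frozen=True)
class SyntheticTileSpec:
    """Parameters of one synthetic tissue tile.

    Nuclei are filled ellipses of random orientation and eccentricity.
    ``touching_fraction`` of the nuclei are placed as touching pairs whose
    outlines overlap by ``overlap_px`` pixels along the line joining their
    centers; contested pixels belong to the later-placed nucleus, so the
    labeled mask is always a partition.
    """

    width: int = 256
    height: int = 256
    n_nuclei: int = 30
    radius_range: tuple[int, int] = (5, 12)
    touching_fraction: float = 0.0
    overlap_px: int = 0
    nucleus_rgb: tuple[float, float, float] = (96.0, 60.0, 150.0)
    nucleus_sd: float = 14.0
    background_rgb: tuple[float, float, float] = (235.0, 200.0, 220.0)
    noise_sd: float = 6.0
    seed: int = 0

    def validate(self):
        if self.width < 200 or self.height < 200:
            raise ValueError("tile must be at least 200x200")
        if self.radius_range[0] < 3:
            raise ValueError("minimum nucleus radius is 3 px")
        if not 0.0 <= self.touching_fraction <= 1.0:
            raise ValueError("touching_fraction must be in [0, 1]")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")


def _ellipse_mask(shape, center, radii, angle):
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _draw_ellipse_params(rng, spec):
    r = rng.uniform(spec.radius_range[0], spec.radius_range[1])
    ecc = rng.uniform(0.6, 1.0)
    angle = rng.uniform(0.0, np.pi)
    return (r, max(spec.radius_range[0] * 0.9, r * ecc)), angle


def generate_nuclei_tile(spec: SyntheticTileSpec):
    """Render one synthetic tile.

    Returns ``(image, mask)`` where ``image`` is uint8 RGB of shape
    (height, width, 3) and ``mask`` is an int32 labeled mask with contiguous
    ids ``1..n``.  Singly placed nuclei are pairwise non-adjacent
    (8-connectivity); each touching pair shares an 8-connected interface while
    keeping interior pixels at least 2 px away from its partner.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=np.int32)
    n = spec.n_nuclei
    n_pairs = int(np.ceil(spec.touching_fraction * n / 2.0)) if n else 0
    n_singles = n - 2 * n_pairs
    if n_singles < 0:
        n_pairs = n // 2
        n_singles = n - 2 * n_pairs

    occupied = np.zeros((h, w), dtype=bool)  # dilated footprint of placed nuclei
    next_id = 1
    margin = spec.radius_range[1] + 2

    def place_single(extra_clearance=2):
        nonlocal next_id
        for _ in range(400):
            radii, angle = _draw_ellipse_params(rng, spec)
            cr = rng.uniform(margin, h - margin)
            cc = rng.uniform(margin, w - margin)
            ell = _ellipse_mask((h, w), (cr, cc), radii, angle)
            if not ell.any():
                continue
            grown = ndi.binary_dilation(ell, _EIGHT, iterations=extra_clearance)
            if (grown & occupied).any():
                continue
            mask[ell] = next_id
            next_id += 1
            occupied[grown] = True
            return (cr, cc), radii, angle
        raise PlacementError(
            f"could not place nucleus {next_id} after bounded retries")

    def place_pair():
        nonlocal next_id
        for _ in range(400):
            radii1, angle1 = _draw_ellipse_params(rng, spec)
            radii2, angle2 = _draw_ellipse_params(rng, spec)
            cr = rng.uniform(margin * 2, h - margin * 2)
            cc = rng.uniform(margin * 2, w - margin * 2)
            theta = rng.uniform(0.0, 2 * np.pi)
            # distance between centers: just touching minus requested overlap
            d = radii1[0] + radii2[0] - spec.overlap_px
            cr2 = cr + d * np.cos(theta)
            cc2 = cc + d * np.sin(theta)
            if not (margin <= cr2 < h - margin and margin <= cc2 < w - margin):
                continue
            e1 = _ellipse_mask((h, w), (cr, cc), radii1, angle1)
            e2 = _ellipse_mask((h, w), (cr2, cc2), radii2, angle2)
            if not e1.any() or not e2.any():
                continue
            union = e1 | e2
            grown = ndi.binary_dilation(union, _EIGHT, iterations=2)
            if (grown & occupied).any():
                continue
            # the pair must touch (8-adjacent) but each keep a 2 px interior
            touching = (ndi.binary_dilation(e1, _EIGHT) & e2).any()
            core1 = ndi.binary_erosion(e1 & ~e2, _EIGHT, iterations=2)
            core2 = ndi.binary_erosion(e2, _EIGHT, iterations=2)
            if not touching or not core1.any() or not core2.any():
                continue
            id1, id2 = next_id, next_id + 1
            mask[e1] = id1
            mask[e2] = id2  # contested pixels go to the later id
            if not (mask == id1).any():
                mask[e1] = 0
                mask[e2] = 0
                continue
            next_id += 2
            occupied[grown] = True
            return True
        raise PlacementError(
            f"could not place touching pair {next_id} after bounded retries")

    for _ in range(n_pairs):
        place_pair()
    for _ in range(n_singles):
        place_single()

    image = _render(rng, spec, mask)
    return image, mask


def _render(rng, spec, mask):
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = np.asarray(spec.background_rgb)
    fg = mask > 0
    if fg.any():
        base = np.asarray(spec.nucleus_rgb)
        n = int(mask.max())
        # per-nucleus stain jitter so instances are visually distinct
        jitter = rng.normal(0.0, spec.nucleus_sd, size=(n + 1, 3))
        img[fg] = base + jitter[mask[fg]]
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_split_merge_case(mode: str, object_px: int):
    """Canonical reference/prediction mask pair for the Ensemble Dice metric.

    ``identical``: the same single-object mask twice.  ``split``: the
    reference holds one rectangular object of ``object_px`` pixels while the
    prediction covers the same support with two equal halves.  ``merge`` is
    the transpose of ``split``.
    """
    if mode not in ("identical", "split", "merge"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "identical" and object_px % 2:
        raise ValueError("object_px must be even for split/merge")
    height = 8
    if object_px % height:
        height = 2
    width = object_px // height
    if mode != "identical" and width % 2:
        height *= 2
        width = object_px // height
    if height * width != object_px or (mode != "identical" and width % 2):
        raise ValueError(f"cannot shape {object_px} px into a splittable rectangle")
    shape = (height + 4, width + 4)
    whole = np.zeros(shape, dtype=np.int32)
    whole[2:2 + height, 2:2 + width] = 1
    if mode == "identical":
        return whole, whole.copy()
    halves = np.zeros(shape, dtype=np.int32)
    halves[2:2 + height, 2:2 + width // 2] = 1
    halves[2:2 + height, 2 + width // 2:2 + width] = 2
    if mode == "split":
        return whole, halves
    return halves, whole


def generate_probability_maps(grid_h: int, grid_w: int, dominant_class: str,
                              effect: float, seed: int):
    """Random per-cell class-probability grids over a slide's patch grid.

    Cells are Dirichlet(1, 1, 1) mixed with the one-hot vector of
    ``dominant_class`` by weight ``effect``; every cell sums to one and the
    expected fraction of cells whose argmax is the dominant class increases
    monotonically with ``effect`` (uniform at 0, all cells at 1).

    Returns a dict mapping class name to a float64 (grid_h, grid_w) array.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must be in [0, 1]")
    if dominant_class not in CLASS_NAMES:
        raise ValueError(f"unknown class {dominant_class!r}")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(3), size=(grid_h, grid_w))
    onehot = np.zeros(3)
    onehot[CLASS_NAMES.index(dominant_class)] = 1.0
    probs = (1.0 - effect) * probs + effect * onehot
    return {name: probs[:, :, k].copy() for k, name in enumerate(CLASS_NAMES)}


@dataclass(frozen=True)
class PatchRecord:
    """One classification patch with its provenance."""

    image: np.ndarray
    label: str
    slide_id: str
    row: int
    col: int

    def __post_init__(self):
        if self.image.shape != (256, 256, 3):
            raise ValueError("classification patches are 256x256 RGB")


_CLASS_RGB = {
    "LUAD": np.array([120.0, 90.0, 170.0]),   # blue/purple-leaning
    "LUSC": np.array([110.0, 175.0, 110.0]),  # green-leaning
    "ND": np.array([235.0, 205.0, 150.0]),    # yellow/orange-leaning
}


def _textured_patch(rng, mean_rgb, margin, noise_sd=18.0):
    """256x256 patch: class-shifted mean color + smooth blob texture."""
    low = rng.normal(0.0, 1.0, size=(32, 32, 3))
    low = ndi.gaussian_filter(low, sigma=(4, 4, 0))
    low = np.kron(low, np.ones((8, 8, 1)))
    img = mean_rgb * (margin) + 190.0 * (1 - margin)
    img = img + 160.0 * margin * low + rng.normal(0.0, noise_sd, size=(256, 256, 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_classification_patches(n_slides: int, patches_per_slide: int,
                                    seed: int, class_margin: float = 1.0,
                                    nd_fraction: float = 0.0):
    """Synthetic per-slide patch grids with class-conditional texture.

    Slide labels alternate LUAD/LUSC (balanced; LUAD gets the extra slide if
    ``n_slides`` is odd).  Patches are laid out row-major on a near-square
    grid.  ``class_margin`` in [0, 1] scales how far the two classes' color
    and texture statistics are separated; ``nd_fraction`` of each slide's
    patches are rendered as non-diagnostic tissue instead of the slide class.

    Returns ``(records, slide_labels)`` where ``records`` is a list of
    :class:`PatchRecord` and ``slide_labels`` maps slide id to label.
    """
    if n_slides < 1 or patches_per_slide < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    grid_w = int(np.ceil(np.sqrt(patches_per_slide)))
    records: list[PatchRecord] = []
    slide_labels: dict[str, str] = {}
    for s in range(n_slides):
        label = "LUAD" if s % 2 == 0 else "LUSC"
        slide_id = f"slide{s:03d}"
        slide_labels[slide_id] = label
        for p in range(patches_per_slide):
            if rng.random() < nd_fraction:
                patch_class = "ND"
            else:
                patch_class = label
            img = _textured_patch(rng, _CLASS_RGB[patch_class], class_margin)
            records.append(PatchRecord(img, patch_class, slide_id,
                                       p // grid_w, p % grid_w))
    return records, slide_labels
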