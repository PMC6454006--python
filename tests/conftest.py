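import numpy as np
import pytest

from histotools import fixtures
from histotools.io import TileRecord


def flood_fill_components(binary: np.ndarray) -> int:
    """Independent 8-connected component counter (BFS flood fill)."""
    binary = np.asarray(binary) > 0
    seen = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w
                                    and binary[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


def dice2_bruteforce(reference: np.ndarray, prediction: np.ndarray) -> float:
    """Set-based re-implementation of the Ensemble Dice matching rule."""
    def objects(mask):
        return {int(i): set(zip(*np.where(mask == i)))
                for i in np.unique(mask) if i > 0}

    q, p = objects(reference), objects(prediction)
    if not q and not p:
        return 1.0
    if not q or not p:
        return 0.0

    def directed(a_objs, b_objs):
        num = den = 0.0
        for _, a in sorted(a_objs.items()):
            overlaps = {bid: len(a & b) for bid, b in b_objs.items() if a & b}
            if overlaps:
                bid, inter = min(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))
                num += 2.0 * inter
                den += len(a) + len(b_objs[bid])
            else:
                den += len(a)
        return num / den

    return 0.5 * (directed(q, p) + directed(p, q))


@pytest.fixture(scope="session")
def small_tile():
    """256x256 tile, 12 nuclei, no touching pairs."""
    spec = fixtures.SyntheticTileSpec(n_nuclei=12, touching_fraction=0.0,
                                      seed=11)
    image, mask = fixtures.generate_nuclei_tile(spec)
    return TileRecord(image, mask, magnification="40x", id="small")


@pytest.fixture(scope="session")
def touching_tile():
    """256x256 tile with touching pairs (zero overlap, separable)."""
    spec = fixtures.SyntheticTileSpec(n_nuclei=10, touching_fraction=0.4,
                                      overlap_px=0, radius_range=(6, 12),
                                      seed=3)
    image, mask = fixtures.generate_nuclei_tile(spec)
    return TileRecord(image, mask, magnification="20x", id="touching")
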