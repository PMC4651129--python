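"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid scipy/skimage morphology and the package's own
code paths: opening is implemented from its set-theoretic definition via
explicit shifts, connected components via breadth-first search, and the
weighted-kappa statistic as a literal double sum.
"""

from collections import deque

import numpy as np

from tmascore._util import disc_footprint
from tmascore.types import N, OUTSIDE, T, TYPE1, TYPE2, TYPE3


def _shift(mask: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Shift a boolean raster, padding with False."""
    out = np.zeros_like(mask)
    H, W = mask.shape
    src_i = slice(max(0, -di), min(H, H - di))
    src_j = slice(max(0, -dj), min(W, W - dj))
    dst_i = slice(max(0, di), min(H, H + di))
    dst_j = slice(max(0, dj), min(W, W + dj))
    out[dst_i, dst_j] = mask[src_i, src_j]
    return out


def brute_opening(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Opening from first principles: erosion (AND of shifts), then dilation
    (OR of shifts) with the reflected footprint."""
    r = footprint.shape[0] // 2
    offsets = [(int(i) - r, int(j) - r) for i, j in np.argwhere(footprint)]
    eroded = np.ones_like(mask)
    for di, dj in offsets:
        eroded &= _shift(mask, -di, -dj)
    opened = np.zeros_like(mask)
    for di, dj in offsets:
        opened |= _shift(eroded, di, dj)
    return opened


def _bfs_component(t_raster: np.ndarray, start: tuple[int, int]) -> set:
    """8-connected component of True pixels containing ``start``."""
    H, W = t_raster.shape
    seen = {start}
    queue = deque([start])
    while queue:
        i, j = queue.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                x, y = i + di, j + dj
                if 0 <= x < H and 0 <= y < W and t_raster[x, y] and (x, y) not in seen:
                    seen.add((x, y))
                    queue.append((x, y))
    return seen


def brute_classify(labels_a: np.ndarray, labels_b: np.ndarray, cell_diameter_px: int) -> np.ndarray:
    """Literal pixel-by-pixel application of the three disagreement rules.

    Returns a raster with values in {0, TYPE1, TYPE2, TYPE3} (0 where there
    is no disagreement).
    """
    inside = labels_a != OUTSIDE
    disagree = (labels_a != labels_b) & inside
    foot = disc_footprint(cell_diameter_px)
    opened = brute_opening(disagree, foot)

    out = np.zeros(labels_a.shape, np.uint8)
    out[disagree & ~opened] = TYPE1

    comp_cache: dict[tuple[int, int, int], bool] = {}
    for i, j in np.argwhere(disagree & opened):
        own, other = (labels_a, labels_b) if labels_a[i, j] == T else (labels_b, labels_a)
        own_id = 0 if own is labels_a else 1
        key = None
        t_raster = own == T
        comp = _bfs_component(t_raster, (int(i), int(j)))
        anchor = min(comp)
        key = (own_id, *anchor)
        if key not in comp_cache:
            comp_cache[key] = any(other[x, y] == T for x, y in comp)
        out[i, j] = TYPE2 if comp_cache[key] else TYPE3
    return out


def brute_weighted_kappa(counts: np.ndarray, power: int = 2) -> float:
    """Weighted kappa as an explicit double sum over category pairs."""
    counts = np.asarray(counts, float)
    k = counts.shape[0]
    total = counts.sum()
    row = counts.sum(axis=1) / total
    col = counts.sum(axis=0) / total
    num = 0.0
    den = 0.0
    for i in range(k):
        for j in range(k):
            w = (abs(i - j) / (k - 1)) ** power
            num += w * counts[i, j] / total
            den += w * row[i] * col[j]
    return 1.0 - num / den


def random_mask_pair(rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random T/N mask pairs covering all disagreement flavours.

    Mask A is a thresholded smooth random field; mask B is one of: an
    independent field, a morphological variant of A (shift/grow), or A with
    an extra/removed blob — so thin offsets, extent changes and whole-region
    flips all occur.
    """
    from scipy import ndimage

    def blob_mask(seed_field: np.ndarray, frac: float) -> np.ndarray:
        smooth = ndimage.gaussian_filter(seed_field, sigma=size / 10)
        thr = np.quantile(smooth, 1 - frac)
        return smooth >= thr

    frac = rng.uniform(0.15, 0.45)
    a_t = blob_mask(rng.standard_normal((size, size)), frac)
    flavour = rng.integers(0, 4)
    if flavour == 0:  # independent
        b_t = blob_mask(rng.standard_normal((size, size)), rng.uniform(0.15, 0.45))
    elif flavour == 1:  # small shift -> thin boundary offsets
        sh = int(rng.integers(1, 4))
        b_t = _shift(a_t, sh, -sh)
    elif flavour == 2:  # grow -> extent disagreement
        b_t = ndimage.binary_dilation(a_t, iterations=int(rng.integers(1, 5)))
    else:  # extra blob -> presence/absence
        b_t = a_t.copy()
        r, c = rng.integers(5, size - 5, 2)
        rad = int(rng.integers(3, 9))
        ii, jj = np.mgrid[0:size, 0:size]
        b_t |= (ii - r) ** 2 + (jj - c) ** 2 <= rad**2

    # optionally restrict to a circular spot with a shared OUTSIDE set
    if rng.random() < 0.5:
        c0 = (size - 1) / 2
        ii, jj = np.mgrid[0:size, 0:size]
        inside = (ii - c0) ** 2 + (jj - c0) ** 2 <= c0**2
    else:
        inside = np.ones((size, size), bool)

    def to_labels(t):
        out = np.full((size, size), OUTSIDE, np.uint8)
        out[inside] = N
        out[t & inside] = T
        return out

    return to_labels(a_t), to_labels(b_t)
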