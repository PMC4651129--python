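"""Pixel-level comparison of two tumour segmentation masks.

Two masks of the same spot are compared label-by-label over in-spot pixels,
giving a 2x2 contingency table over {(T,T), (T,N), (N,T), (N,N)}.  Because
raw pixel counts hide qualitative differences between segmentations, every
disagreement pixel is additionally classified into one of three types:

* **Type 1** — thin boundary offsets, too narrow to contain an epithelial
  cell, hence inconsequential for downstream IHC scoring.  Operationalised
  as the disagreement pixels *removed* by morphological opening of the
  disagreement raster with a disc of one minimum cell diameter.
* **Type 2** — extent disagreements: the pixel's own-mask tumour component
  overlaps tumour in the other mask, so the two masks agree a tumour is
  present but disagree about its spatial extent.
* **Type 3** — everything else: presence/absence disagreements about whole
  regions, i.e. differences of opinion about whether a group of cells is
  malignant.

The rules are applied in the fixed order Type 1 -> Type 2 -> Type 3 and are
symmetric in the two masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._util import disc_footprint
from .types import (
    AGREE_N,
    AGREE_T,
    LabelMask,
    N,
    OUTSIDE,
    T,
    TYPE1,
    TYPE2,
    TYPE3,
    SpotImage,
    check_comparable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "DisagreementMap",
    "DisagreementSummary",
    "pixel_contingency",
    "classify_disagreements",
    "summarise_disagreements",
    "render_difference_image",
    "DEFAULT_CELL_DIAMETER_UM",
]

#: minimum epithelial cell diameter used to define Type 1 disagreements
DEFAULT_CELL_DIAMETER_UM = 8.0

_EIGHT = np.ones((3, 3), int)


@dataclass
class ContingencyTable2x2:
    """In-spot pixel counts for label pairs (A-label, B-label).

    ``counts[i, j]`` holds the number of in-spot pixels labelled ``i`` in
    mask A and ``j`` in mask B with index order (T, N); the normalised view
    divides by the total and sums to 1.
    """

    counts: np.ndarray  # 2x2 int, index order (T, N) x (T, N)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 2x2 table")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty contingency table")
        return self.counts / self.total

    @property
    def n_disagree(self) -> int:
        return int(self.counts[0, 1] + self.counts[1, 0])


def pixel_contingency(mask_a: LabelMask, mask_b: LabelMask) -> ContingencyTable2x2:
    """2x2 contingency of T/N labels over in-spot pixels of two masks."""
    inside = check_comparable(mask_a, mask_b)
    a_t = mask_a.labels == T
    b_t = mask_b.labels == T
    tt = int((a_t & b_t & inside).sum())
    tn = int((a_t & ~b_t & inside).sum())
    nt = int((~a_t & b_t & inside).sum())
    nn = int((~a_t & ~b_t & inside).sum())
    return ContingencyTable2x2(np.array([[tt, tn], [nt, nn]]))


@dataclass
class DisagreementMap:
    """Per-pixel agreement/disagreement classes for one mask pair."""

    classes: np.ndarray  # values in {OUTSIDE, AGREE_N, AGREE_T, TYPE1, TYPE2, TYPE3}
    cell_diameter_px: int

    def count(self, cls: int) -> int:
        return int((self.classes == cls).sum())

    @property
    def type_counts(self) -> tuple[int, int, int]:
        return self.count(TYPE1), self.count(TYPE2), self.count(TYPE3)

    @property
    def n_disagree(self) -> int:
        return sum(self.type_counts)

    def type_proportions(self) -> np.ndarray | None:
        """Per-type proportions over this spot's disagreement pixels (None if none)."""
        n = self.n_disagree
        if n == 0:
            return None
        return np.asarray(self.type_counts, float) / n


def classify_disagreements(
    mask_a: LabelMask, mask_b: LabelMask, cell_diameter_px: int
) -> DisagreementMap:
    """Classify every disagreement pixel as Type 1, 2 or 3.

    Rules, in order: (1) Type 1 pixels are those removed by opening the
    disagreement raster with a disc of ``cell_diameter_px`` — strips too
    thin to contain a cell; (2) among the remainder, a pixel whose own-mask
    T component (8-connected) intersects at least one T pixel of the other
    mask is Type 2; (3) the rest are Type 3.
    """
    if cell_diameter_px < 1:
        raise ValueError("cell_diameter_px must be >= 1")
    inside = check_comparable(mask_a, mask_b)
    a = mask_a.labels
    b = mask_b.labels
    disagree = (a != b) & inside

    foot = disc_footprint(cell_diameter_px)
    opened = ndimage.binary_opening(disagree, structure=foot)
    type1 = disagree & ~opened
    remainder = disagree & opened

    classes = np.full(a.shape, OUTSIDE, np.uint8)
    classes[inside & (a == b) & (a == T)] = AGREE_T
    classes[inside & (a == b) & (a == N)] = AGREE_N
    classes[type1] = TYPE1
    classes[remainder] = TYPE3  # provisional; upgraded to TYPE2 below

    # Type 2: own-mask T component overlaps the other mask's T raster.
    for own, other in ((a, b), (b, a)):
        own_t = own == T
        other_t = other == T
        lab, n = ndimage.label(own_t, structure=_EIGHT)
        if n == 0:
            continue
        overlaps = np.zeros(n + 1, bool)
        hit = np.unique(lab[other_t & own_t])
        overlaps[hit[hit > 0]] = True
        cand = remainder & own_t & ~other_t
        classes[cand & overlaps[lab]] = TYPE2

    return DisagreementMap(classes, int(cell_diameter_px))


@dataclass
class DisagreementSummary:
    """Cohort summary of per-spot disagreement-type proportions.

    ``per_spot`` holds one (type1, type2, type3) proportion triple per spot
    with any disagreement; spots with zero disagreement are excluded from
    the cohort mean (and counted in ``n_excluded``).  Cohort statistics are
    the unweighted mean and sd over spots.
    """

    per_spot: np.ndarray  # (n_spots, 3) proportions
    mean: np.ndarray  # (3,)
    sd: np.ndarray  # (3,)
    n_excluded: int = 0


def summarise_disagreements(maps: list[DisagreementMap]) -> DisagreementSummary:
    """Per-spot type proportions and their unweighted cohort mean ± sd."""
    if not maps:
        raise ValueError("at least one DisagreementMap is required")
    rows = []
    n_excluded = 0
    for m in maps:
        p = m.type_proportions()
        if p is None:
            n_excluded += 1
            continue
        rows.append(p)
    if n_excluded:
        logger.info(
            "excluded %d spot(s) with zero disagreement pixels from cohort summary",
            n_excluded,
        )
    if not rows:
        nanv = np.full(3, np.nan)
        return DisagreementSummary(np.empty((0, 3)), nanv, nanv, n_excluded)
    per_spot = np.vstack(rows)
    mean = per_spot.mean(axis=0)
    sd = per_spot.std(axis=0, ddof=1) if per_spot.shape[0] > 1 else np.zeros(3)
    return DisagreementSummary(per_spot, mean, sd, n_excluded)


_TYPE_COLOURS = {
    TYPE1: (255, 0, 0),  # red
    TYPE2: (0, 255, 0),  # green
    TYPE3: (0, 0, 255),  # blue
}


def render_difference_image(
    dmap: DisagreementMap, background: SpotImage | None = None
) -> np.ndarray:
    """Colour-coded difference image: Type 1 red, Type 2 green, Type 3 blue.

    Agreement pixels show the background image when given, otherwise neutral
    grey (AGREE_T slightly darker); OUTSIDE is black.
    """
    shape = dmap.classes.shape
    if background is not None:
        if background.shape != shape:
            raise ValueError("background shape does not match the disagreement map")
        rgb = background.pixels.copy()
    else:
        rgb = np.zeros(shape + (3,), np.uint8)
        rgb[dmap.classes == AGREE_N] = (220, 220, 220)
        rgb[dmap.classes == AGREE_T] = (160, 160, 160)
    for cls, colour in _TYPE_COLOURS.items():
        rgb[dmap.classes == cls] = colour
    rgb[dmap.classes == OUTSIDE] = (0, 0, 0)
    return rgb
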