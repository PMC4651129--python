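"""Core raster containers shared across the pipeline.

A tissue-microarray (TMA) *spot* is one circular tissue core imaged as an
RGB raster.  Pixels outside the delineated spot perimeter are excluded from
every downstream computation; masks therefore carry a three-way label
``{OUTSIDE, N, T}`` where ``N`` is non-tumour and ``T`` tumour tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Fixed on-disk label encoding for single-channel 8-bit mask images.
OUTSIDE: int = 0
N: int = 1
T: int = 2

LABEL_NAMES = {OUTSIDE: "OUTSIDE", N: "N", T: "T"}

# Disagreement-map classes (see tmascore.comparison).
AGREE_N: int = 1
AGREE_T: int = 2
TYPE1: int = 3
TYPE2: int = 4
TYPE3: int = 5


@dataclass
class SpotImage:
    """RGB TMA spot raster with pixel-size metadata and circular validity region.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
        8-bit RGB image data.
    pixel_size_um : float
        Physical pixel edge length in micrometres.
    inside_spot : ndarray, shape (H, W), bool
        True for pixels inside the spot perimeter; everything outside is
        ignored by segmentation, comparison and scoring.
    """

    pixels: np.ndarray
    pixel_size_um: float
    inside_spot: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.inside_spot = np.asarray(self.inside_spot, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB raster")
        if self.pixels.shape[:2] != self.inside_spot.shape:
            raise ValueError("inside_spot shape must match pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelMask:
    """Per-pixel tumour/non-tumour labels for one spot.

    ``labels`` takes values in ``{OUTSIDE, N, T}`` = {0, 1, 2}; OUTSIDE must
    coincide exactly with the complement of the paired image's validity
    region.  This is the unit both pathologists and the automated segmenter
    produce.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        bad = np.setdiff1d(np.unique(self.labels), [OUTSIDE, N, T])
        if bad.size:
            raise ValueError(f"mask contains unknown label values: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def inside_spot(self) -> np.ndarray:
        return self.labels != OUTSIDE

    def copy(self) -> "LabelMask":
        return LabelMask(self.labels.copy())


def check_comparable(mask_a: LabelMask, mask_b: LabelMask) -> np.ndarray:
    """Validate that two masks share shape and OUTSIDE set; return inside raster.

    Spot perimeters must agree for a pixel-level comparison to be meaningful.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    inside_a = mask_a.inside_spot
    if not np.array_equal(inside_a, mask_b.inside_spot):
        raise ValueError("masks have different OUTSIDE sets (spot perimeters disagree)")
    return inside_a
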