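"""Nuclear ER IHC scoring restricted to tumour regions.

An open stand-in for commercial nuclear IHC scorers: the RGB spot is
separated into haematoxylin and DAB optical-density (OD) maps by colour
deconvolution, nuclei are detected by thresholding the combined nuclear OD
and splitting touching blobs with a distance-transform watershed, each
nucleus receives a 0–3 DAB intensity bin, and per-spot summary scores are
computed: percent positive cells, the Allred score (intensity 0–3 +
proportion 0–5, positivity cut-off > 2, equivalent to the USCAP 1% rule)
and the Quickscore (intensity 0–3 + proportion 1–6, cut-off > 3).

Only nuclei whose centroid lies on a tumour (T) pixel of the supplied mask
contribute; this mirrors clinical practice where the scorer is handed the
tumour annotation and everything else is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .synthetic import DEFAULT_STAINS, StainModel
from .types import LabelMask, SpotImage, T

logger = logging.getLogger(__name__)

__all__ = [
    "ODMaps",
    "NucleusRecord",
    "NucleusDetectionParams",
    "SpotIHCScore",
    "DEFAULT_INTENSITY_THRESHOLDS",
    "colour_deconvolve",
    "detect_nuclei",
    "assign_intensity_bins",
    "score_spot",
    "score_masked_spot",
]

#: per-nucleus mean DAB OD cut points between intensity bins 0|1, 1|2, 2|3.
#: Calibration constants for the open scorer, overridable per call.
DEFAULT_INTENSITY_THRESHOLDS = (0.15, 0.40, 0.70)


@dataclass
class ODMaps:
    """Haematoxylin/DAB/residual optical-density rasters for one spot."""

    haematoxylin_od: np.ndarray
    dab_od: np.ndarray
    residual_od: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.haematoxylin_od.shape


def colour_deconvolve(image: SpotImage, stains: StainModel = DEFAULT_STAINS) -> ODMaps:
    """Separate an RGB image into haematoxylin and DAB OD maps.

    Per pixel the OD vector ``-log10(rgb / background)`` is decomposed in
    the orthonormalised frame (v_h, v_d, residual) by exact linear solve;
    negative stain projections are clipped to zero (the clipped mass is
    logged).  Zero-intensity pixels are clamped to 1 count before the log.
    """
    rgb = np.maximum(image.pixels.astype(float), 1.0)
    bg = np.maximum(np.asarray(stains.background_rgb, float), 1.0)
    od = -np.log10(rgb / bg)

    basis = np.column_stack([stains.basis, stains.residual_vector])  # 3x3
    conc = od.reshape(-1, 3) @ np.linalg.inv(basis).T
    conc = conc.reshape(od.shape)

    haem = conc[..., 0]
    dab = conc[..., 1]
    clip_mass = float(np.abs(haem[haem < 0]).sum() + np.abs(dab[dab < 0]).sum())
    if clip_mass > 0:
        logger.debug("clipped %.3f total negative OD mass during deconvolution", clip_mass)
    return ODMaps(
        haematoxylin_od=np.maximum(haem, 0.0),
        dab_od=np.maximum(dab, 0.0),
        residual_od=conc[..., 2],
    )


@dataclass
class NucleusRecord:
    """One detected nucleus with its mean stain ODs and intensity bin."""

    centroid: tuple[float, float]
    area_px: int
    mean_dab_od: float
    mean_haem_od: float
    intensity_bin: int = 0

    @property
    def is_positive(self) -> bool:
        return self.intensity_bin >= 1


@dataclass(frozen=True)
class NucleusDetectionParams:
    """Tunables of the open nucleus detector (all in pixels / OD units)."""

    smooth_sigma_px: float = 1.5
    threshold_od: float = 0.30
    min_area_px: int = 12
    max_area_px: int = 4000
    min_peak_distance_px: int = 5

    @classmethod
    def for_scale(cls, pixel_size_um: float, nucleus_radius_um: float = 5.0):
        """Derive sensible detector settings for a given pixel size."""
        r_px = nucleus_radius_um / pixel_size_um
        area = np.pi * r_px**2
        return cls(
            smooth_sigma_px=max(1.0, 0.3 * r_px),
            threshold_od=0.30,
            min_area_px=max(4, int(0.15 * area)),
            max_area_px=int(6.0 * area),
            min_peak_distance_px=max(2, int(round(1.2 * r_px))),
        )


def detect_nuclei(
    od: ODMaps,
    tumour_mask: LabelMask,
    params: NucleusDetectionParams = NucleusDetectionParams(),
) -> list[NucleusRecord]:
    """Detect nuclei and keep those whose centroid lies on a T pixel.

    Candidate raster = Gaussian-smoothed (haem OD + DAB OD) thresholded at
    ``threshold_od``; touching blobs are split by watershed on the distance
    transform seeded at its local maxima; components are discarded if their
    centroid is not on a T pixel or their area falls outside
    ``[min_area_px, max_area_px]``.  Fully deterministic for fixed inputs.
    """
    if od.shape != tumour_mask.shape:
        raise ValueError("OD maps and mask shapes differ")
    t_raster = tumour_mask.labels == T
    if not t_raster.any():
        return []

    nuclear = ndimage.gaussian_filter(
        od.haematoxylin_od + od.dab_od, params.smooth_sigma_px
    )
    binary = nuclear > params.threshold_od
    if not binary.any():
        return []

    distance = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance,
        min_distance=params.min_peak_distance_px,
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(binary.shape, np.int32)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    lab = watershed(-distance, markers, mask=binary)

    records: list[NucleusRecord] = []
    objects = ndimage.find_objects(lab)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp = lab[sl] == i
        area = int(comp.sum())
        if area < params.min_area_px or area > params.max_area_px:
            continue
        rr, cc = np.nonzero(comp)
        r_mean = rr.mean() + sl[0].start
        c_mean = cc.mean() + sl[1].start
        ri, ci = int(round(r_mean)), int(round(c_mean))
        if not t_raster[ri, ci]:
            continue
        # stain means over the eroded core: the watershed boundary includes
        # partial-volume rim pixels that would dilute the nuclear OD
        core = ndimage.binary_erosion(comp)
        if not core.any():
            core = comp
        records.append(
            NucleusRecord(
                centroid=(float(r_mean), float(c_mean)),
                area_px=area,
                mean_dab_od=float(od.dab_od[sl][core].mean()),
                mean_haem_od=float(od.haematoxylin_od[sl][core].mean()),
            )
        )
    return records


def assign_intensity_bins(
    nuclei: list[NucleusRecord],
    thresholds: tuple[float, float, float] = DEFAULT_INTENSITY_THRESHOLDS,
) -> list[NucleusRecord]:
    """Bin each nucleus's mean DAB OD into intensity 0–3.

    Half-open convention: bin 0 below ``t1``, bin 1 on ``[t1, t2)``, bin 2 on
    ``[t2, t3)``, bin 3 at and above ``t3``.  A nucleus is ER-positive iff
    its bin is >= 1.
    """
    t1, t2, t3 = thresholds
    if not (0 < t1 < t2 < t3):
        raise ValueError("thresholds must satisfy 0 < t1 < t2 < t3")
    out = []
    for nuc in nuclei:
        b = int(np.searchsorted([t1, t2, t3], nuc.mean_dab_od, side="right"))
        out.append(replace(nuc, intensity_bin=b))
    return out


def _intensity_bin(value: float, thresholds) -> int:
    t1, t2, t3 = thresholds
    return int(np.searchsorted([t1, t2, t3], value, side="right"))


def allred_proportion_bin(percent_positive: float) -> int:
    """Allred proportion score: 0, (0,1)%→1, [1,10)→2, [10,33⅓)→3, [33⅓,66⅔)→4, ≥66⅔→5."""
    p = percent_positive
    if p <= 0:
        return 0
    if p < 1:
        return 1
    if p < 10:
        return 2
    if p < 100 / 3:
        return 3
    if p < 200 / 3:
        return 4
    return 5


def quickscore_proportion_bin(percent_positive: float) -> int:
    """Quickscore proportion: [0,5)%→1, [5,20)→2, [20,40)→3, [40,60)→4, [60,80)→5, ≥80→6."""
    p = percent_positive
    if p < 5:
        return 1
    if p < 20:
        return 2
    if p < 40:
        return 3
    if p < 60:
        return 4
    if p < 80:
        return 5
    return 6


@dataclass
class SpotIHCScore:
    """Per-spot ER summary: percent positive, Allred and Quickscore components."""

    n_nuclei: int
    percent_positive: float
    intensity_score: int
    allred_proportion: int
    quickscore_proportion: int

    @property
    def allred_total(self) -> int:
        return self.intensity_score + self.allred_proportion

    @property
    def quickscore_total(self) -> int:
        return self.intensity_score + self.quickscore_proportion

    @property
    def er_status_allred(self) -> bool:
        return self.allred_total > 2

    @property
    def er_status_quickscore(self) -> bool:
        return self.quickscore_total > 3


def score_spot(
    nuclei: list[NucleusRecord],
    thresholds: tuple[float, float, float] = DEFAULT_INTENSITY_THRESHOLDS,
    intensity_aggregation: str = "mean_positive",
) -> SpotIHCScore:
    """Aggregate per-nucleus records into the spot-level IHC score.

    The spot intensity score is the bin of the mean DAB OD over positive
    nuclei (``mean_positive``, default) or the modal positive-nucleus bin
    (``modal``); 0 when no nucleus is positive.  With zero nuclei the spot
    scores all-zero (Quickscore proportion 1 by construction of its bins)
    and a warning is logged.
    """
    n = len(nuclei)
    if n == 0:
        logger.warning("scoring a spot with zero detected nuclei; all-zero score")
        return SpotIHCScore(0, 0.0, 0, 0, 1)
    positives = [nuc for nuc in nuclei if nuc.is_positive]
    pct = 100.0 * len(positives) / n
    if not positives:
        intensity = 0
    elif intensity_aggregation == "mean_positive":
        intensity = _intensity_bin(
            float(np.mean([nuc.mean_dab_od for nuc in positives])), thresholds
        )
    elif intensity_aggregation == "modal":
        bins = np.array([nuc.intensity_bin for nuc in positives])
        intensity = int(np.bincount(bins, minlength=4).argmax())
    else:
        raise ValueError(f"unknown intensity_aggregation {intensity_aggregation!r}")
    return SpotIHCScore(
        n_nuclei=n,
        percent_positive=pct,
        intensity_score=intensity,
        allred_proportion=allred_proportion_bin(pct),
        quickscore_proportion=quickscore_proportion_bin(pct),
    )


def score_masked_spot(
    image: SpotImage,
    tumour_mask: LabelMask,
    stains: StainModel = DEFAULT_STAINS,
    params: NucleusDetectionParams | None = None,
    thresholds: tuple[float, float, float] = DEFAULT_INTENSITY_THRESHOLDS,
    intensity_aggregation: str = "mean_positive",
) -> tuple[SpotIHCScore, list[NucleusRecord]]:
    """End-to-end scoring of one spot given its tumour mask."""
    if params is None:
        params = NucleusDetectionParams.for_scale(image.pixel_size_um)
    od = colour_deconvolve(image, stains)
    nuclei = detect_nuclei(od, tumour_mask, params)
    nuclei = assign_intensity_bins(nuclei, thresholds)
    return score_spot(nuclei, thresholds, intensity_aggregation), nuclei
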