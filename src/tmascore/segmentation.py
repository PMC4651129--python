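"""Automated tumour segmentation by superpixel classification.

The spot is first partitioned into compact superpixels (SLIC k-means in
colour+position space) so that cellular-compartment boundaries tend to fall
on superpixel boundaries.  Each superpixel is described by colour statistics
(RGB and deconvolved haematoxylin/DAB OD), Gaussian-derivative texture
statistics, shape descriptors, and the mean colour/texture of its neighbours
on the region-adjacency graph.  A random forest trained on an annotator's
masks labels every superpixel tumour (T) or non-tumour (N); the label is
broadcast back to pixels to form the predicted mask.  Evaluation uses
spot-level k-fold cross-validation: each spot is predicted exactly once by a
model that never saw any of its superpixels.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops
from skimage.segmentation import slic
from sklearn.ensemble import RandomForestClassifier

from .scoring import colour_deconvolve
from .synthetic import DEFAULT_STAINS, StainModel
from .types import LabelMask, N, OUTSIDE, SpotImage, T

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpixelMap",
    "SegmenterModel",
    "compute_superpixels",
    "extract_features",
    "train_segmenter",
    "predict_mask",
    "cross_validate",
    "CrossValidationReport",
    "pixel_agreement",
]

DEFAULT_REGION_SIZE_PX = 16
DEFAULT_COMPACTNESS = 5.0


@dataclass
class SuperpixelMap:
    """Partition of in-spot pixels into connected superpixels.

    ``ids`` holds a non-negative superpixel id per in-spot pixel and -1 on
    OUTSIDE pixels.
    """

    ids: np.ndarray

    @property
    def n_superpixels(self) -> int:
        return int(self.ids.max()) + 1 if (self.ids >= 0).any() else 0


def compute_superpixels(
    image: SpotImage,
    region_size_px: int = DEFAULT_REGION_SIZE_PX,
    compactness: float = DEFAULT_COMPACTNESS,
) -> SuperpixelMap:
    """SLIC superpixels over the in-spot region.

    ``region_size_px`` sets the target superpixel edge length; the number of
    requested segments is the in-spot area divided by ``region_size_px**2``.
    Deterministic for fixed inputs.
    """
    if region_size_px < 4:
        raise ValueError("region_size_px must be >= 4")
    inside = image.inside_spot
    n_inside = int(inside.sum())
    if region_size_px**2 > n_inside:
        raise ValueError("region_size_px is larger than the spot")
    n_segments = max(2, int(round(n_inside / region_size_px**2)))
    seg = slic(
        image.pixels,
        n_segments=n_segments,
        compactness=compactness,
        mask=inside,
        start_label=1,
        enforce_connectivity=True,
        channel_axis=-1,
    )
    seg = seg.astype(np.int64)
    seg[~inside] = 0
    # split any accidentally disconnected label, then compact ids to 0..n-1
    from skimage.measure import label as _cc_label

    ids = _cc_label(seg, background=0, connectivity=2).astype(np.int64) - 1
    ids[~inside] = -1
    return SuperpixelMap(ids)


# texture filter-bank scales in micrometres; converted to pixels at runtime
_TEXTURE_SIGMAS_UM = (1.0, 2.0, 4.0)


def _texture_stack(gray: np.ndarray, pixel_size_um: float) -> list[np.ndarray]:
    responses = []
    for s_um in _TEXTURE_SIGMAS_UM:
        s_px = max(0.5, s_um / pixel_size_um)
        responses.append(ndimage.gaussian_gradient_magnitude(gray, s_px))
        responses.append(ndimage.gaussian_laplace(gray, s_px))
    return responses


def _aggregate(values: np.ndarray, ids_flat: np.ndarray, n: int):
    """Per-superpixel mean and sd of a flat value array via bincount."""
    cnt = np.bincount(ids_flat, minlength=n)
    s = np.bincount(ids_flat, weights=values, minlength=n)
    s2 = np.bincount(ids_flat, weights=values**2, minlength=n)
    mean = s / np.maximum(cnt, 1)
    var = np.maximum(s2 / np.maximum(cnt, 1) - mean**2, 0.0)
    return mean, np.sqrt(var)


def extract_features(
    image: SpotImage,
    spmap: SuperpixelMap,
    reference_mask: LabelMask | None = None,
    stains: StainModel = DEFAULT_STAINS,
) -> pd.DataFrame:
    """Per-superpixel feature table (colour, texture, shape, neighbour context).

    When ``reference_mask`` is given, each superpixel receives the majority
    {N, T} label of its pixels as the training label (exact 50/50 ties go to
    N, never over-calling tumour).  Neighbour aggregates are the mean of the
    adjacent superpixels' colour/texture features on the region-adjacency
    graph.
    """
    ids = spmap.ids
    if ids.shape != image.shape:
        raise ValueError("superpixel map shape does not match image")
    inside = ids >= 0
    n = spmap.n_superpixels
    ids_flat = ids[inside]

    od = colour_deconvolve(image, stains)
    channels: dict[str, np.ndarray] = {
        "r": image.pixels[..., 0].astype(float),
        "g": image.pixels[..., 1].astype(float),
        "b": image.pixels[..., 2].astype(float),
        "haem_od": od.haematoxylin_od,
        "dab_od": od.dab_od,
    }
    gray = image.pixels.astype(float).mean(axis=2) / 255.0
    for i, resp in enumerate(_texture_stack(gray, image.pixel_size_um)):
        channels[f"tex{i}"] = resp

    data: dict[str, np.ndarray] = {}
    for name, ch in channels.items():
        mean, sd = _aggregate(ch[inside], ids_flat, n)
        data[f"{name}_mean"] = mean
        data[f"{name}_sd"] = sd

    # shape descriptors
    props = regionprops(ids + 1)
    area = np.zeros(n)
    ecc = np.zeros(n)
    solidity = np.zeros(n)
    for p in props:
        i = p.label - 1
        area[i] = p.area
        ecc[i] = p.eccentricity
        solidity[i] = p.solidity
    data["area_px"] = area
    data["eccentricity"] = ecc
    data["solidity"] = solidity

    # region-adjacency neighbour means of colour/texture features
    pairs = set()
    for a, b in (
        (ids[:, :-1], ids[:, 1:]),
        (ids[:-1, :], ids[1:, :]),
        (ids[:-1, :-1], ids[1:, 1:]),
        (ids[:-1, 1:], ids[1:, :-1]),
    ):
        diff = (a != b) & (a >= 0) & (b >= 0)
        pairs.update(zip(a[diff].tolist(), b[diff].tolist()))
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        adj[a].append(b)
    context_cols = [f"{name}_mean" for name in channels]
    for col in context_cols:
        vals = data[col]
        nb = np.array(
            [vals[neigh].mean() if neigh else vals[i] for i, neigh in enumerate(adj)]
        )
        data[f"nb_{col}"] = nb

    df = pd.DataFrame(data)
    df.insert(0, "superpixel_id", np.arange(n))
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite feature values")

    if reference_mask is not None:
        if reference_mask.shape != image.shape:
            raise ValueError("reference mask shape does not match image")
        t_frac = np.bincount(
            ids_flat,
            weights=(reference_mask.labels[inside] == T).astype(float),
            minlength=n,
        ) / np.maximum(np.bincount(ids_flat, minlength=n), 1)
        df["label"] = np.where(t_frac > 0.5, T, N)  # exact ties -> N
    return df


FEATURE_EXCLUDE = ("superpixel_id", "label", "spot_id")


def _feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in FEATURE_EXCLUDE]


def _schema_hash(columns: list[str]) -> str:
    return hashlib.sha256("|".join(columns).encode()).hexdigest()[:16]


@dataclass
class SegmenterModel:
    """Fitted superpixel classifier with its feature schema and provenance."""

    classifier: RandomForestClassifier
    feature_columns: list[str]
    schema_hash: str
    annotator_tag: str

    def predict_scores(self, features: pd.DataFrame) -> np.ndarray:
        """Class score in [0, 1] for T, one per feature row."""
        if _schema_hash(_feature_columns(features)) != self.schema_hash:
            raise ValueError("feature schema does not match the trained model")
        x = features[self.feature_columns].to_numpy()
        proba = self.classifier.predict_proba(x)
        t_col = list(self.classifier.classes_).index(T)
        return proba[:, t_col]

    def predict_labels(self, features: pd.DataFrame) -> np.ndarray:
        """{N, T} decision at score > 0.5; exact ties go to N (conservative)."""
        return np.where(self.predict_scores(features) > 0.5, T, N)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "SegmenterModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError("file does not contain a SegmenterModel")
        return model


def train_segmenter(
    feature_tables: list[pd.DataFrame],
    annotator_tag: str,
    seed: int,
    n_estimators: int = 200,
) -> SegmenterModel:
    """Fit the random-forest superpixel classifier on labelled feature tables."""
    labelled = pd.concat(feature_tables, ignore_index=True)
    if "label" not in labelled.columns:
        raise ValueError("feature tables carry no training labels")
    present = set(labelled["label"].unique())
    for cls, name in ((T, "T"), (N, "N")):
        if cls not in present:
            raise ValueError(f"training data contain no {name} superpixels")
    cols = _feature_columns(labelled)
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        min_samples_leaf=2,
    )
    clf.fit(labelled[cols].to_numpy(), labelled["label"].to_numpy())
    return SegmenterModel(clf, cols, _schema_hash(cols), annotator_tag)


def predict_mask(
    image: SpotImage,
    model: SegmenterModel,
    region_size_px: int = DEFAULT_REGION_SIZE_PX,
    compactness: float = DEFAULT_COMPACTNESS,
    min_component_area_px: int = 0,
    stains: StainModel = DEFAULT_STAINS,
) -> LabelMask:
    """Predict a tumour mask: every in-spot pixel gets its superpixel's label.

    ``min_component_area_px`` optionally removes predicted T components
    smaller than the given area (off by default).
    """
    spmap = compute_superpixels(image, region_size_px, compactness)
    features = extract_features(image, spmap, stains=stains)
    labels_per_sp = model.predict_labels(features)
    out = np.full(image.shape, OUTSIDE, np.uint8)
    inside = spmap.ids >= 0
    out[inside] = labels_per_sp[spmap.ids[inside]]
    if min_component_area_px > 0:
        t_mask = out == T
        lab, nlab = ndimage.label(t_mask, structure=np.ones((3, 3), int))
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, nlab + 1))
        for i, size in enumerate(sizes, start=1):
            if size < min_component_area_px:
                out[lab == i] = N
    return LabelMask(out)


def pixel_agreement(mask_a: LabelMask, mask_b: LabelMask) -> float:
    """Fraction of in-spot pixels with identical labels."""
    inside = mask_a.inside_spot
    if not np.array_equal(inside, mask_b.inside_spot):
        raise ValueError("masks have different OUTSIDE sets")
    return float((mask_a.labels[inside] == mask_b.labels[inside]).mean())


@dataclass
class CrossValidationReport:
    """Per-spot predictions and fold bookkeeping from spot-level k-fold CV."""

    predicted_masks: list[LabelMask]
    fold_of_spot: np.ndarray
    per_spot: pd.DataFrame  # spot, fold, pixel_agreement

    @property
    def mean_pixel_agreement(self) -> float:
        return float(self.per_spot["pixel_agreement"].mean())


def assign_folds(n_spots: int, k: int, seed: int) -> np.ndarray:
    """Seeded shuffle then contiguous blocks: fold index per spot."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_spots:
        raise ValueError(f"k={k} exceeds the number of spots ({n_spots})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_spots)
    folds = np.empty(n_spots, int)
    for f, block in enumerate(np.array_split(order, k)):
        folds[block] = f
    return folds


def cross_validate(
    spots: list[tuple[SpotImage, LabelMask]],
    k: int = 8,
    seed: int = 0,
    annotator_tag: str = "A",
    region_size_px: int = DEFAULT_REGION_SIZE_PX,
    compactness: float = DEFAULT_COMPACTNESS,
    min_component_area_px: int = 0,
    stains: StainModel = DEFAULT_STAINS,
) -> CrossValidationReport:
    """Spot-level k-fold cross-validation of the superpixel segmenter.

    Spots are partitioned into k folds at the spot level (never pixel
    level); each spot is predicted exactly once, by a model whose training
    table contains no superpixel from that spot.
    """
    n = len(spots)
    folds = assign_folds(n, k, seed)

    tables = []
    spmaps = []
    for i, (image, mask) in enumerate(spots):
        spmap = compute_superpixels(image, region_size_px, compactness)
        tab = extract_features(image, spmap, reference_mask=mask, stains=stains)
        tab["spot_id"] = i
        tables.append(tab)
        spmaps.append(spmap)

    predicted: list[LabelMask | None] = [None] * n
    rows = []
    for f in range(k):
        train_tables = [tables[i] for i in range(n) if folds[i] != f]
        model = train_segmenter(train_tables, annotator_tag, seed=seed + f)
        for i in range(n):
            if folds[i] != f:
                continue
            assert int(tables[i]["spot_id"].iloc[0]) == i  # leakage guard
            image, mask = spots[i]
            labels_per_sp = model.predict_labels(tables[i])
            out = np.full(image.shape, OUTSIDE, np.uint8)
            inside = spmaps[i].ids >= 0
            out[inside] = labels_per_sp[spmaps[i].ids[inside]]
            pred = LabelMask(out)
            if min_component_area_px > 0:
                pred = _filter_small_components(pred, min_component_area_px)
            predicted[i] = pred
            rows.append(
                {"spot": i, "fold": f, "pixel_agreement": pixel_agreement(pred, mask)}
            )
    report = pd.DataFrame(rows).sort_values("spot").reset_index(drop=True)
    return CrossValidationReport(predicted, folds, report)


def _filter_small_components(mask: LabelMask, min_area: int) -> LabelMask:
    out = mask.labels.copy()
    lab, nlab = ndimage.label(out == T, structure=np.ones((3, 3), int))
    for i in range(1, nlab + 1):
        comp = lab == i
        if comp.sum() < min_area:
            out[comp] = N
    return LabelMask(out)
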