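"""Reading and writing spot images, label masks, nucleus tables and scores.

Masks travel as single-channel 8-bit PNGs with the fixed encoding
0=OUTSIDE, 1=N, 2=T; images as 8-bit RGB PNG or TIFF; ground truth as a CSV
nucleus table plus a JSON sidecar echoing the generator configuration;
per-spot scores as CSV.  All round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .scoring import SpotIHCScore
from .synthetic import GroundTruth, NucleusTruth, SyntheticSpotConfig
from .types import LabelMask, SpotImage

__all__ = [
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "read_scores",
    "write_scores",
    "write_ground_truth",
    "read_nucleus_table",
]

_VALID_MASK_VALUES = {0, 1, 2}


def write_mask(path, mask: LabelMask) -> None:
    iio.imwrite(Path(path), mask.labels.astype(np.uint8), extension=".png")


def read_mask(path) -> LabelMask:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim != 2:
        raise ValueError(f"mask file {path} is not single-channel")
    bad = sorted(set(np.unique(arr).tolist()) - _VALID_MASK_VALUES)
    if bad:
        raise ValueError(f"mask file {path} contains unknown label values: {bad}")
    return LabelMask(arr.astype(np.uint8))


def write_image(path, image: SpotImage) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels, extension=path.suffix or ".png")


def read_image(path, pixel_size_um: float, inside_spot: np.ndarray | None = None) -> SpotImage:
    """Read an 8-bit RGB PNG/TIFF spot image.

    The file formats carry no validity region; pass ``inside_spot`` or the
    full frame is assumed valid.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if inside_spot is None:
        inside_spot = np.ones(arr.shape[:2], bool)
    return SpotImage(arr.astype(np.uint8), pixel_size_um, inside_spot)


SCORE_COLUMNS = [
    "spot_id",
    "mask_source",
    "n_nuclei",
    "percent_positive",
    "intensity",
    "allred_prop",
    "allred_total",
    "qs_prop",
    "qs_total",
    "er_allred",
    "er_qs",
]


def scores_to_frame(scores: dict[tuple[str, str], SpotIHCScore]) -> pd.DataFrame:
    """Tabulate {(spot_id, mask_source): score} as the canonical score frame."""
    rows = []
    for (spot_id, source), s in sorted(scores.items()):
        rows.append(
            {
                "spot_id": spot_id,
                "mask_source": source,
                "n_nuclei": s.n_nuclei,
                "percent_positive": round(s.percent_positive, 6),
                "intensity": s.intensity_score,
                "allred_prop": s.allred_proportion,
                "allred_total": s.allred_total,
                "qs_prop": s.quickscore_proportion,
                "qs_total": s.quickscore_total,
                "er_allred": s.er_status_allred,
                "er_qs": s.er_status_quickscore,
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_scores(path, frame: pd.DataFrame) -> None:
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"score frame is missing columns: {missing}")
    frame.to_csv(Path(path), index=False)


def read_scores(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path))
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"score file {path} is missing columns: {missing}")
    return frame


def write_ground_truth(out_dir, spot_name: str, truth: GroundTruth,
                       config: SyntheticSpotConfig) -> None:
    """Write the nucleus table CSV and a JSON sidecar with the config echo."""
    out_dir = Path(out_dir)
    rows = [
        {
            "row": n.row,
            "col": n.col,
            "compartment": n.compartment,
            "is_positive": n.is_positive,
            "dab_od": n.programmed_dab_od,
        }
        for n in truth.nuclei
    ]
    pd.DataFrame(rows, columns=["row", "col", "compartment", "is_positive", "dab_od"]).to_csv(
        out_dir / f"{spot_name}_nuclei.csv", index=False
    )
    sidecar = {
        "config": config.to_dict(),
        "percent_positive_tumour": truth.percent_positive_tumour,
        "n_nuclei": len(truth.nuclei),
    }
    (out_dir / f"{spot_name}_truth.json").write_text(json.dumps(sidecar, indent=2))


def read_nucleus_table(path) -> list[NucleusTruth]:
    frame = pd.read_csv(Path(path))
    required = ["row", "col", "compartment", "is_positive", "dab_od"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"nucleus table {path} is missing columns: {missing}")
    return [
        NucleusTruth(r.row, r.col, r.compartment, bool(r.is_positive), r.dab_od)
        for r in frame.itertuples()
    ]
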