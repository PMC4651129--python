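"""End-to-end synthetic study orchestration.

`run_study` reproduces the full experimental design on a synthetic cohort:
for every generated spot, two simulated "annotator" masks are derived from
the ground truth by seeded perturbation (annotator A: small boundary jitter;
annotator B: jitter plus occasional whole-region resizes or flips, so the
inter-annotator differences exhibit all three disagreement types).  The
superpixel segmenter is cross-validated twice — once trained on each
annotator — and every mask source is scored.  The report carries the
normalised contingency tables per source pair, the disagreement-type
summary, quadratic-weighted-kappa matrices for each ordinal score,
ER-status concordance per cut-off, and Bland–Altman results for percent
positive.  Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import spawn_seed
from .agreement import (
    ALLRED_TOTAL_RANGE,
    INTENSITY_RANGE,
    QUICKSCORE_TOTAL_RANGE,
    agreement_result,
    bland_altman,
    confusion_from_scores,
    weighted_kappa,
)
from .comparison import (
    classify_disagreements,
    pixel_contingency,
    summarise_disagreements,
)
from .scoring import (
    DEFAULT_INTENSITY_THRESHOLDS,
    NucleusDetectionParams,
    score_masked_spot,
)
from .segmentation import cross_validate
from .synthetic import (
    DEFAULT_STAINS,
    SyntheticSpotConfig,
    generate_spot,
    perturb_mask,
)
from .types import LabelMask, SpotImage

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "DEFAULT_SCORE_GRID"]

#: programmed (percent positive, intensity bin) pairs cycled over the cohort
DEFAULT_SCORE_GRID: tuple[tuple[float, int], ...] = (
    (0.0, 0),
    (0.5, 1),
    (5.0, 2),
    (25.0, 3),
    (50.0, 2),
    (90.0, 3),
    (10.0, 1),
    (70.0, 3),
)

_ORDINAL_SCORES = {
    "intensity": ("intensity", INTENSITY_RANGE),
    "allred_proportion": ("allred_prop", list(range(0, 6))),
    "quickscore_proportion": ("qs_prop", list(range(1, 7))),
    "allred_total": ("allred_total", ALLRED_TOTAL_RANGE),
    "quickscore_total": ("qs_total", QUICKSCORE_TOTAL_RANGE),
}

_SOURCE_PAIRS = (
    ("manualA", "manualB"),
    ("autoA", "manualA"),
    ("autoA", "manualB"),
    ("autoB", "manualA"),
    ("autoB", "manualB"),
)


@dataclass
class StudyConfig:
    """Configuration of one synthetic study; JSON round-trips losslessly."""

    n_spots: int = 16
    k_folds: int = 8
    diameter_px: int = 600
    pixel_size_um: float = 1.0
    tumour_fraction: float = 0.30
    noise_sd: float = 2.0
    score_grid: list = field(default_factory=lambda: [list(p) for p in DEFAULT_SCORE_GRID])
    # segmentation
    region_size_px: int = 16
    compactness: float = 10.0
    min_component_area_px: int = 0
    # comparison
    cell_diameter_um: float = 8.0
    # scoring
    intensity_thresholds: list = field(
        default_factory=lambda: list(DEFAULT_INTENSITY_THRESHOLDS)
    )
    # simulated annotators
    jitter_a_px: int = 3
    jitter_b_px: int = 3
    b_extra_every: int = 3
    resize_magnitude_px: int = 5
    flip_magnitude_px: int = 25
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        return cls(**json.loads(text))


@dataclass
class StudyReport:
    """All cohort-level tables produced by one study run."""

    contingency: pd.DataFrame  # pair, tt, tn, nt, nn (mean normalised) + agreement
    disagreement_types: pd.DataFrame  # pair, type means/sds
    scores: pd.DataFrame  # canonical per-spot score frame
    kappa: pd.DataFrame  # pair, score, weighted kappa
    er_concordance: pd.DataFrame  # pair, cutoff, n_agree, n_total
    bland_altman_table: pd.DataFrame  # pair, bias, loa
    cv_report: pd.DataFrame  # annotator, spot, fold, pixel agreement
    config_json: str

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.contingency.to_csv(out / "contingency.csv", index=False)
        self.disagreement_types.to_csv(out / "disagreement_types.csv", index=False)
        self.scores.to_csv(out / "scores.csv", index=False)
        self.kappa.to_csv(out / "kappa.csv", index=False)
        self.er_concordance.to_csv(out / "er_concordance.csv", index=False)
        self.bland_altman_table.to_csv(out / "bland_altman.csv", index=False)
        self.cv_report.to_csv(out / "cv_report.csv", index=False)
        (out / "study_config.json").write_text(self.config_json)


def _spot_config(cfg: StudyConfig, i: int) -> SyntheticSpotConfig:
    pct, ibin = cfg.score_grid[i % len(cfg.score_grid)]
    return SyntheticSpotConfig(
        diameter_px=cfg.diameter_px,
        pixel_size_um=cfg.pixel_size_um,
        tumour_fraction=cfg.tumour_fraction,
        noise_sd=cfg.noise_sd,
        programmed_percent_positive=pct,
        programmed_intensity_bin=ibin,
        seed=spawn_seed(cfg.seed, 1, i),
    )


def simulate_annotators(
    truth_mask: LabelMask, cfg: StudyConfig, i: int
) -> tuple[LabelMask, LabelMask]:
    """Fabricate the two annotators' masks for spot ``i`` from ground truth."""
    mask_a = perturb_mask(
        truth_mask, "boundary_jitter", cfg.jitter_a_px, spawn_seed(cfg.seed, 2, i)
    )
    mask_b = perturb_mask(
        truth_mask, "boundary_jitter", cfg.jitter_b_px, spawn_seed(cfg.seed, 3, i)
    )
    if cfg.b_extra_every > 0 and i % cfg.b_extra_every == cfg.b_extra_every - 1:
        mode = "region_resize" if (i // cfg.b_extra_every) % 2 == 0 else "component_flip"
        magnitude = (
            cfg.resize_magnitude_px if mode == "region_resize" else cfg.flip_magnitude_px
        )
        direction = "add" if mode == "component_flip" else None
        try:
            mask_b = perturb_mask(
                mask_b, mode, magnitude, spawn_seed(cfg.seed, 4, i), direction=direction
            )
        except ValueError:
            logger.info("skipping %s perturbation on spot %d (no eligible component)", mode, i)
    return mask_a, mask_b


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full synthetic comparison study; see the module docstring."""
    cfg = config
    images: list[SpotImage] = []
    masks: dict[str, list[LabelMask]] = {
        "truth": [], "manualA": [], "manualB": []
    }
    spot_configs = []
    for i in range(cfg.n_spots):
        sc = _spot_config(cfg, i)
        spot_configs.append(sc)
        image, truth = generate_spot(sc, DEFAULT_STAINS)
        images.append(image)
        masks["truth"].append(truth.mask)
        a, b = simulate_annotators(truth.mask, cfg, i)
        masks["manualA"].append(a)
        masks["manualB"].append(b)

    # automated segmentation trained on each annotator, spot-level k-fold CV
    cv_frames = []
    for tag, source in (("A", "manualA"), ("B", "manualB")):
        report = cross_validate(
            list(zip(images, masks[source])),
            k=cfg.k_folds,
            seed=spawn_seed(cfg.seed, 5, ord(tag)),
            annotator_tag=tag,
            region_size_px=cfg.region_size_px,
            compactness=cfg.compactness,
            min_component_area_px=cfg.min_component_area_px,
        )
        masks[f"auto{tag}"] = report.predicted_masks
        frame = report.per_spot.copy()
        frame.insert(0, "annotator", tag)
        cv_frames.append(frame)
    cv_report = pd.concat(cv_frames, ignore_index=True)

    # pairwise pixel comparison
    cell_diam_px = max(1, int(round(cfg.cell_diameter_um / cfg.pixel_size_um)))
    cont_rows, type_rows = [], []
    for s1, s2 in _SOURCE_PAIRS:
        tables = [
            pixel_contingency(masks[s1][i], masks[s2][i]) for i in range(cfg.n_spots)
        ]
        norm = np.mean([t.normalized for t in tables], axis=0)
        pooled = np.sum([t.counts for t in tables], axis=0)
        res = agreement_result(pooled)
        cont_rows.append(
            {
                "pair": f"{s1}:{s2}",
                "tt": norm[0, 0],
                "tn": norm[0, 1],
                "nt": norm[1, 0],
                "nn": norm[1, 1],
                "observed_agreement": res.observed_agreement,
                "cohen_kappa": res.cohen_kappa,
                "disagreement_fraction": norm[0, 1] + norm[1, 0],
            }
        )
        dmaps = [
            classify_disagreements(masks[s1][i], masks[s2][i], cell_diam_px)
            for i in range(cfg.n_spots)
        ]
        summary = summarise_disagreements(dmaps)
        type_rows.append(
            {
                "pair": f"{s1}:{s2}",
                "type1_mean": summary.mean[0],
                "type1_sd": summary.sd[0],
                "type2_mean": summary.mean[1],
                "type2_sd": summary.sd[1],
                "type3_mean": summary.mean[2],
                "type3_sd": summary.sd[2],
                "n_spots_excluded": summary.n_excluded,
            }
        )
    contingency = pd.DataFrame(cont_rows)
    disagreement_types = pd.DataFrame(type_rows)

    # IHC scoring of every mask source
    from .io import scores_to_frame

    params = NucleusDetectionParams.for_scale(cfg.pixel_size_um)
    thresholds = tuple(cfg.intensity_thresholds)
    all_scores: dict[tuple[str, str], object] = {}
    for source, source_masks in masks.items():
        for i in range(cfg.n_spots):
            score, _ = score_masked_spot(
                images[i],
                source_masks[i],
                params=params,
                thresholds=thresholds,
            )
            all_scores[(f"spot{i:03d}", source)] = score
    scores = scores_to_frame(all_scores)

    # ordinal agreement per source pair
    kappa_rows = []
    for s1, s2 in _SOURCE_PAIRS:
        sub1 = scores[scores.mask_source == s1].sort_values("spot_id")
        sub2 = scores[scores.mask_source == s2].sort_values("spot_id")
        for name, (col, rng) in _ORDINAL_SCORES.items():
            conf = confusion_from_scores(sub1[col], sub2[col], rng)
            kappa_rows.append(
                {
                    "pair": f"{s1}:{s2}",
                    "score": name,
                    "weighted_kappa_quadratic": weighted_kappa(conf, "quadratic"),
                }
            )
    kappa = pd.DataFrame(kappa_rows)

    # ER-status concordance per cut-off
    er_rows = []
    for s1, s2 in _SOURCE_PAIRS:
        sub1 = scores[scores.mask_source == s1].sort_values("spot_id")
        sub2 = scores[scores.mask_source == s2].sort_values("spot_id")
        for cutoff, col in (("allred_gt2", "er_allred"), ("quickscore_gt3", "er_qs")):
            agree = int((sub1[col].to_numpy() == sub2[col].to_numpy()).sum())
            er_rows.append(
                {
                    "pair": f"{s1}:{s2}",
                    "cutoff": cutoff,
                    "n_agree": agree,
                    "n_total": cfg.n_spots,
                }
            )
    er_concordance = pd.DataFrame(er_rows)

    # Bland–Altman of percent positive for automated-vs-manual pairs
    ba_rows = []
    for s1, s2 in _SOURCE_PAIRS:
        sub1 = scores[scores.mask_source == s1].sort_values("spot_id")
        sub2 = scores[scores.mask_source == s2].sort_values("spot_id")
        ba = bland_altman(
            zip(sub1["percent_positive"].to_numpy(), sub2["percent_positive"].to_numpy())
        )
        ba_rows.append(
            {
                "pair": f"{s1}:{s2}",
                "bias": ba.bias,
                "sd": ba.sd,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
            }
        )
    bland_altman_table = pd.DataFrame(ba_rows)

    return StudyReport(
        contingency=contingency,
        disagreement_types=disagreement_types,
        scores=scores,
        kappa=kappa,
        er_concordance=er_concordance,
        bland_altman_table=bland_altman_table,
        cv_report=cv_report,
        config_json=cfg.to_json(),
    )
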