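"""Synthetic TMA spot generator with known ground truth.

No image data accompany the study this package supports, so every pipeline
stage is exercised against seeded synthetic spots: a circular tissue core
containing a few irregular tumour regions, normal epithelium patches,
lymphocyte fields and stroma, populated with elliptical nuclei rendered
through a Beer–Lambert haematoxylin/DAB forward model.  The generator emits
the spot image together with the exact label mask, a nucleus inventory and
the programmed ER score, and can fabricate "annotator" masks by perturbing
the ground truth in ways designed to produce each disagreement type.

The forward model is linear in optical density (OD): every nucleus adds an
elliptical OD kernel, overlaps sum, and the RGB image is
``round(background * 10**(-haem_od*v_h - dab_od*v_d))`` per channel.  This
matches the colour-deconvolution model used for scoring, so rendering and
deconvolution are mutual inverses up to quantisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from ._util import disc_footprint
from .types import LabelMask, N, OUTSIDE, SpotImage, T

__all__ = [
    "StainModel",
    "SyntheticSpotConfig",
    "NucleusTruth",
    "GroundTruth",
    "PlacementError",
    "DEFAULT_STAINS",
    "generate_spot",
    "render_stains",
    "perturb_mask",
    "study_scale_config",
]

# Published Ruifrok–Johnston OD triplets for haematoxylin and DAB,
# the de-facto standard basis for H-DAB colour separation.
_RJ_HAEMATOXYLIN = (0.650, 0.704, 0.286)
_RJ_DAB = (0.268, 0.570, 0.776)


@dataclass(frozen=True)
class StainModel:
    """Stain OD basis: unit absorbance vectors per RGB channel plus background.

    ``od_vector_haematoxylin`` and ``od_vector_dab`` are unit 3-vectors of
    optical density contributions per RGB channel; ``background_rgb`` is the
    unstained (glass) intensity.
    """

    od_vector_haematoxylin: tuple[float, float, float] = _RJ_HAEMATOXYLIN
    od_vector_dab: tuple[float, float, float] = _RJ_DAB
    background_rgb: tuple[float, float, float] = (255.0, 255.0, 255.0)

    def __post_init__(self) -> None:
        vh = np.asarray(self.od_vector_haematoxylin, float)
        vd = np.asarray(self.od_vector_dab, float)
        for name, v in (("haematoxylin", vh), ("dab", vd)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                object.__setattr__(
                    self,
                    f"od_vector_{'haematoxylin' if name == 'haematoxylin' else 'dab'}",
                    tuple(v / np.linalg.norm(v)),
                )
        vh = np.asarray(self.od_vector_haematoxylin, float)
        vd = np.asarray(self.od_vector_dab, float)
        cosang = float(np.clip(np.dot(vh, vd), -1.0, 1.0))
        if np.degrees(np.arccos(cosang)) <= 10.0:
            raise ValueError("stain OD vectors are nearly collinear (angle <= 10 deg)")
        if any(not (0 <= b <= 255) for b in self.background_rgb):
            raise ValueError("background_rgb values must lie in [0, 255]")

    @property
    def basis(self) -> np.ndarray:
        """3x2 matrix with stain OD vectors as columns (haem, DAB)."""
        return np.stack(
            [self.od_vector_haematoxylin, self.od_vector_dab], axis=1
        ).astype(float)

    @property
    def residual_vector(self) -> np.ndarray:
        """Unit vector orthogonal to both stain vectors (residual channel)."""
        r = np.cross(self.od_vector_haematoxylin, self.od_vector_dab)
        return r / np.linalg.norm(r)


DEFAULT_STAINS = StainModel()

# Default per-nucleus intensity thresholds used to place programmed DAB OD at
# bin midpoints; kept in sync with tmascore.scoring.DEFAULT_INTENSITY_THRESHOLDS.
_BIN_MIDPOINT_OD = {0: 0.0, 1: 0.275, 2: 0.55, 3: 0.95}


class PlacementError(RuntimeError):
    """Nucleus placement failed: requested density infeasible for a compartment."""


@dataclass
class SyntheticSpotConfig:
    """Programmed content of one synthetic spot.

    Defaults mirror the imaging conditions of the study design this package
    emulates: ~3000-pixel spot diameter at 0.25 um/px (x40-equivalent
    scanning).  Tests and the bundled study configuration use a scaled-down
    600 px spot at 1.0 um/px (a 0.6 mm core) via :func:`study_scale_config`;
    the generator is scale-invariant because all sizes are in micrometres.
    """

    diameter_px: int = 3000
    pixel_size_um: float = 0.25
    tumour_fraction: float = 0.30
    n_tumour_regions: int = 3
    #: nuclei per mm^2 of each compartment
    nucleus_density_per_mm2: dict = field(
        default_factory=lambda: {
            "tumour": 3000.0,
            "normal_epithelium": 2000.0,
            "lymphocyte": 8000.0,
            "stroma_cell": 800.0,
        }
    )
    programmed_percent_positive: float = 50.0
    programmed_intensity_bin: int = 2
    nucleus_radius_um: dict = field(
        default_factory=lambda: {
            "tumour": 5.0,
            "normal_epithelium": 4.0,
            "lymphocyte": 3.0,
            "stroma_cell": 3.0,
        }
    )
    #: fraction of the spot occupied by lymphocyte fields / normal epithelium
    lymphocyte_field_fraction: float = 0.10
    normal_epithelium_fraction: float = 0.10
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0.0 <= self.tumour_fraction <= 1.0:
            raise ValueError("tumour_fraction must lie in [0, 1]")
        if self.n_tumour_regions < 1:
            raise ValueError("n_tumour_regions must be positive")
        if not 0.0 <= self.programmed_percent_positive <= 100.0:
            raise ValueError("programmed_percent_positive must lie in [0, 100]")
        if self.programmed_intensity_bin not in (0, 1, 2, 3):
            raise ValueError("programmed_intensity_bin must be one of {0,1,2,3}")
        if self.programmed_percent_positive == 0 and self.programmed_intensity_bin != 0:
            raise ValueError(
                "programmed_intensity_bin must be 0 when programmed_percent_positive is 0"
            )
        if self.programmed_percent_positive > 0 and self.programmed_intensity_bin == 0:
            raise ValueError(
                "programmed_intensity_bin must be >= 1 when positive nuclei are programmed"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpotConfig":
        return cls(**d)


def study_scale_config(**overrides) -> SyntheticSpotConfig:
    """A 600 px spot at 1.0 um/px: a 0.6 mm core at reduced resolution.

    This is the geometry used throughout the test suite and the bundled
    study configuration; it keeps full spots affordable while preserving
    realistic physical densities and nucleus sizes.
    """
    params = dict(diameter_px=600, pixel_size_um=1.0)
    params.update(overrides)
    return SyntheticSpotConfig(**params)


@dataclass
class NucleusTruth:
    row: float
    col: float
    compartment: str
    is_positive: bool
    programmed_dab_od: float


@dataclass
class GroundTruth:
    """Exact content of a generated spot: mask, nuclei and programmed score."""

    mask: LabelMask
    nuclei: list[NucleusTruth]
    percent_positive_tumour: float
    compartments: np.ndarray | None = None  # per-pixel compartment codes

    @property
    def tumour_nuclei(self) -> list[NucleusTruth]:
        return [n for n in self.nuclei if n.compartment == "tumour"]


def render_stains(
    haem_od_map: np.ndarray,
    dab_od_map: np.ndarray,
    stains: StainModel = DEFAULT_STAINS,
    pixel_size_um: float = 0.25,
    inside_spot: np.ndarray | None = None,
) -> SpotImage:
    """Beer–Lambert forward rendering of haematoxylin/DAB OD maps to 8-bit RGB.

    Per pixel and channel ``c`` the value is
    ``round(background[c] * 10**(-(haem_od*v_h[c] + dab_od*v_d[c])))`` clipped
    to [0, 255].
    """
    haem = np.asarray(haem_od_map, float)
    dab = np.asarray(dab_od_map, float)
    if haem.shape != dab.shape:
        raise ValueError("OD maps must have the same shape")
    if (haem < 0).any() or (dab < 0).any():
        raise ValueError("OD maps must be non-negative")
    vh = np.asarray(stains.od_vector_haematoxylin)
    vd = np.asarray(stains.od_vector_dab)
    od = haem[..., None] * vh + dab[..., None] * vd
    bg = np.asarray(stains.background_rgb, float)
    rgb = np.clip(np.rint(bg * 10.0 ** (-od)), 0, 255).astype(np.uint8)
    if inside_spot is None:
        inside_spot = np.ones(haem.shape, dtype=bool)
    return SpotImage(rgb, pixel_size_um, inside_spot)


# ---------------------------------------------------------------------------
# spot generation

_COMPARTMENT_CODES = {
    "stroma": 1,
    "normal_epithelium": 2,
    "lymphocyte": 3,
    "tumour": 4,
}


def _inscribed_disc(d: int) -> np.ndarray:
    c = (d - 1) / 2.0
    ii, jj = np.mgrid[0:d, 0:d]
    return (ii - c) ** 2 + (jj - c) ** 2 <= c**2


def _blob_field(shape, centres, sigmas, weights) -> np.ndarray:
    ii, jj = np.mgrid[0 : shape[0], 0 : shape[1]]
    f = np.zeros(shape, float)
    for (r, c), s, w in zip(centres, sigmas, weights):
        f += w * np.exp(-(((ii - r) ** 2 + (jj - c) ** 2) / (2.0 * s**2)))
    return f


def _threshold_at_fraction(field: np.ndarray, region: np.ndarray, frac: float) -> np.ndarray:
    """Select the top ``frac`` of ``region`` pixels by field value."""
    out = np.zeros(field.shape, bool)
    n = int(region.sum())
    k = int(round(frac * n))
    if k <= 0:
        return out
    vals = field[region]
    if k >= n:
        out[region] = True
        return out
    thr = np.partition(vals, n - k)[n - k]
    out[region] = vals >= thr
    # ties at the threshold can overshoot; trim deterministically
    excess = int(out.sum()) - k
    if excess > 0:
        rr, cc = np.nonzero(out & (np.abs(field - thr) < 1e-12))
        out[rr[:excess], cc[:excess]] = False
    return out


def _place_nuclei(
    rng: np.random.Generator,
    compartment_px: np.ndarray,
    n_target: int,
    min_sep_px: float,
    name: str,
) -> np.ndarray:
    """Dart-throw ``n_target`` centres onto the compartment with min separation.

    Candidates are the compartment's own pixels in seeded random order; the
    candidate list is the bounded retry budget, so an infeasible density
    raises :class:`PlacementError` naming the compartment.
    """
    if n_target == 0:
        return np.empty((0, 2), int)
    coords = np.argwhere(compartment_px)
    if coords.shape[0] == 0:
        raise PlacementError(
            f"cannot place {n_target} nuclei: compartment '{name}' has no pixels"
        )
    rng.shuffle(coords, axis=0)
    blocked = np.zeros(compartment_px.shape, bool)
    sep = max(1, int(np.ceil(min_sep_px)))
    foot = disc_footprint(2 * sep + 1)
    fr = sep
    accepted = []
    H, W = compartment_px.shape
    for r, c in coords:
        if blocked[r, c]:
            continue
        accepted.append((r, c))
        if len(accepted) == n_target:
            break
        r0, r1 = max(0, r - fr), min(H, r + fr + 1)
        c0, c1 = max(0, c - fr), min(W, c + fr + 1)
        blocked[r0:r1, c0:c1] |= foot[
            fr - (r - r0) : fr + (r1 - r), fr - (c - c0) : fr + (c1 - c)
        ]
    if len(accepted) < n_target:
        raise PlacementError(
            f"nucleus placement failed for compartment '{name}': "
            f"placed {len(accepted)} of {n_target} at the requested density"
        )
    return np.asarray(accepted, int)


def _ellipse_kernel(
    rng: np.random.Generator, radius_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Random elliptical OD kernel with unit mean over its support.

    Flat core with a linear taper over the outer quarter of the radius; the
    kernel is normalised so that scaling by a target OD makes the *mean* OD
    over the nucleus footprint equal that target.
    """
    a = radius_px * rng.uniform(0.9, 1.1)
    b = radius_px * rng.uniform(0.75, 1.0)
    theta = rng.uniform(0, np.pi)
    half = int(np.ceil(max(a, b))) + 1
    ii, jj = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    ct, st = np.cos(theta), np.sin(theta)
    u = np.sqrt(((ii * ct + jj * st) / a) ** 2 + ((-ii * st + jj * ct) / b) ** 2)
    support = u <= 1.0
    prof = np.where(u <= 0.85, 1.0, np.clip((1.0 - u) / 0.15, 0.0, 1.0))
    prof[~support] = 0.0
    mean = prof[support].mean()
    return prof / mean, support


_HAEM_MEAN_OD_NEGATIVE = 0.70  # blue nuclei
_HAEM_MEAN_OD_POSITIVE = 0.35  # counterstain under DAB


def generate_spot(
    config: SyntheticSpotConfig, stains: StainModel = DEFAULT_STAINS
) -> tuple[SpotImage, GroundTruth]:
    """Generate one synthetic spot image with its exact ground truth.

    Deterministic in ``(config, stains)``: a single seeded random stream
    drives region layout, nucleus placement and noise, so identical inputs
    give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    d = config.diameter_px
    inside = _inscribed_disc(d)
    n_inside = int(inside.sum())
    shape = (d, d)

    # --- region layout -----------------------------------------------------
    centre = (d - 1) / 2.0
    r_spot = centre

    def _random_centres(k, max_frac=0.65):
        rad = r_spot * np.sqrt(rng.uniform(0, max_frac**2, k))
        ang = rng.uniform(0, 2 * np.pi, k)
        return np.stack([centre + rad * np.sin(ang), centre + rad * np.cos(ang)], 1)

    tum_field = _blob_field(
        shape,
        _random_centres(config.n_tumour_regions),
        sigmas=rng.uniform(0.12, 0.25, config.n_tumour_regions) * d,
        weights=rng.uniform(0.8, 1.2, config.n_tumour_regions),
    )
    # irregular boundaries
    rough = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=d / 25.0)
    rough /= max(np.abs(rough).max(), 1e-12)
    tum_field = tum_field + 0.08 * tum_field.max() * rough
    tumour = _threshold_at_fraction(tum_field, inside, config.tumour_fraction)

    non_t = inside & ~tumour
    lymph_field = _blob_field(
        shape, _random_centres(2, 0.8), sigmas=rng.uniform(0.06, 0.12, 2) * d,
        weights=rng.uniform(0.8, 1.2, 2),
    )
    lymph_frac = min(
        config.lymphocyte_field_fraction * n_inside / max(int(non_t.sum()), 1), 1.0
    )
    lymph = _threshold_at_fraction(lymph_field, non_t, lymph_frac)

    rest = non_t & ~lymph
    norm_field = _blob_field(
        shape, _random_centres(3, 0.8), sigmas=rng.uniform(0.05, 0.10, 3) * d,
        weights=rng.uniform(0.8, 1.2, 3),
    )
    norm_frac = min(
        config.normal_epithelium_fraction * n_inside / max(int(rest.sum()), 1), 1.0
    )
    normal = _threshold_at_fraction(norm_field, rest, norm_frac)
    stroma = rest & ~normal

    compartments = np.zeros(shape, np.uint8)
    compartments[stroma] = _COMPARTMENT_CODES["stroma"]
    compartments[normal] = _COMPARTMENT_CODES["normal_epithelium"]
    compartments[lymph] = _COMPARTMENT_CODES["lymphocyte"]
    compartments[tumour] = _COMPARTMENT_CODES["tumour"]

    labels = np.full(shape, OUTSIDE, np.uint8)
    labels[inside] = N
    labels[tumour] = T
    mask = LabelMask(labels)

    # --- nuclei ------------------------------------------------------------
    px_area_mm2 = (config.pixel_size_um * 1e-3) ** 2
    comp_px = {
        "tumour": tumour,
        "normal_epithelium": normal,
        "lymphocyte": lymph,
        "stroma_cell": stroma,
    }
    nuclei: list[NucleusTruth] = []
    centres_by_comp: dict[str, np.ndarray] = {}
    for name, px in comp_px.items():
        density = config.nucleus_density_per_mm2.get(name, 0.0)
        n_target = int(round(density * px.sum() * px_area_mm2))
        radius_px = config.nucleus_radius_um[name] / config.pixel_size_um
        centres = _place_nuclei(rng, px, n_target, 2.2 * radius_px, name)
        centres_by_comp[name] = centres

    n_tum = centres_by_comp["tumour"].shape[0]
    n_pos = int(round(config.programmed_percent_positive / 100.0 * n_tum))
    pos_od = _BIN_MIDPOINT_OD[config.programmed_intensity_bin]
    for name, centres in centres_by_comp.items():
        for k, (r, c) in enumerate(centres):
            positive = name == "tumour" and k < n_pos
            nuclei.append(
                NucleusTruth(
                    row=float(r),
                    col=float(c),
                    compartment=name,
                    is_positive=bool(positive),
                    programmed_dab_od=pos_od if positive else 0.0,
                )
            )
    pct_pos = 100.0 * n_pos / n_tum if n_tum else 0.0

    # --- rendering ---------------------------------------------------------
    haem_od = np.zeros(shape, float)
    dab_od = np.zeros(shape, float)
    H, W = shape
    for nuc in nuclei:
        radius_px = config.nucleus_radius_um[nuc.compartment] / config.pixel_size_um
        kern, _ = _ellipse_kernel(rng, radius_px)
        kh = kern.shape[0] // 2
        r, c = int(nuc.row), int(nuc.col)
        r0, r1 = max(0, r - kh), min(H, r + kh + 1)
        c0, c1 = max(0, c - kh), min(W, c + kh + 1)
        sub = kern[kh - (r - r0) : kh + (r1 - r), kh - (c - c0) : kh + (c1 - c)]
        haem_mean = (
            _HAEM_MEAN_OD_POSITIVE if nuc.is_positive else _HAEM_MEAN_OD_NEGATIVE
        )
        haem_od[r0:r1, c0:c1] += haem_mean * sub
        if nuc.programmed_dab_od > 0:
            dab_od[r0:r1, c0:c1] += nuc.programmed_dab_od * sub

    # low-amplitude stroma texture so background statistics are non-degenerate
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6.0)
    tex = (tex - tex.min()) / max(tex.max() - tex.min(), 1e-12)
    haem_od += 0.04 * tex * inside
    # confluent epithelium stains visibly darker than collagenous stroma even
    # between nuclei; this gives region boundaries a real image edge
    epith_bg = (
        0.10 * (compartments == _COMPARTMENT_CODES["tumour"])
        + 0.08 * (compartments == _COMPARTMENT_CODES["normal_epithelium"])
        + 0.05 * (compartments == _COMPARTMENT_CODES["lymphocyte"])
    )
    haem_od += ndimage.gaussian_filter(epith_bg, sigma=1.5)

    image = render_stains(
        haem_od, dab_od, stains, pixel_size_um=config.pixel_size_um, inside_spot=inside
    )
    rgb = image.pixels.astype(float)
    # pinkish (eosinophilic) tint modulated by the same texture field
    rgb[..., 1] -= 14.0 * tex * inside
    rgb[..., 2] -= 5.0 * tex * inside
    if config.noise_sd > 0:
        rgb += rng.normal(0.0, config.noise_sd, rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    rgb[~inside] = np.rint(stains.background_rgb).astype(np.uint8)  # sentinel
    image = SpotImage(rgb, config.pixel_size_um, inside)

    truth = GroundTruth(
        mask=mask,
        nuclei=nuclei,
        percent_positive_tumour=pct_pos,
        compartments=compartments,
    )
    return image, truth


# ---------------------------------------------------------------------------
# annotator-variation perturbations

_PERTURB_MODES = ("boundary_jitter", "region_resize", "component_flip")


def perturb_mask(
    mask: LabelMask,
    mode: str,
    magnitude_px: int,
    seed: int,
    direction: str | None = None,
) -> LabelMask:
    """Fabricate annotator variation by perturbing a label mask.

    ``boundary_jitter`` displaces T/N boundaries by at most ``magnitude_px``
    (small magnitudes yield thin, Type-1-style disagreements);
    ``region_resize`` dilates or erodes whole tumour components by
    ``magnitude_px`` (extent disagreements, Type 2); ``component_flip`` adds
    or deletes an entire tumour component of diameter >= ``magnitude_px``
    (presence/absence disagreements, Type 3).  OUTSIDE pixels are never
    modified.  Deterministic in ``(mask, mode, magnitude_px, seed)``.
    """
    if mode not in _PERTURB_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_PERTURB_MODES}")
    if magnitude_px < 1:
        raise ValueError("magnitude_px must be >= 1")
    rng = np.random.default_rng(seed)
    labels = mask.labels
    inside = labels != OUTSIDE
    t_mask = labels == T

    if mode == "boundary_jitter":
        new_t = _jitter(rng, t_mask, inside, magnitude_px)
    elif mode == "region_resize":
        if not t_mask.any():
            raise ValueError("region_resize requires at least one T component")
        new_t = _resize_components(rng, t_mask, inside, magnitude_px)
    else:  # component_flip
        if direction is None:
            if not t_mask.any():
                direction = "add"
            else:
                direction = "add" if rng.random() < 0.5 else "delete"
        if direction not in ("add", "delete"):
            raise ValueError("direction must be 'add' or 'delete'")
        if direction == "delete" and not t_mask.any():
            raise ValueError("component_flip(delete) requires at least one T component")
        new_t = _flip_component(rng, t_mask, inside, magnitude_px, direction)

    out = np.full(labels.shape, OUTSIDE, labels.dtype)
    out[inside] = N
    out[new_t & inside] = T
    return LabelMask(out)


def _jitter(rng, t_mask, inside, magnitude):
    if not t_mask.any() or not (inside & ~t_mask).any():
        return t_mask.copy()  # no T/N boundary to move
    signed = ndimage.distance_transform_edt(t_mask) - ndimage.distance_transform_edt(
        ~t_mask
    )
    f = ndimage.gaussian_filter(rng.standard_normal(t_mask.shape), sigma=2.0 * magnitude)
    f *= (magnitude / 1.5) / max(float(f.std()), 1e-12)
    f = np.clip(f, -magnitude, magnitude)
    # a pixel can only flip if it lies within magnitude of the boundary
    return (signed + f) > 0


def _resize_components(rng, t_mask, inside, magnitude):
    lab, n = ndimage.label(t_mask, structure=np.ones((3, 3), int))
    foot = disc_footprint(2 * magnitude + 1)
    new_t = np.zeros_like(t_mask)
    for i in range(1, n + 1):
        comp = lab == i
        if rng.random() < 0.5:
            comp = ndimage.binary_dilation(comp, structure=foot) & inside
        else:
            comp = ndimage.binary_erosion(comp, structure=foot)
        new_t |= comp
    return new_t


def _flip_component(rng, t_mask, inside, magnitude, direction):
    if direction == "delete":
        lab, n = ndimage.label(t_mask, structure=np.ones((3, 3), int))
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        diam = 2.0 * np.sqrt(np.asarray(sizes) / np.pi)
        eligible = np.nonzero(diam >= magnitude)[0]
        if eligible.size == 0:
            raise ValueError(
                f"no T component has diameter >= {magnitude} px to delete"
            )
        pick = int(rng.choice(eligible)) + 1
        return t_mask & (lab != pick)
    # add: a disc of diameter >= magnitude on N pixels, disjoint from existing T
    diameter = max(int(magnitude), 3)
    diameter = int(rng.integers(diameter, 2 * diameter + 1))
    foot = disc_footprint(diameter)
    size = foot.shape[0]
    half = size // 2
    candidates = np.argwhere(inside & ~t_mask)
    if candidates.shape[0] == 0:
        raise ValueError("no in-spot N pixels available to add a component")
    H, W = t_mask.shape
    order = rng.permutation(candidates.shape[0])
    grown_t = ndimage.binary_dilation(t_mask, structure=disc_footprint(3))
    for idx in order[: min(500, order.size)]:
        r, c = candidates[idx]
        r0, c0 = r - half, c - half
        if r0 < 0 or c0 < 0 or r0 + size > H or c0 + size > W:
            continue
        window_inside = inside[r0 : r0 + size, c0 : c0 + size]
        window_t = grown_t[r0 : r0 + size, c0 : c0 + size]
        if (foot & ~window_inside).any() or (foot & window_t).any():
            continue
        new_t = t_mask.copy()
        new_t[r0 : r0 + size, c0 : c0 + size] |= foot
        return new_t
    raise ValueError("could not place a new T component disjoint from existing tumour")
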