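"""Synthetic trichrome-like gonad cross-section phantoms with ground truth.

The study design this package serves quantifies reproductive effort on
scanned oyster gonad sections, but such scans are rarely shareable. The
phantom generator therefore renders a cartoon of a Prenant-Gabe trichrome
section — a tissue blob on a white slide background containing elliptical
gonadal tubules and a storage-tissue region, each class with its own color
distribution — together with exact ground-truth masks, so that every
downstream stage (segmentation, morphometry, indices) can be validated
quantitatively.

Geometry is built from a normalized elliptic radius field: a region of a
target pixel area is the set of the k smallest field values inside its
parent region. This makes the true area fractions (and hence the true
GTI/TAI) exact by construction rather than approximate targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import draw as skdraw

from .preprocess import RGBImage

__all__ = [
    "DEFAULT_PALETTE",
    "STAGE_GTI_PERCENT",
    "PhantomSpec",
    "PhantomTruth",
    "PlacementError",
    "generate_phantom",
    "truth_metrics",
    "stage_phantom_spec",
]

# Mean RGB and per-channel sd per tissue class, approximating a
# Prenant-Gabe trichrome: white slide background, pale-pink connective
# tissue, pink-orange storage tissue, blue-violet gonadal tubules. The
# classes are separable both in HSI intensity (background vs tissue) and
# in L*/a* (tubules vs the rest), which is what the segmentation exploits.
DEFAULT_PALETTE: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "background": ((245.0, 245.0, 245.0), (3.0, 3.0, 3.0)),
    "connective": ((230.0, 180.0, 190.0), (6.0, 6.0, 6.0)),
    "storage": ((235.0, 160.0, 140.0), (6.0, 6.0, 6.0)),
    "tubule": ((120.0, 90.0, 160.0), (6.0, 6.0, 6.0)),
}

# Printed per-(ploidy, stage) gonadal-area shares of the whole cross
# section (GTI, %) used by the stage presets. Stage 0 is "around 10-15%"
# for all classes; stages 1 and 3 are class-specific.
STAGE_GTI_PERCENT: dict[tuple[str, int], float] = {
    ("2n", 0): 12.5,
    ("3n_alpha", 0): 12.5,
    ("3n_beta", 0): 12.5,
    ("2n", 1): 20.0,
    ("3n_alpha", 1): 17.0,
    ("3n_beta", 1): 10.0,
    ("2n", 3): 85.0,
    ("3n_alpha", 3): 71.0,
    ("3n_beta", 3): 23.0,
}


class PlacementError(RuntimeError):
    """Raised when a tubule cannot be placed within the attempt budget."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic section.

    ``tubule_semi_axis_um`` gives the (location, scale) of the log-normal
    distribution of the tubule minor semi-axis, in microns; the major
    semi-axis is the minor times an aspect ratio drawn uniformly from
    ``aspect_ratio_range``. ``st_fraction`` is the target storage-tissue
    share of the tissue blob; if ``ga_fraction`` is set instead, an
    explicit gonadal-area region of that share of the blob is drawn,
    tubules are placed inside it and storage tissue fills its remainder,
    so the true gonadal fraction is controlled exactly.
    ``min_separation_um`` is the smallest allowed gap between tubules.
    """

    height_px: int
    width_px: int
    microns_per_pixel: float = 2.0
    n_tubules: int = 12
    tubule_semi_axis_um: tuple[float, float] = (np.log(12.0), 0.2)
    aspect_ratio_range: tuple[float, float] = (1.0, 1.5)
    st_fraction: float = 0.15
    tissue_fraction: float = 0.5
    ga_fraction: Optional[float] = None
    class_palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    noise_sd: float = 8.0
    min_separation_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.n_tubules < 0:
            raise ValueError("n_tubules must be non-negative")
        if not (0 <= self.st_fraction < 1):
            raise ValueError("st_fraction must be in [0, 1)")
        if not (0 < self.tissue_fraction <= 1):
            raise ValueError("tissue_fraction must be in (0, 1]")
        if self.ga_fraction is not None and not (0 <= self.ga_fraction < 1):
            raise ValueError("ga_fraction must be in [0, 1)")
        lo, hi = self.aspect_ratio_range
        if lo < 1 or hi < lo:
            raise ValueError("aspect_ratio_range must satisfy 1 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("background", "connective", "storage", "tubule"):
            if name not in self.class_palette:
                raise ValueError(f"class_palette missing class {name!r}")
            mean, sd = self.class_palette[name]
            if any(not (0 <= m <= 255) for m in mean):
                raise ValueError(f"palette mean for {name!r} outside [0, 255]")
            if any(s < 0 for s in sd):
                raise ValueError(f"palette sd for {name!r} negative")


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: masks, tubule geometry, true indices."""

    whole_mask: np.ndarray
    gt_mask: np.ndarray
    st_mask: np.ndarray
    tubule_params: list[tuple[float, float, float, float, float]]
    true_gti: float
    true_tai: float
    true_n_tubules: int
    true_mean_tubule_area_um2: Optional[float]

    def validate(self) -> None:
        if not (self.whole_mask.shape == self.gt_mask.shape == self.st_mask.shape):
            raise ValueError("truth masks must share a shape")
        if (self.gt_mask & ~self.whole_mask).any():
            raise ValueError("gt_mask must be contained in whole_mask")
        if (self.st_mask & ~self.whole_mask).any():
            raise ValueError("st_mask must be contained in whole_mask")
        if (self.gt_mask & self.st_mask).any():
            raise ValueError("gt_mask and st_mask must be disjoint")
        if self.true_n_tubules != len(self.tubule_params):
            raise ValueError("true_n_tubules inconsistent with tubule_params")


def _radius_field(shape: tuple[int, int], aspect: float = 1.15) -> np.ndarray:
    """Normalized elliptic radius about the frame center.

    Level sets are concentric ellipses with a fixed mild aspect; the set of
    the k smallest values within a parent region is the unique elliptic
    region of exactly k pixels, nested across k.
    """
    h, w = shape
    rows = (np.arange(h) - (h - 1) / 2.0) / h
    cols = (np.arange(w) - (w - 1) / 2.0) / w
    rr = (rows * aspect)[:, None] ** 2
    cc = (cols / aspect)[None, :] ** 2
    return rr + cc


def _region_of_area(fieldvals: np.ndarray, parent: np.ndarray, area_px: int) -> np.ndarray:
    """The ``area_px`` smallest-field pixels inside ``parent``, as a mask."""
    out = np.zeros(parent.shape, dtype=bool)
    if area_px <= 0:
        return out
    vals = fieldvals[parent]
    if area_px >= vals.size:
        return parent.copy()
    thresh = np.partition(vals, area_px - 1)[area_px - 1]
    cand = parent & (fieldvals <= thresh)
    # resolve ties so the pixel count is exact
    excess = int(cand.sum()) - area_px
    if excess > 0:
        tie_idx = np.flatnonzero(cand.ravel() & (fieldvals.ravel() == thresh))
        cand.ravel()[tie_idx[-excess:]] = False
    return cand


def _ellipse_pixels(
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    angle: float,
    shape: tuple[int, int],
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Pixel coordinates of a rotated ellipse, or None if it leaves the frame."""
    rr, cc = skdraw.ellipse(center[0], center[1], semi_major, semi_minor, rotation=angle)
    if rr.size == 0:
        return None
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        return None
    return rr, cc


def generate_phantom(spec: PhantomSpec) -> tuple[RGBImage, PhantomTruth]:
    """Render a phantom section and its exact ground truth.

    Deterministic for a fixed spec (including its seed). Tubules are
    ellipses placed by rejection sampling: fully inside their allowed
    region, pairwise separated by at least ``min_separation_um``.

    Raises :class:`PlacementError` if a tubule cannot be placed within
    1000 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)
    fieldvals = _radius_field(shape)

    n_frame = shape[0] * shape[1]
    blob_px = int(round(spec.tissue_fraction * n_frame))
    whole = _region_of_area(fieldvals, np.ones(shape, dtype=bool), blob_px)
    blob_area = int(whole.sum())

    if spec.ga_fraction is not None:
        ga_px = int(round(spec.ga_fraction * blob_area))
        ga_region = _region_of_area(fieldvals, whole, ga_px)
        allowed = ga_region
    else:
        ga_region = None
        allowed = whole

    gt = np.zeros(shape, dtype=bool)
    tubule_params: list[tuple[float, float, float, float, float]] = []
    tubule_areas_px: list[int] = []
    sep_px = spec.min_separation_um / spec.microns_per_pixel

    if spec.n_tubules > 0:
        rows_any, cols_any = np.nonzero(allowed)
        if rows_any.size == 0:
            raise PlacementError("tubule 0: allowed region is empty")
        r0, r1 = rows_any.min(), rows_any.max()
        c0, c1 = cols_any.min(), cols_any.max()
        for i in range(spec.n_tubules):
            placed = False
            for _ in range(1000):
                u, v = rng.uniform(size=2)
                semi_minor = rng.lognormal(*spec.tubule_semi_axis_um) / spec.microns_per_pixel
                aspect = rng.uniform(*spec.aspect_ratio_range)
                angle = rng.uniform(0, np.pi)
                semi_major = semi_minor * aspect
                center = (r0 + u * (r1 - r0), c0 + v * (c1 - c0))
                px = _ellipse_pixels(center, semi_major, semi_minor, angle, shape)
                if px is None:
                    continue
                rr, cc = px
                if not allowed[rr, cc].all():
                    continue
                # expanded footprint enforces the separation gap
                rr_e, cc_e = skdraw.ellipse(
                    center[0], center[1], semi_major + sep_px, semi_minor + sep_px,
                    rotation=angle, shape=shape,
                )
                if gt[rr_e, cc_e].any():
                    continue
                gt[rr, cc] = True
                tubule_params.append((center[0], center[1], semi_major, semi_minor, angle))
                tubule_areas_px.append(rr.size)
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"tubule {i}: no valid placement after 1000 attempts"
                )

    if ga_region is not None:
        st = ga_region & ~gt
    else:
        st_px = int(round(spec.st_fraction * blob_area))
        st = _region_of_area(fieldvals, whole & ~gt, st_px)

    # class index map: 0 background, 1 connective, 2 storage, 3 tubule
    class_map = np.zeros(shape, dtype=np.uint8)
    class_map[whole] = 1
    class_map[st] = 2
    class_map[gt] = 3
    names = ("background", "connective", "storage", "tubule")
    means = np.array([spec.class_palette[n][0] for n in names])
    sds = np.array([spec.class_palette[n][1] for n in names])
    img = means[class_map] + sds[class_map] * rng.standard_normal(shape + (3,))
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(shape + (3,))
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    mpp2 = spec.microns_per_pixel**2
    whole_area = float(whole.sum())
    ga_area = float((gt | st).sum())
    gt_area = float(gt.sum())
    truth = PhantomTruth(
        whole_mask=whole,
        gt_mask=gt,
        st_mask=st,
        tubule_params=tubule_params,
        true_gti=100.0 * ga_area / whole_area if whole_area else 0.0,
        true_tai=100.0 * gt_area / whole_area if whole_area else 0.0,
        true_n_tubules=len(tubule_params),
        true_mean_tubule_area_um2=(
            float(np.mean(tubule_areas_px)) * mpp2 if tubule_areas_px else None
        ),
    )
    truth.validate()
    return RGBImage(pixels=pixels, microns_per_pixel=spec.microns_per_pixel), truth


def truth_metrics(truth: PhantomTruth, microns_per_pixel: float):
    """Section metrics computed directly from ground-truth masks.

    Bypasses segmentation entirely (GA = GT union ST, no morphology); used
    as the oracle against which the estimated pipeline output is compared.
    """
    from .indices import SectionMetrics, compute_gti, compute_tai

    truth.validate()
    whole_area = int(truth.whole_mask.sum())
    gt_area = int(truth.gt_mask.sum())
    st_area = int(truth.st_mask.sum())
    ga_area = int((truth.gt_mask | truth.st_mask).sum())
    if whole_area == 0:
        raise ValueError("whole mask is empty")
    mpp2 = microns_per_pixel**2
    return SectionMetrics(
        whole_area_px=whole_area,
        ga_area_px=ga_area,
        gt_area_px=gt_area,
        st_area_px=st_area,
        whole_area_um2=whole_area * mpp2,
        ga_area_um2=ga_area * mpp2,
        gt_area_um2=gt_area * mpp2,
        st_area_um2=st_area * mpp2,
        gti_percent=compute_gti(ga_area, whole_area),
        tai_percent=compute_tai(gt_area, whole_area),
        n_tubules=truth.true_n_tubules,
        mean_area_per_tubule_um2=truth.true_mean_tubule_area_um2,
    )


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean of a boolean mask: per-block class fraction in [0, 1].

    Trailing rows/columns that do not fill a block are dropped, matching
    how pure-block training labels are extracted.
    """
    if factor == 1:
        return mask.astype(float)
    h, w = mask.shape
    hh, ww = h // factor, w // factor
    return (
        mask[: hh * factor, : ww * factor]
        .reshape(hh, factor, ww, factor)
        .mean(axis=(1, 3))
    )


def phantom_training_classes(
    truth: PhantomTruth, factor: int, purity: float = 0.999
) -> dict[str, np.ndarray]:
    """Per-class pure-pixel masks of a phantom at the analysis scale.

    A downsampled pixel is labeled only when its source block is purely one
    class (fraction >= ``purity``), so color-mixed boundary pixels never
    enter the classifier's training set.
    """
    w = downsample_mask(truth.whole_mask, factor)
    g = downsample_mask(truth.gt_mask, factor)
    s = downsample_mask(truth.st_mask, factor)
    return {
        "background": w == 0,
        "tubule": g >= purity,
        "storage": s >= purity,
        "connective": (w >= purity) & (g == 0) & (s == 0),
    }


def phantom_reference_and_model(spec: PhantomSpec, downsample_factor: int = 8, seed: int = 0):
    """Color reference and trained ST classifier from a training phantom.

    Renders the phantom, downsamples it to the analysis scale, takes its
    Lab statistics as the normalization reference, and fits the storage
    pixel classifier on its pure-block ground-truth labels. Use a spec
    seed disjoint from the analysis phantoms.
    """
    from .preprocess import ColorReference, downsample
    from .segmentation import fit_st_classifier_from_masks

    image, truth = generate_phantom(spec)
    ds = downsample(image, downsample_factor)
    classes = phantom_training_classes(truth, downsample_factor)
    model = fit_st_classifier_from_masks(ds, classes, seed=seed)
    return ColorReference.from_image(ds), model


def stage_phantom_spec(
    ploidy_class: str,
    stage: int,
    size_px: int = 1024,
    microns_per_pixel: float = 0.25,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> PhantomSpec:
    """Named phantom preset for a (ploidy class, stage) combination.

    The true gonadal-area share of the cross section equals the GTI
    reported for that group (see :data:`STAGE_GTI_PERCENT`). Tubule count
    and size scale with the gonadal region so placement always succeeds;
    the spatial arrangement is uniform at random, a modeling choice (real
    tubules cluster around the digestive gland).
    """
    key = (ploidy_class, stage)
    if key not in STAGE_GTI_PERCENT:
        raise KeyError(
            f"no preset for ploidy {ploidy_class!r} stage {stage}; "
            f"known: {sorted(STAGE_GTI_PERCENT)}"
        )
    ga_fraction = STAGE_GTI_PERCENT[key] / 100.0
    tissue_fraction = 0.5
    blob_area = tissue_fraction * size_px * size_px
    r_ga_um = np.sqrt(ga_fraction * blob_area / np.pi) * microns_per_pixel
    semi_minor_um = 0.15 * r_ga_um
    return PhantomSpec(
        height_px=size_px,
        width_px=size_px,
        microns_per_pixel=microns_per_pixel,
        n_tubules=6,
        tubule_semi_axis_um=(float(np.log(semi_minor_um)), 0.12),
        aspect_ratio_range=(1.0, 1.3),
        tissue_fraction=tissue_fraction,
        ga_fraction=ga_fraction,
        noise_sd=noise_sd,
        min_separation_um=max(2.0 * microns_per_pixel, 0.08 * r_ga_um),
        seed=seed,
    )
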