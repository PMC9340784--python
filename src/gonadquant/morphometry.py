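"""Per-tubule morphometry and the Gravelius circularity filter.

Tubule cross sections are the 8-connected components of the gonadal-tubule
mask. Each is measured (area, Crofton perimeter, moment axes, centroid)
and scored with the Gravelius compactness coefficient

    K = P / (2 * sqrt(pi * A))

which equals 1 for a disk and grows with elongation. Tubules cut obliquely
by the section plane appear elongated; restricting counts and mean areas
to near-circular cross sections (K < 1.7) keeps the per-tubule statistics
comparable across animals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats
from skimage import measure as skmeasure

logger = logging.getLogger(__name__)

__all__ = [
    "TubuleRecord",
    "label_tubules",
    "measure",
    "gravelius",
    "filter_circular",
    "representativeness",
]

#: Default Gravelius threshold retaining near-circular cross sections.
K_MAX_DEFAULT = 1.7


@dataclass(frozen=True)
class TubuleRecord:
    label: int
    area_px: int
    area_um2: float
    perimeter_px: float
    perimeter_um: float
    circularity: float
    major_axis_px: float
    minor_axis_px: float
    gravelius_k: float
    centroid: tuple[float, float]
    touches_border: bool


def gravelius(perimeter: float, area: float) -> float:
    """Gravelius compactness K = P / (2 * sqrt(pi * A)).

    Uses the exact constant 1/(2*sqrt(pi)) ~ 0.2821 (often rounded to
    0.28), so a perfect circle gives exactly 1.
    """
    if perimeter <= 0 or area <= 0:
        raise ValueError("perimeter and area must be positive")
    return perimeter / (2.0 * math.sqrt(math.pi * area))


def label_tubules(
    gt: np.ndarray, min_area_px: int = 30
) -> tuple[np.ndarray, list]:
    """Label 8-connected components of the GT mask, dropping small specks.

    Components with fewer than ``min_area_px`` pixels are discarded (and
    counted in the log); surviving components are relabeled 1..n in raster
    order of their first pixel. Returns the labeled grid and the list of
    skimage region objects in label order.
    """
    gt = np.asarray(gt, dtype=bool)
    labels = skmeasure.label(gt, connectivity=2)
    regions = skmeasure.regionprops(labels)
    kept = [r for r in regions if r.area >= min_area_px]
    dropped = [r for r in regions if r.area < min_area_px]
    if dropped:
        logger.info(
            "label_tubules: discarded %d components (< %d px, %d px total)",
            len(dropped), min_area_px, sum(r.area for r in dropped),
        )
    out = np.zeros_like(labels)
    for new_label, region in enumerate(kept, start=1):
        out[labels == region.label] = new_label
    regions_out = skmeasure.regionprops(out)
    return out, regions_out


def measure(region, microns_per_pixel: float, image_shape: Optional[tuple[int, int]] = None) -> TubuleRecord:
    """Measure one labeled region into a :class:`TubuleRecord`.

    Area is the pixel count; the perimeter is the 4-direction Crofton
    estimator (low bias on smooth blobs — K is quadratic in P, so the
    estimator choice materially affects the circularity filter); axes are
    the equivalent-ellipse axis lengths from the second central moments
    (4 * sqrt(eigenvalue)); circularity is 4*pi*A/P^2.
    """
    if region.area == 0:
        raise ValueError("empty region")
    area_px = int(region.area)
    perimeter_px = float(region.perimeter_crofton)  # 4 directions
    if perimeter_px <= 0:
        # 4-direction Crofton of a single isolated pixel is positive, but
        # guard degenerate inputs from hand-built region stubs
        perimeter_px = 4.0 * math.sqrt(area_px)
    circ = 4.0 * math.pi * area_px / perimeter_px**2
    minr, minc, maxr, maxc = region.bbox
    if image_shape is not None:
        touches = minr == 0 or minc == 0 or maxr == image_shape[0] or maxc == image_shape[1]
    else:
        touches = False
    return TubuleRecord(
        label=int(region.label),
        area_px=area_px,
        area_um2=area_px * microns_per_pixel**2,
        perimeter_px=perimeter_px,
        perimeter_um=perimeter_px * microns_per_pixel,
        circularity=circ,
        major_axis_px=float(region.axis_major_length),
        minor_axis_px=float(region.axis_minor_length),
        gravelius_k=gravelius(perimeter_px, area_px),
        centroid=tuple(float(c) for c in region.centroid),
        touches_border=bool(touches),
    )


def measure_mask(
    gt: np.ndarray, microns_per_pixel: float, min_area_px: int = 30
) -> list[TubuleRecord]:
    """Label and measure all tubules of a GT mask in one call."""
    labels, regions = label_tubules(gt, min_area_px=min_area_px)
    shape = labels.shape
    return [measure(r, microns_per_pixel, image_shape=shape) for r in regions]


def filter_circular(
    records: Sequence[TubuleRecord], k_max: float = K_MAX_DEFAULT
) -> list[TubuleRecord]:
    """Keep tubules with near-circular cross sections: K strictly below k_max."""
    return [r for r in records if r.gravelius_k < k_max]


def representativeness(filtered_counts_per_animal: Sequence[tuple[int, int]]):
    """Test whether the circular-tubule share is homogeneous across animals.

    Each animal contributes its kept/total proportion; the proportions are
    tested against the pooled overall proportion with a one-sample t-test.
    A non-significant result supports treating the circular subset as
    representative of all tubules. Animals with zero tubules are excluded
    with a warning. Zero-variance inputs (all proportions identical) are
    degenerate: reported as no difference (p = 1) with a flag.
    """
    from .stats import ComparisonResult, stars

    usable = []
    for i, (kept, total) in enumerate(filtered_counts_per_animal):
        if not (0 <= kept <= total):
            raise ValueError(f"animal {i}: kept must be in [0, total]")
        if total == 0:
            logger.warning("representativeness: animal %d has no tubules; excluded", i)
            continue
        usable.append((kept, total))
    if len(usable) < 2:
        raise ValueError("need at least two animals with tubules")
    props = np.array([k / t for k, t in usable])
    pooled = sum(k for k, _ in usable) / sum(t for _, t in usable)
    n = len(props)
    mean = float(props.mean())
    sd = float(props.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        t_stat, p = 0.0, 1.0
    else:
        sem = sd / math.sqrt(n)
        t_stat = (mean - pooled) / sem
        p = 2.0 * sstats.t.sf(abs(t_stat), n - 1)
    return ComparisonResult(
        mean_a=mean,
        mean_b=float(pooled),
        sem_a=(sd / math.sqrt(n)) if n > 1 else float("nan"),
        sem_b=0.0,
        t_statistic=float(t_stat),
        degrees_of_freedom=n - 1,
        p_value=float(p),
        stars=stars(float(p)),
        degenerate_flag=degenerate,
    )
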