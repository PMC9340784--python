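"""Per-section reproductive-effort indices.

Two area ratios summarize the reproductive effort of a gonad cross
section. The gonadal area (GA) is the region around the digestive gland
containing both the gonadal tubules (GT) and the storage tissue (ST):

    GTI = 100 * GA / (whole section area)      (Gonadal Tubule Index)
    TAI = 100 * GT / (whole section area)      (Tubule Area Index)

GA is built as the union of the GT and ST masks bridged by a morphological
closing, since the anatomical gonadal area also spans the thin interstitial
gaps between tubules and storage lobes. Tubule counts and mean tubule areas
are reported for the near-circular subset (Gravelius K < 1.7) when the
circular-only mode is on — the mode used for the early-stage analysis —
while the area indices always remain plain mask ratios, unaffected by the
shape filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph

from .morphometry import TubuleRecord, filter_circular, K_MAX_DEFAULT
from .segmentation import TissueMasks

__all__ = [
    "SectionMetrics",
    "gonadal_area",
    "compute_gti",
    "compute_tai",
    "summarize_section",
]


@dataclass
class SectionMetrics:
    whole_area_px: int
    ga_area_px: int
    gt_area_px: int
    st_area_px: int
    whole_area_um2: float
    ga_area_um2: float
    gt_area_um2: float
    st_area_um2: float
    gti_percent: float
    tai_percent: float
    n_tubules: int
    mean_area_per_tubule_um2: Optional[float]
    animal_id: Optional[str] = None
    stage: Optional[int] = None
    ploidy_class: Optional[str] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def compute_gti(ga_area: float, whole_area: float) -> float:
    """GTI = 100 * GA / whole-section area (percent)."""
    if whole_area <= 0:
        raise ValueError("whole_area must be positive")
    if ga_area > whole_area:
        raise ValueError("ga_area cannot exceed whole_area")
    return 100.0 * ga_area / whole_area


def compute_tai(gt_area: float, whole_area: float) -> float:
    """TAI = 100 * GT / whole-section area (percent)."""
    if whole_area <= 0:
        raise ValueError("whole_area must be positive")
    if gt_area > whole_area:
        raise ValueError("gt_area cannot exceed whole_area")
    return 100.0 * gt_area / whole_area


def gonadal_area(masks: TissueMasks, closing_radius: int = 5) -> np.ndarray:
    """GA mask: union of GT and ST, closed, intersected with the whole mask.

    The closing (disk radius ``closing_radius`` px; 0 disables) bridges
    interstitial connective gaps so adjacent tubules and storage lobes
    merge into one gonadal region.
    """
    masks.validate()
    ga = masks.gt | masks.st
    if closing_radius > 0 and ga.any():
        ga = skmorph.closing(ga, skmorph.disk(closing_radius))
        ga = ndimage.binary_fill_holes(ga)
    return ga & masks.whole


def summarize_section(
    masks: TissueMasks,
    records: Sequence[TubuleRecord],
    microns_per_pixel: float,
    animal_id: Optional[str] = None,
    stage: Optional[int] = None,
    ploidy_class: Optional[str] = None,
    circular_only: bool = True,
    k_max: float = K_MAX_DEFAULT,
    ga_closing_radius: int = 5,
) -> SectionMetrics:
    """Assemble all per-section metrics from masks and tubule records.

    ``records`` must have been measured on ``masks.gt``. With
    ``circular_only`` (the early-stage analysis mode), the tubule count and
    mean area cover only records with Gravelius K < ``k_max``; elongated
    tubules still contribute to the GT area and hence to TAI.
    """
    masks.validate()
    whole_area = int(masks.whole.sum())
    if whole_area == 0:
        raise ValueError("whole mask is empty")
    ga = gonadal_area(masks, closing_radius=ga_closing_radius)
    ga_area = int(ga.sum())
    gt_area = int(masks.gt.sum())
    st_area = int(masks.st.sum())
    counted = filter_circular(records, k_max=k_max) if circular_only else list(records)
    mean_area = float(np.mean([r.area_um2 for r in counted])) if counted else None
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
        n_tubules=len(counted),
        mean_area_per_tubule_um2=mean_area,
        animal_id=animal_id,
        stage=stage,
        ploidy_class=ploidy_class,
    )
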