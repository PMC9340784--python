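"""Run configuration for the section/cohort pipeline.

A single flat config object holds every unstated-in-protocol knob —
downsampling factor, thresholds (None means Otsu), morphology radii,
the tubule size/shape filters, and the classifier seed — and is written
into each run's output directory so results stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # acquisition / preprocessing
    microns_per_pixel: float = 0.25
    downsample_factor: int = 8
    normalize: bool = True
    reference_image: Optional[str] = None  # None: first image of the run
    # segmentation
    whole_smooth_sigma: float = 0.0  # smoothing of the intensity channel, px
    gt_smooth_sigma: float = 1.0  # smoothing of L*/a* before thresholding, px
    # whole-tissue segmentation
    whole_intensity_threshold: Optional[float] = None  # None: Otsu
    whole_closing_radius: int = 2
    whole_min_obj_px: int = 64
    # tubule segmentation
    gt_l_threshold: Optional[float] = None  # None: Otsu within whole
    gt_a_threshold: Optional[float] = None
    gt_a_direction: str = "auto"
    gt_l_classes: int = 3  # bands of the multi-Otsu L* cut; 2 = plain Otsu
    gt_closing_radius: int = 2
    # storage-tissue classifier
    st_seed: int = 0
    # morphometry / indices
    min_area_px: int = 30
    k_max: float = 1.7
    circular_only: bool = True
    drop_border_tubules: bool = False
    ga_closing_radius: int = 5
    # statistics
    welch: bool = False
    significance_alpha: float = 0.05
    p_adjust: str = "none"  # 'none' | 'bonferroni' | 'bh'

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.gt_a_direction not in ("auto", "high", "low"):
            raise ValueError("gt_a_direction must be 'auto', 'high' or 'low'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
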