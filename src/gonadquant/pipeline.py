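"""End-to-end orchestration: image -> masks -> morphometry -> indices -> stats.

``run_section`` chains the full per-image analysis (downsample, color
normalization, three-mask segmentation, tubule measurement and filtering,
index computation). ``run_cohort`` maps it over a manifest of sections and
derives the group tables: per-(stage, ploidy) means with SEM and all
pairwise within-stage comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .indices import SectionMetrics, summarize_section
from .morphometry import TubuleRecord, measure_mask
from .preprocess import ColorReference, RGBImage, color_normalize, downsample, load_image
from .segmentation import STClassifier, TissueMasks, segment_all

logger = logging.getLogger(__name__)

__all__ = ["CohortManifest", "SectionResult", "run_section", "run_cohort"]

PLOIDY_CLASSES = ("2n", "3n_alpha", "3n_beta", "3n_undiff")
METRIC_COLUMNS = ("gti_percent", "tai_percent", "n_tubules", "mean_area_per_tubule_um2")


@dataclass
class CohortManifest:
    """Rows mapping section images to animal, ploidy class, and stage."""

    frame: pd.DataFrame

    REQUIRED = ("image_path", "animal_id", "ploidy_class", "stage")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if len(self.frame) == 0:
            raise ValueError("manifest is empty")
        bad_stage = set(self.frame["stage"].astype(int)) - {0, 1, 2, 3}
        if bad_stage:
            raise ValueError(f"invalid stages in manifest: {sorted(bad_stage)}")
        bad_ploidy = set(self.frame["ploidy_class"]) - set(PLOIDY_CLASSES)
        if bad_ploidy:
            raise ValueError(f"invalid ploidy classes in manifest: {sorted(bad_ploidy)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        return cls(pd.read_csv(path))


@dataclass
class SectionResult:
    metrics: SectionMetrics
    records: list[TubuleRecord]
    masks: TissueMasks


def _prepare(
    image: Union[RGBImage, str, Path],
    config: PipelineConfig,
    reference: Optional[ColorReference],
) -> RGBImage:
    if not isinstance(image, RGBImage):
        image = load_image(image, microns_per_pixel=config.microns_per_pixel)
    image = downsample(image, config.downsample_factor)
    if config.normalize and reference is not None:
        image = color_normalize(image, reference)
    return image


def run_section(
    image: Union[RGBImage, str, Path],
    config: Optional[PipelineConfig] = None,
    st_model: Optional[STClassifier] = None,
    reference: Optional[ColorReference] = None,
    exclusion: Optional[np.ndarray] = None,
    animal_id: Optional[str] = None,
    stage: Optional[int] = None,
    ploidy_class: Optional[str] = None,
    out_dir: Optional[str | Path] = None,
) -> SectionResult:
    """Analyze one section image into metrics, tubule records, and masks.

    ``image`` may be an in-memory :class:`RGBImage` or a TIFF/PNG path.
    ``reference`` holds the Lab statistics for color normalization (None
    skips it); ``st_model`` the trained storage-tissue classifier (None
    leaves the ST mask empty). Errors are re-raised with the failing stage
    named.
    """
    config = config or PipelineConfig()
    stage_name = "load/preprocess"
    try:
        prepared = _prepare(image, config, reference)
        stage_name = "segmentation"
        masks = segment_all(
            prepared,
            st_model=st_model,
            exclusion=exclusion,
            whole_kwargs=dict(
                intensity_threshold=config.whole_intensity_threshold,
                closing_radius=config.whole_closing_radius,
                min_obj_px=config.whole_min_obj_px,
                smooth_sigma=config.whole_smooth_sigma,
            ),
            gt_kwargs=dict(
                l_threshold=config.gt_l_threshold,
                a_threshold=config.gt_a_threshold,
                a_direction=config.gt_a_direction,
                l_classes=config.gt_l_classes,
                closing_radius=config.gt_closing_radius,
                smooth_sigma=config.gt_smooth_sigma,
            ),
        )
        stage_name = "morphometry"
        records = measure_mask(
            masks.gt, prepared.microns_per_pixel, min_area_px=config.min_area_px
        )
        if config.drop_border_tubules:
            records = [r for r in records if not r.touches_border]
        stage_name = "indices"
        metrics = summarize_section(
            masks,
            records,
            prepared.microns_per_pixel,
            animal_id=animal_id,
            stage=stage,
            ploidy_class=ploidy_class,
            circular_only=config.circular_only,
            k_max=config.k_max,
            ga_closing_radius=config.ga_closing_radius,
        )
    except Exception as exc:
        raise type(exc)(f"[{stage_name}] {exc}") from exc
    result = SectionResult(metrics=metrics, records=records, masks=masks)
    if out_dir is not None:
        _write_section_outputs(result, Path(out_dir))
    return result


def _write_section_outputs(result: SectionResult, out_dir: Path) -> None:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    for name, mask in (("whole", result.masks.whole), ("gt", result.masks.gt), ("st", result.masks.st)):
        iio.imwrite(out_dir / f"mask_{name}.png", (mask.astype(np.uint8) * 255))
    (out_dir / "thresholds.json").write_text(json.dumps(result.masks.threshold_log, indent=2))
    (out_dir / "metrics.json").write_text(
        json.dumps(result.metrics.to_dict(), indent=2, default=float)
    )
    pd.DataFrame([r.__dict__ for r in result.records]).to_csv(
        out_dir / "tubules.csv", index=False
    )


def run_cohort(
    manifest: Union[CohortManifest, pd.DataFrame, str, Path],
    config: Optional[PipelineConfig] = None,
    st_model: Optional[STClassifier] = None,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Analyze a cohort of sections and build the group tables.

    Returns a dict with ``sections`` (per-section metrics DataFrame),
    ``groups`` (per-(stage, ploidy) mean and SEM for each metric),
    ``comparisons`` (all pairwise within-stage t-tests with stars), and
    ``n_failed``. Failed sections are logged and skipped, not fatal.
    """
    from .stats import GroupSample, t_test

    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        manifest = CohortManifest.from_csv(manifest)
    elif isinstance(manifest, pd.DataFrame):
        manifest = CohortManifest(manifest)

    reference: Optional[ColorReference] = None
    if config.normalize:
        ref_path = config.reference_image or manifest.frame["image_path"].iloc[0]
        ref_img = downsample(
            load_image(ref_path, microns_per_pixel=config.microns_per_pixel),
            config.downsample_factor,
        )
        reference = ColorReference.from_image(ref_img)

    rows, n_failed = [], 0
    for _, row in manifest.frame.iterrows():
        exclusion = None
        if "exclusion_mask_path" in row and isinstance(row["exclusion_mask_path"], str):
            import imageio.v3 as iio

            exclusion = iio.imread(row["exclusion_mask_path"]) > 0
        try:
            result = run_section(
                row["image_path"],
                config=config,
                st_model=st_model,
                reference=reference,
                exclusion=exclusion,
                animal_id=str(row["animal_id"]),
                stage=int(row["stage"]),
                ploidy_class=str(row["ploidy_class"]),
            )
        except Exception as exc:
            logger.error("section %s failed: %s", row["image_path"], exc)
            n_failed += 1
            continue
        rows.append(result.metrics.to_dict())
    if not rows and n_failed:
        raise RuntimeError(f"all {n_failed} sections failed")
    sections = pd.DataFrame(rows)

    group_rows = []
    for (stage, ploidy), grp in sections.groupby(["stage", "ploidy_class"]):
        entry = {"stage": stage, "ploidy_class": ploidy, "n": len(grp)}
        for metric in METRIC_COLUMNS:
            vals = grp[metric].dropna().to_numpy(dtype=float)
            entry[f"{metric}_mean"] = vals.mean() if vals.size else np.nan
            entry[f"{metric}_sem"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            )
        group_rows.append(entry)
    groups = pd.DataFrame(group_rows)

    comp_rows = []
    for stage, stage_grp in sections.groupby("stage"):
        ploidies = sorted(stage_grp["ploidy_class"].unique())
        for i, pa in enumerate(ploidies):
            for pb in ploidies[i + 1 :]:
                for metric in METRIC_COLUMNS:
                    va = stage_grp.loc[stage_grp["ploidy_class"] == pa, metric].dropna()
                    vb = stage_grp.loc[stage_grp["ploidy_class"] == pb, metric].dropna()
                    if len(va) < 2 or len(vb) < 2:
                        continue
                    res = t_test(
                        GroupSample((pa, int(stage)), tuple(va)),
                        GroupSample((pb, int(stage)), tuple(vb)),
                        welch=config.welch,
                    )
                    comp_rows.append(
                        {
                            "stage": stage,
                            "group_a": pa,
                            "group_b": pb,
                            "metric": metric,
                            "mean_a": res.mean_a,
                            "mean_b": res.mean_b,
                            "sem_a": res.sem_a,
                            "sem_b": res.sem_b,
                            "t": res.t_statistic,
                            "df": res.degrees_of_freedom,
                            "p": res.p_value,
                            "stars": res.stars,
                            "degenerate": res.degenerate_flag,
                        }
                    )
    comparisons = pd.DataFrame(comp_rows)
    if config.p_adjust != "none" and len(comparisons):
        from .stats import adjust_pvalues

        comparisons["p_adjusted"] = adjust_pvalues(
            comparisons["p"].tolist(), method=config.p_adjust
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sections.to_csv(out / "sections.csv", index=False)
        groups.to_csv(out / "groups.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        config.to_yaml(out / "config.yaml")
    return {
        "sections": sections,
        "groups": groups,
        "comparisons": comparisons,
        "n_failed": n_failed,
    }
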