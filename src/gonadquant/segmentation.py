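"""Tissue segmentation: whole section, gonadal tubules, storage tissue.

Three masks are extracted from a normalized section image:

* **whole** — the tissue section against the white slide background, by a
  threshold on the intensity component of HSI (tissue is darker than the
  slide; Otsu by default).
* **gt** — gonadal tubules, by a joint threshold on L* and a* of CIE
  L*a*b* within the whole mask (the tubule stain is darker and shifted
  along the green-red axis relative to the pink connective tissue).
* **st** — storage tissue, by supervised pixel classification (random
  forest on per-pixel color plus 3x3 local texture features), applied to
  the tissue outside the tubules. GT has priority where predictions
  conflict, which enforces GT/ST disjointness.

Every threshold actually used is recorded in ``TissueMasks.threshold_log``
so a run can be audited and reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters as skfilters
from skimage import morphology as skmorph
from sklearn.ensemble import RandomForestClassifier

from .preprocess import RGBImage, to_hsi, to_lab

logger = logging.getLogger(__name__)

__all__ = [
    "TissueMasks",
    "NoTissueError",
    "STClassifier",
    "segment_whole",
    "segment_gt",
    "segment_st",
    "fit_st_classifier",
    "fit_st_classifier_from_masks",
    "pixel_features",
    "segment_all",
]


class NoTissueError(RuntimeError):
    """Raised when no tissue is found in the image."""


@dataclass
class TissueMasks:
    """Aligned boolean masks for whole tissue, tubules, and storage tissue."""

    whole: np.ndarray
    gt: np.ndarray
    st: np.ndarray
    threshold_log: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.whole.shape == self.gt.shape == self.st.shape):
            raise ValueError("masks must share a shape")
        if (self.gt & ~self.whole).any():
            raise ValueError("gt must be contained in whole")
        if (self.st & ~self.whole).any():
            raise ValueError("st must be contained in whole")
        if (self.gt & self.st).any():
            raise ValueError("gt and st must be disjoint")


def _clean(mask: np.ndarray, closing_radius: int, min_obj_px: int) -> np.ndarray:
    if closing_radius > 0 and mask.any():
        mask = skmorph.closing(mask, skmorph.disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    if min_obj_px > 1:
        mask = skmorph.remove_small_objects(mask, max_size=min_obj_px - 1, connectivity=2)
    return mask


def segment_whole(
    image: RGBImage,
    exclusion: Optional[np.ndarray] = None,
    intensity_threshold: Optional[float] = None,
    closing_radius: int = 2,
    min_obj_px: int = 64,
    smooth_sigma: float = 0.0,
    threshold_log: Optional[dict] = None,
) -> np.ndarray:
    """Whole-tissue mask from the HSI intensity channel.

    Pixels with intensity below the threshold (Otsu on I unless a fixed
    value is given) are tissue; the raw mask is closed (disk radius 2),
    hole-filled, and small components dropped. ``exclusion`` (e.g. a
    manually outlined gill region) is forced to background.
    """
    _, _, intensity = to_hsi(image)
    if smooth_sigma > 0:
        # optional; the slide/tissue contrast is large, so the default is
        # no smoothing (it shifts the boundary when Otsu sits off-midpoint)
        intensity = ndimage.gaussian_filter(intensity, smooth_sigma)
    if exclusion is not None and exclusion.shape != intensity.shape:
        raise ValueError("exclusion mask shape mismatch")
    if intensity_threshold is None:
        if np.ptp(intensity) == 0:
            intensity_threshold = 0.5
        else:
            intensity_threshold = float(skfilters.threshold_otsu(intensity))
    mask = intensity < intensity_threshold
    mask = _clean(mask, closing_radius, min_obj_px)
    if exclusion is not None:
        mask &= ~exclusion.astype(bool)
    if not mask.any():
        raise NoTissueError("no tissue found below the intensity threshold")
    if threshold_log is not None:
        threshold_log["whole_intensity_threshold"] = float(intensity_threshold)
    return mask


def segment_gt(
    image: RGBImage,
    whole: np.ndarray,
    l_threshold: Optional[float] = None,
    a_threshold: Optional[float] = None,
    a_direction: str = "auto",
    l_classes: int = 3,
    closing_radius: int = 2,
    smooth_sigma: float = 1.0,
    threshold_log: Optional[dict] = None,
) -> np.ndarray:
    """Gonadal-tubule mask by thresholding L* and a* within the whole mask.

    Tubule pixels satisfy L* < t_L and lie on the tubule side of the a*
    threshold. The trichrome tissue region contains three stain classes
    (pale connective, pink storage, dark tubule), so the default L* cut is
    the lowest band of a ``l_classes``-class multi-Otsu on the whole-mask
    pixels — a plain 2-class Otsu can split connective from storage and
    miss scarce tubules entirely (resting-stage sections). The a*
    threshold defaults to 2-class Otsu. ``a_direction``: 'high' keeps
    a* >= t_a, 'low' keeps a* < t_a, 'auto' keeps whichever side has the
    lower mean L* (the tubule stain is the darker one). An empty result is
    valid — resting-stage sections may have no detectable tubule pixels.
    """
    if not whole.any():
        raise ValueError("whole mask is empty")
    lightness, a_chan, _ = to_lab(image)
    if smooth_sigma > 0:
        lightness = ndimage.gaussian_filter(lightness, smooth_sigma)
        a_chan = ndimage.gaussian_filter(a_chan, smooth_sigma)
    if l_threshold is None:
        vals = lightness[whole]
        if np.ptp(vals) == 0:
            l_threshold = -np.inf
        elif l_classes <= 2:
            l_threshold = float(skfilters.threshold_otsu(vals))
        else:
            try:
                l_threshold = float(
                    skfilters.threshold_multiotsu(vals, classes=l_classes)[0]
                )
            except ValueError:  # too few distinct values for 3 bands
                l_threshold = float(skfilters.threshold_otsu(vals))
    if a_threshold is None:
        vals = a_chan[whole]
        a_threshold = float(skfilters.threshold_otsu(vals)) if np.ptp(vals) > 0 else -np.inf
    if a_direction == "auto":
        hi = whole & (a_chan >= a_threshold)
        lo = whole & (a_chan < a_threshold)
        mean_l_hi = lightness[hi].mean() if hi.any() else np.inf
        mean_l_lo = lightness[lo].mean() if lo.any() else np.inf
        a_direction = "high" if mean_l_hi <= mean_l_lo else "low"
    if a_direction == "high":
        a_side = a_chan >= a_threshold
    elif a_direction == "low":
        a_side = a_chan < a_threshold
    else:
        raise ValueError(f"a_direction must be 'high', 'low' or 'auto', got {a_direction!r}")
    mask = whole & (lightness < l_threshold) & a_side
    mask = _clean(mask, closing_radius, min_obj_px=0) & whole
    if threshold_log is not None:
        threshold_log.update(
            gt_l_threshold=float(l_threshold),
            gt_a_threshold=float(a_threshold),
            gt_a_direction=a_direction,
        )
    return mask


def pixel_features(image: RGBImage, window: int = 3) -> np.ndarray:
    """Per-pixel features: R, G, B plus local window mean and sd per channel."""
    px = image.pixels.astype(np.float64)
    feats = [px[..., c] for c in range(3)]
    for c in range(3):
        mean = ndimage.uniform_filter(px[..., c], size=window, mode="nearest")
        sq = ndimage.uniform_filter(px[..., c] ** 2, size=window, mode="nearest")
        sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
        feats.extend([mean, sd])
    return np.stack(feats, axis=-1)


@dataclass
class STClassifier:
    """Trained pixel classifier with the class it treats as storage tissue."""

    forest: RandomForestClassifier
    storage_label: object
    window: int = 3

    @property
    def trained(self) -> bool:
        return hasattr(self.forest, "estimators_")


def fit_st_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    storage_label: object = "storage",
    seed: int = 0,
    n_estimators: int = 50,
) -> STClassifier:
    """Fit the storage-tissue pixel classifier on labeled pixels.

    ``features`` is (n_pixels, n_features) as produced by
    :func:`pixel_features`; ``labels`` the per-pixel class labels.
    Requires at least two classes; fewer than 50 pixels in a class only
    warns. Deterministic for a fixed seed.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to train the pixel classifier")
    for cls, cnt in zip(classes, counts):
        if cnt < 50:
            logger.warning("fit_st_classifier: class %r has only %d pixels", cls, cnt)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(features, labels)
    return STClassifier(forest=forest, storage_label=storage_label)


def fit_st_classifier_from_masks(
    image: RGBImage,
    class_masks: dict[str, np.ndarray],
    seed: int = 0,
    max_px_per_class: int = 4000,
    erosion_radius: int = 1,
) -> STClassifier:
    """Train the ST classifier from an image with known class masks.

    Masks are eroded before sampling so boundary-mixed pixels do not
    pollute the training set; up to ``max_px_per_class`` pixels per class
    are drawn at random.
    """
    rng = np.random.default_rng(seed)
    feats = pixel_features(image)
    xs, ys = [], []
    for name, mask in class_masks.items():
        m = mask.astype(bool)
        if erosion_radius > 0:
            m = skmorph.erosion(m, skmorph.disk(erosion_radius))
        idx = np.flatnonzero(m.ravel())
        if idx.size == 0:
            continue
        if idx.size > max_px_per_class:
            idx = rng.choice(idx, size=max_px_per_class, replace=False)
        xs.append(feats.reshape(-1, feats.shape[-1])[idx])
        ys.append(np.full(idx.size, name, dtype=object))
    if not xs:
        raise ValueError("no labeled pixels available")
    return fit_st_classifier(
        np.concatenate(xs), np.concatenate(ys), storage_label="storage", seed=seed
    )


def segment_st(
    image: RGBImage,
    whole: np.ndarray,
    gt: np.ndarray,
    model: STClassifier,
    threshold_log: Optional[dict] = None,
) -> np.ndarray:
    """Storage-tissue mask: pixels of whole minus gt classified as storage.

    Disjoint from GT by construction (GT has priority over ST).
    """
    if not model.trained:
        raise ValueError("ST classifier is not trained")
    candidates = whole & ~gt
    mask = np.zeros_like(candidates)
    idx = np.flatnonzero(candidates.ravel())
    if idx.size:
        feats = pixel_features(image, window=model.window)
        pred = model.forest.predict(feats.reshape(-1, feats.shape[-1])[idx])
        mask.ravel()[idx] = pred == model.storage_label
    if threshold_log is not None:
        threshold_log["st_classifier"] = {
            "n_estimators": len(model.forest.estimators_),
            "storage_label": str(model.storage_label),
        }
    return mask


def segment_all(
    image: RGBImage,
    st_model: Optional[STClassifier] = None,
    exclusion: Optional[np.ndarray] = None,
    whole_kwargs: Optional[dict] = None,
    gt_kwargs: Optional[dict] = None,
) -> TissueMasks:
    """Run the three-stage segmentation and return validated masks."""
    log: dict = {}
    whole = segment_whole(image, exclusion=exclusion, threshold_log=log, **(whole_kwargs or {}))
    gt = segment_gt(image, whole, threshold_log=log, **(gt_kwargs or {}))
    if st_model is not None:
        st = segment_st(image, whole, gt, st_model, threshold_log=log)
    else:
        st = np.zeros_like(whole)
    masks = TissueMasks(whole=whole, gt=gt, st=st, threshold_log=log)
    masks.validate()
    return masks
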