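# Methods

This note records the models, defaults, and design choices behind the
pipeline, and what the phantom-based validation does and does not show.

## Pipeline model

The analysis operates on 8-bit RGB section images. The native scan scale
is 0.25 µm·px⁻¹; a block-mean downsampling by an integer factor
(default 8, giving 2 µm·px⁻¹) precedes all analysis. Block means rather
than stride sampling are used because the downstream indices are area
ratios, and block averaging keeps area fractions unbiased; output values
are rounded half up, and the physical pixel size is scaled by the
factor.

**Color normalization.** Reinhard mean/std transfer in CIE L\*a\*b\*:
each channel of the image is shifted and scaled to match the Lab mean
and standard deviation of a designated reference image (configurable;
a cohort run defaults to its first image). A zero-variance channel is
mean-shifted only. The transfer is idempotent up to 8-bit round-trip
rounding.

**Whole-tissue mask.** Threshold on the intensity component of classical
HSI (I = (R+G+B)/3·255; S = 1 − min/mean; H by the angular formula,
achromatic hue mapped to 0). Tissue is darker than the slide, so pixels
with I below the threshold (Otsu by default, fixed value via config) are
tissue; the mask is closed (disk radius 2), hole-filled, and components
below `whole_min_obj_px` (default 64) are dropped. No smoothing is
applied to I by default: the slide/tissue contrast is large, and
smoothing shifts the boundary whenever the threshold sits off the edge
midpoint (a measurable GTI bias on high-GA sections).

**Tubule (GT) mask.** Joint threshold on L\* and a\* within the whole
mask: tubule pixels have L\* below t_L and lie on the tubule side of
t_a. Both channels are smoothed with a Gaussian (σ = 1 px, config
`gt_smooth_sigma`) before thresholding; without it, per-pixel color noise
randomly erodes the tubule boundary (the interior is repaired by the
closing, the boundary is not), biasing per-tubule areas low by several
percent at realistic noise. The L\* cut defaults to the *lowest band of a
3-class multi-Otsu*: the tissue region contains three stain classes
(pale connective, pink storage, dark tubule), and a plain 2-class Otsu
can lock onto the connective/storage valley and miss scarce tubules
entirely (resting-stage sections). The a\* direction defaults to `auto`:
of the two sides of the Otsu cut, the one with the lower mean L\* (the
darker stain) is kept; both the direction and every threshold are
overridable for other stains, and every value actually used is written
to `threshold_log`.

**Storage-tissue (ST) mask.** Supervised pixel classification in the
spirit of interactive pixel-classification tools, implemented as a
random forest (50 trees, fixed seed) over 9 per-pixel features: R, G, B
and the 3×3 window mean and standard deviation per channel. Training
pixels come from labeled class masks; when the labels come from a
phantom, only *pure* downsampled pixels (source block ≥ 99.9% one class)
are used, so color-mixed boundary pixels never pollute training. ST is
predicted only on whole ∖ GT, which makes GT/ST disjointness structural
(GT has priority where predictions would conflict).

**Morphometry.** Tubules are the 8-connected components of GT with at
least `min_area_px` pixels (default 30 at 2 µm·px⁻¹, ≈ 120 µm², a
speck filter; discarded components are counted in the log). Per region:
area = pixel count; perimeter = 4-direction Crofton estimator (low bias
on smooth blobs — the compactness is quadratic in P, so the estimator
choice materially affects the filter); circularity = 4πA/P²; axes =
equivalent-ellipse axis lengths from the second central moments;
Gravelius K = P/(2√(πA)) with the exact constant 1/(2√π) ≈ 0.2821 (the
rounded 0.28 breaks the circle identity K=1). The circularity filter
keeps K strictly below 1.7. Border-touching tubules are measured and
flagged, not dropped (config switch to drop). A one-sample t-test of
per-animal kept/total proportions against the pooled proportion checks
that the circular subset is representative; all-equal proportions are a
degenerate case reported as "no difference" with a flag.

**Indices.** GA = GT ∪ ST followed by a closing (disk radius 5 px,
config `ga_closing_radius`, 0 disables) and hole filling, intersected
with the whole mask. The closing is the operational stand-in for the
anatomical statement that the gonadal area *contains* tubules and
storage tissue plus the interstitial gaps between them; its radius is a
documented knob with no claim of anatomical fidelity. GTI = 100·GA/whole
and TAI = 100·GT/whole; the circularity filter affects tubule counts and
mean areas only, never the area indices. TAI ≤ GTI holds structurally.

**Statistics.** Pooled-variance Student's t-test (Welch via config),
two-sided p, with the star mapping \*\*\*\* p<0.0001, \*\*\* p<0.0005,
\*\* p<0.001, \* p<0.05 — the superset of the star sets used across the
figure-style outputs; the reporting significance cutoff is a config
value (default 0.05) because the prose-level criterion (p<0.01) and the
figure legends differ, and that discrepancy is preserved as
configuration rather than resolved. Zero-variance pairs are flagged
degenerate (t=0, p=1 for equal means). SEM uses the n−1 standard
deviation over √n and is undefined (an error) for n=1; cohort summaries
report NaN for singleton groups instead. No multiple-testing correction
is applied by default (a Bonferroni/BH switch exists for reuse). qPCR
relative expression is 2^(−ΔCt) against EF1α, the standard reading of a
Ct-deviation normalization; ΔΔCt against a calibrator is available but
not the default. Mitosis-figure tallies over {G2, early prophase, late
prophase, prometaphase/metaphase, anaphase, telophase} are converted to
percents summing to 100.

## The phantom generator

The phantom is a deliberate cartoon of a Prenant-Gabe trichrome section:
a smooth elliptic tissue blob on a white slide background, elliptical
tubules, and a storage-tissue region, with per-class Gaussian color
variation plus global Gaussian noise, clipped to 8 bits. The default
palette — white background (245,245,245), pale-pink connective
(230,180,190), pink-orange storage (235,160,140), blue-violet tubules
(120,90,160) — was chosen to be separable exactly where the real stain
is: background vs tissue in HSI intensity, tubules vs the rest in
L\*/a\*.

Geometry is built from a normalized elliptic radius field: a region of
target pixel area is the set of the k smallest field values inside its
parent region. Regions built this way are nested, elliptic, and have
*exactly* the requested pixel area, so the true area fractions (and the
true GTI/TAI) are exact by construction rather than approximate targets.
Two modes exist:

* default: tubules placed anywhere in the blob, ST a central region of
  `st_fraction` of the blob, disjoint from tubules;
* `ga_fraction` mode: an explicit gonadal-area region of that share of
  the blob is drawn; tubules are placed inside it and ST fills its
  remainder. This is the mode the stage presets use, because it pins the
  true gonadal share exactly.

Tubules are ellipses with log-normal minor semi-axis (µm), uniform
aspect ratio and orientation, placed by rejection sampling (1000
attempts per tubule, explicit error naming the failing tubule): fully
inside the allowed region and pairwise separated by at least
`min_separation_um` (default 8 µm), enforced with an expanded-ellipse
exclusion footprint. Centers are sampled in coordinates relative to the
allowed region's bounding box, which makes layouts correspond across
image scales for a fixed seed (the scale-equivariance property is exact
up to rasterization). Tubule placement is uniform at random — real
tubules cluster around the digestive gland; the arrangement is a
modeling choice, not an inference.

The stage presets encode the per-(ploidy, stage) gonadal shares of the
section reported for the study groups (stage 1: 20/17/10% for
2n/3nα/3nβ; stage 3: 85/71/23%; stage 0: 12.5% for all, the middle of
the reported 10–15% range; stage 2 values are not reported and have no
preset). Preset tissue share is 0.5 of the frame; tubule size scales
with the gonadal region (minor semi-axis ≈ 0.15 of its equivalent
radius, n = 6) so placement always succeeds across the full range of
gonadal fractions. These presets are generation conditions, fixed once;
the acceptance recoveries run against them unchanged.

**What the phantom does not emulate:** individual germ cells and mitotic
figures, nuclei, gill tissue, stain gradients and batch-to-batch stain
drift, tissue folds, out-of-focus blur, scanner vignetting, and the
clustered spatial arrangement of real tubules. Passing the recovery
suites therefore shows that the pipeline's arithmetic, thresholds, and
filters behave correctly on images whose class colors match the assumed
stain model — it does not certify performance on degraded or atypical
real slides, where the fixed-palette assumptions (and hence the Otsu
defaults) may need the config overrides.

## Numerical choices and degenerate inputs

* 8-bit storage with float64 intermediates throughout.
* 8-connectivity for all component and morphology operations.
* Downsampled pixels round half up; Lab/HSI conversions are float.
* A constant-intensity image cannot be Otsu-thresholded: the whole-mask
  stage then treats an all-bright frame as "no tissue" (an explicit
  error) rather than guessing.
* Empty GT masks are valid (stage-0 sections); empty whole masks are an
  error.
* An animal with zero tubules is excluded (with a warning) from the
  representativeness test; all-identical proportions make it degenerate,
  reported as no difference with a flag.
* Validation problem sizes: recovery suites use 1024×1024 phantoms
  (downsampled by 8) for the index recoveries, matching the intended
  acquisition geometry, and 512×512 phantoms at the 2 µm analysis scale
  for counting/morphometry, where per-tubule pixel counts are large
  enough that rasterization error is small relative to the 5% check.

## Known limitations

* The Otsu-based defaults assume the three stain classes are all present
  in the section; sections with no storage tissue need fixed thresholds
  (the multi-Otsu lowest band can then split the tubule mode).
* The GA closing radius is a free parameter with no ground-truth
  counterpart on real slides; reported GTI depends weakly on it.
* The ST classifier is only as good as its training labels; across
  staining batches it should be retrained or the cohort renormalized to
  a common reference first.
* Per-tubule area has a small negative bias (~2–3% at noise sd 10) from
  boundary pixels lost to thresholding after smoothing; counts are
  unaffected.
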