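# Methods

## The assay being emulated

Endothelial monolayers in a flow chamber are stimulated with histamine,
superfused for ~1 minute with platelets plus either control plasma or plasma
from patients with congenital TTP, fixed, and immunostained for VWF and
CD41. Confocal tiles are acquired as z-stacks (30 μm depth) and each field of
view (FOV) is analyzed independently, ~35 FOVs per sample. Each patient run
is paired with one pooled-control run from the same session and the same
fluvastatin pretreatment status, so every metric is reported as a fold change
over its paired control.

## Synthetic scene model

One synthetic FOV is rendered in three steps: geometry, optics, sensor.

**Geometry.** Strings are random-walk polylines of ~1 px steps whose step
directions are jittered (SD 5°) around the flow axis, so strings are
near-straight and flow-aligned, as expected for unfurled VWF under laminar
flow. The number of strings per FOV is Poisson with mean
`string_count_mean × count_multiplier`; string length is lognormal
(`exp(mu)` median, scaled by `length_multiplier`). String anchors are placed
so a string fits inside the FOV whenever its length allows ("containment
sampling"); longer-than-FOV strings span the frame and the truth records the
actually rendered (clipped) arclength. This choice keeps the drawn string
count equal to the rendered count and keeps condition fold changes of the
total length free of edge-clipping bias. Agglomerates are isotropic Gaussian
blobs (radius 1.5–4 μm); platelets are 1 μm disks placed along string
polylines at a linear density per μm of string plus a uniform background
scatter, which makes platelet coverage track total string length — the
mechanism by which TTP plasma amplifies platelet recruitment.

**Optics.** Structures sit on the apical cell surface, so their signal is
confined to three adjacent slices (weights 0.25/0.5/0.25) of the z-stack
(default 15 slices ≙ 30 μm at 2 μm spacing); each slice is blurred with a
2-D Gaussian PSF (σ 0.3 μm). Axial blur is not modeled separately because
the analysis starts from a maximum-intensity projection.

**Sensor.** Poisson shot noise on (background + signal), additive Gaussian
read noise (SD 3), rounding to unsigned 16-bit. Identical parameters and
seed give bit-identical stacks.

**Condition effects** are multiplicative: TTP plasma scales string length
(×1.4), count (×1.5) and the platelet linear density (×1.8, standing in for
recruitment of plasma UL-VWF that thickens strings); fluvastatin scales
length (×0.6) and count (×0.65) on top of either plasma. With these defaults
the nominal TTP total-length fold is ≈2.1 and the treated TTP arm falls
below the untreated control (2.1 × 0.39 ≈ 0.8), reproducing the assay's
qualitative outcome; the platelet-area fold lands between the total-length
fold and its density-amplified ceiling because the condition-independent
background platelet scatter dilutes it (the reproduction script reports the
measured values). All of these distributions and effect sizes are explicit,
configurable stand-ins: the source images are not public and no quantitative
string-length distributions exist to fit.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.22 μm/px | 20× objective with 1.5× tube lens on a typical spinning-disk camera |
| FOV | 768×768 px (~169 μm) | one confocal tile at that sampling |
| z | 15 slices × 2 μm | 30 μm acquisition depth |
| string count mean | 10 / FOV | order-of-ten strings per field after a 60 s plasma superfusion; sparse enough that strings rarely touch |
| string length | lognormal, median 10 μm, σ=0.7 | median ~10 μm with a populated tail past the 25 μm long-string cutoff |
| string / agglomerate / platelet intensity | 600 / 110 / 150 | post-blur string peak ≈ agglomerate interior; peak SNR ≈ 8 |
| background, read noise | 8, 3 | dim uniform cytoplasmic background, camera read noise |

## Quantification pipeline

**Projection & threshold.** Max-intensity Z-projection per channel; Otsu
threshold per channel per FOV (strict `>`); a fixed threshold is available
when identical thresholds across paired runs are wanted. A constant image
under Otsu returns an all-false mask flagged degenerate.

**Ridge filtering.** The string detector is a matched ridge filter: kernels
with a negated-second-derivative-of-Gaussian cross-section (width σ 1.5 px),
tapered along the ridge axis (length 21 px, σ = length/4), exactly zero-mean
over their support, at 7 orientations spanning flow ± 15°. The response is
the per-pixel maximum over the bank with negatives clipped; borders are
reflected. Zero-mean kernels null uniform regions and agglomerate interiors;
the 21 px support is curvature-mismatched to blob edges, so edge responses
stay well below string responses and fall under the response threshold —
that is the first agglomerate-rejection mechanism.

**Extraction.** Response threshold (Otsu by default, numeric for
reproducibility studies) → 8-connected components → shape filter: ellipse
axis ratio ≥ 3, principal-axis orientation (PCA of pixel coordinates) within
20° of flow, skeleton length ≥ 5 μm — the second, independently switchable
agglomerate-rejection mechanism. Lengths are skeleton chain lengths
(1/√2-weighted steps × pixel size). Noise-broken strings are *not* re-joined
by default (`closing_radius_px = 0`): gap closing inflates lengths and is an
explicit opt-in. Border-touching strings are kept and measured as-is.

**Particles.** 8-connected components within an area gate; platelets use a
minimum area of a 1 μm-radius disk (π μm²) to reject single-pixel noise, the
VWF channel is ungated. Platelet recruitment is reported as CD41 area
fraction per FOV, averaged over FOVs.

**Metrics & statistics.** Per sample: total cumulative string length, median
string length (pooled over the sample's FOVs), string count, count of
strings > 25 μm (strict), platelet and VWF area fractions. Metrics are
computed per experiment and then averaged across experiments, not pooled.
Fold change = patient metric / paired-control metric (undefined and excluded
when the control metric is 0). The paired Wilcoxon signed-rank test drops
zero differences, mid-ranks ties, enumerates the exact sign distribution for
n ≤ 15 (two-sided p doubles the lower tail of min(W⁺, W⁻), the convention of
mainstream statistics packages), and uses the tie-corrected,
continuity-corrected normal approximation above. The unpaired t-test is
Welch by default (Student switchable). No multiple-testing correction is
applied, matching per-panel reporting; a Holm option could be layered on the
tidy test table if wanted.

## Validation experiments and problem sizes

The experiments in `vwfstrings.experiments` (shared by the test suite and
`scripts/acceptance.py`) score the pipeline against rendered ground truth:

- **Recovery**: 35 default FOVs; recall of true strings ≥ 5 μm is 100% in
  pilot runs and summed measured length lands within ~5% of truth (skeleton
  chain length slightly overcounts on diagonal jitter, blur extends
  endpoints; the two biases largely offset).
- **Agglomerate rejection**: blobs are added to otherwise bit-identical
  scenes by summing an independently Poisson-noised blob layer (sums of
  independent Poisson counts are Poisson), and thresholds are frozen on the
  blob-free scene, isolating the blob effect exactly.
- **Effect recovery**: multipliers m ∈ {1.5, 2, 4} applied jointly to length
  and count; 3 experiments × 32 FOVs; the m = 4 condition runs on the full
  768 px FOV so that ~40 μm-median strings are not frame-clipped, smaller
  multipliers on 384 px FOVs. Fold-change errors are dominated by scene
  sampling noise (SD ≈ 5% at this size), with a small negative bias at m = 4
  from string crossings merging components.
- **Null calibration**: all multipliers 1; 5 patients × 3 experiments × both
  arms; controls get 200 FOVs vs 40 per patient run because each arm's
  patient folds share the single pooled-control denominator, and the
  binding precision constraint is the long-string count — a rare-event count
  (≈1 per FOV) whose condition-pooled fold needs ≥ several hundred events
  per side before a ±15% band is a ~2.5 σ statement. Condition-level folds
  are pooled per-FOV rates; with 5 patients the exact signed-rank test's
  smallest attainable two-sided p is 0.0625, so the p > 0.05 null check is
  structurally conservative at this n (it is the fold band that carries the
  information).
- Small FOVs (224–384 px) and thin stacks (3–5 slices) are used in the
  replicated experiments; they change cost, not the study conditions
  (densities, lengths, SNR, multipliers), and containment anchoring keeps
  them clip-free at the lengths involved.

## Numerical choices and degenerate inputs

- Thresholding uses strict `>`; long-string counting uses strict `> 25 μm`.
- Elongation of a degenerate (zero-minor-axis) component is treated as
  infinite — a 1 px-wide line is maximally string-like.
- Median of an empty string set is 0 with the sample flagged (`no_strings`).
- Zero-variance t-test inputs: equal means → p = 1 (degenerate flag);
  unequal → ±∞ statistic with the smallest positive p.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` substreams (kept below 2³¹).

## Limitations

- The generator does not model string unfurling hydrodynamics, exocytosis
  kinetics, ADAMTS-13 proteolysis, inter-patient effect heterogeneity, or a
  realistic nuclei channel; passing its tests shows the *measurement chain*
  is accurate and calibrated on images with known truth, not that real
  images share these statistics.
- Plasma-VWF thickening of strings is folded into the platelet linear
  density only; string intensity itself is condition-independent.
- The original analysis script's exact convolution matrices and shape
  criteria are not public; this module is a principled reconstruction with
  every parameter exposed in `RunConfig` rather than hard-coded.
- Whether total VWF area should be measured on the raw VWF mask or after
  string segmentation is ambiguous in the source description; it is measured
  on the raw mask (it explicitly includes non-string surface VWF).
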