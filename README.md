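# vwfstrings

Quantification of **von Willebrand factor (VWF) strings** and **platelet
recruitment** in endothelial flow-assay microscopy, plus a ground-truthed
synthetic confocal scene generator for validating the whole pipeline.

## The problem

Endothelial cells store VWF in Weibel–Palade bodies and, on stimulation,
release it under flow as long, flow-aligned strings that recruit platelets.
In thrombotic thrombocytopenic purpura (TTP) the VWF-cleaving protease
ADAMTS-13 is deficient, strings persist, and platelet recruitment is greatly
amplified; drugs that shorten Weibel–Palade bodies (e.g. fluvastatin) shorten
the strings and counter the effect. Measuring this in fixed flow-chamber
images means: project each confocal z-stack, threshold the VWF and CD41
(platelet) channels, segment the flow-aligned curvilinear strings while
rejecting roundish VWF agglomerates, measure string lengths, and compare each
patient-plasma run against its paired same-session control run.

`vwfstrings` implements that measurement chain for two-channel z-stack TIFFs
and, because such patient imaging data are rarely public, ships a synthetic
scene generator that renders the same assay with exact ground truth
(string polylines and arclengths, agglomerate and platelet positions) so that
every stage can be validated quantitatively.

## Method at a glance

- **Projection/threshold** — maximum-intensity Z-projection per channel;
  per-channel Otsu (or fixed) threshold; binary masks.
- **String segmentation** — a bank of elongated zero-mean ridge kernels
  (second-derivative-of-Gaussian cross-section) at orientations spanning the
  flow direction ±15°; the per-pixel maximum response highlights flow-aligned
  contiguous signal and suppresses agglomerates; thresholding, 8-connected
  labeling, then a shape filter (elongation ≥ 3, orientation within 20° of
  flow, skeleton length ≥ 5 μm). String length is the skeleton chain length
  (axial step 1, diagonal √2, × pixel size).
- **Particle quantification** — 8-connected component counting and area on
  the binary masks: platelet (CD41) coverage and total VWF coverage per FOV.
- **Per-sample metrics** — total cumulative string length, median string
  length, string count, count of long strings (> 25 μm), platelet area
  fraction, VWF area fraction, aggregated over ~35 fields of view.
- **Statistics** — each patient sample normalized to its paired in-session
  control (fold change); two-sided paired Wilcoxon signed-rank across
  patient/control pairs (exact enumeration for n ≤ 15, tie-corrected normal
  approximation above); Welch unpaired t-test across independent experiments.

## Worked example

Simulate a small four-condition study (control/TTP plasma × vehicle/
fluvastatin) and quantify it:

```
vwf-strings simulate --out runs/demo --seed 7 --n-per-condition 2 \
    --n-fov 4 --n-experiments 1
vwf-strings quantify --manifest runs/demo/manifest.tsv --out runs/demo_results
```

`runs/demo_results/summaries.tsv` then holds one row per sample with the six
metrics; with seed 7 and the default configuration it prints:

```
sample_id                      condition        total_string_length_um  n_strings
control_control_vehicle_exp1   control_vehicle   506.1                  29
patient1_ttp_vehicle_exp1      ttp_vehicle       574.0                  37
patient2_ttp_vehicle_exp1      ttp_vehicle      1180.5                  66
patient1_ttp_fluva_exp1        ttp_fluva         519.1                  38
patient2_ttp_fluva_exp1        ttp_fluva         460.3                  36
```

The TTP samples carry more cumulative string length than the paired control
(patient 2: 2.3-fold — the embedded TTP effect is 1.4× length × 1.5× count ≈
2.1), and fluvastatin pulls each patient's sample below its untreated value
(574 → 519, 1181 → 460 μm). Four FOVs per sample is demo-sized, so individual
folds are noisy; the full study layout uses 35 FOVs × 3 experiments.
`folds.tsv`, `normalized.tsv` and `tests.tsv` hold the per-patient fold
changes and the Wilcoxon/t results.

The same pipeline accepts real data: point `quantify` at any manifest whose
TIFFs are z-stacks with a VWF and a CD41 channel (channel order and pixel
size can be given explicitly for generic TIFFs).

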