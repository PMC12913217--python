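# Methods

This note records what each pipeline computes, the assumptions behind it,
the defaults that matter, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer from the code.

## Nucleolar morphometry

**Model.** A micrograph is treated as a two-channel intensity grid: a DNA
stain delimiting nuclei and a nucleolar marker (NCL, FBL, or FUrd for
nascent-RNA labelling) that is enriched inside nucleoli relative to the
surrounding nucleoplasm. Nuclei are assumed compact, non-overlapping and
brighter than background in the DNA channel; nucleoli are assumed brighter
than the nucleoplasm in the marker channel.

**Procedure.** Nuclei: global Otsu threshold on the DNA channel, hole
filling, removal of objects below `min_area_px` (default 80 px) and of
objects touching the image border (disable with `exclude_border=False`).
Nucleoli: Otsu threshold computed *per nucleus* on the marker channel, so
calls are robust to between-cell brightness variation. A per-nucleus split
is accepted only when the above-threshold mean exceeds the below-threshold
mean by `min_split_enrichment` (default 1.3): Otsu always returns a
threshold, and without this guard a nucleolus-free nucleus would have its
noise split into spurious "objects". Adjacent fragments are merged by
dilating with radius `ceil(merge_distance_px / 2)` (default distance 2 px),
relabelling, and restricting back to the original pixels — fragments whose
boundary gap is within roughly the merge distance become one nucleolus.
Each object is assigned the nucleus containing its centroid.

**Per-nucleus metrics.** Nucleolar pixels are the union of the nucleus'
nucleoli; nucleoplasm is the nucleus minus that union (an exact disjoint
partition). Reported: nucleolus count; `size_fold` = nucleolar/nuclear
area; `presence_ratio` = mean marker over nucleolar pixels divided by mean
over nucleoplasm (NaN when there are no nucleoli or no nucleoplasm);
integrated (sum), mean and median marker intensity over nucleolar pixels.
Areas are pixel counts; µm² columns appear when the image carries a pixel
size. `presence_ratio` and `size_fold` are invariant under rescaling the
marker channel; integrated intensity scales linearly. The nascent-RNA
variant reads the same geometry over the FUrd channel and emits both the
integrated and the median statistic — which of the two is the headline
readout is a reporting choice, so both are kept.

**Quality control.** Manual curation of badly segmented cells is not
reproducible; it is approximated by a `qc_pass` flag (solidity ≥ 0.8 and
nuclear area ≤ 2× the 99th percentile) plus an RGB overlay image with
nucleus (cyan) and nucleolus (red) outlines for visual inspection.

## polyQ aggregation scoring

**Cells.** Each nucleus seed is grown into a cell by seeded watershed on
the inverted polyQ-EGFP intensity, masked to the above-Otsu region plus
the seeds. On intensity plateaus the flood advances at the same rate from
every seed, so two nuclei sharing one uniform blob split close to the
nearest-seed (Voronoi) partition. If nothing exceeds the threshold a cell
falls back to its nucleus footprint. Cells below a configurable minimum
integrated signal (EGFP-negative, e.g. untransfected) can be excluded.

**Texture contrast.** Haralick contrast `sum_{i,j} (i-j)^2 P(i,j)` over a
symmetric gray-level co-occurrence matrix. Defaults: 64 gray levels,
offset 1 px, four directions (0°, 45°, 90°, 135°) averaged. Intensities
are quantized per object between the object's min and max, which makes the
statistic invariant under affine rescaling of a cell's intensities.
Out-of-cell pixels are coded as a sentinel level whose rows/columns are
discarded, so only in-cell pixel pairs contribute. A uniform cell scores
exactly 0; a one-pixel checkerboard at L levels scores (L−1)².

*Known limitation:* per-object min–max quantization means a cell with *no*
structure — only noise — has its noise stretched across the full quantized
range, yielding a large contrast regardless of how small the noise is in
absolute terms. Contrast values are therefore only meaningful for cells
with real signal structure, and contrast-vs-focus-count monotonicity is
verified on noiseless synthetic cells. In practice this is mitigated by
excluding EGFP-negative cells and by using contrast as a between-condition
comparison (rank tests), not an absolute scale.

**Focus counting and scores.** Bright foci are detected per cell by
multi-scale Laplacian-of-Gaussian blob detection (default radius range
1–4 px). A blob is retained when its scale-normalized LoG response clears
two gates: `0.5 * min_prominence` × the in-cell intensity range (the LoG
response of a Gaussian spot at matched scale is half the spot amplitude;
default `min_prominence` 0.05) and `min_snr` (default 5) × a robust MAD
estimate of the background fluctuation of the response field itself. The
second gate keeps signal-free cells from contributing spurious counts; the
fluctuation must be estimated on the LoG response, not the raw intensity,
because linear filtering rescales the noise. Scores: S0 = 0 foci, S1 =
1–5, S2 = > 5. The texture-tertile fallback branch of the scoring rule is
not enabled by default (no published thresholds exist for it); scoring by
detected focus count is the reproducible route.

## Polysome-profile quantification

**Algorithm.** For each OD260 trace: (1) smooth with a centered moving
average (window = 2% of the trace length, forced odd); (2) find peaks
(prominence ≥ 2% of the smoothed dynamic range) and take the tallest as
the 80S monosome — the dominant peak in these gradients; (3) anchor at the
valley between the preceding (60S) peak and the monosome (X = 0) and at
the valley between the monosome and the next (disome) peak; valleys are
located on the smoothed trace and refined to the raw argmin within half a
window, with plateau ties resolved to the leftmost sample; (4) min–max
normalize Y over the whole sample and rescale X affinely so the first
anchor maps to 0 and the last datapoint to 100; (5) monosome fraction =
sum of normalized Y from the first anchor through the mono/di valley,
polysome fraction = sum from the next sample to the end (the boundary
sample is counted once, in the monosome window, switchable); P/M ratio =
polysome/monosome. Points left of X = 0 (40S/60S region) never enter the
sums. Sum-based integration assumes uniform x spacing (enforced at load
time, with optional resampling); a trapezoid option exists for non-uniform
input and agrees with the sums to well under 2% on uniform traces.

The P/M ratio is invariant under affine transforms of either axis
(y → a·y + b with a > 0, any affine x), since anchors, min–max
normalization and index-window sums all commute with them.

**Bias at low ratios.** Because Y is normalized by the *trace minimum*,
any gap between the inter-peak baseline and that minimum (noise pulls the
minimum below the baseline) is summed over every sample of a window. The
polysome window is long, so at small true ratios this inflates the P/M
ratio: on synthetic traces with ~1.4% baseline and ~0.55 % noise the
median error is ~22% at true ratio 0.5, ~9% at 1, and ≤ 3% at 2–4 (median
~5% across the full ratio range; noiseless traces recover all ratios
within 2%). Comparisons between conditions at similar ratio magnitudes
are unaffected; absolute low ratios should be read with this bias in mind.

## Synthetic ground truth

The generators render what the analyses assume, with exact truth tables
derived from internal noiseless label renderings (every count and area is
recomputable by brute-force pixel counting on the returned masks):

* **Nucleolar scenes** — hard-edged disks: nuclei (radius 20 ± 1.5 px,
  default 12 per 512² image, no overlap, off-border) containing 0–4
  nucleoli (uniform; radius 3.5 ± 0.4 px, ≥ 3 px gaps) at a marker
  enrichment of 2× over nucleoplasm (100 intensity units), DNA at 150,
  background 5, additive Gaussian noise (sd 5, clipped at 0). Disks are
  hard-edged so truth-pixel statistics are exact by construction (an
  anti-alias flag softens nucleus edges for visual realism).
* **Aggregation scenes** — cells (radius 25 ± 2 px) with central nuclei;
  per cell, a fixed total EGFP signal (1e5) is split between a uniform
  diffuse pool and f Gaussian foci (σ = 1.25 px) carrying 60% of the
  signal when f > 0; foci are renormalized on the pixel grid so the
  per-cell total is conserved exactly across focus counts.
* **Traces** — baseline + Gaussian peaks (closed-form areas; EMG shape
  behind a flag) sampled uniformly. The canonical profile places 40S, 60S
  and a dominant 80S (area 2.0) before disome–5-some peaks of decreasing
  weight and increasing width whose summed area sets the true P/M ratio;
  baseline 0.005 (~1.4% of peak max), noise sd 0.002 (~0.55%).

They do **not** emulate point-spread-function optics, uneven illumination,
3-D structure, photobleaching, cell-shape irregularity, or spectrometer
drift, so passing recovery tests demonstrates correctness of the
quantification logic under the stated assumptions — not robustness to
every artifact of real micrographs or gradients.

## Statistics

Two-condition texture distributions are compared with a two-sided
Mann–Whitney U test (exact for small untied samples). Fold changes divide
each value by the mean of the designated control condition within the same
assay. Refold capacity is recovered/non-shocked luciferase activity within
genotype; values above 1 warn rather than fail. Benjamini–Hochberg
adjustment is available for batches; per-comparison p-values are reported
unadjusted by default.

## Problem sizes

Verification runs use ~108 nuclei (9 scenes of 12) for morphometry, 55
cells (focus counts 0–10, 5 replicate scenes) for texture monotonicity,
~204 cells for scoring, and 80 traces (ratios 0.5/1/2/4 × 20 seeds) for
ratio recovery — sizes at which every recovery statistic is stable across
seeds while the full suite runs in well under a minute.
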