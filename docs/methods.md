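# Methods

This note documents the models, parameter choices and known limitations of
the `tendonquant` pipelines, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Image quantification model

A section or assembloid cross-section is represented as named 2-D channels
on one pixel grid with a physical `pixel_size` (µm/pixel, origin top-left,
0-based pixel coordinates). The cell registry is nucleus-centric:

1. **Segmentation** (`imgseg.NucleusSegmenter`): Gaussian smoothing
   (default sigma 1 µm), a global threshold (Otsu by default; a fixed value
   for negative controls, where Otsu on near-empty images is meaningless),
   hole filling, connected-component labeling, and removal of regions below
   `min_area` (default 10 µm²). No watershed splitting is applied by
   default: the synthetic fixtures guarantee separable nuclei, and clumped
   real tissue would need a splitting step this package does not claim to
   validate. All parameters are recorded in the mask object.
2. **Proximity attribution** (`imgseg.extract_cells`): mean intensity per
   channel over each nucleus dilated by `proximity_dilation` (default
   2 µm). Secreted or membrane-bound signal (IL-6 around a secreting cell,
   CD90 on the surface) lies outside the nucleus, so a peri-nuclear annulus
   must be included; 2 µm captures that annulus at the 10-µm cryosection
   scale while keeping attribution local. Where dilations collide, each
   pixel is assigned to the nearest nucleus (Euclidean distance transform),
   so pixels are counted exactly once. Mean, not maximum, intensity is used
   for robustness to hot pixels.
3. **Marker calling** (`colocal.MarkerThreshold`): positive ⟺ intensity
   strictly above a threshold calibrated either as the valley between the
   two largest modes of a Silverman-bandwidth KDE on a 512-point grid
   (`density_valley`), or as a percentile (default 99, conservative
   false-positive control) of negative-control intensities. A unimodal
   distribution falls back to the control percentile; with no control this
   is an error rather than a guess. All percentage statistics
   (marker-positive percent of all cells, conditional co-localization
   percent of given-positive cells) are strict-count ratios; an empty
   conditioning set yields NaN, never 0.
4. **Aggregation**: each biological sample contributes one datapoint — the
   mean over its image set — and group statistics act on sample values.

## Recruitment geometry

The assembloid core is a strip: a centerline polyline plus half-width, with
point-to-segment distances (projection clamped at segment endpoints, minima
over segments). Core membership uses the closed interval
(distance ≤ half-width). The in vivo lesion is a circle, default radius
480 µm. The core/extrinsic ratio uses raw marker-positive counts, not
area-normalized densities — the strip and its surrounding region are of
the same section, and the count ratio is the recruitment readout reported
alongside cumulative curves. Cumulative distance curves are evaluated per
sample on a shared grid (default 0 to the maximum distance in 25-µm steps),
then averaged pointwise with the standard error of the mean; one sample
gives sem 0 by convention with a warning. The strip half-width is always
supplied geometry, never inferred from cell positions.

## Synthetic data generator

`synthdata.generate_section_image` emulates the geometry the image pipeline
must quantify: a horizontal core strip (half-width 60 µm on a 512×512 µm
field), nuclei as 4-µm-radius disks, per-marker painted intensities drawn
from positive/negative normal distributions (defaults 1000±100 vs 100±30
a.u.), a 0.5-µm Gaussian PSF and additive Gaussian read noise (sd 20 a.u.,
nuclear amplitude 800, so nuclear SNR ≈ 40). Cells are placed by rejection
sampling with a minimum center separation of 2·r + 4·psf_sigma: at exactly
2·r two rendered disks are tangent and the PSF bridges them into one
connected component, which no thresholding segmenter can split, so the
separation guarantee includes the blur scale. Placement failure after
10,000 retries raises an error naming the density limit. An optional
exponential core-directed gradient (decay length `gradient_scale`) places
extrinsic reporter-positive cells at strip-edge distances drawn from
Exp(gradient_scale), emulating recruitment; it applies to the first marker
in the spec list (the tracked reporter). One seeded generator per image is
derived from the master seed and sample index, so outputs are bit-identical
under a fixed seed.

The generator deliberately omits: 3-D structure, tissue autofluorescence
and texture, Poisson photon statistics (additive Gaussian noise only),
optical aberrations, and nucleus shape variation. Passing the recovery
suite therefore shows the pipeline's logic is correct under resolvable,
well-separated nuclei at realistic SNR — it does not certify performance
on clumped or low-contrast real tissue.

`synthdata.generate_expression_matrix` draws gene variances from the scaled
inverse-chi-square prior s0²·d0/χ²(d0) (defaults d0 = 4, s0² = 0.25, the
regime of small-sample microarray data), baselines N(10, 0.5) log2 units
for expressed genes and N(4, 0.5) for a planted low-expression fraction
(default 0.3) so the median-expression filter removes essentially exactly
the planted genes, a ±1 log2 shift for the DE fraction (default 5%), a
duplicated probe (+N(0, 0.1) noise) for 10% of genes, and 18 + 18 samples
matching the two-group design size of the human reanalysis.

## Differential expression pipeline

Order: log2 → median-expression filter → replicate-probe averaging →
two-group fit → empirical-Bayes moderation → classification.

* **Filter**: the cutoff is the median over all matrix values (half the
  genes on an array are assumed unexpressed); "expressed" means strictly
  above the cutoff, and a gene is kept when expressed in more than two
  samples (≥ 3).
* **Fit**: effect = mean(case) − mean(control); pooled residual variance on
  n1+n2−2 df (identical to per-gene least squares, verified against
  `numpy.linalg.lstsq`).
* **Moderation**: prior (d0, s0²) by method of moments on log variances;
  trigamma inversion by monotone bisection (tolerance 1e-8). Zero-variance
  genes are excluded from prior estimation; all-zero variances are an
  error. `prior_df=0` forces the ordinary pooled t (used as a degeneracy
  check), `prior_df=inf` gives the fully shrunk normal-theory limit. The
  implementation is cross-checked against Bioconductor limma in the test
  suite.
* **Classification** uses strict inequalities. The headline up/down/
  unchanged partition uses p < 0.05 with the sign of the effect and no
  fold-change cutoff: transcripts with sub-unit effect sizes (e.g. an
  IL-6 signal transducer at +0.4 log2) are counted as significantly
  regulated in the narrative this pipeline mirrors, which a |log2FC| > 1
  filter would exclude. The volcano-style thresholds (|log2FC| > 1 or 0.5)
  remain available via `lfc_threshold`.

The GEO series-matrix reader handles the plain-text SOFT dialect (header
`!Sample_*` lines plus the table block). The ten sheathed-tendon GSM
accessions excluded from the GSE26051 comparison ship as a package
constant; exclusion happens before the median cutoff is computed.

## Enrichment

Ranking modes: signed −log10(p) (default for moderated-test output; p = 0
is capped at 0.1× the smallest positive p) or the signed log2 ratio.
Ties break on gene id (stable, deterministic). GSEA uses hit increments
|score|^p normalized by the set total (p = 1 default; p = 0 gives the
unweighted KS statistic), miss decrements 1/(N−|S|), ES = signed maximum
deviation (positive extreme on an exact magnitude tie), a gene-label
permutation null (phenotype permutation is impossible for pre-ranked
input; default 1000 permutations, seeded), add-one-smoothed permutation p,
and NES normalized by the mean |null ES| of matching sign. Set-size bounds
default to [15, 500] after restriction to the ranked list. ORA is the
exact upper-tail hypergeometric test; both analyses BH-adjust across sets.

## Group statistics

Mann-Whitney uses the exact null when n_a·n_b ≤ 400 and the data are
untied, else the normal approximation with tie and continuity corrections;
two fully identical groups return p = 1 by convention (the tie-corrected
variance is zero and the statistic carries no information). Student's t is
the pooled-variance two-sample test; zero pooled variance is an error.
All quantiles are type-7 (linear interpolation) so table medians/IQRs and
boxplot hinges agree. Panel-level comparisons are not adjusted for
multiple testing across panels, matching per-panel reporting practice.

## Problem sizes used in the offline benchmarks

The recovery suite runs 400-cell sections over 10 seeds (test suite) or
5 seeds (acceptance script); prior recovery uses 5000 genes; the type-I
error benchmark uses 10 replicates of 2000 null genes (20,000 null
p-values); GSEA/ORA oracle checks enumerate all subsets of lists up to
length 8 and universes up to 15. These sizes give estimator standard
errors comfortably below the tolerances they are checked against.

## Known limitations

* Segmentation has no clump-splitting; heavily overlapping nuclei will be
  merged and counted once.
* The density-valley threshold assumes a bimodal intensity distribution;
  extreme positive fractions (≳ 90%) leave too small a negative mode and
  should use the negative-control percentile method instead.
* The expression model assumes equal group variances and independent
  genes; correlated gene blocks would widen the type-I error band.
* The GSEA null permutes gene labels, not phenotypes, as is standard for
  pre-ranked input; its p-values are conditional on the observed ranking.
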