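# tendonquant

Quantification pipelines for chronic tendon disease research: spatial
fluorescence quantification of marker-positive cells in tendon sections and
assembloids, and a two-group microarray reanalysis with empirical-Bayes
moderation and gene set enrichment.

## Who this is for

Tendinopathy studies routinely combine two kinds of bespoke quantification:

1. **Image quantification.** Multi-channel confocal images of tendon
   sections or explant//hydrogel assembloids are quantified by building a
   nuclear mask (DAPI/NucBlue), attributing each marker's fluorescence
   (e.g. IL-6, IL-6R, CD90, CD68, a ScxGFP reporter) to the nearest cell by
   spatial proximity, calling marker-positive cells against a threshold
   calibrated from density plots and a negative control, and measuring
   recruitment geometry: the ratio of core-resident to extrinsic
   reporter-positive fibroblasts around a clamped core explant, cumulative
   distance distributions from the core centerline, and the fraction of
   positive cells inside a lesion circle (default radius 480 µm) in vivo.
2. **Expression reanalysis.** Public two-group microarray data (normal vs
   tendinopathic tendon, e.g. GEO accession GSE26051) are reanalyzed with
   log2 transform, a median-expression filter, replicate-probe averaging,
   a gene-wise two-group linear fit, empirical-Bayes variance moderation,
   volcano-style DEG classification, pre-ranked GSEA over MSigDB-style GMT
   collections, and hypergeometric overrepresentation analysis with
   Benjamini-Hochberg FDR control.

`tendonquant` implements both pipelines as a tested library plus a thin
CLI, together with a synthetic-data module that generates images and
expression matrices with exported ground truth, so every stage can be
validated offline against known answers.

## The statistics at the core

**Moderated t.** For gene *g* with pooled two-group residual variance
$s_g^2$ on $d_g = n_1+n_2-2$ df, the variance prior
$s_g^2 \sim s_0^2\, d_0/\chi^2_{d_0}$ is estimated by moment matching on
$\log s_g^2$ (digamma/trigamma inversion), giving the posterior variance

$$\tilde s_g^2 = \frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},\qquad
  \tilde t_g = \frac{\hat\beta_g}{\tilde s_g \sqrt{1/n_1 + 1/n_2}}$$

with $d_0 + d_g$ degrees of freedom. The implementation agrees with
Bioconductor limma to ~1e-10 (cross-checked in the test suite via Rscript).

**Pre-ranked GSEA.** A weighted KS running sum over the ranked list: a hit
adds $|r_i|^p / \sum_{S}|r_j|^p$, a miss subtracts $1/(N-|S|)$; ES is the
signed maximum deviation, with a seeded gene-label permutation null, an
add-one-smoothed permutation p, and NES = ES / mean(|null ES| of matching
sign). Sets are size-filtered to [15, 500] after restriction to the ranked
list.

**ORA.** Upper-tail hypergeometric $P(X \ge k)$ of a selected gene list
against each set in the universe, BH-adjusted across sets.

**Reporting conventions.** Mann-Whitney-Wilcoxon (exact null for small
untied samples) or pooled Student's t; type-7 quantiles; boxplot hinges at
the quartiles with whiskers at 1.5×IQR; median (IQR) reporting; treatment
values expressed as percent of the control-group median.

## Worked example

```python
import tendonquant as tq
from tendonquant import colocal, spatial

config = tq.SynthImageConfig(seed=1)          # 400 cells, 45% marker-positive
stack, truth = tq.generate_section_image(config)

mask = tq.segment_nuclei(stack)               # nuclear mask from the DAPI channel
cells = tq.extract_cells(mask, stack)         # per-cell intensities, 2 µm proximity
thr = colocal.estimate_threshold(cells["marker_mean"])   # density-valley threshold
calls = colocal.call_markers(cells, {"marker": thr})

print(mask.n_cells)                            # 400
print(round(thr.threshold, 1), thr.method)     # 257.2 density_valley
print(colocal.marker_fraction(calls, "marker"))            # 47.25
print(100 * truth["marker_positive"].mean())               # 47.25
```

All 400 planted cells are segmented, and the recovered marker-positive
percentage (47.25% of all cells) equals the generator's ground truth
exactly — the calibrated threshold separates the painted negative and
positive intensity distributions without misclassification.

The same flow is available from the shell:

```bash
tendonquant synth --out run/ --seed 1
tendonquant segment --image run/image.tif --out run/cells.csv
tendonquant quantify --cells run/cells.csv --marker marker --out run/calls.csv
```

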