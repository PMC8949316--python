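# Methods

This note documents the models, numerical choices and limitations behind
`glioims`, in the order the pipeline runs.

## Lipid chemistry

Species are identified at sum-composition resolution: lipid class plus total
chain carbons and chain double bonds (plus a d/t sphingoid-hydroxylation
prefix for sphingolipids). MALDI imaging without on-tissue fragmentation
cannot resolve sn-positions, so `PI 38:4` stands for every isomer with that
composition; since the elemental formula depends only on the totals, mass
arithmetic is exact regardless of the chain split.

Neutral formulas follow closed-form per-class rules: with total carbons C and
double bonds D, the molecule is C(C+a) H(2C−2D+b) plus fixed heteroatoms,
where (a, b) encode the condensed backbone and head group (e.g. PI: a = 9,
b = 15, O₁₃P). PE plasmalogens are their own class: the sn-1
1-O-alk-1′-enyl (vinyl ether) linkage replaces an ester, giving one oxygen
fewer and two hydrogens more than the diacyl species of the same C:D; the
vinyl-ether double bond is carried by the class, not by the D count, matching
common shorthand (`PE P-38:4` ↔ [M−H]⁻ 750.5443). Trihydroxy (t) sphingoid
bases add one oxygen at equal hydrogen count. Element masses are monoisotopic
(CODATA/IUPAC, 6 d.p.) in one constants file; protonated/deprotonated and
alkali adducts fold the electron mass into the ion-mass shift.

Annotation assigns each observed m/z to the panel candidate minimising
|ppm error| within a tolerance (default 9 ppm — the instrument's worst-case
mass accuracy; typical accuracy is better than 3 ppm). When several
candidates fall inside the tolerance the nearest wins and the annotation is
flagged ambiguous; this deterministic tie-break replaces on-tissue MS/MS,
which is out of scope. The packaged panel (124 species, 11 classes:
PE, PE P-, PC, PI, PS, PG, SM, Sulf, HexCer, DG, TG) is a reconstruction of
a typical human-brain MALDI panel around the species the study reports; its
same-polarity masses are separated by > 18 ppm, so annotation at 9 ppm with
≤ 3 ppm jitter is collision-free by construction. Adduct policy: [M−H]⁻ for
acidic phospholipids and sulfatides (negative mode), [M+H]⁺ for choline
lipids, glycerolipids and neutral sphingolipids (positive mode), with
Na⁺/K⁺ available per panel config.

## Synthetic sections

A section is an elliptical tissue area (~78% of a ≥ 20×20 grid) on
matrix-only background, containing one compact proliferative blob (the
MKI67+ proxy, default 20% of tissue pixels) surrounded by bulk parenchyma.
Compositions are profiles of per-polarity class shares of TIC (summing to 1)
and within-class species fractions (summing to 1):

* The four study arms (healthy/GBM × vehicle/TMZ) start from the
  healthy-vehicle baseline; arm-specific class changes are applied as exact
  fold factors (GBM: PE ×1.5, PI ×3.6, SM ×1.8, sulfatide ÷2.9; healthy-TMZ:
  PI ×2.2, sulfatide ÷1.6, HexCer ÷1.8), held classes keep their share, and
  the remaining classes absorb the residual pro rata — so configured folds
  are exact share ratios by construction. Named species mole-% (PI 38:4 at
  54.9/75.7/80.4% for healthy/GBM/TMZ-healthy, diacyl PE 36:1 at 35.6%,
  PE P-36:2 at 20.8% vs 3.6%, and so on) are fixed; unnamed panel species of
  a class share the remainder uniformly.
* Bulk parenchyma is a white-matter-like profile — sulfatide/HexCer-rich,
  with the sulfatide weight spread over five abundant species — chosen once
  for realism and for clean contrast with every proliferative profile.

Per pixel, each panel species of the section's polarity yields one centroided
peak: intensity = class share × species fraction × LogNormal(0, σ)
(multiplicative noise, σ = 0.3 by default — MALDI intensity variation is
positive and heteroscedastic), m/z = theoretical × (1 + U(−j, j)·10⁻⁶) with
j = 3 ppm. Background pixels carry 5–20 spurious peaks at uniform random m/z
totalling ~1% of tissue TIC, so background filtration and the presence
filter are non-trivially exercised. All draws flow from one integer seed.

What the generator does **not** emulate: isotope envelopes and peak shapes,
matrix cluster chemistry, ion suppression, spatial intensity gradients,
histological texture, inter-patient variability beyond seed-to-seed noise,
and batch effects between ion modes. Passing tests therefore demonstrate
correct recovery of the planted statistical structure, not performance on
real spectra.

## Processing and segmentation

Alignment is a greedy one-pass centroid clustering of the globally sorted
peak list: a new consensus bin opens when the gap to the running
intensity-weighted centroid exceeds the tolerance; each pixel contributes at
most one (maximum-intensity) peak per bin. Bins are annotated against the
panel; duplicate (species, adduct) bins are summed so the feature matrix has
one column per feature. TIC normalisation divides each pixel row by its sum
(zero-TIC pixels are dropped and logged). The presence filter keeps features
detected (nonzero in ≥ 1% of a sample's pixels, configurable) in at least
⌈0.8 × n_samples⌉ samples; "samples" are sections, counted per polarity
since a species can only appear in its own ion mode.

Background filtration removes pixels whose raw TIC is below 10% of the
median — a three-orders-of-magnitude margin on the synthetic data.
Clustering is k-means (10 restarts, seeded) on the TIC-normalised vectors,
Euclidean distance, with k chosen from 2..8 by mean silhouette (subsampled
at 2000 pixels for cost); a log1p transform is available by config. The
backend sits behind a narrow interface so a hierarchical variant can be
slotted in. Silhouettes below 0.25 trigger a weak-structure warning — an
empirical threshold: k-means splits of a single homogeneous cloud score
~0.2, planted two-population sections ~0.5–0.75. Cluster-to-ROI matching is
by Dice overlap, argmax selected, ties broken toward the larger cluster; the
Dice criterion replaces the visual IF-to-IMS comparison for
reproducibility.

## Composition statistics

Pixels of the selected cluster are averaged first; class share and species
mole-% are computed from that mean vector (a ratio-of-means estimator, which
is nearly unbiased under multiplicative noise, unlike the mean of per-pixel
ratios). "mole-%" is an intensity share without molar response correction —
values are comparable only within a class. Group tests are Student t by
default (Welch by config) on section-level values, n = 5 sections per arm;
fold changes are reported as group-B/group-A with an "x-fold decrease"
display below 1; species under 5% mean abundance in both groups are flagged
out of the display set. No multiple-testing correction is applied to the
stars (matching per-feature raw-p reporting conventions); a
Benjamini–Hochberg column is emitted alongside for transparency.
Degenerate zero-variance-equal-means comparisons return p = 1. PCA runs on
z-scored rows (constant features dropped with a warning), labels unused in
the fit; group separation is summarised by the silhouette of the PC1–2
scores.

## Co-expression modules and NES

The network is unsigned: adjacency |r|^β with β = 9 over Pearson
correlations of gene rows; dissimilarity 1 − adjacency; average-linkage
hierarchical clustering cut at 0.8; clusters under 10 genes pooled as
"not correlated"; modules whose eigengenes (first PC of the module's
z-scored genes) correlate above 0.9 are merged; hub genes are the top-5 by
intramodular connectivity. Note the cut interacts with β: |r|^9 maps
correlations below ~0.84 to dissimilarities above 0.8, so only tightly
co-regulated gene sets form modules.

Consequently the generator models a planted module as a shared per-sample
latent activity — effect × (subtype indicator + N(0, 1)) — plus independent
gene noise (sd 0.5), rather than a pure per-subtype mean shift: a shift
alone, at any realistic effect size, caps within-module correlation near
0.3 and no cut at 0.8 could recover it. With the latent factor, effect 1.5
gives within-module r ≈ 0.91 (recoverable), effect 0 gives pure noise
(nothing recoverable), and recovery grows monotonically in between — the
planted-recovery and null behaviours tested in the suite.

NES: for each subtype, genes are ranked by mean z-scored expression over
that subtype's samples; the enrichment score is the signed extreme of the
weighted (weight 1) Kolmogorov–Smirnov running sum; the null is 1000
size-matched random gene sets on the same ranking; NES = ES / mean |null
ES|; the two-sided permutation p is BH-adjusted across the
module × subtype grid. Because the step sum is zero, negating the ranking
exactly negates the ES.

## Survival and epigenetics

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines; groups are defined by a median split of one gene's expression
(ties to the low group; the quantile is configurable since the original
cut-point is not stated). With no events, p = 1 by convention. Overall and
disease-specific survival use the same machinery on different event
columns. ANOVA is ordinary one-way (scipy F), post-hoc pairwise comparisons
use the studentized-range Tukey HSD with the classic pooled variance.

The synthetic cohort: 5 subtypes × 20 samples, 300 genes, four planted
25-gene modules anchored by the subtype-characteristic lipid-enzyme genes
(Classical: PLA2G5, FABP7, ELOVL2; Mesenchymal: PLA2G2A, FABP5, PTGS2,
ALOX15B, ALOX5AP; Neural: INPP5F, DGKB; Proneural: UGT8). Survival is
exponential with log-hazard = Σ coef × z over the five adverse genes
(coef = ln 2 per z-unit, baseline median 600 days, administrative censoring
at 5 years plus random censoring); methylation betas for PLA2G5, FABP7 and
ALOX5AP are expit(−2 z + N(0, 0.5)) of the gene's expression z-score, so
high-expression subtypes show low methylation.

## Problem sizes and defaults

Simulated comparisons use 5 sections per arm (matching the study's n = 5
replicates) on 60×60 grids in the reproduction script and 44×44 in the test
suite — at TIC-normalised resolution the estimators depend on pixel count
only through a √n standard error, and both sizes leave the recovered folds
within a fraction of a percent of the configured values. The acceptance
reproduction runs negative-ion sections for the composition comparisons
(all compared classes are negative-mode lipids) and both polarities for the
panel census.

## Known limitations

* The clustering stand-in is k-means with silhouette selection, not the
  original hierarchical density algorithm; only the grouped-pixels contract
  is preserved.
* Sum-composition annotation cannot separate isobaric overlaps a real
  database would disambiguate by MS/MS; ambiguity is only flagged.
* The co-expression null and NES are gene-set permutations, not sample
  permutations; inter-gene correlation inflates neither under the planted
  designs tested, but could on strongly structured real data.
* Methylation probes are plain gene-named columns; no genomic coordinates
  or probe-level effects are modelled.
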