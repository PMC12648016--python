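# Methods

This note documents the models, estimators and numerical choices
behind `offsetforest`, and what the synthetic-data generator does and
does not emulate.

## Synthetic landscapes and genotypes

The generator emulates a fragmented montane tree sampled at 18
populations in five groups: three diverged lineages (West, East,
South) and two admixed groups (Wmix = West × South, Emix = East ×
South).  Sites are placed deterministically around fixed group centres
on a regular lon/lat grid (default 24 × 36 cells spanning roughly
100–112°E, 26–34°N); within-group sites scatter over ~10–15% of the
grid, mirroring how sampled populations of one lineage spread across a
mountain range.  Climate layers (defaults: bio1, bio2, bio7, bio12,
bio18, in °C and mm) are linear east–west and north–south trends plus
a seeded sinusoidal wiggle; the future stack adds a per-variable
constant shift (default: +3.2 °C annual mean temperature, −60 mm
annual precipitation, and smaller shifts for the others — an
end-of-century high-emissions flavour).

**Neutral loci.** An ancestral frequency p ~ Beta(0.8, 0.8) (clipped
to [0.02, 0.98]) is drawn per locus; each lineage draws
p_L ~ Beta(p(1−F)/F, (1−p)(1−F)/F), the Balding–Nichols model, whose
variance is exactly F·p(1−p) for the target differentiation F
(`fst_target`, default 0.3).  An earlier additive-Normal-with-
truncation variant realised F_ST ≈ 0.22 at a 0.3 target because
truncation near the frequency boundary destroys variance; the Beta
parameterisation realises θ ≈ 0.297 and is the default for that
reason.  Admixed groups take (1−α)·recipient + α·donor frequencies
(`admix_alpha`, default 0.3; the study's measured f4-ratios of ~0.1
are used as the background in the introgression-recovery tests).

**Adaptive loci.** A minority of loci (default 100 of 1000) carry a
logistic cline in one climate variable (drivers assigned round-robin):
freq = logistic(logit(p_base) + b·z(env)), where p_base is the group's
drift background and z the site's standardised driver value.  The
cline acts *on top of* the drift background, so `cline_slope = 0`
degenerates exactly to a neutral locus — this is what makes the GEA
null-calibration tests meaningful.  Slope magnitude is `cline_slope`
(default 3); sign is random per locus.  Slopes much beyond ~4 saturate
the logistic at most sites and start to mimic plain lineage structure
rather than a detectable cline.

**Introgression windows.** Declared windows (chromosome,
within-chromosome locus span, donor, optional recipient group) replace
the admixed group's frequencies with the donor lineage's.  With
`window_contrast = c`, donor and recipient lineage frequencies inside
windows are set to 0.5 ± c/2 (c = 1 → donor-fixed differences), giving
tracts a controlled detectability.  Genotypes are Binomial(2, freq)
with uniform missingness (default 10%, at most 40%).

**What the generator does not emulate:** linkage disequilibrium decay
within chromosomes (loci are exchangeable given their frequencies),
coalescent site-frequency spectra, sequencing error, spatially
autocorrelated sampling noise, and isolation-by-distance within
groups.  Tests passing on this generator therefore demonstrate
estimator correctness and statistical calibration under the planted
model, not robustness to every feature of real reduced-representation
data.

## Population-genetic estimators

* **Filtering** keeps loci with missing fraction strictly below 0.4
  and MAF ≥ 0.01 (computed on non-missing calls), the standard
  RAD-seq thresholds.
* **LD pruning** slides windows of 100 SNPs advanced by 10 per
  chromosome; within a window, a pair with dosage r² > 0.2
  (pairwise-complete Pearson; undefined pairs count as 0) is broken by
  removing the locus with more missing calls, ties to the larger
  index.  Pairs are visited in ascending index order, which makes the
  retained set deterministic and lets a brute-force oracle re-derive
  it exactly.
* **π** is Σ_sites 2p̂(1−p̂)·n/(n−1) over variant sites divided by the
  user-supplied covered length (per-base units); a population fixed
  everywhere has π = 0 exactly.
* **F_ST** is Weir & Cockerham (1984) θ with ratio-of-sums averaging,
  the stable choice for low-diversity loci; pairwise values are
  clipped to [0, 1].
* **PCA** mean-imputes missing dosages per locus, centres, and takes
  the SVD; component signs are fixed by making the largest-magnitude
  score positive.
* **MEM** builds great-circle distances, truncates at the longest
  minimum-spanning-tree edge (distances beyond it set to 4× the
  threshold), double-centres −d²/2 and keeps the top-k
  positive-eigenvalue eigenvectors (dbMEM).  Moran's I of MEM_j under
  the matching similarity weights 1 − (d/(4t))² decreases with j.

## Introgression statistics

Group allele frequencies are polarised on the pseudo-outgroup's major
allele; sites with outgroup MAF > 0.2 or missing in any trio
population are dropped.  Patterson's D uses the frequency products
ABBA = Σ(1−p1)p2p3(1−pO) etc.; Z is D over its delete-one standard
error from 20 contiguous equal-SNP jackknife blocks.  Windowed f_dM
follows the dynamic-donor definition (the larger of p2,p3 — or p1,p3
on the negative branch — replaces the putative recipient in the
denominator), signed so P3→P2 sharing is positive; windows hold 50
informative SNPs stepped by 25, and calling requires D > 0 and
f_dM > 0.15 (both strict).

The f4-ratio splits the donor into seeded random halves P3a/P3b and
estimates α = f4(P1,P2;P3a,O)/f4(P1,P3b;P3a,O).  (The superficially
similar form with f4(P1,O;P3b,P3a) in the denominator has expectation
zero under the admixture model and cannot recover α; the form used
here recovers a planted α = 0.3 to within ±0.02 on average.)

Tract recovery is assessed by the Jaccard overlap between loci inside
called window *spans* and the planted tract loci.  Window resolution
(50/25) caps attainable Jaccard: called windows overhang tract edges
by up to one window, so recovery is tested with tracts of ~200 loci
against which the overhang is small.

## Genotype–environment association

The latent-factor model tests each locus against each standardised
environmental variable conditional on K latent factors (default
K = 3, matching the three-lineage structure).  Factors solve the
ridge-penalised problem min ‖Y − W − XB‖² + λ‖B‖² by alternating the
ridge solve for B with a rank-K SVD truncation of Y − XB.  The penalty
defaults to λ = 0.3·n (X standardised, so X'X ≈ n·I): because group
structure and climate are strongly collinear in this design, a small λ
lets genuine lineage differences leak into the per-locus environmental
coefficient (genomic inflation ≈ 11), while λ → ∞ reduces to
conditioning on plain genotype PCs, which absorbs real clines and
halves power.  λ = 0.3·n keeps the null false-positive rate at
0.05–0.06 with uniform p-values *and* ~99% power against planted
clines of moderate slope; both regimes remain available
(`factor_method="pca"`, explicit `ridge=`).  Z-scores are rescaled by
the genomic inflation factor median(z²)/0.4549 before χ²₁ p-values;
candidates have calibrated p < 0.05 for at least one variable
(Benjamini–Hochberg optional).

RDA regresses centred dosages on the standardised (decorrelated,
|r| < 0.7 greedy subset) predictors, eigen-decomposes the fitted
values, and flags loci whose loadings on the first three constrained
axes lie more than 3 SD from the axis mean.  The final candidate set
is the LFMM ∩ RDA intersection.

## Gradient forest

Each SNP's population-frequency response is fit by a regression forest:
bootstrapped rows, variance-reduction (CART) splitting, depth ≤ 4,
minimum leaf of 2 — shallow because there are only ~18 rows.  By
default every predictor is tried at every split: with the 5–6
predictors typical here, random predictor subsetting mostly forces
splits on irrelevant variables whose chance gains would otherwise
accumulate (a pure-noise predictor would collect ~30–40% of a
noise-free driver's importance at mtry = 1); subsetting remains
available via `mtry` for wider predictor tables.  Out-of-bag R² is
computed from rows left out of each bootstrap; only SNPs with R² > 0
contribute to the aggregation, and negative-R² SNPs are excluded
rather than floored.

Aggregation: each split contributes its impurity reduction, normalised
within its tree, to one of 101 equal-width bins along the split
predictor's observed range; per SNP the binned importances are divided
by the empirical data density (bin histogram normalised to mean 1;
empty bins fall back to 1), rescaled so the SNP's total equals its R²,
summed over SNPs and cumulated.  The resulting turnover function F_p
starts at 0, is monotone non-decreasing, and ends at the predictor's
overall importance (conservation: Σ_p F_p(max) = Σ R², tolerance
1e-6).  Evaluation interpolates between bin edges and clamps outside
the fitted range.  MEM predictors participate in fitting (absorbing
spatial autocorrelation) but are never projected onto climate rasters:
they have no future analogue.

## Offsets and migration geometry

Climate stacks are transformed band-wise through F_p; offsets are
Euclidean distances in the transformed space.  Forward/reverse offsets
minimise over destination/source cells within a great-circle cap
(haversine, R = 6371.0088 km; cells exactly at the cap included); ties
are broken by smaller migration distance, then smaller cell index, so
maps are deterministic.  Migration distance and initial bearing
(normalised to [0, 360), 0 for a cell mapped to itself) point to the
forward-minimising cell.  The decline curve reports mean forward
offset per cap (0 km ≡ local) with step and cumulative percent
declines.  Group regions default to nearest-sampled-population Voronoi
assignment of in-mask cells; group comparisons use the two-sided
Mann–Whitney U normal approximation with continuity and tie
correction.

## Problem sizes and defaults

Library defaults follow the workflow's standard settings: MAF ≥ 0.01,
missingness < 0.4, LD 100/10/0.2, K = 3 latent factors, p < 0.05,
±3 SD RDA outliers, f_dM windows 50/25 with threshold 0.15, 500 trees,
distance caps {50, 100, 250, 500, ∞} km.  The test suite exercises
statistical recovery at desk scale — 2 000–5 000 loci, 18 populations,
10 seeds for parameter-recovery checks — which keeps the full suite
within a few minutes while leaving Monte-Carlo noise well inside the
asserted tolerances.

## Known limitations

* Climate grids are plain-text regular lon/lat stacks; there is no
  GeoTIFF/CRS handling, and raster I/O assumes co-registered layers.
* The LFMM backend is the deterministic ridge/SVD formulation, not an
  MCMC sampler; its calibration is demonstrated on the synthetic
  model, and the ridge default (0.3·n) is a bias–variance compromise,
  not a universally optimal choice.
* Forward/reverse offsets are O(cells²) in memory and time; grids
  beyond ~10⁴ masked cells need tiling.
* The generator draws loci independently: window statistics see clean
  tract boundaries rather than recombination-blurred ones.
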