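# offsetforest

Genomic-vulnerability analysis for fragmented tree populations: from a
genotype matrix and climate rasters to maps of how much a population's
climate-adapted genetic composition will be mismatched under future
climate, and where assisted migration could take it.

The package targets the study design of a relict montane tree sampled
across a handful of diverged lineages plus admixed (hybrid-zone)
groups: it identifies climate-associated SNPs, quantifies introgression
from a donor lineage into the admixed groups, fits a gradient-forest
turnover model, and maps genomic offsets.  A synthetic-data generator
with full ground truth (lineage structure, adaptive clines, planted
introgression tracts) makes the whole pipeline testable without any
sequencing data.

## What it computes

* **Population genetics** — MAF/missingness filtering, PLINK-style LD
  pruning (`--indep-pairwise`-like sliding windows), per-base
  nucleotide diversity π, observed/expected heterozygosity, pairwise
  Weir–Cockerham (1984) F_ST (ratio-of-sums), PCA, and distance-based
  Moran's eigenvector maps (dbMEM) as spatial predictors.
* **Introgression** — Patterson's D = (ABBA − BABA)/(ABBA + BABA) on
  polarised group allele frequencies with a block-jackknife Z-score,
  the f4-ratio admixture fraction α = f4(P1,P2;P3a,O)/f4(P1,P3b;P3a,O),
  and sliding-window f_dM scans (windows with D > 0 and f_dM > 0.15
  are called introgressed).
* **Genotype–environment association** — a latent-factor mixed model
  (ridge-regularised alternating factor estimation, genomic-inflation
  calibrated p-values) and redundancy analysis (RDA, ±3 SD loading
  outliers on the leading constrained axes); candidates are the
  intersection, optionally annotated against a GFF3 (±2.5 kb).
* **Gradient forest** — per-SNP regression forests (500 trees) over
  climate and MEM predictors; split impurity reductions from SNPs with
  positive out-of-bag R² are binned along each predictor,
  density-standardised, R²-scaled and cumulated into monotone turnover
  functions F_p; climate layers are mapped through F_p into a common
  genetic-importance space.
* **Offsets** — per-cell local offset ‖T_fut − T_cur‖₂; forward and
  reverse offsets (minimum offset over destination/source cells within
  a great-circle distance cap) with migration distance and initial
  bearing to the minimising cell; distance-cap decline curves; RGB
  composites; Wilcoxon rank-sum comparisons among group regions.

## Worked example

```python
import numpy as np, pandas as pd
import offsetforest as of

cfg = of.SimConfig(seed=42, n_neutral=1800, n_adaptive=200,
                   n_per_group=20, missing_rate=0.1, cline_slope=2.5)
current, future = of.make_landscape(cfg)
G, truth = of.simulate_genotypes(cfg, current)
Gf = of.filter_snps(G, maf_min=0.01, max_missing=0.4)

res = of.patterson_d(Gf, ("West", "Wmix", "South", "East"), f4_seed=42)
env = pd.DataFrame(current.values_at(Gf.samples["lon"].to_numpy(),
                                     Gf.samples["lat"].to_numpy()),
                   columns=current.names)
lf = of.lfmm_associate(Gf, env, K=3)
rd = of.rda_associate(Gf, env)
shared, venn = of.intersect_candidates(lf.lfmm_candidates,
                                       rd.rda_candidates)

freqs = Gf.group_freqs(by="population").iloc[:, sorted(shared)]
sites = Gf.samples.drop_duplicates("population")
env_pop = pd.DataFrame(current.values_at(sites["lon"].to_numpy(),
                                         sites["lat"].to_numpy()),
                       columns=current.names, index=sites["population"])
model = of.fit_gradient_forest(freqs.fillna(freqs.mean()), env_pop,
                               n_trees=500, seed=42)
t_cur = of.transform_climate(model, current)
t_fut = of.transform_climate(model, future)
maps = of.forward_offset(t_cur, t_fut, max_km=250.0)
```

Output for this configuration:

```
simulated 100 samples x 2000 SNPs
retained 1731 SNPs after MAF/missingness filtering
Patterson's D = 0.182, Z = 8.02, f4-ratio = 0.306
candidates: LFMM 372, RDA 36, shared 34
32/34 candidate SNPs with positive R2
mean local offset    = 2.9491
mean forward offset  = 1.6506 (max 250 km)
```

Reading it: the simulator planted admixture fraction 0.3 from the
South lineage into the Wmix group — the f4-ratio recovers 0.306, and
the strongly positive D (Z = 8 ≫ 3) correctly detects the gene flow.
The 34 intersected GEA candidates feed the turnover model; forward
offsets are lower than local offsets because populations can reach
better-matched climates within 250 km.

The same flow is available from the shell:

```bash
offsetforest simulate --config sim.yaml --out data/
offsetforest dstats --vcf data/genotypes.vcf --meta data/samples.tsv \
    --trios trios.yaml --out dstats.tsv
offsetforest run --config pipeline.yaml   # full pipeline + manifest
```

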