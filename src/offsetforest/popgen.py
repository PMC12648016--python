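"""SNP filtering, LD pruning, diversity statistics and PCA.

Differentiation uses the Weir & Cockerham (1984) variance-component
estimator of F_ST with ratio-of-sums averaging across loci, the standard
choice for low-diversity reduced-representation data.  Nucleotide
diversity is computed over variant sites and divided by the total
covered length supplied by the caller, mirroring how RAD-seq coverage
is used to put pi on a per-base scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["DiversityTable", "filter_snps", "locus_stats", "ld_prune",
           "diversity_stats", "weir_cockerham_fst", "pca"]


@dataclass
class DiversityTable:
    """Per-population diversity and pairwise differentiation.

    ``per_population`` columns: population, n_samples, pi, het_obs,
    het_exp (pi is per covered base; NaN marks undefined entries).
    ``fst`` is a symmetric DataFrame of pairwise Weir-Cockerham F_ST
    values clipped to [0, 1], zero diagonal.
    """

    per_population: pd.DataFrame
    fst: pd.DataFrame

    def to_tsv(self, pop_path, fst_path) -> None:
        self.per_population.to_csv(pop_path, sep="\t", index=False)
        self.fst.to_csv(fst_path, sep="\t")


# ---------------------------------------------------------------------------
# filtering


def locus_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus missing fraction and minor-allele frequency."""
    d = G.dosages_float()
    n_samples = G.n_samples
    n_called = np.sum(~np.isnan(d), axis=0)
    missing = 1.0 - n_called / n_samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(n_called == 0, 0.0, maf)
    return pd.DataFrame({"missing": missing, "maf": maf})


def filter_snps(G: GenotypeMatrix, maf_min: float = 0.01,
                max_missing: float = 0.4) -> GenotypeMatrix:
    """Retain loci with missing fraction < max_missing (strict) and
    MAF >= maf_min (inclusive), computed on non-missing calls.

    Locus order is preserved.  Filtering is idempotent.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    st = locus_stats(G)
    keep = (st["missing"].to_numpy() < max_missing) & \
           (st["maf"].to_numpy() >= maf_min)
    if not keep.any():
        warnings.warn("all loci removed by filtering; returning empty matrix")
    return G.take_loci(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# LD pruning


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns on
    pairwise-complete observations; undefined pairs (zero variance or
    fewer than two shared calls) give 0."""
    r = pd.DataFrame(d).corr(min_periods=2).fillna(0.0).to_numpy()
    r2 = r ** 2
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(G: GenotypeMatrix, window_snps: int = 100, step_snps: int = 10,
             r2_max: float = 0.2) -> np.ndarray:
    """Sliding-window LD pruning (PLINK ``--indep-pairwise`` style).

    Within every window of ``window_snps`` consecutive loci advanced by
    ``step_snps`` per chromosome, pairs of retained loci with squared
    dosage correlation > ``r2_max`` are broken by removing the locus
    with more missing calls (tie: the larger locus index).  Pairs are
    visited in ascending (i, j) index order; r^2 uses pairwise-complete
    observations and is defined as 0 when either locus has no variance.

    Returns the sorted array of retained locus indices.
    """
    if not window_snps > step_snps > 0:
        raise ValueError("require window_snps > step_snps > 0")
    d = G.dosages_float()
    n_missing = np.sum(np.isnan(d), axis=0)
    keep = np.ones(G.n_loci, dtype=bool)
    chroms = G.loci["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        n = len(cidx)
        for start in range(0, max(n - 1, 1), step_snps):
            widx = cidx[start:start + window_snps]
            if len(widx) < 2:
                continue
            r2 = _pairwise_r2(d[:, widx])
            for a in range(len(widx)):
                ia = widx[a]
                if not keep[ia]:
                    continue
                for b in range(a + 1, len(widx)):
                    ib = widx[b]
                    if not keep[ib]:
                        continue
                    if r2[a, b] > r2_max:
                        if n_missing[ia] > n_missing[ib]:
                            keep[ia] = False
                            break
                        keep[ib] = False
            if start + window_snps >= n:
                break
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# diversity and differentiation


def _pop_counts(G: GenotypeMatrix, pops: list[str], by: str):
    """Per population: allele counts n_i (diploids called), freqs p_i and
    observed het h_i, each (n_pops, n_loci)."""
    d = G.dosages_float()
    n = np.zeros((len(pops), G.n_loci))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for i, pop in enumerate(pops):
        sub = d[G.sample_index(by, pop)]
        called = ~np.isnan(sub)
        n[i] = called.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p[i] = np.nanmean(sub, axis=0) / 2.0
            h[i] = np.nanmean(sub == 1, axis=0)
    return n, p, h


def weir_cockerham_fst(n: np.ndarray, p: np.ndarray,
                       h: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) theta from per-population per-locus
    sample sizes ``n`` (diploid individuals), allele frequencies ``p``
    and observed heterozygote fractions ``h`` (arrays (r, L)).

    Returns (theta, a, a+b+c) with per-locus variance components summed
    ratio-of-sums style; loci with fewer than two populations having
    data are skipped.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    valid = (n > 0)
    r_eff = valid.sum(axis=0)
    use = r_eff >= 2
    n = n[:, use]
    p = np.where(valid[:, use], p[:, use], 0.0)
    h = np.where(valid[:, use], h[:, use], 0.0)
    r = r_eff[use].astype(float)

    nsum = n.sum(axis=0)
    nbar = nsum / r
    nc = (nsum - (n ** 2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n * p).sum(axis=0) / nsum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / nsum

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    tot = a + b + c
    ok = np.isfinite(a) & np.isfinite(tot)
    denom = float(tot[ok].sum())
    theta = float(a[ok].sum() / denom) if denom != 0 else np.nan
    return theta, a[ok], tot[ok]


def diversity_stats(G: GenotypeMatrix, covered_bases: int,
                    by: str = "population") -> DiversityTable:
    """Per-population pi, heterozygosity and pairwise W-C F_ST.

    pi per population = sum over variant sites of 2*p*(1-p) * n/(n-1)
    (n = non-missing allele count at the site) divided by
    ``covered_bases``.  Populations with fewer than 2 called alleles at
    every locus are flagged undefined (NaN).
    """
    if covered_bases < G.n_loci:
        raise ValueError("covered_bases must be >= number of variant sites")
    pops = list(pd.unique(G.samples[by]))
    d = G.dosages_float()
    rows = []
    for pop in pops:
        sub = d[G.sample_index(by, pop)]
        called = ~np.isnan(sub)
        n_alleles = 2.0 * called.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(sub, axis=0) / 2.0
            ho = np.nanmean(sub == 1, axis=0)
        ok = n_alleles >= 2
        if not ok.any():
            rows.append((pop, sub.shape[0], np.nan, np.nan, np.nan))
            continue
        pi_site = 2 * p[ok] * (1 - p[ok]) * n_alleles[ok] / (n_alleles[ok] - 1)
        pi = float(pi_site.sum() / covered_bases)
        he = float(np.mean(2 * p[ok] * (1 - p[ok])))
        rows.append((pop, sub.shape[0], pi, float(np.nanmean(ho[ok])), he))
    per_pop = pd.DataFrame(rows, columns=["population", "n_samples", "pi",
                                          "het_obs", "het_exp"])

    n, p, h = _pop_counts(G, pops, by)
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            theta, _, _ = weir_cockerham_fst(n[[i, j]], p[[i, j]], h[[i, j]])
            theta = float(np.clip(theta, 0.0, 1.0)) if np.isfinite(theta) else np.nan
            fst.iloc[i, j] = fst.iloc[j, i] = theta
    return DiversityTable(per_pop, fst)


def multi_population_fst(G: GenotypeMatrix, pops: list[str] | None = None,
                         by: str = "population") -> float:
    """Overall W-C theta across several populations (ratio of sums)."""
    if pops is None:
        pops = list(pd.unique(G.samples[by]))
    n, p, h = _pop_counts(G, pops, by)
    theta, _, _ = weir_cockerham_fst(n, p, h)
    return theta


# ---------------------------------------------------------------------------
# PCA


def pca(G: GenotypeMatrix, n_components: int = 10, scale: bool = False):
    """PCA of the dosage matrix with per-locus mean imputation.

    Loci are centred on their mean dosage (and optionally scaled to unit
    variance); missing calls are imputed at the locus mean.  Scores are
    sample coordinates U*S from the SVD of the centred matrix; explained
    variance fractions are relative to the total variance and therefore
    sum to <= 1 and are non-increasing.
    """
    if G.n_samples < 2 or G.n_loci < 2:
        raise ValueError("need at least 2 samples and 2 loci")
    kmax = min(G.n_samples, G.n_loci)
    if n_components > kmax:
        warnings.warn(f"n_components clipped from {n_components} to {kmax}")
        n_components = kmax
    d = G.dosages_float()
    mu = np.nanmean(d, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    X = np.where(np.isnan(d), mu, d) - mu
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd == 0, 1.0, sd)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    # deterministic sign convention
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    ev = s ** 2 / (G.n_samples - 1)
    total_var = X.var(axis=0, ddof=1).sum()
    frac = ev[:n_components] / total_var if total_var > 0 else ev[:n_components] * 0
    return scores, frac
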