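"""Four-taxon introgression statistics on genotype frequencies.

Implements frequency-based Patterson's D with a block-jackknife
Z-score, the f4-ratio admixture-fraction estimate, and sliding-window
f_dM scans for localising introgressed regions, following the
Dsuite-style definitions.  A trio is specified as four population (or
group) labels (P1, P2, P3, O) under the assumed topology
(((P1, P2), P3), O); positive D indicates excess allele sharing between
P2 and P3.

Without a true outgroup, alleles are polarised on the designated
pseudo-outgroup's major allele; sites where the outgroup is too
polymorphic are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["TrioResult", "WindowScan", "d_from_sums", "patterson_d",
           "f4_ratio", "window_fdm", "call_introgressed_windows",
           "overlap_with_candidates"]


@dataclass
class TrioResult:
    trio: tuple[str, str, str, str]
    d: float
    z: float
    f4_ratio: float | None
    bbaa: float
    abba: float
    baba: float
    n_sites: int


@dataclass
class WindowScan:
    """Sliding-window D and f_dM.  ``windows`` columns: chrom,
    start_idx, end_idx (indices into the trio-informative site list),
    start_pos, end_pos, n_snps, d, fdm, flagged."""

    trio: tuple[str, str, str, str]
    windows: pd.DataFrame
    site_loci: pd.DataFrame  # chrom/pos of the informative sites used

    def to_tsv(self, path) -> None:
        cols = ["chrom", "start_pos", "end_pos", "n_snps", "d", "fdm",
                "flagged"]
        self.windows[cols].to_csv(path, sep="\t", index=False)


def d_from_sums(abba: float, baba: float) -> float:
    """Patterson's D = (ABBA - BABA)/(ABBA + BABA)."""
    tot = abba + baba
    if tot == 0:
        return np.nan
    return (abba - baba) / tot


# ---------------------------------------------------------------------------
# site preparation


def _trio_freqs(G: GenotypeMatrix, trio, out_maf_max: float = 0.2):
    """Derived-allele frequencies (p1, p2, p3, pO) at usable sites.

    A site is usable when every trio population has at least one
    non-missing call, the four frequencies are not all equal, and the
    outgroup minor-allele frequency is <= ``out_maf_max``.  Frequencies
    are polarised so the outgroup major allele is ancestral.
    Returns (freqs (4, n_sites), locus index array).
    """
    by = "group" if set(trio) <= set(G.samples["group"]) else "population"
    d = G.dosages_float()
    freqs = []
    for label in trio:
        idx = G.sample_index(by, label)
        if len(idx) == 0:
            raise ValueError(f"no samples labelled {label!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freqs.append(np.nanmean(d[idx], axis=0) / 2.0)
    p = np.vstack(freqs)
    usable = ~np.isnan(p).any(axis=0)
    pO = p[3]
    with np.errstate(invalid="ignore"):
        usable &= np.minimum(pO, 1 - pO) <= out_maf_max
        usable &= ~np.all(p == p[0], axis=0)
    p = p[:, usable]
    flip = p[3] > 0.5
    p[:, flip] = 1.0 - p[:, flip]
    return p, np.flatnonzero(usable)


def _pattern_sums(p: np.ndarray):
    """Site-pattern sums (bbaa, abba, baba) from derived freqs (4, n)."""
    p1, p2, p3, pO = p
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    bbaa = p1 * p2 * (1 - p3) * (1 - pO)
    return bbaa, abba, baba


# ---------------------------------------------------------------------------
# D statistic with block jackknife


def patterson_d(G: GenotypeMatrix, trio, n_blocks: int = 20,
                out_maf_max: float = 0.2, f4_seed: int | None = None
                ) -> TrioResult:
    """Patterson's D over all usable sites with jackknife Z-score.

    Z is D divided by its standard error from a delete-one block
    jackknife over ``n_blocks`` contiguous equal-SNP blocks (reduced
    with a warning if fewer usable sites than blocks exist).
    """
    p, sites = _trio_freqs(G, trio, out_maf_max)
    bbaa, abba, baba = _pattern_sums(p)
    s_abba, s_baba, s_bbaa = abba.sum(), baba.sum(), bbaa.sum()
    d = d_from_sums(s_abba, s_baba)

    n_sites = p.shape[1]
    if n_sites < n_blocks:
        warnings.warn(f"only {n_sites} usable sites; reducing jackknife "
                      f"blocks from {n_blocks}")
        n_blocks = max(n_sites, 1)
    z = np.nan
    if np.isfinite(d) and n_blocks >= 2:
        bounds = np.linspace(0, n_sites, n_blocks + 1).astype(int)
        d_del = []
        for b in range(n_blocks):
            sl = slice(bounds[b], bounds[b + 1])
            d_del.append(d_from_sums(s_abba - abba[sl].sum(),
                                     s_baba - baba[sl].sum()))
        d_del = np.asarray(d_del)
        ok = np.isfinite(d_del)
        m = ok.sum()
        if m >= 2:
            se = np.sqrt((m - 1) / m * np.sum((d_del[ok] - d_del[ok].mean()) ** 2))
            z = d / se if se > 0 else np.nan

    f4r = None
    if f4_seed is not None:
        f4r = f4_ratio(G, trio, seed=f4_seed, out_maf_max=out_maf_max)
    return TrioResult(tuple(trio), float(d), float(z), f4r,
                      float(s_bbaa), float(s_abba), float(s_baba), n_sites)


# ---------------------------------------------------------------------------
# f4-ratio


def f4_ratio(G: GenotypeMatrix, trio, seed: int = 0,
             out_maf_max: float = 0.2) -> float:
    """Admixture fraction of donor P3 ancestry in P2.

    The donor population is split into random halves P3a/P3b (seeded)
    and alpha is estimated by the Patterson f4-ratio
    f4(P1, P2; P3a, O) / f4(P1, P3b; P3a, O), clipped to [0, 1].
    Returns NaN when the denominator is numerically zero.
    """
    by = "group" if set(trio) <= set(G.samples["group"]) else "population"
    p3_idx = G.sample_index(by, trio[2])
    if len(p3_idx) < 2:
        raise ValueError("donor population needs at least 2 samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(p3_idx))
    half = len(p3_idx) // 2
    ia, ib = p3_idx[perm[:half]], p3_idx[perm[half:]]

    d = G.dosages_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        labels = {lab: np.nanmean(d[G.sample_index(by, lab)], axis=0) / 2.0
                  for lab in (trio[0], trio[1], trio[3])}
        p3a = np.nanmean(d[ia], axis=0) / 2.0
        p3b = np.nanmean(d[ib], axis=0) / 2.0
    p1, p2, pO = labels[trio[0]], labels[trio[1]], labels[trio[3]]
    stack = np.vstack([p1, p2, p3a, p3b, pO])
    use = ~np.isnan(stack).any(axis=0)
    with np.errstate(invalid="ignore"):
        use &= np.minimum(pO, 1 - pO) <= out_maf_max
    p1, p2, p3a, p3b, pO = stack[:, use]
    flip = pO > 0.5
    for arr in (p1, p2, p3a, p3b, pO):
        arr[flip] = 1.0 - arr[flip]

    num = np.sum((p1 - p2) * (p3a - pO))
    den = np.sum((p1 - p3b) * (p3a - pO))
    if abs(den) < 1e-12:
        return np.nan
    return float(np.clip(num / den, 0.0, 1.0))


# ---------------------------------------------------------------------------
# windowed f_dM


def _fdm_window(p: np.ndarray) -> float:
    """Malinsky-style f_dM for one window of derived freqs (4, n).

    Numerator ABBA - BABA; the denominator replaces the putative
    recipient by the dynamic donor (the larger of the two candidate
    frequencies per sign branch), so complete P3->P2 sharing gives +1
    and P3->P1 sharing gives -1.
    """
    p1, p2, p3, pO = p
    num = ((1 - p1) * p2 * p3 * (1 - pO) - p1 * (1 - p2) * p3 * (1 - pO))
    pD23 = np.maximum(p2, p3)
    pD13 = np.maximum(p1, p3)
    den_pos = ((1 - p1) * pD23 * pD23 * (1 - pO)
               - p1 * (1 - pD23) * pD23 * (1 - pO))
    den_neg = ((1 - pD13) * p2 * pD13 * (1 - pO)
               - pD13 * (1 - p2) * pD13 * (1 - pO))
    branch_pos = p2 >= p1
    den = np.where(branch_pos, den_pos, -den_neg)
    s = den.sum()
    if s == 0:
        return np.nan
    return float(num.sum() / s)


def window_fdm(G: GenotypeMatrix, trio, window_snps: int = 50,
               step_snps: int = 25, out_maf_max: float = 0.2,
               fdm_min: float = 0.15) -> WindowScan:
    """Sliding-window D and f_dM over trio-informative sites.

    Windows hold ``window_snps`` informative sites advanced by
    ``step_snps`` within each chromosome; the final window of a
    chromosome may be shorter.  Windows are flagged as introgressed
    when D > 0 and f_dM > ``fdm_min`` (both strict).
    """
    p, sites = _trio_freqs(G, trio, out_maf_max)
    loci = G.loci.iloc[sites]  # index keeps the original locus ids
    rows = []
    chroms = loci["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cpos = np.flatnonzero(chroms == chrom)
        n = len(cpos)
        start = 0
        while start < n:
            idx = cpos[start:start + window_snps]
            sub = p[:, idx]
            _, abba, baba = _pattern_sums(sub)
            d_w = d_from_sums(abba.sum(), baba.sum())
            fdm = _fdm_window(sub)
            rows.append({
                "chrom": chrom,
                "start_idx": int(idx[0]), "end_idx": int(idx[-1]),
                "start_pos": int(loci["pos"].iloc[idx[0]]),
                "end_pos": int(loci["pos"].iloc[idx[-1]]),
                "n_snps": len(idx), "d": d_w, "fdm": fdm,
            })
            if start + window_snps >= n:
                break
            start += step_snps
    win = pd.DataFrame(rows)
    if len(win):
        win["flagged"] = ((win["d"] > 0) & (win["fdm"] > fdm_min)
                          & np.isfinite(win["fdm"]))
    else:
        win = pd.DataFrame(columns=["chrom", "start_idx", "end_idx",
                                    "start_pos", "end_pos", "n_snps",
                                    "d", "fdm", "flagged"])
    return WindowScan(tuple(trio), win, loci)


def call_introgressed_windows(scan: WindowScan,
                              fdm_min: float = 0.15) -> pd.DataFrame:
    """Windows with D > 0 and f_dM > fdm_min (strict inequalities)."""
    w = scan.windows
    keep = (w["d"] > 0) & (w["fdm"] > fdm_min) & np.isfinite(w["fdm"])
    return w[keep].reset_index(drop=True)


def flagged_site_ids(scan: WindowScan, windows: pd.DataFrame) -> set[int]:
    """Original locus indices covered by the given windows (via the
    informative-site index ranges, endpoints inclusive)."""
    ids: set[int] = set()
    site_index = scan.site_loci.index.to_numpy()
    for _, w in windows.iterrows():
        ids.update(int(i) for i in
                   site_index[int(w["start_idx"]):int(w["end_idx"]) + 1])
    return ids


def overlap_with_candidates(windows: pd.DataFrame, loci: pd.DataFrame,
                            candidate_ids: set[int] | list[int]
                            ) -> tuple[int, int, float]:
    """Count candidate loci inside called windows.

    ``loci`` is the full locus table (chrom/pos, indexed by locus id);
    a candidate is counted when its position falls inside a window's
    [start_pos, end_pos] span on the same chromosome (inclusive).
    Returns (n_overlapping_candidates, n_window_snps, fraction), where
    the fraction is relative to the number of SNPs covered by windows.
    """
    cand = set(int(c) for c in candidate_ids)
    n_window_snps = 0
    in_windows: set[int] = set()
    chrom_arr = loci["chrom"].to_numpy()
    pos_arr = loci["pos"].to_numpy()
    for _, w in windows.iterrows():
        hit = ((chrom_arr == w["chrom"]) & (pos_arr >= w["start_pos"])
               & (pos_arr <= w["end_pos"]))
        ids = np.flatnonzero(hit)
        n_window_snps += len(ids)
        in_windows.update(int(i) for i in ids)
    n_overlap = len(cand & in_windows)
    frac = n_overlap / len(in_windows) if in_windows else 0.0
    return n_overlap, len(in_windows), frac
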