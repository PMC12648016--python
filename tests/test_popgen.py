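import numpy as np
import pandas as pd
import pytest

import offsetforest as of
from offsetforest.genotypes import MISSING
from offsetforest.popgen import locus_stats, multi_population_fst
from conftest import toy_matrix


# ---------------------------------------------------------------------------
# filtering


def test_filter_monomorphic_and_boundary_missing():
    # locus0 monomorphic (MAF 0); locus1 has 2/5 missing = 40% (boundary)
    d = [[0, 1], [0, 1], [0, MISSING], [0, MISSING], [0, 0]]
    G = toy_matrix(d)
    Gf = of.filter_snps(G, maf_min=0.01, max_missing=0.4)
    assert Gf.n_loci == 0  # monomorphic removed; 40% missing removed (strict)


def test_filter_planted_recount(rng):
    n, L = 30, 200
    d = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    bad = rng.choice(L, size=40, replace=False)
    fail_maf, fail_miss = bad[:20], bad[20:]
    d[:, fail_maf] = 0  # monomorphic -> MAF 0
    d[: int(0.5 * n), fail_miss] = MISSING  # 50% missing
    G = toy_matrix(d)
    Gf = of.filter_snps(G, maf_min=0.01, max_missing=0.4)
    st = locus_stats(G)
    expected = [i for i in range(L)
                if st["missing"][i] < 0.4 and st["maf"][i] >= 0.01]
    assert Gf.n_loci == len(expected)
    assert set(bad).isdisjoint(expected)


def test_filter_idempotent(small_sim):
    G = small_sim["G"]
    once = of.filter_snps(G)
    twice = of.filter_snps(once)
    assert np.array_equal(once.dosages, twice.dosages)


# ---------------------------------------------------------------------------
# LD pruning


def _r2_complete_case(x, y):
    """Plain complete-case Pearson r^2, written out longhand."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    vx, vy = (xs ** 2).sum(), (ys ** 2).sum()
    if vx == 0 or vy == 0:
        return 0.0
    return float((xs @ ys) ** 2 / (vx * vy))


def _prune_oracle(G, window, step, r2_max):
    """Independent re-implementation of the pruning rule."""
    d = G.dosages_float()
    miss = np.sum(np.isnan(d), axis=0)
    keep = np.ones(G.n_loci, dtype=bool)
    chroms = G.loci["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        for start in range(0, max(len(cidx) - 1, 1), step):
            w = cidx[start:start + window]
            r = np.array([[_r2_complete_case(d[:, i], d[:, j])
                           for j in w] for i in w])
            for a in range(len(w)):
                if not keep[w[a]]:
                    continue
                for b in range(a + 1, len(w)):
                    if not keep[w[b]]:
                        continue
                    if r[a, b] > r2_max:
                        if miss[w[a]] > miss[w[b]]:
                            keep[w[a]] = False
                            break
                        keep[w[b]] = False
            if start + window >= len(cidx):
                break
    return np.flatnonzero(keep)


def test_prune_duplicated_locus_removed():
    d = np.array([[0, 0, 1], [1, 1, 0], [2, 2, 2], [0, 0, 1], [1, 1, 0]],
                 dtype=np.int8)
    G = toy_matrix(d)
    kept = of.ld_prune(G, window_snps=10, step_snps=2, r2_max=0.2)
    assert 0 in kept and 1 not in kept  # tie on missing -> larger index out


def test_prune_independent_loci_all_kept(rng):
    d = rng.integers(0, 3, size=(200, 30)).astype(np.int8)
    G = toy_matrix(d)
    kept = of.ld_prune(G, window_snps=10, step_snps=2, r2_max=0.2)
    assert len(kept) == 30


def test_prune_matches_bruteforce_oracle(rng):
    # correlated blocks + missing data on one chromosome
    n, L = 60, 300
    base = rng.integers(0, 3, size=(n, L)).astype(float)
    for j in range(0, L, 7):  # plant LD: copies with noise
        k = min(j + 3, L - 1)
        flip = rng.random(n) < 0.1
        base[:, k] = np.where(flip, rng.integers(0, 3, n), base[:, j])
    base[rng.random((n, L)) < 0.05] = MISSING
    G = toy_matrix(base.astype(np.int8))
    kept = of.ld_prune(G, window_snps=100, step_snps=10, r2_max=0.2)
    oracle = _prune_oracle(G, 100, 10, 0.2)
    assert np.array_equal(kept, oracle)


def test_prune_result_has_no_violating_pair(small_sim):
    G = of.filter_snps(small_sim["G"]).take_loci(np.arange(150))
    kept = of.ld_prune(G, window_snps=100, step_snps=10, r2_max=0.2)
    dk = G.dosages_float()[:, kept]
    r2 = np.array([[_r2_complete_case(dk[:, i], dk[:, j])
                    for j in range(dk.shape[1])]
                   for i in range(dk.shape[1])])
    # exhaustive check within every sliding window over the kept set
    chrom_idx = {c: np.flatnonzero(G.loci["chrom"].to_numpy() == c)
                 for c in pd.unique(G.loci["chrom"])}
    pos_of = {int(k): i for i, k in enumerate(kept)}
    for cidx in chrom_idx.values():
        for start in range(0, len(cidx), 10):
            w = [pos_of[int(i)] for i in cidx[start:start + 100]
                 if int(i) in pos_of]
            for a in range(len(w)):
                for b in range(a + 1, len(w)):
                    assert r2[w[a], w[b]] <= 0.2 + 1e-12


# ---------------------------------------------------------------------------
# diversity and F_ST


def test_fst_identical_populations_near_zero(rng):
    d = rng.integers(0, 3, size=(50, 300)).astype(np.int8)
    G = toy_matrix(np.vstack([d, d]), pops=["A"] * 50 + ["B"] * 50)
    div = of.diversity_stats(G, covered_bases=10_000)
    assert abs(div.fst.loc["A", "B"]) < 0.02


def test_fst_fixed_differences_near_one():
    d = np.vstack([np.zeros((50, 100)), np.full((50, 100), 2)]).astype(np.int8)
    G = toy_matrix(d, pops=["A"] * 50 + ["B"] * 50)
    div = of.diversity_stats(G, covered_bases=10_000)
    assert div.fst.loc["A", "B"] >= 0.95


def test_weir_cockerham_hand_oracle():
    """Two populations, one locus: p1=0.2, p2=0.8, n=10 each, all
    variant alleles in heterozygotes.  Hand-stepped WC84:
    a=0.17333, b=-0.03333, c=0.2 -> theta = 0.509804."""
    n = np.array([[10.0], [10.0]])
    p = np.array([[0.2], [0.8]])
    h = np.array([[0.4], [0.4]])
    theta, a, tot = of.weir_cockerham_fst(n, p, h)
    assert theta == pytest.approx(0.17333333 / 0.34, abs=1e-6)
    assert a[0] == pytest.approx(0.17333333, abs=1e-6)


def test_pi_zero_when_fixed():
    d = np.full((20, 50), 2, dtype=np.int8)
    G = toy_matrix(d)
    div = of.diversity_stats(G, covered_bases=1_000)
    assert div.per_population["pi"].iloc[0] == 0.0


def test_pi_per_base_scaling():
    # single variant site with p=0.5 among 10 diploids: pi_site =
    # 2*0.5*0.5*20/19; covered length 1000
    d = np.array([[0]] * 5 + [[2]] * 5, dtype=np.int8)
    G = toy_matrix(d)
    div = of.diversity_stats(G, covered_bases=1000)
    assert div.per_population["pi"].iloc[0] == pytest.approx(
        (2 * 0.25 * 20 / 19) / 1000)


def test_fst_recovers_simulation_target():
    cfg = of.SimConfig(seed=0, n_neutral=5000, n_adaptive=0, n_per_group=20)
    cur, _ = of.make_landscape(cfg)
    G, _ = of.simulate_genotypes(cfg, cur)
    theta = multi_population_fst(G, ["West", "East", "South"], by="group")
    assert abs(theta - 0.3) < 0.05


# ---------------------------------------------------------------------------
# PCA


def test_pca_separates_lineages():
    cfg = of.SimConfig(seed=9, n_neutral=800, n_adaptive=0, fst_target=0.4,
                       n_per_group=15)
    cur, _ = of.make_landscape(cfg)
    G, _ = of.simulate_genotypes(cfg, cur)
    idx = np.flatnonzero(G.samples["group"].isin(["West", "East"]))
    sub = G.take_samples(idx)
    scores, _ = of.pca(sub, n_components=2)
    labels = (sub.samples["group"] == "West").to_numpy()
    x = scores[:, 0]
    # silhouette on PC1, computed directly
    sil = []
    for i in range(len(x)):
        same = np.abs(x[i] - x[labels == labels[i]])
        other = np.abs(x[i] - x[labels != labels[i]])
        a = same.sum() / (len(same) - 1)
        b = other.mean()
        sil.append((b - a) / max(a, b))
    assert np.mean(sil) > 0.8


def test_pca_duplicate_samples_get_identical_scores(small_sim):
    G = small_sim["G"].take_loci(np.arange(200))
    dup = of.GenotypeMatrix(
        np.vstack([G.dosages, G.dosages]),
        G.loci,
        pd.concat([G.samples,
                   G.samples.assign(sample_id=G.samples.sample_id + "_d")],
                  ignore_index=True))
    scores, _ = of.pca(dup, n_components=3)
    n = G.n_samples
    assert np.allclose(scores[:n], scores[n:], atol=1e-8)


def test_pca_scores_orthogonal_and_variance_fractions(small_sim):
    G = small_sim["G"]
    scores, frac = of.pca(G, n_components=5)
    gram = scores.T @ scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()
    assert np.all(np.diff(frac) <= 1e-12)
    assert frac.sum() <= 1.0 + 1e-9


def test_pca_clips_components():
    G = toy_matrix(np.random.default_rng(0).integers(0, 3, (4, 10)
                                                     ).astype(np.int8))
    with pytest.warns(UserWarning, match="clipped"):
        scores, frac = of.pca(G, n_components=8)
    assert scores.shape[1] == 4
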