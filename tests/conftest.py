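import numpy as np
import pandas as pd
import pytest

import offsetforest as of


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic dataset shared by read-only tests."""
    cfg = of.SimConfig(seed=7, n_neutral=600, n_adaptive=60, n_per_group=12,
                       missing_rate=0.1)
    current, future = of.make_landscape(cfg)
    G, truth = of.simulate_genotypes(cfg, current)
    return {"config": cfg, "current": current, "future": future,
            "G": G, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_stack_pair(rng, rows, cols, n_bands=3, mask_p=0.8):
    """Co-registered random current/future stacks for offset tests."""
    from offsetforest.climate import ClimateStack

    mask = rng.random((rows, cols)) < mask_p
    if not mask.any():
        mask[0, 0] = True
    lon = np.sort(rng.uniform(100, 110, cols))
    lat = np.sort(rng.uniform(25, 33, rows))[::-1]
    names = [f"b{i}" for i in range(n_bands)]
    cur = ClimateStack(names, rng.normal(0, 1, (n_bands, rows, cols)),
                       lon, lat, mask)
    fut = ClimateStack(names, rng.normal(0, 1, (n_bands, rows, cols)),
                       lon, lat, mask)
    return cur, fut


def toy_matrix(dosages, chrom=None, pops=None, groups=None):
    """GenotypeMatrix from a plain dosage array with minimal metadata."""
    d = np.asarray(dosages, dtype=np.int8)
    n, L = d.shape
    if chrom is None:
        chrom = ["chr1"] * L
    chrom = np.asarray(chrom)
    loci = pd.DataFrame({
        "chrom": chrom,
        "pos": np.concatenate([np.arange(1, 1 + (chrom == c).sum()) * 100
                               for c in pd.unique(chrom)]),
        "ref": "A", "alt": "T"})
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "population": pops if pops is not None else ["p0"] * n,
        "group": groups if groups is not None else ["g0"] * n,
        "lon": np.linspace(100, 101, n),
        "lat": np.linspace(30, 31, n)})
    return of.GenotypeMatrix(d, loci, samples)
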