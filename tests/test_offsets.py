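import numpy as np
import pandas as pd
import pytest
from scipy import stats

import offsetforest as of
from offsetforest.climate import ClimateStack
from offsetforest.spatial import great_circle
from conftest import random_stack_pair


def _stack(data, names=None, mask=None):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    n, rows, cols = data.shape
    names = names or [f"b{i}" for i in range(n)]
    return ClimateStack(names, data, np.linspace(100, 100 + cols - 1, cols),
                        np.linspace(30 + rows - 1, 30, rows), mask)


def _oracle_offsets(cur, fut, cap):
    A, lon, lat = cur.masked_table()
    B, _, _ = fut.masked_table()
    n = len(A)
    fwd = np.full(n, np.nan)
    rev = np.full(n, np.nan)
    for i in range(n):
        bf = br = np.inf
        for j in range(n):
            d, _ = great_circle(lon[i], lat[i], lon[j], lat[j])
            if cap is not None and d > cap:
                continue
            bf = min(bf, float(np.sqrt(((A[i] - B[j]) ** 2).sum())))
            br = min(br, float(np.sqrt(((B[i] - A[j]) ** 2).sum())))
        fwd[i], rev[i] = bf, br
    return fwd, rev


# ---------------------------------------------------------------------------
# local offset


def test_local_offset_identity(rng):
    cur, _ = random_stack_pair(rng, 5, 6)
    out = of.local_offset(cur, cur)
    assert np.nanmax(out) == 0.0
    assert np.all(np.isnan(out[~cur.mask]))


def test_local_offset_single_band_delta():
    cur = _stack(np.zeros((3, 3)))
    fut_data = np.zeros((3, 3))
    fut_data[1, 2] = -1.75
    fut = _stack(fut_data)
    out = of.local_offset(cur, fut)
    assert out[1, 2] == pytest.approx(1.75)
    out[1, 2] = 0
    assert np.allclose(out, 0)


def test_local_offset_hand_computed_three_bands():
    cur = _stack(np.zeros((3, 2, 2)))
    fut = _stack(np.array([[[1.0, 0], [0, 2]],
                           [[2.0, 0], [0, 3]],
                           [[2.0, 0], [0, 6]]]))
    out = of.local_offset(cur, fut)
    assert out[0, 0] == pytest.approx(3.0, abs=1e-12)  # sqrt(1+4+4)
    assert out[1, 1] == pytest.approx(7.0, abs=1e-12)  # sqrt(4+9+36)
    assert out[0, 1] == 0.0


def test_band_mismatch_named():
    a = _stack(np.zeros((2, 2)), names=["x"])
    b = _stack(np.zeros((2, 2)), names=["y"])
    with pytest.raises(ValueError, match="x.*y"):
        of.local_offset(a, b)


# ---------------------------------------------------------------------------
# forward / reverse


def test_forward_cap_zero_equals_local(rng):
    cur, fut = random_stack_pair(rng, 6, 6)
    maps = of.forward_offset(cur, fut, max_km=0.0)
    assert np.allclose(maps.forward[cur.mask], maps.local[cur.mask],
                       atol=1e-12)
    assert np.all(maps.migration_km[cur.mask] == 0.0)


def test_forward_never_exceeds_local(rng):
    cur, fut = random_stack_pair(rng, 7, 8)
    maps = of.forward_offset(cur, fut)
    m = cur.mask
    assert np.all(maps.forward[m] <= maps.local[m] + 1e-12)


def test_forward_reverse_match_bruteforce(rng):
    for _ in range(8):
        rows, cols = rng.integers(3, 8, 2)
        cur, fut = random_stack_pair(rng, rows, cols)
        cap = [None, 150.0, 400.0][int(rng.integers(3))]
        maps = of.forward_offset(cur, fut, max_km=cap)
        rev = of.reverse_offset(cur, fut, max_km=cap)
        fwd_o, rev_o = _oracle_offsets(cur, fut, cap)
        assert np.allclose(maps.forward[cur.mask], fwd_o, atol=1e-12,
                           equal_nan=True)
        assert np.allclose(rev[cur.mask], rev_o, atol=1e-12, equal_nan=True)


def test_forward_monotone_in_cap(rng):
    cur, fut = random_stack_pair(rng, 6, 7)
    prev = None
    for cap in (0.0, 100.0, 300.0, None):
        f = of.forward_offset(cur, fut, max_km=cap).forward
        if prev is not None:
            assert np.all(f[cur.mask] <= prev[cur.mask] + 1e-12)
        prev = f


def test_reverse_identity_and_single_cell(rng):
    cur, fut = random_stack_pair(rng, 5, 5)
    assert np.allclose(of.reverse_offset(cur, cur)[cur.mask], 0.0)
    mask1 = np.zeros((5, 5), dtype=bool)
    mask1[2, 2] = True
    c1 = ClimateStack(cur.names, cur.data, cur.lon, cur.lat, mask1)
    f1 = ClimateStack(fut.names, fut.data, fut.lon, fut.lat, mask1)
    rev = of.reverse_offset(c1, f1)
    loc = of.local_offset(c1, f1)
    assert rev[2, 2] == pytest.approx(loc[2, 2], abs=1e-12)


def test_reverse_equals_forward_with_roles_swapped(rng):
    cur, fut = random_stack_pair(rng, 6, 6)
    rev = of.reverse_offset(cur, fut)
    fwd_swapped = of.forward_offset(fut, cur).forward
    assert np.allclose(rev[cur.mask], fwd_swapped[cur.mask], atol=1e-12)


def test_forward_rejects_negative_cap(rng):
    cur, fut = random_stack_pair(rng, 4, 4)
    with pytest.raises(ValueError, match="non-negative"):
        of.forward_offset(cur, fut, max_km=-5.0)


def test_migration_geometry_consistent(rng):
    cur, fut = random_stack_pair(rng, 6, 6, mask_p=1.0)
    maps = of.forward_offset(cur, fut)
    _, lon, lat = cur.masked_table()
    m = cur.mask
    arg = maps.argmin_cell[m]
    d, b = great_circle(lon, lat, lon[arg], lat[arg])
    assert np.allclose(maps.migration_km[m], d, atol=1e-9)
    assert np.allclose(maps.bearing_deg[m], b, atol=1e-9)


# ---------------------------------------------------------------------------
# decline curve


def test_decline_curve_monotone_and_definition(rng):
    cur, fut = random_stack_pair(rng, 6, 7)
    dec = of.offset_decline_curve(cur, fut, [100.0, 300.0, np.inf])
    means = dec["mean_forward"].to_numpy()
    assert np.all(np.diff(means) <= 1e-12)
    local_mean = np.nanmean(of.local_offset(cur, fut))
    assert means[0] == pytest.approx(local_mean)
    total = 1 - means[-1] / means[0]
    assert dec["share_of_total_decline_pct"].iloc[-1] == pytest.approx(100.0)
    # cumulative share recomputed from the means themselves
    share1 = 100 * (means[0] - means[1]) / (means[0] - means[-1])
    assert dec["share_of_total_decline_pct"].iloc[1] == pytest.approx(share1)


def test_decline_requires_sorted():
    cur, fut = random_stack_pair(np.random.default_rng(0), 4, 4)
    with pytest.raises(ValueError, match="sorted"):
        of.offset_decline_curve(cur, fut, [300.0, 100.0])


# ---------------------------------------------------------------------------
# RGB stacking


def test_rgb_equal_layers_gray(rng):
    a = rng.random((5, 5))
    img = of.rgb_stack(a, a, a)
    assert np.array_equal(img[..., 0], img[..., 1])
    assert np.array_equal(img[..., 1], img[..., 2])
    assert np.all(img[..., 3] == 255)


def test_rgb_extreme_cell_pure_red():
    local = np.array([[0.0, 1.0], [0.2, 0.4]])
    fwd = np.array([[1.0, 0.0], [0.2, 0.4]])
    rev = np.array([[1.0, 0.0], [0.2, 0.4]])
    img = of.rgb_stack(local, fwd, rev)
    assert tuple(img[0, 1, :3]) == (255, 0, 0)


def test_rgb_matches_direct_formula(rng):
    layers = [rng.random((4, 6)) for _ in range(3)]
    img = of.rgb_stack(*layers)
    for k, a in enumerate(layers):
        expect = np.round((a - a.min()) / (a.max() - a.min()) * 255)
        assert np.array_equal(img[..., k], expect.astype(np.uint8))


def test_rgb_constant_layer_warns(rng):
    a = rng.random((3, 3))
    with pytest.warns(UserWarning, match="constant"):
        img = of.rgb_stack(a, np.ones((3, 3)), a)
    assert np.all(img[..., 1] == 0)


# ---------------------------------------------------------------------------
# group comparisons


def test_wilcoxon_u_matches_exhaustive_count():
    a = np.array([1.2, 3.4, 2.2, 5.0])
    b = np.array([2.0, 4.1, 0.5, 6.0])
    offset = np.concatenate([a, b]).reshape(2, 4)
    regions = np.array([["A"] * 4, ["B"] * 4], dtype=object)
    summary, tests = of.compare_groups(offset, regions, min_cells=3)
    u_hand = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    assert tests["u_stat"].iloc[0] == pytest.approx(u_hand)


def test_wilcoxon_separated_groups_tiny_p(rng):
    a = rng.uniform(0, 1, 20)
    b = rng.uniform(10, 11, 20)
    offset = np.concatenate([a, b]).reshape(2, 20)
    regions = np.array([["A"] * 20, ["B"] * 20], dtype=object)
    _, tests = of.compare_groups(offset, regions)
    assert tests["p"].iloc[0] < 1e-6


def test_wilcoxon_null_p_uniform():
    rng = np.random.default_rng(77)
    pvals = []
    for _ in range(200):
        vals = rng.normal(0, 1, 100)
        regions = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
        _, tests = of.compare_groups(vals, regions)
        pvals.append(tests["p"].iloc[0])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_small_groups_excluded(rng):
    vals = rng.normal(0, 1, 10)
    regions = np.array(["A"] * 7 + ["B"] * 2 + ["C"] * 1, dtype=object)
    with pytest.raises(ValueError, match="two groups"):
        with pytest.warns(UserWarning, match="excluded"):
            of.compare_groups(vals, regions)


def test_assign_regions_partition(small_sim):
    cur = small_sim["current"]
    sites = small_sim["G"].samples.drop_duplicates("population")
    regions = of.assign_regions(cur, sites)
    labels = regions[cur.mask]
    assert set(labels) == set(sites["group"])
    assert all(l is not None for l in labels)


# ---------------------------------------------------------------------------
# end-to-end directionality


def test_eastern_shift_orders_group_offsets():
    """A climate shift applied only to the eastern half of the
    landscape must raise local offsets for the eastern groups above the
    western groups', with the mid-range admixed groups in between."""
    cfg = of.SimConfig(seed=13, n_neutral=200, n_adaptive=60,
                       n_per_group=15, missing_rate=0.0, cline_slope=2.5)
    cur, _ = of.make_landscape(cfg)
    fut = cur.copy()
    cols = cur.shape[1]
    shift = np.zeros(cur.shape)
    shift[:, cols // 2:] = 1.0
    fut.data = fut.data + shift[None] * np.array(
        [2.5, 0.5, 1.5, -150.0, -80.0])[:, None, None]

    G, truth = of.simulate_genotypes(cfg, cur)
    freqs = G.group_freqs(by="population").iloc[:, truth.adaptive_locus_ids]
    freqs = freqs.fillna(freqs.mean())
    sites = G.samples.drop_duplicates("population")
    env = pd.DataFrame(cur.values_at(sites["lon"].to_numpy(),
                                     sites["lat"].to_numpy()),
                       columns=cur.names, index=sites["population"])
    model = of.fit_gradient_forest(freqs, env, n_trees=150, seed=13)
    t_cur = of.transform_climate(model, cur)
    t_fut = of.transform_climate(model, fut)
    local = of.local_offset(t_cur, t_fut)
    regions = of.assign_regions(cur, sites)
    summary, _ = of.compare_groups(local, regions)
    mean = summary.set_index("group")["mean"]
    assert mean["East"] > mean["West"]
    assert mean["Emix"] > mean["West"]
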