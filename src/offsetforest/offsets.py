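"""Genomic offsets, assisted-migration geometry and group comparisons.

All offsets operate on climate stacks already transformed into
genetic-importance space by the turnover model:

* local offset — Euclidean distance between a cell's current and
  future transformed climate: the maladaptation risk of staying put;
* forward offset — the minimum distance between a cell's *current*
  genetic composition and the *future* climate of any destination cell
  (optionally capped by great-circle migration distance): the residual
  risk after optimal assisted migration, together with the distance and
  initial bearing to the best destination;
* reverse offset — the minimum distance between a cell's *future*
  climate and any cell's *current* composition: how well the future
  climate at a site is matched by genotypes existing anywhere today.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .climate import ClimateStack
from .spatial import great_circle, haversine_matrix

__all__ = ["OffsetMaps", "local_offset", "forward_offset", "reverse_offset",
           "offset_decline_curve", "rgb_stack", "compare_groups",
           "assign_regions"]


@dataclass
class OffsetMaps:
    """Per-cell offset grids (NaN outside the mask)."""

    local: np.ndarray
    forward: np.ndarray | None = None
    reverse: np.ndarray | None = None
    migration_km: np.ndarray | None = None
    bearing_deg: np.ndarray | None = None
    argmin_cell: np.ndarray | None = None  # flat in-mask cell index


def _check_bands(cur: ClimateStack, fut: ClimateStack) -> None:
    if cur.names != fut.names:
        raise ValueError(f"band mismatch: {cur.names} vs {fut.names}")
    if cur.shape != fut.shape or not np.array_equal(cur.mask, fut.mask):
        raise ValueError("stacks must share grid and mask")


def local_offset(cur: ClimateStack, fut: ClimateStack) -> np.ndarray:
    """Cellwise Euclidean distance between transformed stacks."""
    _check_bands(cur, fut)
    diff = fut.data - cur.data
    out = np.sqrt(np.nansum(diff ** 2, axis=0))
    out[~cur.mask] = np.nan
    return out


def _minimise(A: np.ndarray, B: np.ndarray, geo: np.ndarray,
              max_km: float | None):
    """For each row cell i, argmin over columns j of ||A_i - B_j||
    subject to geo[i, j] <= max_km.  Ties: smaller geo distance, then
    smaller j.  Returns (values, argmin, feasible mask)."""
    D = cdist(A, B)
    if max_km is not None:
        if max_km < 0:
            raise ValueError("max_km must be non-negative")
        D = np.where(geo <= max_km, D, np.inf)
    n = D.shape[0]
    vals = np.empty(n)
    arg = np.full(n, -1, dtype=int)
    cols = np.arange(D.shape[1])
    for i in range(n):
        row = D[i]
        m = row.min()
        if not np.isfinite(m):
            vals[i] = np.nan
            continue
        tied = cols[row == m]
        if len(tied) > 1:
            g = geo[i, tied]
            tied = tied[g == g.min()]
        arg[i] = int(tied[0])
        vals[i] = m
    return vals, arg


def forward_offset(cur: ClimateStack, fut: ClimateStack,
                   max_km: float | None = None) -> OffsetMaps:
    """Minimum offset achievable by migrating to any in-mask cell.

    For each in-mask cell i, minimises the distance between the current
    transformed climate at i and the future transformed climate at any
    destination j with great-circle distance <= max_km (the focal cell
    itself is always a candidate; max_km = 0 reduces to the local
    offset).  Records the destination, migration distance (km) and
    initial bearing (degrees).
    """
    _check_bands(cur, fut)
    A, lon, lat = cur.masked_table()
    B, _, _ = fut.masked_table()
    geo = haversine_matrix(lon, lat)
    vals, arg = _minimise(A, B, geo, max_km)

    def grid(flat_vals, fill=np.nan, dtype=float):
        g = np.full(cur.shape, fill, dtype=dtype)
        g[cur.mask] = flat_vals
        return g

    ok = arg >= 0
    dist = np.full(len(vals), np.nan)
    bear = np.full(len(vals), np.nan)
    if ok.any():
        d, b = great_circle(lon[ok], lat[ok], lon[arg[ok]], lat[arg[ok]])
        dist[ok], bear[ok] = np.atleast_1d(d), np.atleast_1d(b)
    return OffsetMaps(
        local=local_offset(cur, fut),
        forward=grid(vals),
        migration_km=grid(dist),
        bearing_deg=grid(bear),
        argmin_cell=grid(arg, fill=-1, dtype=int),
    )


def reverse_offset(cur: ClimateStack, fut: ClimateStack,
                   max_km: float | None = None) -> np.ndarray:
    """Minimum distance between each cell's future climate and the
    current transformed climate of any (distance-capped) source cell."""
    _check_bands(cur, fut)
    A, lon, lat = fut.masked_table()
    B, _, _ = cur.masked_table()
    geo = haversine_matrix(lon, lat)
    vals, _ = _minimise(A, B, geo, max_km)
    out = np.full(cur.shape, np.nan)
    out[cur.mask] = vals
    return out


def offset_decline_curve(cur: ClimateStack, fut: ClimateStack,
                         distances=(50.0, 100.0, 250.0, 500.0, np.inf)
                         ) -> pd.DataFrame:
    """Mean forward offset per migration-distance cap.

    The 0-km cap equals the local offset.  Emits the percent decline
    between consecutive caps and the cumulative share of the total
    (0 -> unlimited) decline achieved by each cap.
    """
    distances = list(distances)
    if sorted(distances) != distances:
        raise ValueError("distances must be sorted ascending")
    caps = [0.0] + distances
    means = []
    for cap in caps:
        m = forward_offset(cur, fut, max_km=None if np.isinf(cap) else cap)
        means.append(float(np.nanmean(m.forward)))
    rows = []
    total_decline = means[0] - means[-1]
    for k, cap in enumerate(caps):
        step = (100.0 * (means[k - 1] - means[k]) / means[k - 1]
                if k > 0 and means[k - 1] > 0 else 0.0)
        cum = (100.0 * (means[0] - means[k]) / total_decline
               if total_decline > 0 else np.nan)
        rows.append({"max_km": cap, "mean_forward": means[k],
                     "decline_from_prev_pct": step,
                     "share_of_total_decline_pct": cum})
    return pd.DataFrame(rows)


def rgb_stack(local: np.ndarray, forward: np.ndarray,
              reverse: np.ndarray) -> np.ndarray:
    """Min-max scale the three offset layers to [0, 255] over valid
    cells (R = local, G = forward, B = reverse).

    Returns an (rows, cols, 4) uint8 RGBA image; no-data cells are
    fully transparent.  A constant layer scales to 0 with a warning.
    """
    layers = [np.asarray(a, dtype=float) for a in (local, forward, reverse)]
    if len({a.shape for a in layers}) != 1:
        raise ValueError("layers must be co-registered")
    valid = np.all([np.isfinite(a) for a in layers], axis=0)
    img = np.zeros(layers[0].shape + (4,), dtype=np.uint8)
    for k, a in enumerate(layers):
        v = a[valid]
        lo, hi = v.min(), v.max()
        if hi == lo:
            warnings.warn(f"constant offset layer {k}; scaled to 0")
            scaled = np.zeros_like(v)
        else:
            scaled = (v - lo) / (hi - lo) * 255.0
        img[..., k][valid] = np.round(scaled).astype(np.uint8)
    img[..., 3][valid] = 255
    return img


# ---------------------------------------------------------------------------
# group regions and comparisons


def assign_regions(stack: ClimateStack, sites: pd.DataFrame) -> np.ndarray:
    """Nearest-sampled-population Voronoi assignment of in-mask cells.

    ``sites`` needs columns lon, lat, group.  Returns an object-dtype
    grid of group labels (None outside the mask).
    """
    _, lon, lat = stack.masked_table()
    geo = haversine_matrix(lon, lat, sites["lon"].to_numpy(),
                           sites["lat"].to_numpy())
    nearest = np.argmin(geo, axis=1)
    labels = sites["group"].to_numpy()[nearest]
    out = np.full(stack.shape, None, dtype=object)
    out[stack.mask] = labels
    return out


def compare_groups(offset: np.ndarray, regions: np.ndarray,
                   min_cells: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-wise offset summaries and pairwise Wilcoxon rank-sum tests.

    Uses the two-sided normal approximation with continuity and tie
    correction (Mann-Whitney U).  Groups with fewer than ``min_cells``
    valid cells are excluded with a warning.

    Returns (summary DataFrame, pairwise DataFrame with columns
    group_a, group_b, u_stat, p).
    """
    values: dict[str, np.ndarray] = {}
    for g in pd.unique(regions[regions != None]):  # noqa: E711
        v = np.asarray(offset[regions == g], dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < min_cells:
            warnings.warn(f"group {g!r} has {len(v)} cells (<{min_cells}); "
                          "excluded")
            continue
        values[str(g)] = v
    if len(values) < 2:
        raise ValueError("need at least two groups with enough cells")
    summary = pd.DataFrame(
        [{"group": g, "n_cells": len(v), "mean": v.mean(),
          "median": float(np.median(v))} for g, v in values.items()])
    rows = []
    names = list(values)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = values[names[i]], values[names[j]]
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
            rows.append({"group_a": names[i], "group_b": names[j],
                         "u_stat": float(res.statistic),
                         "p": float(res.pvalue)})
    return summary, pd.DataFrame(rows)
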