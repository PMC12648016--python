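"""Great-circle geometry and distance-based Moran's eigenvector maps.

MEMs are the spatial predictors used to absorb spatial genetic
autocorrelation in genotype-environment models: eigenvectors of a
truncated, double-centred great-circle distance matrix (the classic
dbMEM construction).  The truncation threshold is the longest edge of
the minimum spanning tree over the sampling sites, which guarantees the
connection graph stays connected.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

EARTH_RADIUS_KM = 6371.0088

__all__ = ["great_circle", "haversine_matrix", "compute_mem", "moran_i",
           "EARTH_RADIUS_KM"]


def great_circle(lon1, lat1, lon2, lat2):
    """Haversine distance (km) and initial bearing (degrees in [0,360)).

    Accepts scalars or broadcastable arrays of WGS84 degrees.  The
    bearing of a point to itself is 0 by convention.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(v, dtype=float)
                              for v in (lon1, lat1, lon2, lat2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude outside [-90, 90]")
    f1, f2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    df = f2 - f1
    a = np.sin(df / 2) ** 2 + np.cos(f1) * np.cos(f2) * np.sin(dl / 2) ** 2
    dist = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    y = np.sin(dl) * np.cos(f2)
    x = np.cos(f1) * np.sin(f2) - np.sin(f1) * np.cos(f2) * np.cos(dl)
    bearing = np.degrees(np.arctan2(y, x)) % 360.0
    bearing = np.where(dist == 0, 0.0, bearing)
    if bearing.ndim == 0:
        return float(dist), float(bearing)
    return dist, bearing


def haversine_matrix(lon, lat, lon2=None, lat2=None) -> np.ndarray:
    """Pairwise great-circle distance matrix in km."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon2 is None:
        lon2, lat2 = lon, lat
    lon2 = np.asarray(lon2, dtype=float)
    lat2 = np.asarray(lat2, dtype=float)
    d, _ = great_circle(lon[:, None], lat[:, None], lon2[None, :], lat2[None, :])
    return d


def compute_mem(lon, lat, k: int = 5):
    """Distance-based MEM eigenvectors from sampling coordinates.

    Steps: great-circle distance matrix; truncation at the longest
    minimum-spanning-tree edge (beyond-threshold distances replaced by
    4x the threshold); principal-coordinate double-centring; eigen-
    decomposition.  Returns the ``k`` eigenvectors with the largest
    positive eigenvalues (fewer, with a warning, if fewer exist).

    Returns
    -------
    vectors : ndarray (n, k') columns MEM1..MEMk' ordered by eigenvalue
    eigenvalues : ndarray (k',)
    threshold : float, the truncation distance in km
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(lon)
    pts = {(round(x, 9), round(y, 9)) for x, y in zip(lon, lat)}
    if len(pts) < k + 2:
        raise ValueError(f"need at least {k + 2} distinct locations")
    D = haversine_matrix(lon, lat)
    mst = minimum_spanning_tree(D).toarray()
    thr = float(mst.max())
    Dt = np.where(D > thr, 4.0 * thr, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-8 * max(1.0, abs(vals[0]))
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive MEM eigenvalues available "
                      f"(requested {k})")
    k_eff = min(k, n_pos)
    vecs = vecs[:, :k_eff].copy()
    # deterministic sign: largest-magnitude element positive
    for j in range(k_eff):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] *= -1
    return vecs, vals[:k_eff], thr


def moran_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I of ``values`` under a symmetric spatial weight matrix."""
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    n = len(x)
    z = x - x.mean()
    denom = float(z @ z)
    s0 = W.sum()
    return float(n / s0 * (z @ W @ z) / denom)
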