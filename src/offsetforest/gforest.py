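"""Gradient forest: turnover functions from per-SNP regression forests.

For every SNP, a small regression forest (bootstrapped rows, random
predictor subset at each split, variance-reduction splitting, shallow
trees suited to a handful of populations) models allele frequency as a
function of the environmental predictors.  SNPs with positive
out-of-bag R^2 contribute each split's impurity reduction (normalised
within its tree) to a per-predictor importance distribution along the
predictor's observed range.  Binned importances are standardised by the
empirical data density, rescaled so each SNP contributes exactly its
R^2, summed over SNPs and cumulated, yielding one monotone
cumulative-importance "turnover" curve F_p per predictor.  F_p(min) = 0
and F_p(max) equals the predictor's overall importance, so climate
layers can be mapped into a common genetic-importance space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .climate import ClimateStack

__all__ = ["TurnoverModel", "fit_gradient_forest", "predictor_importance",
           "transform_climate"]


# ---------------------------------------------------------------------------
# regression trees


def _build_tree(X, y, rows, rng, mtry, max_depth, min_leaf, records):
    """Recursive CART on rows; appends (feature, threshold, gain) to
    records.  Returns a nested node tuple."""
    yn = y[rows]
    n = len(rows)
    mean = yn.mean()
    if max_depth == 0 or n < 2 * min_leaf or np.ptp(yn) == 0.0:
        return (mean,)
    sse_parent = float(((yn - mean) ** 2).sum())

    p = X.shape[1]
    feats = np.sort(rng.choice(p, size=min(mtry, p), replace=False))
    best_gain, best = 0.0, None
    for f in feats:
        x = X[rows, f]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], yn[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys ** 2)
        tot, totsq = csum[-1], csq[-1]
        i = np.arange(1, n)
        valid = (xs[1:] != xs[:-1]) & (i >= min_leaf) & (n - i >= min_leaf)
        if not valid.any():
            continue
        sl, sql = csum[:-1], csq[:-1]
        nl, nr = i, n - i
        sse = (sql - sl ** 2 / nl) + ((totsq - sql) - (tot - sl) ** 2 / nr)
        gain = np.where(valid, sse_parent - sse, -np.inf)
        j = int(np.argmax(gain))
        if gain[j] > best_gain + 1e-12:
            best_gain = float(gain[j])
            best = (f, (xs[j] + xs[j + 1]) / 2.0)
    if best is None:
        return (mean,)
    f, thr = best
    records.append((int(f), float(thr), best_gain))
    left = rows[X[rows, f] <= thr]
    right = rows[X[rows, f] > thr]
    return (int(f), float(thr),
            _build_tree(X, y, left, rng, mtry, max_depth - 1, min_leaf, records),
            _build_tree(X, y, right, rng, mtry, max_depth - 1, min_leaf, records))


def _predict_tree(node, X, rows):
    out = np.empty(len(rows))
    for k, r in enumerate(rows):
        nd = node
        while len(nd) == 4:
            nd = nd[2] if X[r, nd[0]] <= nd[1] else nd[3]
        out[k] = nd[0]
    return out


def _fit_forest(X, y, n_trees, rng, max_depth, min_leaf, mtry, bootstrap):
    """One forest for one SNP.

    Returns (oob_r2, tree_split_records); oob_r2 is NaN when bootstrap
    is off (no out-of-bag rows exist)."""
    n = len(y)
    all_rows = np.arange(n)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=int)
    tree_records = []
    for _ in range(n_trees):
        if bootstrap:
            idx = rng.integers(0, n, n)
        else:
            idx = all_rows
        records: list[tuple[int, float, float]] = []
        tree = _build_tree(X, y, idx, rng, mtry, max_depth, min_leaf, records)
        tree_records.append(records)
        if bootstrap:
            inbag = np.zeros(n, dtype=bool)
            inbag[idx] = True
            oob = all_rows[~inbag]
            if len(oob):
                oob_sum[oob] += _predict_tree(tree, X, oob)
                oob_cnt[oob] += 1
    if not bootstrap:
        return np.nan, tree_records
    seen = oob_cnt > 0
    if not seen.any():
        return np.nan, tree_records
    pred = oob_sum[seen] / oob_cnt[seen]
    sst = float(((y[seen] - y[seen].mean()) ** 2).sum())
    if sst == 0:
        return np.nan, tree_records
    sse = float(((y[seen] - pred) ** 2).sum())
    return 1.0 - sse / sst, tree_records


# ---------------------------------------------------------------------------
# turnover model


@dataclass
class TurnoverModel:
    """Fitted aggregate turnover functions.

    ``bin_edges[p]`` (n_bins+1 values spanning the observed range of
    predictor p) and ``cum_importance[p]`` (same length, starting at 0,
    monotone non-decreasing) define F_p; ``importance[p]`` equals
    F_p(max).  ``snp_r2`` is the per-SNP out-of-bag R^2;
    ``positive_snps`` lists the SNPs with R^2 > 0 that contribute to
    the aggregation.  ``transformable`` names the predictors eligible
    for projection onto climate rasters (spatial MEM predictors are
    fitted but never projected: they have no future analogue).
    """

    predictors: list[str]
    bin_edges: dict[str, np.ndarray]
    cum_importance: dict[str, np.ndarray]
    importance: dict[str, float]
    snp_r2: pd.Series
    positive_snps: list[str]
    transformable: list[str]
    per_snp_importance: dict[str, dict[str, np.ndarray]] = field(
        default_factory=dict)

    def turnover(self, predictor: str, values) -> np.ndarray:
        """Evaluate F_p with clamping to the fitted range."""
        edges = self.bin_edges[predictor]
        cum = self.cum_importance[predictor]
        return np.interp(np.asarray(values, dtype=float), edges, cum)

    def to_json(self, path: str | Path) -> None:
        d = {
            "predictors": self.predictors,
            "transformable": self.transformable,
            "bin_edges": {k: v.tolist() for k, v in self.bin_edges.items()},
            "cum_importance": {k: v.tolist()
                               for k, v in self.cum_importance.items()},
            "importance": self.importance,
            "snp_r2": self.snp_r2.to_dict(),
            "positive_snps": self.positive_snps,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "TurnoverModel":
        d = json.loads(Path(path).read_text())
        return cls(
            predictors=d["predictors"],
            bin_edges={k: np.asarray(v) for k, v in d["bin_edges"].items()},
            cum_importance={k: np.asarray(v)
                            for k, v in d["cum_importance"].items()},
            importance=d["importance"],
            snp_r2=pd.Series(d["snp_r2"]),
            positive_snps=d["positive_snps"],
            transformable=d["transformable"],
        )


def fit_gradient_forest(responses: pd.DataFrame, predictors: pd.DataFrame,
                        n_trees: int = 500, seed: int = 0,
                        max_depth: int = 4, min_leaf: int = 2,
                        mtry: int | None = None, n_bins: int = 101,
                        bootstrap: bool = True,
                        spatial_prefix: str = "MEM") -> TurnoverModel:
    """Fit the aggregate turnover model.

    Parameters
    ----------
    responses
        Populations x SNPs table of allele frequencies in [0, 1] (an
        individuals x SNPs dosage/2 table works identically).
    predictors
        Populations x predictors table (climate variables and,
        optionally, spatial MEM eigenvectors, recognised by
        ``spatial_prefix`` and excluded from projection).
    n_trees, max_depth, min_leaf, mtry
        Forest geometry.  ``mtry`` (predictors tried per split) defaults
        to all predictors: with the handful of climate variables typical
        of these tables, per-split predictor subsetting mostly injects
        chance splits on irrelevant variables, so tree randomness comes
        from the bootstrap alone; set ``mtry`` to subsample predictors
        in wider tables.
    n_bins
        Equal-width importance bins per predictor.
    bootstrap
        Disable only for the deterministic single-tree analysis; the
        out-of-bag R^2 filter then cannot be applied and all SNPs
        contribute.
    """
    if len(responses) != len(predictors):
        raise ValueError("responses and predictors must share rows")
    if len(responses) < 5:
        raise ValueError("need at least 5 populations")
    R = responses.to_numpy(dtype=float)
    if np.nanmin(R) < -1e-9 or np.nanmax(R) > 1 + 1e-9:
        raise ValueError("responses must be allele frequencies in [0, 1]")

    usable = [c for c in predictors.columns
              if predictors[c].nunique() >= 2]
    dropped = [c for c in predictors.columns if c not in usable]
    if dropped:
        warnings.warn(f"excluding constant predictors: {dropped}")
    X = predictors[usable].to_numpy(dtype=float)
    p = X.shape[1]
    if mtry is None:
        mtry = p

    edges = {c: np.linspace(X[:, j].min(), X[:, j].max(), n_bins + 1)
             for j, c in enumerate(usable)}
    # empirical data density per bin, normalised to mean 1 over occupied
    # bins; empty bins fall back to 1 (splits sit between data points)
    density = {}
    for j, c in enumerate(usable):
        hist, _ = np.histogram(X[:, j], bins=edges[c])
        dens = hist.astype(float)
        occupied = dens > 0
        dens /= dens[occupied].mean()
        dens[~occupied] = 1.0
        density[c] = dens

    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    total = {c: np.zeros(n_bins) for c in usable}
    per_snp: dict[str, dict[str, np.ndarray]] = {}
    r2s = {}
    positive = []
    for s, snp in enumerate(responses.columns):
        y = R[:, s]
        r2, tree_records = _fit_forest(X, y, n_trees, rng, max_depth,
                                       min_leaf, mtry, bootstrap)
        r2s[snp] = r2
        if bootstrap and not (np.isfinite(r2) and r2 > 0):
            continue
        raw = {c: np.zeros(n_bins) for c in usable}
        any_split = False
        for records in tree_records:
            if not records:
                continue
            tree_total = sum(g for *_, g in records)
            if tree_total <= 0:
                continue
            any_split = True
            for f, thr, gain in records:
                c = usable[f]
                b = int(np.clip(np.searchsorted(edges[c], thr, side="right")
                                - 1, 0, n_bins - 1))
                raw[c][b] += gain / tree_total
        if not any_split:
            continue
        std = {c: raw[c] / density[c] for c in usable}
        mass = sum(v.sum() for v in std.values())
        scale = (r2 if bootstrap else 1.0) / mass
        snp_imp = {c: v * scale for c, v in std.items()}
        per_snp[snp] = snp_imp
        for c in usable:
            total[c] += snp_imp[c]
        positive.append(snp)

    if not positive:
        raise ValueError("no SNP has positive out-of-bag R^2; "
                         "turnover model is invalid")
    cum = {c: np.concatenate([[0.0], np.cumsum(total[c])]) for c in usable}
    importance = {c: float(cum[c][-1]) for c in usable}
    transformable = [c for c in usable if not c.startswith(spatial_prefix)]
    return TurnoverModel(
        predictors=usable, bin_edges=edges, cum_importance=cum,
        importance=importance,
        snp_r2=pd.Series(r2s, name="oob_r2"),
        positive_snps=positive, transformable=transformable,
        per_snp_importance=per_snp,
    )


def predictor_importance(model: TurnoverModel) -> pd.DataFrame:
    """Predictors ranked by overall importance (descending; ties broken
    alphabetically).  ``df.attrs['n_positive_snps']`` carries the count
    of SNPs with positive R^2."""
    df = pd.DataFrame({"predictor": list(model.importance),
                       "importance": list(model.importance.values())})
    df = df.sort_values(["importance", "predictor"],
                        ascending=[False, True]).reset_index(drop=True)
    df.attrs["n_positive_snps"] = len(model.positive_snps)
    return df


def transform_climate(model: TurnoverModel, stack: ClimateStack,
                      predictors: list[str] | None = None) -> ClimateStack:
    """Map climate layers into genetic-importance space, band-wise.

    Each transformable predictor's layer is passed through its turnover
    function with clamping to the fitted range (below-minimum values
    map to 0, above-maximum to the overall importance).  Spatial MEM
    predictors are never transformed.  Raises when a required predictor
    band is missing from the stack.
    """
    preds = predictors if predictors is not None else model.transformable
    missing = [p for p in preds if p not in stack.names]
    if missing:
        raise ValueError(f"stack lacks predictor bands: {missing}")
    out = np.full((len(preds),) + stack.shape, np.nan)
    for i, name in enumerate(preds):
        layer = stack.layer(name)
        vals = model.turnover(name, layer[stack.mask])
        band = np.full(stack.shape, np.nan)
        band[stack.mask] = vals
        out[i] = band
    return ClimateStack(list(preds), out, stack.lon.copy(), stack.lat.copy(),
                        stack.mask.copy())
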