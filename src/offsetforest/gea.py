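"""Genotype-environment association scans.

Two complementary candidate-SNP detectors:

* a latent-factor association model: per-locus linear association
  between dosage and one environmental variable, conditioning on K
  latent factors that absorb population structure (estimated from the
  top singular vectors of the env-residualised genotype matrix, a
  deterministic ridge/SVD formulation of the latent-factor mixed
  model), with genomic-inflation calibration of the z-scores;
* redundancy analysis (RDA): constrained ordination of the dosage
  matrix on the decorrelated environmental predictors, flagging loci
  with extreme loadings on the leading constrained axes.

Candidates from both methods are intersected, and candidate SNPs can be
assigned to genes within a flanking distance from a GFF3 annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = 0.4549364231195724  # median of chi-squared with 1 df

__all__ = ["GEAResult", "select_uncorrelated_vars", "lfmm_associate",
           "rda_associate", "intersect_candidates", "assign_to_genes"]


@dataclass
class GEAResult:
    """Per-locus association statistics and candidate flags.

    ``lfmm``: tidy DataFrame (locus, variable, z, p).
    ``rda_loadings``: loci x axes loadings.
    ``lfmm_candidates`` / ``rda_candidates`` / ``candidates``: locus id
    sets (the last is the intersection).
    ``gif``: genomic inflation factor per variable.
    """

    lfmm: pd.DataFrame | None = None
    rda_loadings: pd.DataFrame | None = None
    lfmm_candidates: set[int] = field(default_factory=set)
    rda_candidates: set[int] = field(default_factory=set)
    candidates: set[int] = field(default_factory=set)
    gif: dict[str, float] = field(default_factory=dict)
    venn: dict[str, int] = field(default_factory=dict)
    rda_eigenvalues: np.ndarray | None = None


def _imputed_centered(G: GenotypeMatrix) -> np.ndarray:
    d = G.dosages_float()
    mu = np.nanmean(d, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    return np.where(np.isnan(d), mu, d) - mu


def _standardize(env: pd.DataFrame) -> np.ndarray:
    X = env.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant environmental variable(s): "
                         f"{list(env.columns[sd == 0])}")
    return (X - X.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# variable decorrelation


def select_uncorrelated_vars(env: pd.DataFrame, r_max: float = 0.7,
                             priority: list[str] | None = None):
    """Greedy decorrelation: walk variables in priority order, keep one
    when its |Pearson r| with every already-kept variable is < r_max.

    Returns (kept variable names, full correlation matrix).
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    corr = env.corr(method="pearson")
    order = priority if priority is not None else list(env.columns)
    kept: list[str] = []
    for v in order:
        if all(abs(corr.loc[v, u]) < r_max for u in kept):
            kept.append(v)
    return kept, corr


# ---------------------------------------------------------------------------
# latent-factor association


def _latent_factors(Y: np.ndarray, X: np.ndarray, K: int,
                    ridge: float | None = None,
                    n_iter: int = 25) -> np.ndarray:
    """Latent factors from the ridge-regularised alternating solution.

    Minimises ||Y - W - X B||_F^2 + ridge * ||B||_F^2 over a rank-K
    matrix W and environmental effects B by alternating (a) the ridge
    solve for B given W and (b) the rank-K SVD truncation of Y - X B.
    The ridge pushes variance shared between environment and structure
    into the factors, which keeps the per-locus conditional tests
    calibrated when environment and lineage structure are collinear.
    Returns the K left singular vectors of the final W.
    """
    if K == 0:
        return np.empty((Y.shape[0], 0))
    if ridge is None:
        # X is standardised, so X'X ~ n on the diagonal; a penalty of
        # 0.3n shrinks env effects enough that structure collinear with
        # the environment stays in the factors (keeping the null tests
        # calibrated) without absorbing genuine per-locus clines
        ridge = 0.3 * len(X)
    Xi = np.column_stack([np.ones(len(X)), X])
    XtX = Xi.T @ Xi + ridge * np.eye(Xi.shape[1])
    W = np.zeros_like(Y)
    for _ in range(n_iter):
        B = np.linalg.solve(XtX, Xi.T @ (Y - W))
        R = Y - Xi @ B
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        W_new = (U[:, :K] * s[:K]) @ Vt[:K]
        if np.linalg.norm(W_new - W) <= 1e-8 * max(np.linalg.norm(W), 1e-12):
            W = W_new
            break
        W = W_new
    U, _, _ = np.linalg.svd(W, full_matrices=False)
    return U[:, :K]


def lfmm_associate(G: GenotypeMatrix, env: pd.DataFrame, K: int = 3,
                   alpha: float = 0.05, calibrate: bool = True,
                   fdr: bool = False, ridge: float | None = None,
                   factor_method: str = "ridge") -> GEAResult:
    """Latent-factor association of each locus with each variable.

    For each environmental variable the per-locus effect is estimated
    by least squares conditional on the K latent factors; z-scores are
    rescaled by the genomic inflation factor (median chi2 / 0.4549)
    before p-values.  Candidates are loci with calibrated p < alpha for
    at least one variable (Benjamini-Hochberg across loci per variable
    when ``fdr`` is set).

    ``factor_method`` selects how the K latent factors are estimated:
    ``"ridge"`` (default) solves the ridge-regularised alternating
    least-squares factor model (factors estimated jointly with the
    environmental effects; penalty ``ridge``, default 0.3 x samples),
    which balances null calibration against power when environment and
    population structure are collinear; ``"pca"`` conditions on the
    top-K genotype principal components instead (the infinite-ridge
    limit: maximally conservative).

    Zero-variance loci get p = 1.  K must be smaller than the sample
    count.
    """
    n = G.n_samples
    if K >= n:
        raise ValueError("K must be smaller than the number of samples")
    Y = _imputed_centered(G)
    X = _standardize(env)
    if factor_method == "pca" or K == 0:
        U, _, _ = np.linalg.svd(Y, full_matrices=False)
        factors = U[:, :K]
    elif factor_method == "ridge":
        factors = _latent_factors(Y, X, K, ridge=ridge)
    else:
        raise ValueError(f"unknown factor_method: {factor_method!r}")
    zero_var = Y.std(axis=0) == 0

    records = []
    gif: dict[str, float] = {}
    cand: set[int] = set()
    for vi, vname in enumerate(env.columns):
        D = np.column_stack([np.ones(n), X[:, vi], factors])
        q = D.shape[1]
        DtD_inv = np.linalg.inv(D.T @ D)
        B = DtD_inv @ (D.T @ Y)
        resid = Y - D @ B
        dof = n - q
        sigma2 = (resid ** 2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(sigma2 * DtD_inv[1, 1], 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = B[1] / se
        z = np.where(zero_var, 0.0, z)
        lam = 1.0
        if calibrate:
            finite = np.isfinite(z) & ~zero_var
            if finite.any():
                lam = float(np.median(z[finite] ** 2) / CHI2_MEDIAN_1DF)
                lam = max(lam, 1e-12)
        z_cal = z / np.sqrt(lam)
        p = stats.chi2.sf(z_cal ** 2, df=1)
        p = np.where(zero_var, 1.0, p)
        gif[vname] = lam
        records.append(pd.DataFrame({
            "locus": np.arange(G.n_loci), "variable": vname,
            "z": z_cal, "p": p}))
        p_rule = p.copy()
        if fdr:
            p_rule = stats.false_discovery_control(p, method="bh")
        cand.update(np.flatnonzero(p_rule < alpha).tolist())
    res = GEAResult(lfmm=pd.concat(records, ignore_index=True),
                    lfmm_candidates=cand, gif=gif)
    return res


# ---------------------------------------------------------------------------
# redundancy analysis


def rda_associate(G: GenotypeMatrix, env: pd.DataFrame, sd_mult: float = 3.0,
                  n_axes: int = 3) -> GEAResult:
    """Constrained ordination outlier scan.

    The centred dosage matrix is regressed on the standardised
    environmental predictors; the fitted values are eigen-decomposed
    and per-locus loadings on the first ``n_axes`` constrained axes are
    screened: a locus is a candidate when its loading is more than
    ``sd_mult`` standard deviations from the axis mean on any used
    axis.  Collinear predictor columns are dropped with a warning.
    """
    Y = _imputed_centered(G)
    X = _standardize(env)
    # drop collinear columns via QR diagonal
    _, R = np.linalg.qr(X, mode="reduced")
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, abs(R[0, 0]))
    if not keep.all():
        bad = [env.columns[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping collinear predictors: {bad}")
        cols = [c for c, k in zip(env.columns, keep) if k]
        X = _standardize(env[cols])
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ B
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0])) if len(s) else 0
    n_axes_eff = min(n_axes, rank)
    V = Vt[:n_axes_eff].T  # loci x axes, unit-norm columns
    # deterministic sign
    for j in range(n_axes_eff):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] *= -1
    loadings = pd.DataFrame(V, columns=[f"RDA{j + 1}"
                                        for j in range(n_axes_eff)])
    cand: set[int] = set()
    for j in range(n_axes_eff):
        v = V[:, j]
        lim = sd_mult * v.std()
        cand.update(np.flatnonzero(np.abs(v - v.mean()) > lim).tolist())
    res = GEAResult(rda_loadings=loadings, rda_candidates=cand,
                    rda_eigenvalues=(s[:rank] ** 2) / (len(Y) - 1))
    return res


def intersect_candidates(lfmm_set: set[int], rda_set: set[int]):
    """Intersection plus Venn counts (lfmm_only, rda_only, shared)."""
    shared = set(lfmm_set) & set(rda_set)
    venn = {"lfmm_only": len(set(lfmm_set) - shared),
            "rda_only": len(set(rda_set) - shared),
            "shared": len(shared)}
    return shared, venn


# ---------------------------------------------------------------------------
# gene assignment


def _parse_gff_genes(gff_path) -> pd.DataFrame:
    rows, skipped = [], 0
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                skipped += 1
                continue
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                skipped += 1
                continue
            gene_id = "NA"
            for kv in parts[8].split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            rows.append((parts[0], start, end, gene_id))
    if skipped:
        logger.warning("skipped %d malformed GFF lines", skipped)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def assign_to_genes(candidates: list[int], loci: pd.DataFrame, gff_path,
                    flank_bp: int = 2500):
    """Map candidate SNPs to genes within ``flank_bp`` of the gene span.

    A candidate at position p maps to every gene whose flanked interval
    [start - flank, end + flank] contains p (1-based, inclusive).
    Returns (assignment DataFrame with locus/chrom/pos/gene_id,
    list of unassigned candidate ids).
    """
    genes = _parse_gff_genes(gff_path)
    out, unassigned = [], []
    for lid in sorted(candidates):
        chrom = loci["chrom"].iloc[lid]
        pos = int(loci["pos"].iloc[lid])
        sub = genes[(genes["chrom"] == chrom)
                    & (genes["start"] - flank_bp <= pos)
                    & (genes["end"] + flank_bp >= pos)]
        if len(sub) == 0:
            unassigned.append(lid)
        for _, g in sub.iterrows():
            out.append((lid, chrom, pos, g["gene_id"]))
    table = pd.DataFrame(out, columns=["locus", "chrom", "pos", "gene_id"])
    return table, unassigned
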