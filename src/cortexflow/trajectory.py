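"""Trajectory-level analyses downstream of the transport plans.

* barycentric (ternary) coordinates of the three fate probabilities;
* probabilistic differential expression between responsive and
  non-responsive fates at one time point (probability-weighted mean
  contrast with a permutation null);
* a transcriptional-diversity pseudotime (detected-gene count smoothed
  over embedding neighbors, rank-scaled, stage-anchored orientation);
* smoothed expression trends along pseudotime;
* a spline F-test for association of expression with pseudotime.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from scipy.interpolate import BSpline
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io_preprocess import CountMatrix, NormExpr, Embedding, normalize_log, pca_embed, qc_filter
from .transport import FATE_COLUMNS

__all__ = ["barycentric_coordinates", "trajectory_de", "diversity_pseudotime",
           "expression_trends", "stage_association_test", "TRIANGLE_VERTICES"]

# non-responsive lower left, responsive lower right, other on top
TRIANGLE_VERTICES = {
    "p_nonresponsive": np.array([0.0, 0.0]),
    "p_responsive": np.array([1.0, 0.0]),
    "p_other": np.array([0.5, np.sqrt(3.0) / 2.0]),
}


def barycentric_coordinates(ft: pd.DataFrame) -> pd.DataFrame:
    """Map each fate-probability triple to a point in the reference triangle.

    The map is affine in the probabilities; triples must sum to 1 (± 1e-6).
    Returns (cell, time_h, x, y).
    """
    probs = ft[list(FATE_COLUMNS)].to_numpy(float)
    defined = ~np.isnan(probs).any(axis=1)
    sums = probs[defined].sum(axis=1)
    if defined.any() and np.max(np.abs(sums - 1.0)) > 1e-6:
        raise ValueError("fate probabilities must sum to 1")
    V = np.vstack([TRIANGLE_VERTICES[c] for c in FATE_COLUMNS])  # 3 × 2
    xy = probs @ V
    out = ft[["cell", "time_h"]].copy() if "cell" in ft else pd.DataFrame(index=ft.index)
    out["x"] = xy[:, 0]
    out["y"] = xy[:, 1]
    return out


def trajectory_de(ne: NormExpr, ft: pd.DataFrame, time_h: float,
                  n_perm: int = 1000, seed: int = 0,
                  min_support: int = 3) -> pd.DataFrame:
    """Probability-weighted DE between responsive and non-responsive fates.

    At the requested time point each cell contributes with weight
    p_responsive (normalized to sum 1) to the responsive mean and
    p_nonresponsive to the non-responsive mean; the statistic is the
    difference of weighted means. Significance comes from jointly permuting
    the weight pairs over cells, with the add-one correction
    p = (1 + #{|stat_perm| ≥ |stat_obs|}) / (1 + n_perm), and BH over genes.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    sub = ft[(ft["time_h"] == time_h)].dropna(subset=list(FATE_COLUMNS))
    if sub.empty:
        raise ValueError(f"no fate probabilities at time {time_h}")
    nloc = ne.subset_cells(sub["cell"].to_numpy())
    X = nloc.dense()
    w_r = sub["p_responsive"].to_numpy(float)
    w_n = sub["p_nonresponsive"].to_numpy(float)
    if w_r.sum() == 0 or w_n.sum() == 0:
        raise ValueError("one fate carries zero total probability at this time")
    support_r = int((w_r > 0).sum())
    support_n = int((w_n > 0).sum())
    w_r = w_r / w_r.sum()
    w_n = w_n / w_n.sum()

    mean_r = w_r @ X
    mean_n = w_n @ X
    stat = mean_r - mean_n

    rng = np.random.default_rng(seed)
    d = w_r - w_n
    n_cells = len(d)
    perm_idx = np.argsort(rng.random((n_perm, n_cells)), axis=1)
    stat_perm = d[perm_idx] @ X                       # n_perm × genes
    exceed = (np.abs(stat_perm) >= np.abs(stat)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    fdr = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame({
        "gene": nloc.gene_ids, "time_h": time_h, "weighted_stat": stat,
        "p_perm": p, "fdr": fdr, "mean_responsive": mean_r,
        "mean_nonresponsive": mean_n,
        "low_support": min(support_r, support_n) < min_support,
    })
    return out


def diversity_pseudotime(cm: CountMatrix, meta: pd.DataFrame, lineage: str,
                         k_smooth: int = 30, embedding: Embedding = None,
                         anchor_stage: str = "proliferation") -> pd.Series:
    """Transcriptional-diversity pseudotime for one lineage (cell type).

    The raw score is the number of detected genes per cell; when the lineage
    holds more cells than ``k_smooth`` the score is averaged over each cell's
    k nearest embedding neighbors (self included). Scores are rank-scaled to
    [0, 1] (ties → midpoint, so identical cells land at 0.5) and oriented so
    that ``anchor_stage`` cells sit near 0.
    """
    cells = meta.index[meta["celltype"] == lineage]
    if len(cells) == 0:
        raise ValueError(f"lineage {lineage!r} absent from metadata")
    sub = cm.subset_cells(np.asarray(cells, object))
    raw = sub.genes_detected().astype(float)

    n = len(cells)
    if n > k_smooth:
        if embedding is None:
            filt = qc_filter(sub, min_counts=1)
            emb = pca_embed(normalize_log(filt), K=min(30, min(filt.n_cells, filt.n_genes)))
        else:
            emb = embedding.subset_cells(np.asarray(cells, object))
        nn = NearestNeighbors(n_neighbors=min(k_smooth, n)).fit(emb.coords)
        _, idx = nn.kneighbors(emb.coords)
        raw = raw[idx].mean(axis=1)

    ranks = scipy.stats.rankdata(raw, method="average")
    pt = (ranks - 1.0) / max(n - 1, 1)
    stages = meta.loc[cells, "stage"]
    anchor = stages == anchor_stage
    if anchor.any() and (~anchor).any():
        if pt[anchor.to_numpy()].mean() > pt[(~anchor).to_numpy()].mean():
            pt = 1.0 - pt
    return pd.Series(pt, index=pd.Index(cells, name="cell"), name="pseudotime")


def expression_trends(ne: NormExpr, pt: pd.Series, genes,
                      n_bins: int = 50) -> pd.DataFrame:
    """Per-gene z-scaled mean expression over equal-width pseudotime bins.

    Empty bins are linearly interpolated; constant genes yield all-zero rows.
    Genes absent from the matrix are skipped with a warning.
    """
    nloc = ne.subset_cells(pt.index.to_numpy(object))
    gene_index = pd.Index(nloc.gene_ids)
    present = [g for g in genes if g in gene_index]
    absent = [g for g in genes if g not in gene_index]
    if absent:
        warnings.warn(f"{len(absent)} gene(s) not in matrix, skipped: "
                      f"{absent[:5]}", stacklevel=2)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pt.to_numpy(), edges[1:-1]), 0, n_bins - 1)
    occupied = np.bincount(which, minlength=n_bins) > 0

    rows = []
    cols = gene_index.get_indexer(present)
    X = nloc.dense()[:, cols]
    centers = (edges[:-1] + edges[1:]) / 2.0
    for j, g in enumerate(present):
        means = np.full(n_bins, np.nan)
        for b in np.where(occupied)[0]:
            means[b] = X[which == b, j].mean()
        if (~occupied).any():
            means[~occupied] = np.interp(centers[~occupied], centers[occupied],
                                         means[occupied])
        sd = means.std()
        rows.append((means - means.mean()) / sd if sd > 0 else np.zeros(n_bins))
    return pd.DataFrame(rows, index=pd.Index(present, name="gene"),
                        columns=[f"bin{b}" for b in range(n_bins)])


def _spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline basis with df columns, knots at interior quantiles."""
    degree = 3
    n_interior = max(df - degree, 0)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs) if n_interior else np.array([])
    lo, hi = x.min(), x.max()
    if hi <= lo:
        hi = lo + 1e-9
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    n_basis = len(t) - degree - 1
    B = np.empty((len(x), n_basis))
    for i in range(n_basis):
        c = np.zeros(n_basis)
        c[i] = 1.0
        B[:, i] = BSpline(t, c, degree, extrapolate=False)(np.clip(x, lo, hi))
    return np.nan_to_num(B)


def stage_association_test(ne: NormExpr, pt: pd.Series,
                           df: int = 4) -> pd.DataFrame:
    """Spline F-test of expression versus pseudotime, per gene.

    Compares a df-knot cubic-spline regression against the intercept-only
    model with a classical F-test; BH over genes. A gene "varies with
    development" if fdr < 0.05.
    """
    nloc = ne.subset_cells(pt.index.to_numpy(object))
    n = nloc.n_cells
    if n < 10:
        raise ValueError("at least 10 cells required")
    if n < df + 2:
        raise ValueError("fewer cells than spline degrees of freedom")
    B = _spline_basis(pt.to_numpy(float), df)
    X = np.column_stack([np.ones(n), B])
    rank = np.linalg.matrix_rank(X)
    Y = nloc.dense()
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0, keepdims=True))**2).sum(axis=0)
    df_model = rank - 1
    df_resid = n - rank
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df_model) / np.maximum(rss1 / df_resid, 1e-300)
    F = np.where(rss0 <= 1e-300, 0.0, F)          # constant gene → F = 0
    p = scipy.stats.f.sf(F, df_model, df_resid)
    p = np.where(rss0 <= 1e-300, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": nloc.gene_ids, "F": F, "p": p, "fdr": fdr})
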