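"""Context-resolved pseudobulk differential expression.

Counts are summed per replicate × cell type × stage × condition group, and
each (cell type, stage) context is tested separately with a negative-binomial
Wald test: per-gene group means are fitted by Newton iteration with
log-library-size offsets, dispersion comes from a method-of-moments estimate
shrunk toward a mean–dispersion trend, and Benjamini–Hochberg correction is
applied within each context. A gene is called "up"/"down" only if its
|fold change| exceeds ``fc_threshold`` (default 1.5, interpreted as
|log2fc| > log2(1.5)) and its FDR is below ``fdr_threshold`` (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_preprocess import CountMatrix

__all__ = ["PseudobulkMatrix", "DEResult", "aggregate_pseudobulk",
           "estimate_dispersion", "de_test", "deg_summary"]

log = logging.getLogger(__name__)

DEFAULT_GROUP_COLS = ("replicate", "celltype", "stage", "condition")


@dataclass
class PseudobulkMatrix:
    """Per-group summed counts plus group metadata."""

    sums: np.ndarray               # groups × genes, non-negative ints
    groups: pd.DataFrame           # one row per group; includes n_cells
    gene_ids: np.ndarray

    def context_rows(self, celltype: str, stage: str) -> np.ndarray:
        return np.where((self.groups["celltype"] == celltype)
                        & (self.groups["stage"] == stage))[0]


@dataclass
class DEResult:
    """Per-gene results for one contrast in one context."""

    table: pd.DataFrame            # gene, log2fc, base_mean, p, fdr, direction
    celltype: str
    stage: str
    contrast: tuple
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05

    def genes(self, direction: str) -> list:
        t = self.table
        return t.loc[t["direction"] == direction, "gene"].tolist()


def aggregate_pseudobulk(cm: CountMatrix, meta: pd.DataFrame,
                         min_cells: int = 10,
                         group_cols=DEFAULT_GROUP_COLS) -> PseudobulkMatrix:
    """Sum raw counts over cells per replicate × celltype × stage × condition.

    Groups with fewer than ``min_cells`` member cells are dropped (logged).
    """
    meta = meta.loc[pd.Index(cm.cell_ids)]
    keys = meta[list(group_cols)].astype(str).agg("|".join, axis=1)
    codes, uniques = pd.factorize(keys, sort=True)
    n_groups = len(uniques)
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_groups, len(codes)))
    sums = np.asarray((ind @ sp.csr_matrix(cm.counts)).todense()).astype(np.int64)
    sizes = np.bincount(codes, minlength=n_groups)

    rows = pd.DataFrame([u.split("|") for u in uniques], columns=list(group_cols))
    rows["n_cells"] = sizes
    keep = sizes >= min_cells
    dropped = int((~keep).sum())
    if dropped:
        log.info("aggregate_pseudobulk: dropped %d/%d groups below %d cells",
                 dropped, n_groups, min_cells)
    if not keep.any():
        raise ValueError(
            f"no pseudobulk group reaches min_cells={min_cells}")
    return PseudobulkMatrix(sums[keep], rows.loc[keep].reset_index(drop=True),
                            np.asarray(cm.gene_ids, dtype=object))


def _size_factors(sums: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (robust to a minority of DE genes);
    falls back to total-count scaling when too few genes are always observed."""
    sums = np.asarray(sums, dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(sums)
    ref = logs.mean(axis=0)
    usable = np.isfinite(ref)
    if usable.sum() >= 100:
        sf = np.exp(np.median(logs[:, usable] - ref[usable], axis=1))
    else:
        totals = sums.sum(axis=1)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def estimate_dispersion(pb: PseudobulkMatrix, context: tuple,
                        condition_col: str = "condition",
                        shrink_weight: float = 0.7,
                        floor: float = 1e-8) -> np.ndarray:
    """Method-of-moments NB dispersion per gene within one context.

    Per condition, α̂ solves var(y/s) = μ·mean(1/s) + α·μ² on size-factor
    normalized sums; estimates are pooled across conditions, clipped at zero,
    and shrunk (weight ``shrink_weight``) toward a fitted a0 + a1/μ trend over
    base mean. Raises if any condition has fewer than 2 replicates.
    """
    rows = pb.context_rows(*context)
    if rows.size == 0:
        raise ValueError(f"context {context} absent from pseudobulk")
    sub = pb.sums[rows].astype(float)
    conds = pb.groups.loc[rows, condition_col].to_numpy()
    s = _size_factors(pb.sums)[rows]

    num = np.zeros(pb.sums.shape[1])
    den = 0.0
    mu_all = np.zeros(pb.sums.shape[1])
    wsum = 0.0
    for c in np.unique(conds):
        m = conds == c
        if m.sum() < 2:
            raise ValueError(
                f"condition {c!r} has {int(m.sum())} replicate(s) in context "
                f"{context}; at least 2 are required")
        z = sub[m] / s[m][:, None]
        mu = z.mean(axis=0)
        v = z.var(axis=0, ddof=1)
        inv_s = np.mean(1.0 / s[m])
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (v - mu * inv_s) / np.maximum(mu, 1e-12) ** 2, 0.0)
        w = m.sum() - 1
        num += w * np.clip(a, 0.0, None)
        den += w
        mu_all += m.sum() * mu
        wsum += m.sum()
    alpha_hat = num / den
    mu_all = mu_all / wsum

    # trend: alpha ≈ a0 + a1/mu, fitted on expressed genes
    expressed = mu_all > 1.0
    if expressed.sum() >= 10:
        X = np.column_stack([np.ones(expressed.sum()), 1.0 / mu_all[expressed]])
        coef, *_ = np.linalg.lstsq(X, alpha_hat[expressed], rcond=None)
        coef = np.clip(coef, 0.0, None)
        trend = coef[0] + coef[1] / np.maximum(mu_all, 1e-12)
    else:
        trend = np.full_like(alpha_hat, np.median(alpha_hat))
    alpha = (1 - shrink_weight) * alpha_hat + shrink_weight * trend
    return np.maximum(alpha, floor)


def _nb_group_fit(y: np.ndarray, s: np.ndarray, alpha: np.ndarray):
    """Newton fit of per-gene NB means with offsets; returns (mean, info).

    Solves sum_j (y_jg - s_j m_g) / (1 + alpha_g s_j m_g) = 0 for m_g, all
    genes at once. Genes with zero total counts get m floored at 0.5/sum(s).
    """
    tot = y.sum(axis=0)
    S = s.sum()
    m = np.maximum(tot, 0.5) / S
    for _ in range(50):
        mu = s[:, None] * m[None, :]
        denom = 1.0 + alpha[None, :] * mu
        f = ((y - mu) / denom).sum(axis=0)
        fp = -(s[:, None] * (1.0 + alpha[None, :] * y) / denom**2).sum(axis=0)
        step = f / np.minimum(fp, -1e-12)
        # damped multiplicative update keeps m positive
        step = np.clip(step / np.maximum(m, 1e-12), -0.5, 0.5)
        m = m * (1.0 - step)
        if np.max(np.abs(step)) < 1e-10:
            break
    m = np.where(tot == 0, 0.5 / S, m)
    mu = s[:, None] * m[None, :]
    info = (mu / (1.0 + alpha[None, :] * mu)).sum(axis=0)
    return m, info


def de_test(pb: PseudobulkMatrix, contrast: tuple, context: tuple,
            fc_threshold: float = 1.5, fdr_threshold: float = 0.05,
            condition_col: str = "condition",
            dispersion: np.ndarray = None,
            shrink_weight: float = 0.7) -> DEResult:
    """NB Wald test of ``contrast = (numerator, denominator)`` in one context.

    log2fc is the numerator condition relative to the denominator. Genes with
    zero counts in both conditions receive p = 1 and direction "ns". The Wald
    statistic is referred to the standard normal; the trend-shrunk dispersion
    borrows strength across genes, which keeps the normal reference honest at
    few replicates.
    """
    num_cond, den_cond = contrast
    rows = pb.context_rows(*context)
    conds = pb.groups.loc[rows, condition_col].to_numpy()
    for c in contrast:
        if (conds == c).sum() < 2:
            raise ValueError(
                f"condition {c!r} needs >= 2 replicates in context {context}")
    if dispersion is None:
        dispersion = estimate_dispersion(pb, context, condition_col,
                                         shrink_weight=shrink_weight)
    s = _size_factors(pb.sums)[rows]
    sub = pb.sums[rows].astype(float)

    m_n = conds == num_cond
    m_d = conds == den_cond
    mA, iA = _nb_group_fit(sub[m_n], s[m_n], dispersion)
    mB, iB = _nb_group_fit(sub[m_d], s[m_d], dispersion)

    log2fc = (np.log(mA) - np.log(mB)) / np.log(2)
    se = np.sqrt(1.0 / np.maximum(iA, 1e-12) + 1.0 / np.maximum(iB, 1e-12))
    z = (np.log(mA) - np.log(mB)) / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))

    both_zero = (sub[m_n].sum(axis=0) == 0) & (sub[m_d].sum(axis=0) == 0)
    p[both_zero] = 1.0
    log2fc[both_zero] = 0.0

    fdr = multipletests(p, method="fdr_bh")[1]
    lfc_cut = np.log2(fc_threshold) if np.isfinite(fc_threshold) else np.inf
    direction = np.where(
        (np.abs(log2fc) > lfc_cut) & (fdr < fdr_threshold) & ~both_zero,
        np.where(log2fc > 0, "up", "down"), "ns")

    base_mean = (sub / s[:, None]).mean(axis=0)
    table = pd.DataFrame({
        "gene": pb.gene_ids, "celltype": context[0], "stage": context[1],
        "log2fc": log2fc, "base_mean": base_mean, "p": p, "fdr": fdr,
        "direction": direction,
    })
    return DEResult(table, context[0], context[1], contrast,
                    fc_threshold, fdr_threshold)


def deg_summary(results) -> pd.DataFrame:
    """Per-context up/down DEG counts for a single contrast."""
    rows = []
    for r in results:
        t = r.table
        rows.append({"celltype": r.celltype, "stage": r.stage,
                     "n_up": int((t["direction"] == "up").sum()),
                     "n_down": int((t["direction"] == "down").sum())})
    out = pd.DataFrame(rows, columns=["celltype", "stage", "n_up", "n_down"])
    if len(out):
        out = out.sort_values(["celltype", "stage"]).reset_index(drop=True)
    return out


def write_de_tsv(results, path: str) -> str:
    """Write one contrast's DEResults (all contexts) as a single TSV."""
    pd.concat([r.table for r in results], ignore_index=True).to_csv(
        path, sep="\t", index=False)
    return path
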