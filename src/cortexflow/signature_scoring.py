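"""Cell-wall signature scoring and responsive-state classification.

The per-cell score is the classic bin-matched module score: the mean
normalized expression of the signature genes minus the mean over a pool of
control genes drawn, per signature gene, from the same mean-expression bin.
Cells of the cortex with a score of at least ``threshold`` (default 1) are
"responsive cortex cells"; cortex cells below threshold are
"non-responsive"; all other cell types are "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_preprocess import NormExpr, gene_means

__all__ = ["SignatureScores", "score_cells", "classify_states",
           "responsive_fraction_by_group",
           "STATE_RESPONSIVE", "STATE_NONRESPONSIVE", "STATE_OTHER"]

STATE_RESPONSIVE = "cortex-responsive"
STATE_NONRESPONSIVE = "cortex-nonresponsive"
STATE_OTHER = "other"
STATES = (STATE_RESPONSIVE, STATE_NONRESPONSIVE, STATE_OTHER)


@dataclass
class SignatureScores:
    """Per-cell score and three-state classification."""

    table: pd.DataFrame            # index cell id; columns score, state
    signature_name: str
    threshold: float = 1.0

    @property
    def states(self) -> pd.Series:
        return self.table["state"]

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]


def score_cells(ne: NormExpr, signature, n_bins: int = 25, n_ctrl: int = 100,
                seed: int = 0) -> pd.Series:
    """Bin-matched signature score per cell.

    Genes are ranked by mean normalized expression and cut into ``n_bins``
    equal-size bins; each signature gene contributes up to ``n_ctrl`` control
    genes sampled without replacement from its bin (signature genes excluded
    from the pool unless that would empty it). Controls are sampled once per
    dataset and seed and shared across cells, keeping scores comparable
    cell-to-cell.
    """
    signature = list(dict.fromkeys(signature))
    gene_index = pd.Index(ne.gene_ids)
    pos = gene_index.get_indexer(signature)
    missing = [g for g, p in zip(signature, pos) if p < 0]
    if len(missing) == len(signature):
        raise ValueError(f"no signature gene found in matrix; missing ids: "
                         f"{missing[:10]}")
    sig_pos = pos[pos >= 0]
    if n_bins > ne.n_genes:
        raise ValueError("n_bins exceeds the number of genes")
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be positive")

    mu = gene_means(ne)
    # equal-size bins by expression rank (stable: ties resolved by gene order)
    order = np.argsort(mu, kind="stable")
    bin_of = np.empty(ne.n_genes, dtype=int)
    bin_of[order] = np.minimum((np.arange(ne.n_genes) * n_bins) // ne.n_genes,
                               n_bins - 1)

    rng = np.random.default_rng(seed)
    sig_set = set(sig_pos.tolist())
    ctrl_positions = []
    for p in sig_pos:
        pool = np.where(bin_of == bin_of[p])[0]
        non_sig = pool[~np.isin(pool, list(sig_set))]
        pool = non_sig if non_sig.size else pool
        take = min(n_ctrl, pool.size)
        ctrl_positions.append(rng.choice(pool, size=take, replace=False))
    ctrl_positions = np.concatenate(ctrl_positions)

    X = ne.values
    if sp.issparse(X):
        sig_mean = np.asarray(X[:, sig_pos].mean(axis=1)).ravel()
        ctrl_mean = np.asarray(X[:, ctrl_positions].mean(axis=1)).ravel()
    else:
        X = np.asarray(X)
        sig_mean = X[:, sig_pos].mean(axis=1)
        ctrl_mean = X[:, ctrl_positions].mean(axis=1)
    return pd.Series(sig_mean - ctrl_mean, index=pd.Index(ne.cell_ids),
                     name="score")


def classify_states(scores: pd.Series, meta: pd.DataFrame,
                    threshold: float = 1.0,
                    signature_name: str = "cell_wall",
                    cortex_label: str = "cortex") -> SignatureScores:
    """Three-state classification from scores and cell-type annotation.

    responsive ⇔ cortex and score ≥ threshold (inclusive); non-responsive ⇔
    cortex below threshold; any other cell type ⇔ "other".
    """
    if not scores.index.equals(pd.Index(meta.index)):
        if set(scores.index) != set(meta.index):
            raise ValueError("scores and metadata cell ids do not match")
        meta = meta.loc[scores.index]
    is_cortex = (meta["celltype"] == cortex_label).to_numpy()
    state = np.where(~is_cortex, STATE_OTHER,
                     np.where(scores.to_numpy() >= threshold,
                              STATE_RESPONSIVE, STATE_NONRESPONSIVE))
    table = pd.DataFrame({"score": scores, "state": state}, index=scores.index)
    return SignatureScores(table, signature_name, threshold)


def responsive_fraction_by_group(ss: SignatureScores, meta: pd.DataFrame,
                                 group_by) -> pd.Series:
    """Fraction of responsive cells per metadata group.

    Empty groups (possible with categorical metadata) are reported as NaN,
    never as 0.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    meta = meta.loc[ss.table.index]
    resp = (ss.states == STATE_RESPONSIVE).astype(float)
    grouped = resp.groupby([meta[c] for c in group_by], observed=False)
    n = grouped.size()
    frac = grouped.sum() / n
    frac[n == 0] = np.nan
    frac.name = "responsive_fraction"
    return frac
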