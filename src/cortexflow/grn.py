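"""Context-specific GRN inference within a TF–target prior.

Per target gene, expression is regressed on its candidate TFs (restricted
to the base-network prior) with ridge regression, bagged over bootstrap
resamples of cells. An edge survives if its mean coefficient magnitude
exceeds the (1 − keep_frac) quantile of all candidate-edge magnitudes, its
sign is consistent in ≥ 80% of bags, and its bootstrap t-statistic
(|mean| / bootstrap SD) reaches ``t_min`` — the last condition is what
actually rejects edges whose target is independent of the TF, since
bootstrap signs alone correlate with the full-sample fit. TFs are then prioritized by
out-degree centrality — the statistic behind hub discovery — and networks
from different contexts can be compared by exact (TF, target) edge overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_preprocess import NormExpr
from .synthetic_data import BaseNetwork

__all__ = ["GRN", "fit_grn", "network_centrality", "rank_tfs",
           "extract_subnetwork", "compare_networks", "write_edge_list"]

log = logging.getLogger(__name__)


@dataclass
class GRN:
    """Signed, weighted TF→target edges for one context."""

    context: str
    edges: pd.DataFrame            # tf, target, weight, sign
    diagnostics: dict = field(default_factory=dict)

    @property
    def edge_pairs(self) -> set:
        return set(zip(self.edges["tf"], self.edges["target"]))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for _, row in self.edges.iterrows():
            g.add_edge(row["tf"], row["target"], weight=row["weight"],
                       sign=row["sign"])
        return g


def fit_grn(ne: NormExpr, base: BaseNetwork, alpha: float = 1.0,
            n_bag: int = 20, keep_frac: float = 0.1, seed: int = 0,
            sign_consistency: float = 0.8, t_min: float = 2.0,
            context: str = "") -> GRN:
    """Bagged ridge regression of each target on its prior candidate TFs.

    ``ne`` should already be restricted to the cells of one context
    (cell type × stage × time point) with at least 20 cells. Deterministic
    given the seed; invariant to cell order (bootstrap draws operate on a
    canonically sorted cell index).
    """
    if ne.n_cells < 20:
        raise ValueError("context must contain at least 20 cells")
    if not 0.0 <= keep_frac <= 1.0:
        raise ValueError("keep_frac must lie in [0, 1]")
    order = np.argsort(np.asarray(ne.cell_ids, dtype=object))
    X = ne.dense()[order]
    gene_index = pd.Index(ne.gene_ids)

    candidates = {}
    skipped = 0
    for tf, tg in sorted(base.edges):
        if tf in gene_index and tg in gene_index:
            candidates.setdefault(tg, []).append(tf)
        else:
            skipped += 1
    if skipped:
        log.info("fit_grn: %d prior edges reference genes absent from the "
                 "matrix", skipped)

    # center only: weights stay on the regression (expression) scale
    Z = X - X.mean(axis=0)

    rng = np.random.default_rng(seed)
    n = Z.shape[0]
    boot = rng.integers(0, n, size=(n_bag, n))

    rows = []
    for target in sorted(candidates):
        tfs = sorted(candidates[target])
        cols = gene_index.get_indexer(tfs)
        ycol = gene_index.get_loc(target)
        coefs = np.empty((n_bag, len(tfs)))
        for b in range(n_bag):
            idx = boot[b]
            Xb = Z[idx][:, cols]
            yb = Z[idx, ycol]
            A = Xb.T @ Xb + alpha * np.eye(len(tfs))
            coefs[b] = np.linalg.solve(A, Xb.T @ yb)
        mean_c = coefs.mean(axis=0)
        boot_sd = coefs.std(axis=0, ddof=1)
        tstat = np.abs(mean_c) / np.maximum(boot_sd, 1e-12)
        sign_frac = np.maximum((coefs > 0).mean(axis=0), (coefs < 0).mean(axis=0))
        for j, tf in enumerate(tfs):
            rows.append((tf, target, mean_c[j], sign_frac[j], tstat[j]))
    if not rows:
        return GRN(context, pd.DataFrame(columns=["tf", "target", "weight", "sign"]))

    cand = pd.DataFrame(rows, columns=["tf", "target", "weight", "sign_frac",
                                       "tstat"])
    mags = np.abs(cand["weight"].to_numpy())
    if keep_frac == 0.0:
        cutoff = np.inf
    else:
        cutoff = np.quantile(mags, 1.0 - keep_frac)
    stable = (cand["sign_frac"] >= sign_consistency) & (cand["tstat"] >= t_min)
    keep = (mags > cutoff) & stable
    if keep_frac == 1.0:
        keep = stable
    edges = cand.loc[keep, ["tf", "target", "weight"]].copy()
    edges["sign"] = np.where(edges["weight"] > 0, "+", "-")
    edges = edges.sort_values(["tf", "target"]).reset_index(drop=True)
    assert set(zip(edges["tf"], edges["target"])) <= {
        (a, b) for a, b in base.edges}, "fit produced an edge outside the prior"
    return GRN(context, edges,
               {"n_candidate_edges": len(cand), "n_kept": int(keep.sum()),
                "n_cells": n})


def network_centrality(g: GRN) -> pd.DataFrame:
    """Degree table on retained edges.

    degree_centrality = (in + out) / (n_nodes − 1); rank_by_out_degree is a
    permutation with ties broken by node id.
    """
    if len(g.edges) == 0:
        return pd.DataFrame(columns=["node", "out_degree", "in_degree",
                                     "degree_centrality", "rank_by_out_degree"])
    dig = g.to_networkx()
    n_nodes = dig.number_of_nodes()
    rows = [(node, dig.out_degree(node), dig.in_degree(node))
            for node in dig.nodes]
    table = pd.DataFrame(rows, columns=["node", "out_degree", "in_degree"])
    table["degree_centrality"] = (table["out_degree"] + table["in_degree"]) / \
        max(n_nodes - 1, 1)
    table = table.sort_values(["out_degree", "node"],
                              ascending=[False, True]).reset_index(drop=True)
    table["rank_by_out_degree"] = np.arange(1, len(table) + 1)
    return table


def rank_tfs(tables: dict, top_n: int = 10, tf_ids=None) -> dict:
    """Top-n regulators by out-degree per context (stable tie order by id)."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    out = {}
    for ctx, table in tables.items():
        t = table
        if tf_ids is not None:
            t = t[t["node"].isin(set(tf_ids))]
        out[ctx] = t["node"].head(top_n).tolist()
    return out


def extract_subnetwork(g: GRN, nodes, include_neighbor_targets: bool = False) -> GRN:
    """Induced subnetwork on ``nodes``.

    With ``include_neighbor_targets`` edges from listed TFs to any target are
    kept as well (first-neighbor expansion used for hub-focused panels).
    """
    nodes = set(nodes)
    if not nodes:
        raise ValueError("empty node set")
    e = g.edges
    mask = e["tf"].isin(nodes) & e["target"].isin(nodes)
    if include_neighbor_targets:
        mask = mask | e["tf"].isin(nodes)
    sub = e.loc[mask].reset_index(drop=True)
    if sub.empty:
        import warnings

        warnings.warn("subnetwork has no edges", stacklevel=2)
    return GRN(g.context + "|sub", sub, dict(g.diagnostics))


def compare_networks(a: GRN, b: GRN) -> tuple:
    """Exact (TF, target) edge overlap, ignoring sign and weight.

    Returns (shared_edges, union_edges, jaccard).
    """
    ea, eb = a.edge_pairs, b.edge_pairs
    shared = len(ea & eb)
    union = len(ea | eb)
    return shared, union, shared / union if union else float("nan")


def write_edge_list(g: GRN, path: str) -> str:
    g.edges.to_csv(path, sep="\t", index=False)
    return path
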