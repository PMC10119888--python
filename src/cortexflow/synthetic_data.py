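"""Synthetic time-course scRNA-seq generator with planted ground truth.

Emulates the statistical design of a hormone-induction root time course:
six sampling times (0, 0.5, 1, 2, 4, 8 h), several cell types stratified
into four developmental stages, negative-binomial UMI counts, and four
planted structures that downstream modules must recover:

* a cell-wall induction module — ``n_signature_genes`` genes whose
  log-mean in cortex transition/elongation cells rises with a saturating
  time curve ``ln(signature_fold) · t / (t + induction_halftime_h)``
  under hormone (BL) treatment in the wild type, and not at all in the
  receptor-null genotype. Signature genes additionally carry a baseline
  elevation in cortex transition/elongation cells (cell-wall genes are
  elongation-associated), which makes them developmentally varying even
  before induction;
* a responsive/non-responsive dichotomy — each cortex
  transition/elongation cell is induction-competent with probability
  ``competence_prob`` (default 0.8);
* stage-dependent relative growth rates, consumed as transport masses;
* a TF hub network — ``n_tfs`` transcription factors whose per-cell
  activity (active in cortex cells) shifts the log-mean of their true
  targets by ``grn_effect_size``; one hub TF has out-degree
  ``hub_out_degree``, strictly larger than every other TF. The hub TF is
  itself hormone-induced in competent cortex cells.

Counts are NB with var = μ + α·μ²; the same seed yields byte-identical
output, and gene/network parameters are drawn from a genotype-independent
stream so wild-type and receptor-null datasets are directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_preprocess import CountMatrix

__all__ = ["SimConfig", "GroundTruth", "BaseNetwork", "simulate_timecourse",
           "make_base_network"]

STAGES = ("proliferation", "transition", "elongation", "differentiation")
INDUCED_STAGES = ("transition", "elongation")


def _default_celltypes():
    return {
        "cortex": 0.30,
        "atrichoblast": 0.15,
        "trichoblast": 0.10,
        "endodermis": 0.15,
        "stele": 0.20,
        "columella": 0.10,
    }


def _default_stages():
    return {"proliferation": 0.30, "transition": 0.25,
            "elongation": 0.25, "differentiation": 0.20}


def _default_growth():
    return {"proliferation": 2.0, "transition": 1.5,
            "elongation": 1.0, "differentiation": 0.8}


@dataclass
class SimConfig:
    """Configuration of the synthetic time course (defaults = study design)."""

    n_cells_per_timepoint: int = 1500
    time_points_h: tuple = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
    celltype_proportions: dict = field(default_factory=_default_celltypes)
    stage_proportions_per_celltype: dict = field(default_factory=dict)
    n_genes: int = 2000
    n_signature_genes: int = 107
    signature_fold: float = 4.0
    induction_halftime_h: float = 1.0
    nb_dispersion: float = 0.1
    baseline_mean_logspace: tuple = (0.0, 1.0)
    n_tfs: int = 20
    hub_out_degree: int = 40
    grn_effect_size: float = 0.5
    growth_rate_by_stage: dict = field(default_factory=_default_growth)
    replicates: int = 3
    seed: int = 0
    genotype_mode: str = "WT"
    # secondary knobs (fixed study conditions, exposed for tests)
    competence_prob: float = 0.8
    signature_stage_bonus: float = 0.5
    tf_activity_sd: float = 1.0
    tf_hub_fold: float = 3.0
    other_out_degree_range: tuple = (4, 10)
    decoy_ratio: float = 1.0
    replicate_effect_sd: float = 0.05
    depth_sd: float = 0.3
    diversity_decay: float = 0.25
    n_other_responsive_genes: int = 15
    conditions: tuple = ("BL", "mock")

    def stage_props(self, celltype: str) -> dict:
        return self.stage_proportions_per_celltype.get(celltype, _default_stages())

    def validate(self):
        if abs(sum(self.celltype_proportions.values()) - 1) > 1e-8:
            raise ValueError("celltype proportions must sum to 1")
        for ct in self.celltype_proportions:
            if abs(sum(self.stage_props(ct).values()) - 1) > 1e-8:
                raise ValueError(f"stage proportions for {ct} must sum to 1")
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes exceeds n_genes")
        if self.nb_dispersion <= 0 or self.induction_halftime_h <= 0:
            raise ValueError("rates must be positive")
        if any(r <= 0 for r in self.growth_rate_by_stage.values()):
            raise ValueError("growth rates must be positive")
        if self.genotype_mode not in ("WT", "receptor_null"):
            raise ValueError("genotype_mode must be 'WT' or 'receptor_null'")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset."""

    signature_gene_ids: list
    responsive_cells: dict          # time_h (as str) -> list of cell ids
    true_de_genes: dict             # "celltype|stage" -> {gene: log2fc at 2 h}
    true_edges: list                # (tf, target, sign)
    hub_tf_id: str
    tf_ids: list
    true_growth: dict               # cell id -> relative growth rate
    core_gene_ids: list
    mean_table: dict = None         # optional: per-gene expected mean (diagnostics)

    def to_json(self, path: str):
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str):
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class BaseNetwork:
    """Candidate TF→target prior within which GRN weights are fit."""

    edges: set                      # set of (tf, target)
    tf_ids: list
    provenance: str = "synthetic prior"

    def __post_init__(self):
        self.edges = {tuple(e) for e in self.edges}
        tfset = set(self.tf_ids)
        for tf, tg in self.edges:
            if tf == tg:
                raise ValueError(f"self-loop edge {tf}")
            if tf not in tfset:
                raise ValueError(f"edge source {tf} missing from tf_ids")


# ---------------------------------------------------------------------------
# parameter planting (genotype-independent streams)
# ---------------------------------------------------------------------------

def _gene_params(cfg: SimConfig):
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_genes
    gene_ids = np.array([f"g{i:04d}" for i in range(n)], dtype=object)
    mu0, sd0 = cfg.baseline_mean_logspace
    baseline = rng.normal(mu0, sd0, size=n)

    # transcription factors occupy the first n_tfs slots
    tf_idx = np.arange(cfg.n_tfs)
    baseline[tf_idx] = rng.normal(1.0, 0.4, size=cfg.n_tfs)

    pool = np.arange(cfg.n_tfs, n)
    sig_idx = rng.choice(pool, size=cfg.n_signature_genes, replace=False)
    baseline[sig_idx] = rng.normal(1.0, 0.4, size=cfg.n_signature_genes)

    rest = np.setdiff1d(pool, sig_idx)
    celltypes = list(cfg.celltype_proportions)
    ct_effect = np.zeros((len(celltypes), n))
    markers = {}
    for k, ct in enumerate(celltypes):
        m = rng.choice(rest, size=min(50, rest.size), replace=False)
        ct_effect[k, m] += rng.normal(1.0, 0.3, size=m.size)
        markers[ct] = m
    # developmental gradient genes (slope per stage index)
    grad_idx = rng.choice(rest, size=min(150, rest.size), replace=False)
    stage_slope = np.zeros(n)
    stage_slope[grad_idx] = rng.normal(0.0, 0.4, size=grad_idx.size)

    # off-target hormone response planted in atrichoblast
    other_resp = rng.choice(rest, size=cfg.n_other_responsive_genes, replace=False)

    return dict(gene_ids=gene_ids, baseline=baseline, tf_idx=tf_idx,
                sig_idx=np.sort(sig_idx), ct_effect=ct_effect,
                stage_slope=stage_slope, celltypes=celltypes,
                other_resp=np.sort(other_resp))


def _network_params(cfg: SimConfig, params=None):
    params = params or _gene_params(cfg)
    rng = np.random.default_rng([cfg.seed, 2])
    lo, hi = cfg.other_out_degree_range
    if cfg.hub_out_degree <= hi and cfg.n_tfs > 1:
        raise ValueError(
            "hub_out_degree must strictly exceed the maximum other-TF degree")
    if cfg.hub_out_degree > cfg.n_genes - 1:
        raise ValueError("hub_out_degree exceeds number of possible targets")
    gene_ids = params["gene_ids"]
    tf_ids = [gene_ids[i] for i in params["tf_idx"]]
    hub = tf_ids[0]
    targets_pool = np.arange(cfg.n_tfs, cfg.n_genes)
    true_edges = []
    for j, tf in enumerate(tf_ids):
        k = cfg.hub_out_degree if tf == hub else int(rng.integers(lo, hi + 1)) if cfg.n_tfs > 1 else cfg.hub_out_degree
        tg = rng.choice(targets_pool, size=k, replace=False)
        for t in tg:
            sign = 1 if rng.random() < 0.8 else -1
            true_edges.append((tf, gene_ids[t], sign))
    return dict(tf_ids=tf_ids, hub=hub, true_edges=true_edges, params=params)


def make_base_network(cfg: SimConfig) -> tuple:
    """Build the candidate-edge prior: planted true edges plus decoys.

    Returns ``(BaseNetwork, true_edges)`` where true_edges are
    (tf, target, sign) triples. Decoy candidate edges are added at
    ``cfg.decoy_ratio`` × the number of true edges.
    """
    cfg.validate()
    net = _network_params(cfg)
    gene_ids = net["params"]["gene_ids"]
    true_pairs = {(tf, tg) for tf, tg, _ in net["true_edges"]}
    rng = np.random.default_rng([cfg.seed, 4])
    n_decoys = int(round(cfg.decoy_ratio * len(true_pairs)))
    decoys = set()
    targets_pool = gene_ids[cfg.n_tfs:]
    while len(decoys) < n_decoys:
        tf = net["tf_ids"][int(rng.integers(len(net["tf_ids"])))]
        tg = targets_pool[int(rng.integers(len(targets_pool)))]
        if (tf, tg) not in true_pairs:
            decoys.add((tf, tg))
    base = BaseNetwork(edges=true_pairs | decoys, tf_ids=list(net["tf_ids"]))
    return base, net["true_edges"]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _induction_lfc(cfg: SimConfig, t: float) -> float:
    """Natural-log induction at time t (saturating curve)."""
    if t <= 0:
        return 0.0
    return np.log(cfg.signature_fold) * t / (t + cfg.induction_halftime_h)


def simulate_timecourse(cfg: SimConfig):
    """Simulate the full time course.

    Returns ``(CountMatrix, CellMeta DataFrame, GroundTruth)``. CellMeta has
    columns sample, replicate, time_h, genotype, condition, celltype, stage.
    """
    cfg.validate()
    params = _gene_params(cfg)
    net = _network_params(cfg, params)
    gene_ids = params["gene_ids"]
    celltypes = params["celltypes"]
    n_genes = cfg.n_genes
    geno_idx = 0 if cfg.genotype_mode == "WT" else 1
    rng = np.random.default_rng([cfg.seed, 3, geno_idx])

    # per-(replicate × condition × time) biological effects (sample effects)
    sample_keys = []
    for t in cfg.time_points_h:
        for cond in cfg.conditions:
            for r in range(cfg.replicates):
                sample_keys.append((t, cond, f"rep{r + 1}"))
    rep_fx = rng.normal(0.0, cfg.replicate_effect_sd,
                        size=(len(sample_keys), n_genes))
    sample_pos = {k: i for i, k in enumerate(sample_keys)}

    sig_idx = params["sig_idx"]
    hub_col = int(np.where(gene_ids == net["hub"])[0][0])
    ct_pos = {ct: k for k, ct in enumerate(celltypes)}
    stage_pos = {s: k for k, s in enumerate(STAGES)}

    # pre-index network targets per TF
    tf_cols = {tf: int(np.where(gene_ids == tf)[0][0]) for tf in net["tf_ids"]}
    tf_targets = {tf: ([], []) for tf in net["tf_ids"]}
    for tf, tg, sign in net["true_edges"]:
        cols, signs = tf_targets[tf]
        cols.append(int(np.where(gene_ids == tg)[0][0]))
        signs.append(sign)

    blocks, meta_rows = [], []
    responsive = {}
    true_growth = {}
    cell_counter = 0
    per_cond = cfg.n_cells_per_timepoint // len(cfg.conditions)

    for t in cfg.time_points_h:
        resp_ids = []
        for cond in cfg.conditions:
            n_cells = per_cond
            cts = rng.choice(len(celltypes), size=n_cells,
                             p=list(cfg.celltype_proportions.values()))
            stages = np.empty(n_cells, dtype=int)
            for k, ct in enumerate(celltypes):
                m = cts == k
                if m.any():
                    props = [cfg.stage_props(ct)[s] for s in STAGES]
                    stages[m] = rng.choice(len(STAGES), size=m.sum(), p=props)
            reps = rng.integers(0, cfg.replicates, size=n_cells)
            depth = rng.normal(0.0, cfg.depth_sd, size=n_cells)

            ln_mu = np.tile(params["baseline"], (n_cells, 1))
            ln_mu += params["ct_effect"][cts]
            ln_mu += stages[:, None] * params["stage_slope"][None, :]
            # transcriptional diversity falls as cells differentiate: a global
            # per-stage downshift that thins the detected-gene repertoire
            ln_mu -= cfg.diversity_decay * stages[:, None]

            cortex_te = (cts == ct_pos.get("cortex", -1)) & np.isin(
                stages, [stage_pos[s] for s in INDUCED_STAGES])
            # baseline cell-wall program of elongating cortex
            ln_mu[np.ix_(cortex_te, sig_idx)] += cfg.signature_stage_bonus
            ln_mu[cortex_te, hub_col] += cfg.signature_stage_bonus

            competent = rng.random(n_cells) < cfg.competence_prob
            induced = cortex_te & competent & (cond == "BL") & \
                (cfg.genotype_mode == "WT") & (t > 0)
            lfc_t = _induction_lfc(cfg, t)
            if lfc_t != 0.0 and induced.any():
                ln_mu[np.ix_(induced, sig_idx)] += lfc_t
                ln_mu[induced, hub_col] += \
                    np.log(cfg.tf_hub_fold) * t / (t + cfg.induction_halftime_h)
            # off-target response in atrichoblast (both stages pooled)
            atr = cts == ct_pos.get("atrichoblast", -1)
            if cond == "BL" and cfg.genotype_mode == "WT" and t > 0 and atr.any():
                ln_mu[np.ix_(atr, params["other_resp"])] += \
                    np.log(3.0) * t / (t + cfg.induction_halftime_h)

            # TF hub network active in cortex cells
            cortex = cts == ct_pos.get("cortex", -1)
            if cortex.any():
                act = rng.normal(0.0, cfg.tf_activity_sd,
                                 size=(int(cortex.sum()), cfg.n_tfs))
                rows = np.where(cortex)[0]
                for j, tf in enumerate(net["tf_ids"]):
                    ln_mu[rows, tf_cols[tf]] += act[:, j]
                    cols, signs = tf_targets[tf]
                    if cols:
                        ln_mu[np.ix_(rows, cols)] += (
                            cfg.grn_effect_size * act[:, j][:, None]
                            * np.asarray(signs, float)[None, :])

            sample_idx = np.array([sample_pos[(t, cond, f"rep{r + 1}")]
                                   for r in reps])
            ln_mu += rep_fx[sample_idx]
            ln_mu += depth[:, None]

            mu = np.exp(ln_mu)
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, mu * cfg.nb_dispersion)
            counts = rng.poisson(lam)
            blocks.append(sp.csr_matrix(counts))

            ids = [f"cell{cell_counter + i:06d}" for i in range(n_cells)]
            cell_counter += n_cells
            for i, cid in enumerate(ids):
                ct = celltypes[cts[i]]
                st = STAGES[stages[i]]
                meta_rows.append({
                    "cell": cid,
                    "sample": f"{cfg.genotype_mode}_{cond}_{t}h_rep{reps[i] + 1}",
                    "replicate": f"rep{reps[i] + 1}",
                    "time_h": float(t),
                    "genotype": cfg.genotype_mode,
                    "condition": cond,
                    "celltype": ct,
                    "stage": st,
                })
                true_growth[cid] = float(cfg.growth_rate_by_stage[st])
            if cond == "BL":
                resp_ids.extend(np.asarray(ids, object)[induced].tolist())
        responsive[str(float(t))] = sorted(resp_ids) if (
            cfg.genotype_mode == "WT" and cfg.signature_fold > 1) else []

    counts = sp.vstack(blocks).astype(np.int64)
    meta = pd.DataFrame(meta_rows).set_index("cell")
    cm = CountMatrix(counts, meta.index.to_numpy(object), gene_ids)

    # planted DE truth at the 2 h contrast, per (celltype, stage) context
    true_de = {}
    lfc2 = _induction_lfc(cfg, 2.0) / np.log(2)
    if cfg.genotype_mode == "WT" and lfc2 > 0:
        sig_genes = [gene_ids[i] for i in sig_idx]
        for st in INDUCED_STAGES:
            ctx = {g: lfc2 for g in sig_genes}
            ctx[net["hub"]] = np.log2(cfg.tf_hub_fold) * 2.0 / (2.0 + cfg.induction_halftime_h)
            true_de[f"cortex|{st}"] = ctx
        other = {gene_ids[i]: np.log2(3.0) * 2.0 / (2.0 + cfg.induction_halftime_h)
                 for i in params["other_resp"]}
        for st in STAGES:
            true_de[f"atrichoblast|{st}"] = dict(other)

    sig_gene_ids = [gene_ids[i] for i in sig_idx]
    gt = GroundTruth(
        signature_gene_ids=sig_gene_ids,
        responsive_cells=responsive,
        true_de_genes=true_de,
        true_edges=[(tf, tg, int(s)) for tf, tg, s in net["true_edges"]],
        hub_tf_id=net["hub"],
        tf_ids=list(net["tf_ids"]),
        true_growth=true_growth,
        core_gene_ids=sorted(sig_gene_ids + [net["hub"]]) if cfg.genotype_mode == "WT"
        else [],
    )
    return cm, meta, gt
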