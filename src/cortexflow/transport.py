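"""Growth-adjusted entropic (unbalanced) optimal transport between time points.

This is the trajectory-reconstruction core: adjacent snapshots of a
time course are coupled by entropic optimal transport in PCA space, with
KL-relaxed marginals so that estimated proliferation (growth) enters as
source mass rather than a hard constraint. Longer-range ancestor/descendant
queries compose adjacent plans; fate probabilities are mass fractions
transported into a reference-time partition of cells into
{cortex-responsive, cortex-nonresponsive, other}.

The solver runs diagonal scaling iterations in the log domain
(overflow-safe for any ε ≥ 1e-3 after median cost normalization):

    f ← λ1/(λ1+ε) · (ε·log p − Smin_j),  Smin_j = ε·LSE_j((g_j − C_ij)/ε)
    g ← λ2/(λ2+ε) · (ε·log q − Smin_i)

with λ = ∞ recovering balanced entropic transport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import Embedding
from .signature_scoring import STATE_RESPONSIVE, STATE_NONRESPONSIVE, STATE_OTHER

__all__ = ["SinkhornParams", "TransportPlan", "pairwise_cost", "growth_weights",
           "sinkhorn_unbalanced", "compose_plans", "fate_probabilities",
           "ancestor_distribution"]

FATE_STATES = (STATE_RESPONSIVE, STATE_NONRESPONSIVE, STATE_OTHER)
FATE_COLUMNS = ("p_responsive", "p_nonresponsive", "p_other")


@dataclass
class SinkhornParams:
    """Regularization and convergence settings.

    epsilon — entropic regularization (on median-normalized cost, so
    scale-free); lambda1/lambda2 — KL relaxation strengths of the source and
    target marginals (np.inf = exact/balanced). The looser source default
    tolerates growth-rate error while the tight target constraint trusts the
    observed cells.
    """

    epsilon: float = 0.05
    lambda1: float = 1.0
    lambda2: float = 50.0
    max_iter: int = 5000
    tol: float = 1e-9
    marginal_tol: float = 1e-9
    growth_iters: int = 1

    def __post_init__(self):
        if self.epsilon <= 0 or self.tol <= 0:
            raise ValueError("epsilon and tol must be positive")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1/lambda2 must be positive (inf = balanced)")


@dataclass
class TransportPlan:
    """Coupling between cells of two adjacent time points."""

    source_ids: np.ndarray
    target_ids: np.ndarray
    coupling: np.ndarray
    source_mass: np.ndarray
    target_mass: np.ndarray
    params: SinkhornParams
    converged: bool = True
    marginal_error: float = 0.0
    t_source: float = None
    t_target: float = None
    trace: list = field(default_factory=list)


def pairwise_cost(embA: Embedding, embB: Embedding,
                  normalize: bool = True) -> np.ndarray:
    """Squared Euclidean cost, median-normalized so ε is scale-free."""
    if embA.K != embB.K:
        raise ValueError(f"embedding dimensions differ: {embA.K} vs {embB.K}")
    A, B = embA.coords, embB.coords
    sq = (A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2.0 * (A @ B.T)
    C = np.maximum(sq, 0.0)
    if normalize:
        med = np.median(C)
        if med > 0:
            C = C / med
    return C


def growth_weights(meta: pd.DataFrame, rates: dict, dt_h: float) -> pd.Series:
    """Per-cell source mass p_i ∝ rate(stage_i)^dt_h, normalized to sum 1."""
    if dt_h <= 0:
        raise ValueError("dt_h must be positive")
    stages = meta["stage"]
    missing = sorted(set(stages) - set(rates))
    if missing:
        raise KeyError(f"no growth rate for stage(s) {missing}")
    w = stages.map(rates).astype(float) ** dt_h
    return w / w.sum()


def _softmin_rows(logM: np.ndarray) -> np.ndarray:
    m = logM.max(axis=1)
    return m + np.log(np.exp(logM - m[:, None]).sum(axis=1))


def sinkhorn_unbalanced(C: np.ndarray, p: np.ndarray, q: np.ndarray,
                        params: SinkhornParams,
                        source_ids=None, target_ids=None) -> TransportPlan:
    """Entropic (un)balanced OT by log-domain diagonal scaling.

    Minimizes ⟨Π,C⟩ − ε·H(Π) + λ1·KL(Π1 ∥ p) + λ2·KL(Πᵀ1 ∥ q). With both λ
    infinite this is balanced entropic transport. Non-convergence at max_iter
    returns the current plan flagged ``converged=False`` with its marginal
    error.
    """
    C = np.asarray(C, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not np.isfinite(C).all() or (C < 0).any():
        raise ValueError("cost matrix must be finite and non-negative")
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError("marginals must be strictly positive")
    n, m = C.shape
    eps = params.epsilon
    fi = 1.0 if np.isinf(params.lambda1) else params.lambda1 / (params.lambda1 + eps)
    fj = 1.0 if np.isinf(params.lambda2) else params.lambda2 / (params.lambda2 + eps)
    balanced = np.isinf(params.lambda1) and np.isinf(params.lambda2)

    lp = eps * np.log(p)
    lq = eps * np.log(q)
    f = np.zeros(n)
    g = np.zeros(m)
    trace = []
    converged = False
    for it in range(params.max_iter):
        f_prev, g_prev = f, g
        f = fi * (lp - eps * _softmin_rows((g[None, :] - C) / eps))
        g = fj * (lq - eps * _softmin_rows((f[:, None] - C).T / eps))
        err = max(np.max(np.abs(f - f_prev)), np.max(np.abs(g - g_prev)))
        if balanced and (it % 10 == 0 or err < params.tol):
            logP = (f[:, None] + g[None, :] - C) / eps
            P = np.exp(logP)
            # dual objective (monotone non-decreasing for balanced Sinkhorn)
            trace.append(float(f @ p + g @ q - eps * P.sum()))
            # after an f,g sweep columns match q exactly; rows measure error
            if np.abs(P.sum(axis=1) - p).sum() < params.marginal_tol:
                converged = True
                break
        if err < params.tol:
            converged = True
            break
    plan = np.exp((f[:, None] + g[None, :] - C) / eps)
    marg = float(np.abs(plan.sum(1) - p).sum() + np.abs(plan.sum(0) - q).sum())
    if source_ids is None:
        source_ids = np.arange(n)
    if target_ids is None:
        target_ids = np.arange(m)
    return TransportPlan(np.asarray(source_ids, object),
                         np.asarray(target_ids, object),
                         plan, p, q, params, converged, marg, trace=trace)


def _row_normalized(plan: TransportPlan) -> np.ndarray:
    P = plan.coupling
    r = P.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Pn = np.where(r > 0, P / r, 0.0)
    return Pn


def compose_plans(plans) -> TransportPlan:
    """Compose a head-to-tail chain of plans into one long-range coupling.

    Couplings are row-normalized (Markov transitions) and chained, then
    re-weighted by the first plan's source masses; composing with an identity
    plan is a no-op.
    """
    plans = list(plans)
    if not plans:
        raise ValueError("empty plan list")
    for a, b in zip(plans, plans[1:]):
        if not np.array_equal(a.target_ids, b.source_ids):
            raise ValueError(
                f"plan chain mismatch: targets at t={a.t_target} differ from "
                f"sources at t={b.t_source}")
    M = _row_normalized(plans[0])
    for b in plans[1:]:
        M = M @ _row_normalized(b)
    gamma = plans[0].source_mass[:, None] * M
    return TransportPlan(plans[0].source_ids, plans[-1].target_ids, gamma,
                         plans[0].source_mass, gamma.sum(axis=0),
                         plans[0].params, all(pl.converged for pl in plans),
                         0.0, plans[0].t_source, plans[-1].t_target)


def _chain(plans, t_from: float, t_to: float):
    sub = [pl for pl in plans if t_from <= pl.t_source and pl.t_target <= t_to]
    sub.sort(key=lambda pl: pl.t_source)
    if not sub or sub[0].t_source != t_from or sub[-1].t_target != t_to:
        raise ValueError(f"no contiguous plan chain from t={t_from} to t={t_to}")
    return compose_plans(sub)


def fate_probabilities(plans, reference_partition: pd.Series,
                       t_ref: float) -> pd.DataFrame:
    """Per-cell probabilities over the three reference states.

    ``reference_partition`` maps every cell observed at ``t_ref`` to one of
    the three states. For t < t_ref the probability of state S is the
    fraction of the cell's transported mass landing in S-cells at t_ref
    (ancestor construction); for t > t_ref the symmetric descendant
    construction applies; at t_ref probabilities are membership indicators.
    Cells with zero transported mass get NaN rows (reported, not imputed).
    Returns a tidy frame (cell, time_h, p_responsive, p_nonresponsive,
    p_other) whose defined rows sum to 1.
    """
    plans = sorted(plans, key=lambda pl: pl.t_source)
    times = sorted({pl.t_source for pl in plans} | {pl.t_target for pl in plans})
    if t_ref not in times:
        raise ValueError(f"t_ref={t_ref} not among plan time points {times}")
    ref_ids = reference_partition.index
    bad = set(reference_partition) - set(FATE_STATES)
    if bad:
        raise ValueError(f"unknown states in reference partition: {sorted(bad)}")
    state_masks = {s: (reference_partition == s).to_numpy() for s in FATE_STATES}

    frames = []
    for t in times:
        if t == t_ref:
            probs = np.column_stack([state_masks[s].astype(float)
                                     for s in FATE_STATES])
            cells = np.asarray(ref_ids, object)
        elif t < t_ref:
            gamma = _chain(plans, t, t_ref)
            if not np.array_equal(gamma.target_ids, np.asarray(ref_ids, object)):
                raise ValueError("reference partition ids do not match plan "
                                 f"targets at t_ref={t_ref}")
            tot = gamma.coupling.sum(axis=1)
            probs = np.column_stack(
                [gamma.coupling[:, state_masks[s]].sum(axis=1) for s in FATE_STATES])
            with np.errstate(invalid="ignore", divide="ignore"):
                probs = np.where(tot[:, None] > 0, probs / tot[:, None], np.nan)
            if (tot == 0).any():
                warnings.warn(f"{int((tot == 0).sum())} cells at t={t} have zero "
                              "transported mass; probabilities undefined",
                              stacklevel=2)
            cells = gamma.source_ids
        else:
            gamma = _chain(plans, t_ref, t)
            if not np.array_equal(gamma.source_ids, np.asarray(ref_ids, object)):
                raise ValueError("reference partition ids do not match plan "
                                 f"sources at t_ref={t_ref}")
            tot = gamma.coupling.sum(axis=0)
            probs = np.column_stack(
                [gamma.coupling[state_masks[s], :].sum(axis=0) for s in FATE_STATES])
            with np.errstate(invalid="ignore", divide="ignore"):
                probs = np.where(tot[:, None] > 0, probs / tot[:, None], np.nan)
            if (tot == 0).any():
                warnings.warn(f"{int((tot == 0).sum())} cells at t={t} receive "
                              "zero mass; probabilities undefined", stacklevel=2)
            cells = gamma.target_ids
        df = pd.DataFrame(probs, columns=list(FATE_COLUMNS))
        df.insert(0, "time_h", t)
        df.insert(0, "cell", cells)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def ancestor_distribution(plans, cell_set, t_ref: float,
                          t_query: float) -> pd.Series:
    """Pullback of the uniform distribution on ``cell_set`` to t_query.

    Columns of the composed coupling are normalized, averaged over the set,
    and renormalized to sum 1 over cells at t_query.
    """
    cell_set = list(cell_set)
    if not cell_set:
        raise ValueError("empty cell set")
    if not t_query < t_ref:
        raise ValueError("t_query must precede t_ref")
    gamma = _chain(plans, t_query, t_ref)
    idx = pd.Index(gamma.target_ids).get_indexer(cell_set)
    if (idx < 0).any():
        raise KeyError("cell_set contains ids absent at t_ref")
    P = gamma.coupling
    colsum = P.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Pc = np.where(colsum[None, :] > 0, P / colsum[None, :], 0.0)
    d = Pc[:, idx].mean(axis=1)
    total = d.sum()
    if total == 0:
        raise ValueError("no mass reaches the query time for this cell set")
    return pd.Series(d / total, index=pd.Index(gamma.source_ids, name="cell"),
                     name="ancestor_mass")
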