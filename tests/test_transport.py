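import numpy as np
import pandas as pd
import pytest

from cortexflow.io_preprocess import Embedding
from cortexflow.transport import (SinkhornParams, TransportPlan,
                                  ancestor_distribution, compose_plans,
                                  fate_probabilities, growth_weights,
                                  pairwise_cost, sinkhorn_unbalanced)


def _emb(coords, prefix="c"):
    coords = np.atleast_2d(np.asarray(coords, float))
    return Embedding(coords, np.array([f"{prefix}{i}"
                                       for i in range(len(coords))], object))


class TestPairwiseCost:
    def test_identical_points_zero(self):
        C = pairwise_cost(_emb([[1.0, 2.0]]), _emb([[1.0, 2.0]]))
        assert C.shape == (1, 1) and C[0, 0] == 0.0

    def test_raw_cost_on_line(self):
        C = pairwise_cost(_emb([[0.0]]), _emb([[3.0]]), normalize=False)
        assert C[0, 0] == 9.0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        A, B = rng.random((4, 3)), rng.random((3, 3))
        C = pairwise_cost(_emb(A), _emb(B), normalize=False)
        for i in range(4):
            for j in range(3):
                assert np.isclose(C[i, j], ((A[i] - B[j]) ** 2).sum())

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_cost(_emb([[1.0, 2.0]]), _emb([[1.0]]))


class TestGrowthWeights:
    def _meta(self, stages):
        return pd.DataFrame({"stage": stages},
                            index=[f"c{i}" for i in range(len(stages))])

    def test_uniform_when_rates_one(self):
        w = growth_weights(self._meta(["a", "b", "a"]), {"a": 1.0, "b": 1.0}, 2.0)
        assert np.allclose(w, 1 / 3)

    def test_two_stage_example(self):
        w = growth_weights(self._meta(["proliferation", "elongation"]),
                           {"proliferation": 2.0, "elongation": 1.0}, 1.0)
        assert np.allclose(w.to_numpy(), [2 / 3, 1 / 3])

    def test_power_in_dt(self, small_sim):
        cfg, cm, meta, gt = small_sim
        sub = meta[meta["time_h"] == 0.0]
        w = growth_weights(sub, cfg.growth_rate_by_stage, dt_h=0.5)
        expect = np.array([gt.true_growth[c] for c in sub.index]) ** 0.5
        assert np.allclose(w.to_numpy(), expect / expect.sum(), atol=1e-12)

    def test_missing_stage_raises(self):
        with pytest.raises(KeyError, match="elongation"):
            growth_weights(self._meta(["elongation"]), {"other": 1.0}, 1.0)


BAL = dict(lambda1=np.inf, lambda2=np.inf)


class TestSinkhorn:
    def test_one_by_one(self):
        pl = sinkhorn_unbalanced(np.array([[5.0]]), np.array([1.0]),
                                 np.array([1.0]),
                                 SinkhornParams(epsilon=0.7, **BAL))
        assert np.isclose(pl.coupling[0, 0], 1.0)

    def test_symmetric_instance_symmetric_plan(self):
        rng = np.random.default_rng(1)
        M = rng.random((6, 6))
        C = (M + M.T) / 2
        p = np.full(6, 1 / 6)
        pl = sinkhorn_unbalanced(C, p, p, SinkhornParams(
            epsilon=0.1, max_iter=20000, tol=1e-13, **BAL))
        assert np.abs(pl.coupling - pl.coupling.T).max() < 1e-8

    def test_dual_objective_monotone(self):
        rng = np.random.default_rng(2)
        C = rng.random((15, 15))
        p = rng.random(15); p /= p.sum()
        q = rng.random(15); q /= q.sum()
        pl = sinkhorn_unbalanced(C, p, q, SinkhornParams(
            epsilon=0.05, max_iter=50000, tol=1e-13, **BAL))
        assert all(b >= a - 1e-9 for a, b in zip(pl.trace, pl.trace[1:]))

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(3)
        C = rng.random((10, 10))
        p = np.full(10, 0.1)
        pl = sinkhorn_unbalanced(C, p, p, SinkhornParams(
            epsilon=0.001, max_iter=5, tol=1e-14, marginal_tol=1e-14, **BAL))
        assert not pl.converged and pl.marginal_error > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sinkhorn_unbalanced(np.array([[np.inf]]), np.array([1.0]),
                                np.array([1.0]), SinkhornParams())
        with pytest.raises(ValueError):
            sinkhorn_unbalanced(np.array([[1.0]]), np.array([0.0]),
                                np.array([1.0]), SinkhornParams())


def _plan(coupling, src, tgt, t0=0.0, t1=1.0):
    coupling = np.asarray(coupling, float)
    return TransportPlan(np.asarray(src, object), np.asarray(tgt, object),
                         coupling, coupling.sum(1), coupling.sum(0),
                         SinkhornParams(), True, 0.0, t0, t1)


class TestComposePlans:
    def test_single_plan_identity(self):
        pl = _plan(np.array([[0.2, 0.3], [0.1, 0.4]]), ["a", "b"], ["x", "y"])
        comp = compose_plans([pl])
        assert np.allclose(comp.coupling, pl.coupling)

    def test_identity_chain(self):
        eye = np.eye(3) / 3
        p1 = _plan(eye, list("abc"), list("xyz"), 0, 1)
        p2 = _plan(eye, list("xyz"), list("uvw"), 1, 2)
        comp = compose_plans([p1, p2])
        assert np.allclose(comp.coupling, eye)

    def test_matches_matrix_chain_oracle(self):
        rng = np.random.default_rng(4)
        A = rng.random((3, 3)); B = rng.random((3, 3))
        p1 = _plan(A, list("abc"), list("xyz"), 0, 1)
        p2 = _plan(B, list("xyz"), list("uvw"), 1, 2)
        comp = compose_plans([p1, p2])
        An = A / A.sum(1, keepdims=True)
        Bn = B / B.sum(1, keepdims=True)
        expect = np.diag(A.sum(1)) @ An @ Bn
        assert np.allclose(comp.coupling, expect)

    def test_id_mismatch_raises(self):
        p1 = _plan(np.eye(2), ["a", "b"], ["x", "y"], 0, 1)
        p2 = _plan(np.eye(2), ["w", "y"], ["u", "v"], 1, 2)
        with pytest.raises(ValueError, match="chain"):
            compose_plans([p1, p2])


class TestFateProbabilities:
    def _partition(self, states, ids):
        return pd.Series(states, index=pd.Index(ids))

    def test_reference_time_is_indicator(self):
        pl = _plan(np.full((3, 3), 1 / 9), list("abc"), list("xyz"), 0, 2)
        part = self._partition(["cortex-responsive", "cortex-nonresponsive",
                                "other"], list("xyz"))
        ft = fate_probabilities([pl], part, t_ref=2.0)
        ref = ft[ft["time_h"] == 2.0].set_index("cell")
        assert ref.loc["x"].tolist()[1:] == [1.0, 0.0, 0.0]
        assert ref.loc["y"].tolist()[1:] == [0.0, 1.0, 0.0]
        assert ref.loc["z"].tolist()[1:] == [0.0, 0.0, 1.0]

    def test_identity_plans_propagate_membership(self):
        eye = np.eye(3) / 3
        p1 = _plan(eye, list("abc"), list("xyz"), 0, 1)
        p2 = _plan(eye, list("xyz"), list("uvw"), 1, 2)
        part = self._partition(["cortex-responsive", "other", "other"],
                               list("uvw"))
        ft = fate_probabilities([p1, p2], part, t_ref=2.0)
        t0 = ft[ft["time_h"] == 0.0].set_index("cell")
        assert t0.loc["a", "p_responsive"] == 1.0
        assert t0.loc["b", "p_other"] == 1.0

    def test_hand_computed_two_time_fixture(self):
        coupling = np.array([[0.3, 0.1, 0.1],
                             [0.0, 0.2, 0.2],
                             [0.05, 0.0, 0.05]])
        pl = _plan(coupling, list("abc"), list("xyz"), 0, 2)
        part = self._partition(["cortex-responsive", "cortex-nonresponsive",
                                "other"], list("xyz"))
        ft = fate_probabilities([pl], part, t_ref=2.0)
        t0 = ft[ft["time_h"] == 0.0].set_index("cell")
        assert np.isclose(t0.loc["a", "p_responsive"], 0.3 / 0.5)
        assert np.isclose(t0.loc["b", "p_nonresponsive"], 0.2 / 0.4)
        assert np.isclose(t0.loc["c", "p_other"], 0.05 / 0.1)
        sums = t0[["p_responsive", "p_nonresponsive", "p_other"]].sum(1)
        assert np.allclose(sums, 1.0, atol=1e-8)

    def test_descendant_direction(self):
        coupling = np.array([[0.4, 0.1], [0.1, 0.4]])
        pl = _plan(coupling, ["r1", "o1"], ["d1", "d2"], 2, 4)
        part = self._partition(["cortex-responsive", "other"], ["r1", "o1"])
        ft = fate_probabilities([pl], part, t_ref=2.0)
        t4 = ft[ft["time_h"] == 4.0].set_index("cell")
        assert np.isclose(t4.loc["d1", "p_responsive"], 0.4 / 0.5)
        assert np.isclose(t4.loc["d2", "p_responsive"], 0.1 / 0.5)

    def test_zero_mass_cell_reported_missing(self):
        coupling = np.array([[0.5, 0.5], [0.0, 0.0]])
        pl = _plan(coupling, ["a", "b"], ["x", "y"], 0, 2)
        part = self._partition(["cortex-responsive", "other"], ["x", "y"])
        with pytest.warns(UserWarning, match="zero"):
            ft = fate_probabilities([pl], part, t_ref=2.0)
        t0 = ft[ft["time_h"] == 0.0].set_index("cell")
        assert np.isnan(t0.loc["b", "p_responsive"])


class TestAncestorDistribution:
    def test_conservation_full_set(self):
        rng = np.random.default_rng(5)
        p = rng.random(4); p /= p.sum()
        q = rng.random(4); q /= q.sum()
        pl = _plan(np.outer(p, q), list("abcd"), list("wxyz"), 0, 2)
        d = ancestor_distribution([pl], list("wxyz"), t_ref=2.0, t_query=0.0)
        assert np.allclose(d.to_numpy(), p)

    def test_singleton_identity_plan(self):
        pl = _plan(np.eye(3) / 3, list("abc"), list("xyz"), 0, 2)
        d = ancestor_distribution([pl], ["y"], t_ref=2.0, t_query=0.0)
        assert d["b"] == 1.0 and d["a"] == 0.0

    def test_hand_computed_pullback(self):
        coupling = np.array([[0.2, 0.2], [0.2, 0.4]])
        pl = _plan(coupling, ["a", "b"], ["x", "y"], 0, 2)
        d = ancestor_distribution([pl], ["x", "y"], t_ref=2.0, t_query=0.0)
        expect = np.array([0.5 * (0.2 / 0.4 + 0.2 / 0.6),
                           0.5 * (0.2 / 0.4 + 0.4 / 0.6)])
        assert np.allclose(d.to_numpy(), expect / expect.sum())

    def test_empty_set_raises(self):
        pl = _plan(np.eye(2) / 2, ["a", "b"], ["x", "y"], 0, 2)
        with pytest.raises(ValueError, match="empty"):
            ancestor_distribution([pl], [], t_ref=2.0, t_query=0.0)
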