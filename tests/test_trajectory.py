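import numpy as np
import pandas as pd
import pytest

from cortexflow.io_preprocess import CountMatrix, NormExpr
from cortexflow.trajectory import (barycentric_coordinates,
                                   diversity_pseudotime, expression_trends,
                                   stage_association_test, trajectory_de)


def _ft(triples, time_h=2.0):
    triples = np.atleast_2d(np.asarray(triples, float))
    return pd.DataFrame({
        "cell": [f"c{i}" for i in range(len(triples))],
        "time_h": time_h,
        "p_responsive": triples[:, 0],
        "p_nonresponsive": triples[:, 1],
        "p_other": triples[:, 2],
    })


class TestBarycentric:
    def test_vertices(self):
        xy = barycentric_coordinates(_ft([[1, 0, 0], [0, 1, 0], [0, 0, 1]]))
        assert np.allclose(xy[["x", "y"]].to_numpy(),
                           [[1.0, 0.0],                      # responsive: lower right
                            [0.0, 0.0],                      # non-responsive: lower left
                            [0.5, np.sqrt(3) / 2]])          # other: top

    def test_centroid_and_edge_midpoint(self):
        xy = barycentric_coordinates(_ft([[1 / 3, 1 / 3, 1 / 3],
                                          [0.5, 0.5, 0.0]]))
        assert np.allclose(xy.loc[0, ["x", "y"]].astype(float),
                           [0.5, np.sqrt(3) / 6])
        assert np.allclose(xy.loc[1, ["x", "y"]].astype(float), [0.5, 0.0])

    def test_affinity_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.dirichlet([1, 1, 1])
            b = rng.dirichlet([1, 1, 1])
            lam = rng.random()
            mix = lam * a + (1 - lam) * b
            xa = barycentric_coordinates(_ft([a]))[["x", "y"]].to_numpy()[0]
            xb = barycentric_coordinates(_ft([b]))[["x", "y"]].to_numpy()[0]
            xm = barycentric_coordinates(_ft([mix]))[["x", "y"]].to_numpy()[0]
            assert np.allclose(xm, lam * xa + (1 - lam) * xb, atol=1e-12)

    def test_non_simplex_raises(self):
        with pytest.raises(ValueError, match="sum to 1"):
            barycentric_coordinates(_ft([[0.5, 0.2, 0.1]]))


def _ne(X, cells=None):
    X = np.asarray(X, float)
    cells = cells or [f"c{i}" for i in range(X.shape[0])]
    return NormExpr(X, np.asarray(cells, object),
                    np.array([f"g{j}" for j in range(X.shape[1])], object))


class TestTrajectoryDE:
    def test_identical_weights_null(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 5))
        ft = _ft(np.tile([0.3, 0.3, 0.4], (20, 1)))
        res = trajectory_de(_ne(X), ft, 2.0, n_perm=200, seed=0)
        assert np.allclose(res["weighted_stat"], 0.0)
        assert (res["p_perm"] == 1.0).all()

    def test_stat_sign_flips_when_weights_swap(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 8))
        w = rng.dirichlet(np.ones(3), size=30)
        ft = _ft(w)
        swapped = _ft(w[:, [1, 0, 2]])
        r1 = trajectory_de(_ne(X), ft, 2.0, n_perm=200, seed=3)
        r2 = trajectory_de(_ne(X), swapped, 2.0, n_perm=200, seed=3)
        assert np.allclose(r1["weighted_stat"], -r2["weighted_stat"])
        assert np.allclose(r1["p_perm"], r2["p_perm"])

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(3)
        n = 120
        resp = np.zeros(n); resp[:60] = 1
        X = rng.normal(0, 1, size=(n, 40))
        X[:60, :5] += 2.0
        w = np.column_stack([resp, 1 - resp, np.zeros(n)])
        res = trajectory_de(_ne(X), _ft(w), 2.0, n_perm=500, seed=4)
        assert (res["fdr"][:5] < 0.05).all()
        assert (res["weighted_stat"][:5] > 0).all()

    def test_min_permutations_enforced(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="n_perm"):
            trajectory_de(_ne(X), _ft(np.tile([0.5, 0.5, 0], (5, 1))), 2.0,
                          n_perm=10)


class TestDiversityPseudotime:
    def _setup(self, counts, stages):
        n = counts.shape[0]
        cm = CountMatrix(counts, [f"c{i}" for i in range(n)],
                         [f"g{j}" for j in range(counts.shape[1])])
        meta = pd.DataFrame({"celltype": "cortex", "stage": stages},
                            index=cm.cell_ids)
        return cm, meta

    def test_identical_cells_mid_rank(self):
        cm, meta = self._setup(np.ones((4, 10), dtype=int), ["proliferation"] * 4)
        pt = diversity_pseudotime(cm, meta, "cortex")
        assert np.allclose(pt.to_numpy(), 0.5)

    def test_two_cell_anchoring(self):
        counts = np.zeros((2, 100), dtype=int)
        counts[0, :100] = 1       # proliferation cell: all genes detected
        counts[1, :10] = 1
        cm, meta = self._setup(counts, ["proliferation", "elongation"])
        pt = diversity_pseudotime(cm, meta, "cortex")
        assert pt.iloc[0] == 0.0 and pt.iloc[1] == 1.0

    def test_absent_lineage_raises(self):
        cm, meta = self._setup(np.ones((2, 4), dtype=int), ["proliferation"] * 2)
        with pytest.raises(ValueError, match="absent"):
            diversity_pseudotime(cm, meta, "stele")

    def test_uniform_scaling_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3, size=(40, 60))
        cm, meta = self._setup(counts, ["proliferation"] * 20 + ["elongation"] * 20)
        pt1 = diversity_pseudotime(cm, meta, "cortex", k_smooth=5)
        cm2 = CountMatrix(counts * 3, cm.cell_ids, cm.gene_ids)
        pt2 = diversity_pseudotime(cm2, meta, "cortex", k_smooth=5)
        # detected genes unchanged under uniform scaling of counts
        assert np.allclose(pt1.to_numpy(), pt2.to_numpy())

    def test_recovers_stage_order_on_synthetic_cortex(self, small_sim):
        import scipy.stats

        cfg, cm, meta, _ = small_sim
        bl = meta[meta["condition"] == "BL"]
        pt = diversity_pseudotime(cm.subset_cells(np.asarray(bl.index, object)),
                                  bl, "cortex")
        order = bl.loc[pt.index, "stage"].map({
            "proliferation": 0, "transition": 1, "elongation": 2,
            "differentiation": 3})
        rho = scipy.stats.spearmanr(pt.to_numpy(), order.to_numpy())[0]
        assert rho >= 0.7


class TestExpressionTrends:
    def test_constant_gene_zero_row(self):
        X = np.ones((30, 2))
        pt = pd.Series(np.linspace(0, 1, 30),
                       index=[f"c{i}" for i in range(30)])
        tr = expression_trends(_ne(X), pt, ["g0"], n_bins=5)
        assert np.allclose(tr.loc["g0"], 0.0)

    def test_step_gene_monotone(self):
        pt = pd.Series(np.linspace(0, 1, 40),
                       index=[f"c{i}" for i in range(40)])
        X = np.zeros((40, 1))
        X[pt.to_numpy() > 0.5, 0] = 1.0
        tr = expression_trends(_ne(X), pt, ["g0"], n_bins=8)
        assert (np.diff(tr.loc["g0"].to_numpy()) >= -1e-12).all()

    def test_three_bin_hand_computed(self):
        pt = pd.Series([0.1, 0.2, 0.5, 0.9],
                       index=[f"c{i}" for i in range(4)])
        X = np.array([[1.0], [3.0], [5.0], [7.0]])
        tr = expression_trends(_ne(X), pt, ["g0"], n_bins=3)
        means = np.array([2.0, 5.0, 7.0])       # bin means by hand
        expect = (means - means.mean()) / means.std()
        assert np.allclose(tr.loc["g0"].to_numpy(), expect)

    def test_absent_gene_warns(self):
        pt = pd.Series([0.0, 1.0], index=["c0", "c1"])
        with pytest.warns(UserWarning, match="skipped"):
            tr = expression_trends(_ne(np.ones((2, 1))), pt, ["g0", "nope"],
                                   n_bins=2)
        assert list(tr.index) == ["g0"]


class TestStageAssociation:
    def test_constant_gene_null(self):
        rng = np.random.default_rng(6)
        n = 60
        pt = pd.Series(np.linspace(0, 1, n), index=[f"c{i}" for i in range(n)])
        X = np.column_stack([np.full(n, 3.0), rng.normal(size=n)])
        res = stage_association_test(_ne(X), pt)
        assert res.loc[0, "p"] > 0.99

    def test_linear_gene_detected(self):
        rng = np.random.default_rng(7)
        n = 100
        pt = pd.Series(np.linspace(0, 1, n), index=[f"c{i}" for i in range(n)])
        X = np.column_stack([5 * pt.to_numpy() + rng.normal(0, 0.1, n),
                             rng.normal(size=n)])
        res = stage_association_test(_ne(X), pt)
        assert res.loc[0, "fdr"] < 0.05
        assert res.loc[1, "p"] > 0.01

    def test_null_gaussian_calibration(self):
        rng = np.random.default_rng(8)
        n = 200
        pt = pd.Series(rng.random(n), index=[f"c{i}" for i in range(n)])
        X = rng.normal(size=(n, 2000))
        res = stage_association_test(_ne(X), pt)
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_too_few_cells_raises(self):
        pt = pd.Series(np.linspace(0, 1, 5), index=[f"c{i}" for i in range(5)])
        with pytest.raises(ValueError):
            stage_association_test(_ne(np.ones((5, 2))), pt)
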