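from itertools import combinations

import numpy as np
import pytest
from scipy.stats import chi2

from helpers import chain_model, sample_gaussian
from symptomnet import (edge_count_test, edge_ratio_chi2, estimate_network,
                        global_strength, holm, nct, structure_statistic)
from symptomnet.comparison import nct_all
from symptomnet.residualize import ResidualMatrix


class TestGlobalStrength:
    def test_empty_and_path(self):
        assert global_strength(np.zeros((4, 4))) == 0.0
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        assert global_strength(W) == pytest.approx(1.0)

    def test_handshake_identity(self, rng):
        W = rng.uniform(-0.5, 0.5, (5, 5))
        W = np.triu(W, 1) + np.triu(W, 1).T
        assert global_strength(W) == pytest.approx(np.abs(W).sum() / 2)


class TestEdgeRatioChi2:
    def test_paper_count_worked_example(self):
        # 119/210 vs 1/210 nonzero edges: hand-evaluated Pearson chi-square
        stat, p, degen = edge_ratio_chi2(119, 1, 210)
        table = np.array([[119, 91], [1, 209]], float)
        expected = table.sum(axis=1)[:, None] * table.sum(axis=0) / table.sum()
        hand = ((table - expected) ** 2 / expected).sum()
        assert not degen
        assert stat == pytest.approx(hand)
        assert stat == pytest.approx(162.4, abs=0.5)
        assert p < 1e-15

    def test_identical_counts_give_p_one(self):
        stat, p, degen = edge_ratio_chi2(30, 30, 210)
        assert stat == 0.0 and p == 1.0 and not degen

    def test_degenerate_table_flagged(self):
        stat, p, degen = edge_ratio_chi2(0, 0, 210)
        assert degen and p == 1.0


class TestHolm:
    def test_hand_worked_step_down(self):
        raw = [0.01, 0.04, 0.03, 0.2, 0.5, 0.9]
        adj = holm(raw)
        np.testing.assert_allclose(adj, [0.06, 0.16, 0.15, 0.6, 1.0, 1.0], atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        raw = rng.uniform(0, 1, 10)
        adj = holm(raw)
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestEdgeCountTest:
    def test_pairwise_tables_and_holm(self, rng):
        K, _ = chain_model(5, 0.4)
        nets = {
            "A": estimate_network(sample_gaussian(K, 800, rng)),
            "B": estimate_network(sample_gaussian(K, 800, rng)),
            "C": estimate_network(rng.standard_normal((800, 5))),
        }
        res = edge_count_test(nets)
        assert res.possible_edges == 10
        assert len(res.table) == 3
        assert np.all(res.table["p_holm"] >= res.table["p_raw"] - 1e-15)
        assert np.all(res.table["p_holm"] <= 1.0)


class TestNCT:
    est = {"n_lambda": 20, "lambda_min_ratio": 0.05}

    def test_identical_datasets_give_p_one(self, rng):
        K, _ = chain_model(4, 0.35)
        X = sample_gaussian(K, 60, rng)
        res = nct(X, X.copy(), B=50, seed=1, estimator=self.est)
        assert res.strength_diff == 0.0
        assert res.structure_stat == 0.0
        assert res.p_strength == 1.0
        assert res.p_structure == 1.0

    def test_label_swap_symmetry(self, rng):
        K, _ = chain_model(4, 0.35)
        XA = sample_gaussian(K, 40, rng)
        XB = sample_gaussian(K, 25, rng)
        r1 = nct(XA, XB, B=80, seed=7, estimator=self.est)
        r2 = nct(XB, XA, B=80, seed=7, estimator=self.est)
        assert r1.p_strength == r2.p_strength
        assert r1.p_structure == r2.p_structure

    def test_p_values_never_zero(self, rng):
        XA = sample_gaussian(chain_model(3, 0.5)[0], 30, rng)
        XB = rng.standard_normal((30, 3))
        res = nct(XA, XB, B=20, seed=3, estimator=self.est)
        assert res.p_strength >= 1 / 21
        assert res.p_structure >= 1 / 21

    def test_matches_exhaustive_enumeration_on_tiny_sample(self, rng):
        # nA = nB = 3, p = 2: only C(6,3)=20 assignments exist; the sampled
        # permutation p-value must approach the exhaustively enumerated one
        XA = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0]])
        XB = np.array([[0.0, 2.0], [2.0, 1.0], [1.0, 1.5]])
        est = {"n_lambda": 10, "lambda_min_ratio": 0.1}

        def stats(A, B):
            na, nb = estimate_network(A, **est), estimate_network(B, **est)
            return (abs(global_strength(na) - global_strength(nb)),
                    structure_statistic(na, nb))

        obs = stats(XA, XB)
        pooled = np.vstack([XA, XB])
        ge = [0, 0]
        combos = list(combinations(range(6), 3))
        for c in combos:
            rest = [i for i in range(6) if i not in c]
            s = stats(pooled[list(c)], pooled[rest])
            for k in range(2):
                ge[k] += s[k] >= obs[k] - 1e-12
        exact = [g / len(combos) for g in ge]
        res = nct(XA, XB, B=600, seed=5, estimator=est)
        assert res.p_strength == pytest.approx(exact[0], abs=0.08)
        assert res.p_structure == pytest.approx(exact[1], abs=0.08)

    def test_power_exceeds_type_i_rate(self):
        # one group has an extra edge (partial 0.4): structure test should
        # reject far more often than alpha
        K1, _ = chain_model(6, 0.4)
        K0 = np.eye(6)
        rejections = 0
        reps = 12
        for s in range(reps):
            rng = np.random.default_rng(500 + s)
            XA = sample_gaussian(K1, 300, rng)
            XB = sample_gaussian(K0, 300, rng)
            res = nct(XA, XB, B=200, seed=s, estimator=self.est)
            rejections += res.p_structure <= 0.05
        assert rejections / reps > 0.5

    def test_nct_all_runs_holm_per_family(self, rng):
        K, _ = chain_model(3, 0.4)
        values = np.vstack([sample_gaussian(K, 30, rng) for _ in range(3)])
        resid = ResidualMatrix(values=values,
                               group=np.repeat(["A", "B", "C"], 30),
                               item_names=["i1", "i2", "i3"])
        df = nct_all(resid, B=30, seed=2, estimator=self.est)
        assert len(df) == 3
        assert np.all(df["p_strength_holm"] >= df["p_strength"] - 1e-15)
        assert np.all(df["p_structure_holm"] >= df["p_structure"] - 1e-15)
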