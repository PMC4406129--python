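"""Weighted assortativity, jackknife SE, and the permutation engine."""

import numpy as np
import pytest

from socsel import (
    AssociationNetwork,
    AssortativityUndefinedError,
    DataStreamPermutation,
    DegenerateGBIError,
    GroupByIndividual,
    assortativity_se,
    permute_datastream,
    weighted_assortativity,
)
from conftest import random_weighted_network


def brute_force_r(W, z):
    """Weighted Pearson correlation over the enumerated directed edges."""
    j, k, w = [], [], []
    n = len(z)
    for a in range(n):
        for b in range(n):
            if a != b and W[a, b] > 0:
                j.append(z[a])
                k.append(z[b])
                w.append(W[a, b])
    j, k, w = map(np.asarray, (j, k, w))
    Wt = w.sum()
    mj, mk = (w * j).sum() / Wt, (w * k).sum() / Wt
    cov = (w * (j - mj) * (k - mk)).sum() / Wt
    sj = np.sqrt((w * (j - mj) ** 2).sum() / Wt)
    sk = np.sqrt((w * (k - mk) ** 2).sum() / Wt)
    return cov / (sj * sk)


def net_from(W):
    W = W / max(W.max(), 1.0)
    return AssociationNetwork(W, [f"I{i}" for i in range(len(W))])


class TestWeightedAssortativity:
    def test_perfectly_assorted_components(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.9
        r = weighted_assortativity(net_from(W), np.array([1.0, 1.0, 2.0, 2.0]))
        assert r.r_hat == pytest.approx(1.0)

    def test_single_edge_disassorted(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.3
        r = weighted_assortativity(net_from(W), np.array([0.0, 1.0]))
        assert r.r_hat == pytest.approx(-1.0)

    def test_brute_force_oracle_random_networks(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            W = random_weighted_network(rng, n=30, density=0.2)
            z = rng.normal(size=30)
            net = net_from(W)
            expected = brute_force_r(net.toarray(), z)
            assert weighted_assortativity(net, z).r_hat == pytest.approx(expected, abs=1e-12)

    def test_affine_trait_invariance(self):
        rng = np.random.default_rng(2)
        W = random_weighted_network(rng, n=20)
        z = rng.normal(size=20)
        net = net_from(W)
        r1 = weighted_assortativity(net, z).r_hat
        r2 = weighted_assortativity(net, 3.5 * z - 7.0).r_hat
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        W = random_weighted_network(rng, n=20)
        W = W / W.max()
        z = rng.normal(size=20)
        roster = [f"I{i}" for i in range(20)]
        r1 = weighted_assortativity(AssociationNetwork(W, roster), z).r_hat
        r2 = weighted_assortativity(AssociationNetwork(0.2 * W, roster), z).r_hat
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_no_edges_undefined(self):
        net = AssociationNetwork(np.zeros((3, 3)), ["A", "B", "C"])
        with pytest.raises(AssortativityUndefinedError):
            weighted_assortativity(net, np.arange(3.0))

    def test_constant_endpoint_trait_undefined(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        with pytest.raises(AssortativityUndefinedError):
            weighted_assortativity(net_from(W), np.array([1.0, 1.0, 5.0]))


class TestJackknifeSE:
    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(6)
        W = random_weighted_network(rng, n=12, density=0.4)
        W = W / W.max()
        z = rng.normal(size=12)
        net = net_from(W)
        se = assortativity_se(net, z)
        i, j, w = net.edges()
        r_loo = []
        for e in range(len(w)):
            Wd = net.toarray().copy()
            Wd[i[e], j[e]] = Wd[j[e], i[e]] = 0.0
            r_loo.append(
                weighted_assortativity(
                    AssociationNetwork(Wd, net.roster), z
                ).r_hat
            )
        r_loo = np.asarray(r_loo)
        m = len(r_loo)
        expected = np.sqrt((m - 1) / m * ((r_loo - r_loo.mean()) ** 2).sum())
        assert se == pytest.approx(expected, abs=1e-10)

    def test_perfect_assortment_zero_se(self):
        W = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            W[a, b] = W[b, a] = 0.5
        z = np.array([1.0, 1.0, 1.0, 4.0, 4.0, 4.0])
        assert assortativity_se(net_from(W), z) == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_edges_shrink_se(self):
        # many interchangeable components -> leave-one-out barely moves r
        def dup_net(k):
            n = 2 * k
            W = np.zeros((n, n))
            z = np.empty(n)
            for c in range(k):
                W[2 * c, 2 * c + 1] = W[2 * c + 1, 2 * c] = 0.5
                z[2 * c], z[2 * c + 1] = (0.0, 1.0) if c % 2 else (1.0, 0.0)
            # one like-with-like edge among unlike pairs keeps |r| < 1
            W[0, 4] = W[4, 0] = 0.25
            return net_from(W), z

        net_small, z_small = dup_net(4)
        net_big, z_big = dup_net(24)
        assert assortativity_se(net_big, z_big) < assortativity_se(net_small, z_small)

    def test_fewer_than_two_edges_undefined(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.5
        with pytest.raises(AssortativityUndefinedError):
            assortativity_se(net_from(W), np.array([0.0, 1.0]))


class TestPermutationEngine:
    def _gbi(self, rng, n_ev=60, n_ind=25, p=0.2):
        X = (rng.random((n_ev, n_ind)) < p).astype(np.uint8)
        X = X[X.sum(axis=1) > 0]
        return GroupByIndividual(
            X, [f"e{i}" for i in range(len(X))], [f"I{j}" for j in range(n_ind)]
        )

    def test_every_swap_preserves_margins(self):
        rng = np.random.default_rng(1)
        gbi = self._gbi(rng)
        chain = DataStreamPermutation(gbi, rng=rng)
        rows0, cols0 = gbi.event_sizes(), gbi.observation_counts()
        for _ in range(2000):
            chain.step()
            assert (chain.matrix.sum(axis=1) == rows0).all()
            assert (chain.matrix.sum(axis=0) == cols0).all()

    def test_strata_respected(self):
        rng = np.random.default_rng(2)
        gbi = self._gbi(rng, n_ev=40)
        strata = np.array(["a", "b"] * (gbi.n_events // 2))
        chain = DataStreamPermutation(gbi, strata=strata, rng=rng)
        # per-stratum column counts are conserved when swaps stay in-stratum
        before = [chain.matrix[strata == s].sum(axis=0).copy() for s in ("a", "b")]
        for _ in range(500):
            chain.step()
        after = [chain.matrix[strata == s].sum(axis=0) for s in ("a", "b")]
        np.testing.assert_array_equal(before[0], after[0])
        np.testing.assert_array_equal(before[1], after[1])

    def test_degenerate_gbi_raises(self):
        # one event: no pair of events exists to swap between
        X = np.ones((1, 3), dtype=np.uint8)
        gbi = GroupByIndividual(X, ["e0"], ["A", "B", "C"])
        with pytest.raises(DegenerateGBIError):
            DataStreamPermutation(gbi, rng=np.random.default_rng(0), max_tries=200).step()

    def test_pvalue_add_one_bounds(self):
        rng = np.random.default_rng(3)
        gbi = self._gbi(rng)
        null = permute_datastream(
            gbi, lambda g: float(g.toarray()[0].sum()), n_perm=19, seed=0
        )
        assert 1 / 20 <= null.p_value <= 1.0
        assert len(null.statistic_values) == 19
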