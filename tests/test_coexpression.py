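import numpy as np
import pandas as pd
import pytest

from symbiopart.coexpression import (
    StrongPair, consensus_tom, correlation_matrix, detect_modules,
    shared_pairs, soft_adjacency, strong_pairs, topological_overlap,
)
from symbiopart.source_classifier import (
    FLAGELLATE, TERMITE, UNCLEAR, SourceCall,
)


def df(a, names=None):
    a = np.asarray(a, dtype=float)
    names = names or [f"n{i}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=names, columns=names)


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestCorrelation:
    def test_self_correlation_one_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        tmm = pd.DataFrame([x, 2 * x + 5, -x],
                           index=["a", "b", "c"],
                           columns=[f"s{i}" for i in range(10)])
        cor = correlation_matrix(tmm, transform="none")
        assert cor.loc["a", "a"] == pytest.approx(1.0)
        assert cor.loc["a", "b"] == pytest.approx(1.0)
        assert cor.loc["a", "c"] == pytest.approx(-1.0)

    def test_constant_transcript_flagged_zero(self):
        rng = np.random.default_rng(1)
        tmm = pd.DataFrame([rng.normal(size=8), np.full(8, 3.0)],
                           index=["a", "const"],
                           columns=[f"s{i}" for i in range(8)])
        cor = correlation_matrix(tmm, transform="none")
        assert cor.loc["a", "const"] == 0.0
        assert cor.loc["const", "const"] == 1.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, size=(10, 6))
        tmm = pd.DataFrame(x, index=[f"t{i}" for i in range(10)],
                           columns=[f"s{i}" for i in range(6)])
        cor = correlation_matrix(tmm, transform="log2p1").to_numpy()
        lx = np.log2(x + 1)
        for i in range(10):
            for j in range(10):
                xi, xj = lx[i] - lx[i].mean(), lx[j] - lx[j].mean()
                expected = np.sum(xi * xj) / np.sqrt(
                    np.sum(xi**2) * np.sum(xj**2))
                assert cor[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self):
        tmm = pd.DataFrame(np.ones((3, 2)), columns=["s1", "s2"])
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(tmm)


class TestAdjacency:
    def test_direct_exponentiation(self):
        cor = df([[1, 0.5], [0.5, 1]])
        a = soft_adjacency(cor, beta=12)
        assert a.iloc[0, 1] == pytest.approx(0.5**12)
        assert a.iloc[0, 0] == 0.0   # zero diagonal

    def test_beta_one_is_absolute_value(self):
        cor = df([[1, -0.7], [-0.7, 1]])
        assert soft_adjacency(cor, beta=1).iloc[0, 1] == pytest.approx(0.7)

    def test_increasing_beta_weakly_decreases_entries(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(-0.99, 0.99, size=(6, 6))
        cor = df(np.clip((c + c.T) / 2, -1, 1))
        np.fill_diagonal(cor.values, 1.0)
        a6 = soft_adjacency(cor, beta=6).to_numpy()
        a12 = soft_adjacency(cor, beta=12).to_numpy()
        assert (a12 <= a6 + 1e-15).all()

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            soft_adjacency(df([[1.0]]), beta=0)


class TestTom:
    def test_two_nodes_full_adjacency(self):
        tom = topological_overlap(df([[0, 1], [1, 0]]))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency(self):
        tom = topological_overlap(df(np.zeros((4, 4))))
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off == 0).all()
        assert (np.diag(tom) == 1.0).all()

    def test_matches_bruteforce_on_random_networks(self):
        rng = np.random.default_rng(4)
        for n in (3, 6, 8):
            a = rng.uniform(0, 1, size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = topological_overlap(df(a)).to_numpy()
            assert np.allclose(tom, tom_bruteforce(a), atol=1e-12)

    def test_tom_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            a = rng.uniform(0, 1, size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = topological_overlap(df(a)).to_numpy()
            assert (tom >= -1e-12).all() and (tom <= 1 + 1e-12).all()


class TestConsensus:
    def test_identical_inputs_returned_unchanged(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 0.9, size=(5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = df(a)
        cons = consensus_tom(tom, tom)
        assert np.allclose(cons.to_numpy(), a, atol=1e-12)

    def test_min_upper_bound(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 0.9, size=(6, 6))
        b = rng.uniform(0, 0.9, size=(6, 6))
        a, b = (a + a.T) / 2, (b + b.T) / 2
        np.fill_diagonal(a, 1.0)
        np.fill_diagonal(b, 1.0)
        cons = consensus_tom(df(a), df(b)).to_numpy()
        assert (cons <= a + 1e-12).all()

    def test_handworked_quantile_scaling(self):
        a = df([[1, .8, .2, .1], [.8, 1, .3, .2],
                [.2, .3, 1, .4], [.1, .2, .4, 1]])
        b = df([[1, .4, .1, .05], [.4, 1, .15, .1],
                [.1, .15, 1, .2], [.05, .1, .2, 1]])
        off = ~np.eye(4, dtype=bool)
        qa = np.quantile(a.to_numpy()[off], 0.95)
        qb = np.quantile(b.to_numpy()[off], 0.95)
        scaled_b = b.to_numpy() ** (np.log(qa) / np.log(qb))
        expected = np.minimum(a.to_numpy(), scaled_b)
        assert np.allclose(consensus_tom(a, b).to_numpy(), expected,
                           atol=1e-12)

    def test_mismatched_nodes_rejected(self):
        a = df(np.eye(3))
        b = df(np.eye(3), names=["x", "y", "z"])
        with pytest.raises(ValueError, match="node set"):
            consensus_tom(a, b)


class TestModules:
    def test_planted_blocks_recovered(self):
        n = 30
        tom = np.full((n, n), 0.002)
        tom[:15, :15] = 0.8
        tom[15:, 15:] = 0.8
        np.fill_diagonal(tom, 1.0)
        modules = detect_modules(df(tom), min_size=10)
        labels = modules.to_numpy()
        assert len(set(labels)) == 2 and 0 not in labels
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1

    def test_zero_tom_all_unassigned(self):
        tom = df(np.eye(12))
        assert (detect_modules(tom, min_size=10) == 0).all()

    def test_min_size_larger_than_n(self):
        tom = np.full((5, 5), 0.9)
        np.fill_diagonal(tom, 1.0)
        assert (detect_modules(df(tom), min_size=10) == 0).all()


def calls_for(nodes, sources, orders=None):
    orders = orders or {}
    return {n: SourceCall(n, s, order=orders.get(n))
            for n, s in zip(nodes, sources)}


class TestStrongPairs:
    def test_threshold_is_inclusive(self):
        tom = df([[1, 0.5], [0.5, 1]], names=["f", "t"])
        calls = calls_for(["f", "t"], [FLAGELLATE, TERMITE])
        pairs = strong_pairs(tom, calls)
        assert len(pairs) == 1 and pairs[0].weight == 0.5
        below = df([[1, 0.4999], [0.4999, 1]], names=["f", "t"])
        assert strong_pairs(below, calls) == []

    def test_no_flagellate_calls_gives_empty_list(self):
        tom = df(np.full((3, 3), 0.9), names=["a", "b", "c"])
        calls = calls_for(["a", "b", "c"], [TERMITE, UNCLEAR, TERMITE])
        assert strong_pairs(tom, calls) == []

    def test_order_resolved_flagellate_pairs_excluded(self):
        tom = df(np.full((2, 2), 0.9), names=["f1", "f2"])
        both = calls_for(["f1", "f2"], [FLAGELLATE, FLAGELLATE],
                         orders={"f1": 101, "f2": 102})
        assert strong_pairs(tom, both) == []
        one = calls_for(["f1", "f2"], [FLAGELLATE, FLAGELLATE],
                        orders={"f1": 101})
        pairs = strong_pairs(tom, one)
        assert len(pairs) == 1
        assert pairs[0].flagellate == "f1"
        assert pairs[0].partner_class == "flagellate-unclassified"

    def test_node_permutation_leaves_pair_set_unchanged(self):
        rng = np.random.default_rng(8)
        n = 8
        t = rng.uniform(0, 1, size=(n, n))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 1.0)
        names = [f"n{i}" for i in range(n)]
        calls = calls_for(names, [FLAGELLATE] * 3 + [TERMITE] * 5)
        tom = df(t, names=names)
        base = {p.key for p in strong_pairs(tom, calls, threshold=0.6)}
        perm = rng.permutation(n)
        tom_p = tom.iloc[perm, perm]
        assert {p.key for p in strong_pairs(tom_p, calls, 0.6)} == base

    def test_shared_pairs_is_key_intersection(self):
        p1 = StrongPair("f1", "t1", "termite", 0.8)
        p2 = StrongPair("f1", "t2", "termite", 0.7)
        p3 = StrongPair("f1", "t1", "termite", 0.6)
        shared = shared_pairs([p1, p2], [p3])
        assert [p.key for p in shared] == [("f1", "t1")]
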