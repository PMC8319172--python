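import networkx as nx
import numpy as np
import pytest

from neuroperc._fit import fit_saturating_exponential
from neuroperc.allometry import (
    RootedTree,
    allometric_exponent,
    exponent_by_root,
    exponent_for_root,
    rank_decay_fit,
    root_tree,
    subtree_metrics,
)
from neuroperc.errors import DataError, FitError
from neuroperc.trees import SpanningTree


def chain_tree(n):
    return SpanningTree(edges=[(i, i + 1, 1.0) for i in range(n - 1)], n_nodes=n)


def star_tree(n):
    return SpanningTree(edges=[(0, i, 1.0) for i in range(1, n)], n_nodes=n)


def chain_rooted(n):
    return RootedTree(root=0, parent=np.arange(-1, n - 1), order=np.arange(n))


def star_rooted(n):
    parent = np.zeros(n, dtype=np.int64)
    parent[0] = -1
    return RootedTree(root=0, parent=parent, order=np.arange(n))


def random_tree(n, seed):
    t = nx.random_labeled_tree(n, seed=seed)
    rng = np.random.default_rng(seed)
    return SpanningTree(
        edges=[(u, v, float(rng.uniform(0.1, 1))) for u, v in t.edges], n_nodes=n
    )


class TestRooting:
    def test_chain_rooted_at_end(self):
        rt = root_tree(chain_tree(3), 0)
        assert rt.parent[1] == 0 and rt.parent[2] == 1 and rt.parent[0] == -1

    def test_chain_rooted_at_middle(self):
        rt = root_tree(chain_tree(3), 1)
        assert sorted(rt.children_of()[1]) == [0, 2]

    def test_parent_count(self):
        tree = random_tree(20, 3)
        rt = root_tree(tree, 5)
        assert np.sum(rt.parent == -1) == 1
        assert rt.parent[5] == -1

    def test_unknown_root(self):
        with pytest.raises(DataError, match="root"):
            root_tree(chain_tree(3), 7)


class TestSubtreeMetrics:
    def test_single_edge(self):
        a, c = subtree_metrics(chain_rooted(2))
        assert list(a) == [2, 1] and list(c) == [3, 1]

    def test_chain_of_three(self):
        a, c = subtree_metrics(chain_rooted(3))
        assert list(a) == [3, 2, 1]
        assert list(c) == [6, 3, 1]

    def test_star_hub_and_leaves(self):
        a, c = subtree_metrics(star_rooted(4))
        assert a[0] == 4 and c[0] == 7  # C_hub = 2N - 1
        assert np.all(a[1:] == 1) and np.all(c[1:] == 1)

    def test_identities_on_random_trees(self):
        for seed in range(20):
            tree = random_tree(30, seed)
            rt = root_tree(tree, int(np.random.default_rng(seed).integers(30)))
            a, c = subtree_metrics(rt)
            assert a[rt.root] == 30
            assert c[rt.root] == a.sum()
            assert np.all(a <= c) and np.all(c <= a**2)

    def test_against_descendant_enumeration(self):
        for seed in range(10):
            tree = random_tree(25, seed)
            rt = root_tree(tree, 0)
            a, c = subtree_metrics(rt)
            children = rt.children_of()
            for i in range(25):
                # brute force: collect the full subtree of i
                sub, stack = [], [i]
                while stack:
                    u = stack.pop()
                    sub.append(u)
                    stack.extend(children[u])
                assert a[i] == len(sub)
                assert c[i] == sum(a[k] for k in sub)

    def test_orientation_scheme_irrelevant(self):
        # DFS orientation gives the same (A, C) as BFS
        tree = random_tree(20, 11)
        rt_bfs = root_tree(tree, 4)
        adj = tree.adjacency()
        parent = np.full(20, -1, dtype=np.int64)
        order, stack, seen = [], [4], {4}
        while stack:
            u = stack.pop()
            order.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    stack.append(v)
        rt_dfs = RootedTree(root=4, parent=parent, order=np.array(order))
        a1, c1 = subtree_metrics(rt_bfs)
        a2, c2 = subtree_metrics(rt_dfs)
        assert np.array_equal(a1, a2) and np.array_equal(c1, c2)


class TestAllometricExponent:
    def test_exact_power_law(self):
        a = np.arange(1, 20, dtype=float)
        c = a**1.5
        for mode in ("intercept", "origin"):
            eta, err = allometric_exponent(a, c, mode)
            assert eta == pytest.approx(1.5, abs=1e-12)

    def test_chain_limit(self):
        a, c = subtree_metrics(chain_rooted(1000))
        eta, _ = allometric_exponent(a, c, "intercept")
        assert eta == pytest.approx(2.0, abs=0.05)

    def test_star_through_origin_closed_form(self):
        for n in (100, 1000):
            a, c = subtree_metrics(star_rooted(n))
            eta, _ = allometric_exponent(a, c, "origin")
            assert eta == pytest.approx(np.log(2 * n - 1) / np.log(n), abs=1e-12)

    def test_chain_and_star_monotone_limits(self):
        chain_etas, star_etas = [], []
        for n in (100, 1000, 10000):
            a, c = subtree_metrics(chain_rooted(n))
            chain_etas.append(allometric_exponent(a, c, "intercept")[0])
            a, c = subtree_metrics(star_rooted(n))
            star_etas.append(allometric_exponent(a, c, "intercept")[0])
        assert np.all(np.diff(chain_etas) > 0)  # toward 2
        assert np.all(np.diff(star_etas) < 0)  # toward 1

    def test_degenerate_input(self):
        with pytest.raises(FitError):
            allometric_exponent([1.0, 1.0], [1.0, 1.0])


class TestExponentByRoot:
    def test_fast_path_matches_naive(self):
        for seed in range(15):
            tree = random_tree(24, seed)
            for mode in ("intercept", "origin"):
                fast = exponent_by_root(tree, mode)
                naive = [exponent_for_root(tree, r, mode) for r in range(24)]
                assert np.allclose(fast, naive, atol=1e-9)

    def test_chain_end_vs_center(self):
        tree = chain_tree(51)
        etas = exponent_by_root(tree)
        assert etas[0] > etas[25]
        assert etas[0] == pytest.approx(etas[50])

    def test_star_leaf_symmetry(self):
        etas = exponent_by_root(star_tree(30))
        assert np.allclose(etas[1:], etas[1])

    def test_through_origin_bounds(self):
        for seed in range(30):
            etas = exponent_by_root(random_tree(40, seed), "origin")
            assert np.all(etas >= 1.0) and np.all(etas <= 2.0)

    def test_intercept_mode_near_bounds(self):
        # empirically eta stays within [1 - eps, 2 + eps] for random trees
        for seed in range(50):
            etas = exponent_by_root(random_tree(50, seed), "intercept")
            assert np.all(etas >= 0.95) and np.all(etas <= 2.05)


class TestRankDecay:
    def test_fit_self_consistency(self):
        ranks = np.arange(1, 5)
        eta = (1.5 - 1.1) * np.exp(-ranks / 0.7) + 1.1
        eta0, eta_inf, sr, _ = fit_saturating_exponential(ranks, eta)
        assert eta0 == pytest.approx(1.5, abs=1e-6)
        assert eta_inf == pytest.approx(1.1, abs=1e-6)
        assert sr == pytest.approx(0.7, abs=1e-6)

    def test_identical_subjects_zero_ci(self):
        ex = np.tile(np.array([[1.5, 1.4, 1.3, 1.25]])[:, :, None], (3, 1, 10))
        fit = rank_decay_fit(ex)
        assert np.allclose(fit.eta_ci_halfwidth, 0.0)
        assert np.allclose(fit.eta_mean, [1.5, 1.4, 1.3, 1.25])

    def test_too_few_ranks(self):
        with pytest.raises(FitError):
            fit_saturating_exponential([1, 2], [1.5, 1.4])
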