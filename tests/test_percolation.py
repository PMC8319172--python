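import numpy as np
import pytest

from neuroperc.errors import DataError, DisconnectedGraphError
from neuroperc.networks import WeightedBrainGraph
from neuroperc.percolation import (
    auc_reduction_analysis,
    compare_dvc_distributions,
    degree_variation_coefficient,
    group_average_curve,
    percolation_profile,
    reduction_thresholds,
)
from neuroperc._fit import fit_exponential_decay

from conftest import random_weighted_graph


def graph_from(weights, labels=None):
    w = np.asarray(weights, dtype=float)
    return WeightedBrainGraph(
        weights=w, node_labels=labels or [f"n{i}" for i in range(w.shape[0])]
    )


def flood_fill_components(n, edges):
    """Independent BFS oracle: component node sets of an edge list."""
    adj = {i: [] for i in range(n)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u])
        seen |= comp
        comps.append(comp)
    return comps


class TestPercolationProfile:
    def test_triangle_by_hand(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.8
        w[1, 2] = w[2, 1] = 0.9
        p = percolation_profile(graph_from(w))
        assert list(p.thresholds) == [0.5, 0.8, 0.9]
        assert list(p.n_components) == [1, 2, 3]
        assert list(p.gc_size) == [3, 2, 1]

    def test_final_state_fully_disconnected(self, make_graph):
        g = make_graph(9)
        p = percolation_profile(g)
        assert p.n_components[-1] == 9
        assert p.gc_size[-1] == 1

    def test_monotone_trajectories(self, make_graph):
        for _ in range(5):
            p = percolation_profile(make_graph(10))
            assert np.all(np.diff(p.n_components) >= 0)
            assert np.all(np.diff(p.gc_size) <= 0)

    def test_against_flood_fill_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            g = random_weighted_graph(rng, n)
            p = percolation_profile(g)
            iu = np.triu_indices(n, 1)
            edges = sorted(zip(g.weights[iu], iu[0], iu[1]))
            for k in range(1, len(edges) + 1):
                surviving = [(u, v) for _, u, v in edges[k:]]
                comps = flood_fill_components(n, surviving)
                assert p.n_components[k - 1] == len(comps)
                assert p.gc_size[k - 1] == max(len(c) for c in comps)
                assert sum(len(c) for c in comps) == n

    def test_degree_track_sum_is_twice_surviving_edges(self, make_graph):
        g = make_graph(8)
        p = percolation_profile(g)
        iu = np.triu_indices(8, 1)
        w = g.weights[iu]
        for j in (0, 50, 150, 200):
            t = p.degree_grid[j]
            assert p.degree_tracks[:, j].sum() == 2 * np.sum(w > t)

    def test_step_function_evaluation(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.8
        w[1, 2] = w[2, 1] = 0.9
        p = percolation_profile(graph_from(w))
        assert p.components_at(0.4) == 1
        assert p.components_at(0.5) == 1  # removing 0.5 leaves path 1-2-0
        assert p.components_at(0.8) == 2
        assert p.components_at(1.0) == 3
        assert p.gc_at(0.0) == 3 and p.gc_at(1.0) == 1

    def test_disconnected_input_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        with pytest.raises(DisconnectedGraphError):
            percolation_profile(graph_from(w))


class TestGroupAverageCurve:
    def test_identical_profiles_zero_width(self, make_graph):
        g = make_graph(7)
        ps = [percolation_profile(g), percolation_profile(g)]
        grid, mean, lo, hi = group_average_curve(ps)
        assert np.allclose(lo, mean) and np.allclose(hi, mean)

    def test_hand_computed_ci(self, make_graph):
        # component counts 1 and 3 at one grid point: mean 2, CI 2 +/- 1.96
        a = percolation_profile(make_graph(6))
        import copy

        b = copy.deepcopy(a)
        b.n_components = np.full_like(b.n_components, 3)
        a.n_components = np.ones_like(a.n_components)
        grid = np.array([a.thresholds[2]])
        _, mean, lo, hi = group_average_curve([a, b], grid)
        assert mean[0] == pytest.approx(2.0)
        assert hi[0] - mean[0] == pytest.approx(1.96 * np.sqrt(2) / np.sqrt(2))

    def test_mean_curve_monotone(self, make_graph):
        ps = [percolation_profile(make_graph(8)) for _ in range(4)]
        _, mean, _, _ = group_average_curve(ps)
        assert np.all(np.diff(mean) >= -1e-12)


class TestReduction:
    def path_profile(self):
        # path 0-1-2-3-4-5 with ascending weights: gc shrinks one node at a time
        n = 6
        w = np.zeros((n, n))
        for i, wt in enumerate([0.1, 0.2, 0.3, 0.4, 0.5]):
            w[i, i + 1] = w[i + 1, i] = wt
        return percolation_profile(graph_from(w))

    def test_hand_built_profile(self):
        p = self.path_profile()
        # after removing 0.1, gc = 5; 0.2 -> 4; ...
        assert list(p.gc_size) == [5, 4, 3, 2, 1]
        t = reduction_thresholds(p, [0.2, 0.5])
        # ceil(0.8*6)=5 -> first t with gc<=5 is 0.1; ceil(0.5*6)=3 -> 0.3
        assert t[0] == pytest.approx(0.1)
        assert t[1] == pytest.approx(0.3)

    def test_thresholds_sorted(self, make_graph):
        p = percolation_profile(make_graph(10))
        t = reduction_thresholds(p, np.arange(0.05, 0.51, 0.05))
        assert np.all(np.diff(t) >= 0)

    def test_invalid_fraction(self):
        with pytest.raises(DataError, match="fractions"):
            reduction_thresholds(self.path_profile(), [1.5])

    def test_degenerate_cohort_auc_equals_thresholds(self):
        p = self.path_profile()
        red = auc_reduction_analysis([p, p, p], [0.2, 0.4, 0.5])
        t = reduction_thresholds(p, [0.2, 0.4, 0.5])
        assert np.allclose(red.auc_per_fraction, t)
        assert red.auc_max_gc == pytest.approx(p.first_split_threshold())

    def test_sod_fit_self_consistency(self):
        k = np.arange(1, 11, dtype=float)
        y = 0.5 * np.exp(-k / 4.0)
        a, sod, _, _ = fit_exponential_decay(k, y)
        assert a == pytest.approx(0.5, abs=1e-6)
        assert sod == pytest.approx(4.0, abs=1e-6)


class TestDegreeVariation:
    def test_formula_on_known_tracks(self):
        p = percolation_profile(graph_from(np.array([[0, 0.5], [0.5, 0]])))
        p.degree_tracks = np.array([[3, 2, 1, 0], [3, 3, 0, 0]])
        p.degree_grid = np.arange(4.0)
        dvc = degree_variation_coefficient(p)
        assert dvc[0] == pytest.approx(np.sqrt(3))
        assert dvc[1] == pytest.approx(3.0)  # abrupt loss scores higher

    def test_zero_iff_constant(self, make_graph):
        p = percolation_profile(make_graph(7))
        dvc = degree_variation_coefficient(p)
        constant = np.all(np.diff(p.degree_tracks, axis=1) == 0, axis=1)
        assert np.all((dvc == 0) == constant)
        assert np.all(dvc >= 0)

    def test_single_point_grid_rejected(self, make_graph):
        p = percolation_profile(make_graph(5))
        p.degree_grid = p.degree_grid[:1]
        with pytest.raises(DataError, match="single threshold"):
            degree_variation_coefficient(p)

    def test_self_comparison_is_null(self, tiny_spec):
        from neuroperc.synthetic import generate_cohort

        cohort = generate_cohort(tiny_spec, "control-like")
        res = compare_dvc_distributions(cohort, cohort)
        assert res.mww.p == pytest.approx(1.0)
        assert res.mww.Z == pytest.approx(0.0)
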