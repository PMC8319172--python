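"""Allometric scaling of rooted spanning trees.

Rooting an undirected tree at a node orients every edge away from the root.
For each node i of the rooted tree two masses are defined:

* ``A_i`` - the number of nodes of the subtree rooted at i (including i);
* ``C_i`` - the sum of ``A_k`` over all nodes k of that subtree.

Across transport-like trees these obey an approximate power law C ~ A**eta.
The exponent eta measures global tree shape: eta -> 1 for a star, eta = 2
for a one-dimensional chain, and for any tree the through-origin log-log
slope is provably confined to [1, 2] because A <= C <= A**2 node-wise.

``exponent_by_root`` evaluates the fitted exponent for every choice of root
in O(n) total per tree via a re-rooting sweep: A and C for a node depend
only on which of its neighbours lies toward the root, so all per-root
regression sums differ between adjacent roots by a single edge flip.

``group_rank_profile`` averages exponents over roots within subject, then
over subjects per spanning-tree rank, and fits the saturating exponential
``eta(rank) = (eta0 - eta_inf) * exp(-rank / SR) + eta_inf`` whose decay
constant SR ("speed of reduction") summarises how fast successive
edge-disjoint backbones lose chain-like structure.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from ._fit import fit_saturating_exponential
from .errors import DataError, FitError
from .networks import Cohort
from .trees import SpanningTree, ranked_msts

FIT_MODES = ("intercept", "origin")


@dataclass
class RootedTree:
    """A tree oriented away from one root.

    ``parent[v]`` is v's parent (-1 at the root); ``order`` lists nodes in an
    orientation-consistent traversal (every parent precedes its children).
    """

    root: int
    parent: np.ndarray
    order: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def children_of(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in self.order[1:]:
            ch[self.parent[v]].append(int(v))
        return ch


def root_tree(tree: SpanningTree, root: int) -> RootedTree:
    """Orient a spanning tree away from ``root`` by breadth-first traversal."""
    n = tree.n_nodes
    if not 0 <= root < n:
        raise DataError(f"root {root} is not a node of a {n}-node tree")
    adj = tree.adjacency()
    parent = np.full(n, -1, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    seen = np.zeros(n, dtype=bool)
    seen[root] = True
    queue = deque([root])
    k = 0
    while queue:
        u = queue.popleft()
        order[k] = u
        k += 1
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                queue.append(v)
    if k != n:  # pragma: no cover - SpanningTree is connected by construction
        raise DataError("tree is not connected")
    return RootedTree(root=root, parent=parent, order=order)


def subtree_metrics(rtree: RootedTree) -> tuple[np.ndarray, np.ndarray]:
    """Subtree node counts A and cumulative masses C, one post-order pass.

    ``A[i] = 1 + sum_children A``; ``C[i] = A[i] + sum_children C``.
    Invariants (asserted): A[root] = n, C[root] = sum_i A[i], and
    A <= C <= A**2 node-wise.
    """
    n = rtree.n_nodes
    parent = rtree.parent
    a = np.ones(n, dtype=np.int64)
    for v in rtree.order[:0:-1]:
        a[parent[v]] += a[v]
    c = a.copy()
    for v in rtree.order[:0:-1]:
        c[parent[v]] += c[v]
    assert a[rtree.root] == n
    assert c[rtree.root] == a.sum()
    assert np.all(a <= c) and np.all(c <= a.astype(np.int64) ** 2)
    return a, c


def allometric_exponent(a, c, fit_mode: str = "intercept") -> tuple[float, float]:
    """Least-squares exponent of C ~ A**eta over all nodes of one rooted tree.

    ``intercept`` (default) fits slope and intercept of log C on log A,
    allowing a proportionality constant; ``origin`` forces the line through
    the origin, which confines the slope to [1, 2] on any tree.  Leaves sit
    at (0, 0) and are legitimate data points under both modes.

    Returns ``(eta, stderr)``.
    """
    if fit_mode not in FIT_MODES:
        raise DataError(f"fit_mode must be one of {FIT_MODES}, got {fit_mode!r}")
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    n = a.size
    if n < 3:
        raise FitError("allometric fit needs at least 3 nodes")
    x = np.log(a)
    y = np.log(c)
    sxx0 = float((x * x).sum())
    if sxx0 == 0.0:
        raise FitError("degenerate allometric fit: all subtree sizes are 1")
    if fit_mode == "origin":
        slope = float((x * y).sum() / sxx0)
        resid = y - slope * x
        var = float((resid**2).sum()) / max(n - 1, 1)
        return slope, float(np.sqrt(var / sxx0))
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise FitError("degenerate allometric fit: no spread in subtree sizes")
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    resid = y - ym - slope * (x - xm)
    var = float((resid**2).sum()) / max(n - 2, 1)
    return slope, float(np.sqrt(var / sxx))


def exponent_for_root(tree: SpanningTree, root: int, fit_mode: str = "intercept") -> float:
    """Exponent for a single root (convenience composition)."""
    a, c = subtree_metrics(root_tree(tree, root))
    return allometric_exponent(a, c, fit_mode)[0]


def exponent_by_root(tree: SpanningTree, fit_mode: str = "intercept") -> np.ndarray:
    """Fitted exponent for every node of the tree used as root.

    Equivalent to ``[exponent_for_root(tree, r) for r in range(n)]`` but runs
    in O(n) per tree.  For root r the regression data are the (log A, log C)
    pairs of the n-1 edges oriented away from r plus the root's own point
    (log n, log C_root); moving the root to a neighbour flips exactly one
    edge orientation, so all regression sums are updated in O(1) per step.
    """
    if fit_mode not in FIT_MODES:
        raise DataError(f"fit_mode must be one of {FIT_MODES}, got {fit_mode!r}")
    n = tree.n_nodes
    if n < 3:
        raise FitError("allometric fit needs at least 3 nodes")
    rt = root_tree(tree, 0)
    parent = rt.parent
    order = rt.order

    # downward masses: subtree below each node when rooted at 0
    a_down = np.ones(n, dtype=np.int64)
    for v in order[:0:-1]:
        a_down[parent[v]] += a_down[v]
    c_down = a_down.copy()
    for v in order[:0:-1]:
        c_down[parent[v]] += c_down[v]

    # complement masses: for v != 0, the subtree on the parent side of the
    # edge (v, parent[v]), i.e. the whole tree minus v's branch
    childsum_c = np.zeros(n, dtype=np.int64)
    for v in order[1:]:
        childsum_c[parent[v]] += c_down[v]
    a_comp = np.ones(n, dtype=np.int64)  # index 0 (the seed root) is never read
    c_comp = np.ones(n, dtype=np.int64)
    for v in order[1:]:
        u = parent[v]
        a_comp[v] = n - a_down[v]
        extra = childsum_c[u] - c_down[v]
        if u != 0:
            extra += c_comp[u]
        c_comp[v] = a_comp[v] + extra

    # per-edge regression contributions, both orientations
    with np.errstate(divide="ignore", invalid="ignore"):
        lx_d = np.log(a_down.astype(float))
        ly_d = np.log(c_down.astype(float))
        lx_c = np.log(a_comp.astype(float))
        ly_c = np.log(c_comp.astype(float))

    def sums(idx_x, idx_y, mask):
        x = idx_x[mask]
        y = idx_y[mask]
        return np.array([x.sum(), y.sum(), (x * x).sum(), (x * y).sum(), (y * y).sum()])

    nonroot = np.ones(n, dtype=bool)
    nonroot[0] = False
    # sums over the n-1 edges oriented away from root 0 (the "down" values)
    s = np.zeros((n, 5))
    sa = np.zeros(n)  # raw sum of A over away-edges (for C_root)
    s[0] = sums(lx_d, ly_d, nonroot)
    sa[0] = float(a_down[nonroot].sum())
    d_vec = np.stack([lx_d, ly_d, lx_d * lx_d, lx_d * ly_d, ly_d * ly_d], axis=1)
    c_vec = np.stack([lx_c, ly_c, lx_c * lx_c, lx_c * ly_c, ly_c * ly_c], axis=1)
    for v in order[1:]:
        u = parent[v]
        s[v] = s[u] - d_vec[v] + c_vec[v]
        sa[v] = sa[u] - a_down[v] + a_comp[v]

    # add each root's own data point (log n, log C_root)
    c_root = n + sa
    rx = np.full(n, np.log(float(n)))
    ry = np.log(c_root)
    sx = s[:, 0] + rx
    sy = s[:, 1] + ry
    sxx = s[:, 2] + rx * rx
    sxy = s[:, 3] + rx * ry

    if fit_mode == "origin":
        return sxy / sxx
    denom = n * sxx - sx * sx
    return (n * sxy - sx * sy) / denom


def rank_exponents(
    cohort: Cohort, n_ranks: int = 4, fit_mode: str = "intercept"
) -> np.ndarray:
    """Per-subject, per-rank, per-root exponents for a whole cohort.

    Returns an array of shape (n_subjects, n_ranks, n_nodes).
    """
    out = np.empty((cohort.n_subjects, n_ranks, cohort.n_nodes))
    for si, graph in enumerate(cohort.graphs):
        for ri, tree in enumerate(ranked_msts(graph, n_ranks)):
            out[si, ri] = exponent_by_root(tree, fit_mode=fit_mode)
    return out


@dataclass
class RankDecayFit:
    """Decay of the mean allometric exponent across spanning-tree ranks."""

    ranks: np.ndarray
    eta_mean: np.ndarray
    eta_ci_halfwidth: np.ndarray
    eta0: float
    eta_inf: float
    sr: float
    sr_stderr: float

    def to_dict(self) -> dict:
        return {
            "ranks": [int(r) for r in self.ranks],
            "eta_mean": [float(e) for e in self.eta_mean],
            "eta_ci_halfwidth": [float(e) for e in self.eta_ci_halfwidth],
            "eta0": float(self.eta0),
            "eta_inf": float(self.eta_inf),
            "sr": float(self.sr),
            "sr_stderr": float(self.sr_stderr),
        }


def rank_decay_fit(exponents: np.ndarray) -> RankDecayFit:
    """Fit the rank decay from a (n_subjects, n_ranks, n_roots) array.

    Exponents are averaged over roots within subject, then over subjects per
    rank (95% CI: mean +/- 1.96 * SE over subjects); the per-rank means are
    fitted to the saturating exponential.
    """
    per_subject = exponents.mean(axis=2)  # roots first
    n_subj, n_ranks = per_subject.shape
    mean = per_subject.mean(axis=0)
    if n_subj > 1:
        se = per_subject.std(axis=0, ddof=1) / np.sqrt(n_subj)
    else:
        se = np.zeros(n_ranks)
    ranks = np.arange(1, n_ranks + 1)
    eta0, eta_inf, sr, sr_err = fit_saturating_exponential(ranks, mean)
    return RankDecayFit(
        ranks=ranks, eta_mean=mean, eta_ci_halfwidth=1.96 * se,
        eta0=eta0, eta_inf=eta_inf, sr=sr, sr_stderr=sr_err,
    )


def group_rank_profile(
    cohorts: list[Cohort], n_ranks: int = 4, fit_mode: str = "intercept"
) -> dict[str, RankDecayFit]:
    """Rank-decay fit of the mean allometric exponent for each cohort."""
    out: dict[str, RankDecayFit] = {}
    for cohort in cohorts:
        out[cohort.group_label] = rank_decay_fit(
            rank_exponents(cohort, n_ranks=n_ranks, fit_mode=fit_mode)
        )
    return out
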