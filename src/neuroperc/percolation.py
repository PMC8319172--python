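"""Subject-wise percolation of weighted graphs.

Edges are removed one at a time in ascending weight order (ties broken by
lexicographic node pair).  After each removal the number of connected
components (singletons count) and the size of the largest one (the giant
component, GC) are recorded.  As step functions of the removal threshold t
both trajectories are right-continuous: an edge of weight w is gone for all
t >= w, i.e. the surviving graph at t keeps exactly the edges with weight
strictly greater than t.  That strictly-greater convention is the single
place threshold semantics live; degree tracks use it too.

On top of the raw trajectories the module provides

* group-averaged percolation curves with 95% confidence bands,
* "lines of reduction": the thresholds at which each subject's GC has lost
  5-50% of its nodes, their across-subject areas (AUC), and the exponential
  speed-of-decay (SoD) fit of the normalised consecutive-area differences,
* the Degree Variation Coefficient (DVC): per node, the root sum of squared
  consecutive degree changes over a uniform threshold grid, plus the pooled
  group comparison of DVC distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._disjoint import DisjointSet
from ._fit import fit_exponential_decay
from .errors import DataError, DisconnectedGraphError
from .networks import Cohort, WeightedBrainGraph
from .variability import LognormalFit, MWWResult, fit_lognormal, mww_compare

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
DEFAULT_GRID_SIZE = 201


@dataclass
class PercolationProfile:
    """Percolation trajectories of one subject.

    ``thresholds`` are the removed weights in removal order (ascending);
    ``n_components[k]`` and ``gc_size[k]`` describe the graph after the
    (k+1)-th removal.  ``degree_tracks[i, g]`` is node i's surviving degree
    at ``degree_grid[g]`` (edges with weight > grid value).
    """

    thresholds: np.ndarray
    n_components: np.ndarray
    gc_size: np.ndarray
    degree_grid: np.ndarray
    degree_tracks: np.ndarray
    n_nodes: int
    subject_id: str = ""
    weight_mode: str = "r2"
    incident_sorted: np.ndarray = None  # (n, n) row-sorted weights, for re-gridding

    def degree_tracks_on(self, grid: np.ndarray) -> np.ndarray:
        """Degree tracks evaluated on an arbitrary threshold grid."""
        if self.incident_sorted is None:
            raise DataError("profile was built without incident weights")
        grid = np.asarray(grid, dtype=float)
        n = self.n_nodes
        tracks = np.empty((n, grid.size), dtype=np.int64)
        for i in range(n):
            tracks[i] = n - np.searchsorted(self.incident_sorted[i], grid, side="right")
        return tracks

    def components_at(self, t) -> np.ndarray:
        """Component count at threshold(s) t (right-continuous step function)."""
        k = np.searchsorted(self.thresholds, np.asarray(t, dtype=float), side="right")
        out = np.where(k == 0, 1, self.n_components[np.maximum(k, 1) - 1])
        return out

    def gc_at(self, t) -> np.ndarray:
        """Giant-component size at threshold(s) t."""
        k = np.searchsorted(self.thresholds, np.asarray(t, dtype=float), side="right")
        return np.where(k == 0, self.n_nodes, self.gc_size[np.maximum(k, 1) - 1])

    def first_split_threshold(self) -> float:
        """Smallest removed weight at which the GC drops below n_nodes."""
        idx = int(np.argmax(self.gc_size < self.n_nodes))
        if self.gc_size[idx] >= self.n_nodes:  # pragma: no cover - full percolation
            raise DataError("giant component never split; graph did not percolate")
        return float(self.thresholds[idx])


@dataclass
class ReductionAnalysis:
    """Lines-of-reduction AUC analysis with speed-of-decay fit."""

    fractions: tuple
    auc_per_fraction: np.ndarray
    auc_max_gc: float
    delta_auc_normalized: np.ndarray
    sod: float
    sod_stderr: float
    amplitude: float

    def to_dict(self) -> dict:
        return {
            "fractions": list(self.fractions),
            "auc_per_fraction": [float(a) for a in self.auc_per_fraction],
            "auc_max_gc": float(self.auc_max_gc),
            "delta_auc_normalized": [float(d) for d in self.delta_auc_normalized],
            "sod": float(self.sod),
            "sod_stderr": float(self.sod_stderr),
            "amplitude": float(self.amplitude),
        }


@dataclass
class DVCComparison:
    """Pooled Degree Variation Coefficient comparison between two groups."""

    fit_a: LognormalFit
    fit_b: LognormalFit
    mww: MWWResult
    values_a: np.ndarray = field(repr=False, default=None)
    values_b: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "fit_a": self.fit_a.to_dict(),
            "fit_b": self.fit_b.to_dict(),
            "mww": self.mww.to_dict(),
        }


def percolation_profile(
    graph: WeightedBrainGraph, grid_size: int = DEFAULT_GRID_SIZE
) -> PercolationProfile:
    """Full percolation trajectory of one weighted graph.

    The component structure after each removal is obtained by running the
    process in reverse: edges are *added* strongest-first into a union-find
    structure, which yields component count and GC size after every prefix of
    additions; reversing that record gives the state after every removal.
    """
    w_mat = graph.weights
    n = graph.n_nodes
    if n == 0:
        raise DataError("empty graph")
    if grid_size < 2:
        raise DataError("degree grid needs at least 2 points")
    iu, jv = np.triu_indices(n, 1)
    present = w_mat[iu, jv] > 0
    ei, ej, w = iu[present], jv[present], w_mat[iu, jv][present]
    m = w.size
    if m == 0:
        raise DataError("graph has no edges")
    # ascending removal order: weight, then lexicographic node pair
    order = np.lexsort((ej, ei, w))
    ei, ej, w = ei[order], ej[order], w[order]

    # reverse pass: add edges strongest-first
    ds = DisjointSet(n)
    ncomp_added = np.empty(m + 1, dtype=np.int64)
    gc_added = np.empty(m + 1, dtype=np.int64)
    ncomp_added[0] = n
    gc_added[0] = 1
    ei_l, ej_l = ei.tolist(), ej.tolist()
    for j in range(m):
        ds.union(ei_l[m - 1 - j], ej_l[m - 1 - j])
        ncomp_added[j + 1] = ds.n_components
        gc_added[j + 1] = ds.max_size
    if ds.n_components != 1:
        raise DisconnectedGraphError(
            f"input graph is disconnected ({ds.n_components} components)",
            components=ds.components(),
        )
    # state after removing the first k edges == state with the last m-k added
    n_components = ncomp_added[m - 1 :: -1]
    gc_size = gc_added[m - 1 :: -1]

    # squared correlations live in [0, 1]; grid over the full weight domain
    # keeps DVC comparable across subjects.  Unbounded (fisher-z2) weights
    # fall back to the subject's own maximum.
    grid_top = 1.0 if graph.weight_mode == "r2" else float(w[-1])
    grid = np.linspace(0.0, grid_top, grid_size)
    rows = np.sort(w_mat, axis=1)
    profile = PercolationProfile(
        thresholds=w.copy(),
        n_components=n_components.copy(),
        gc_size=gc_size.copy(),
        degree_grid=grid,
        degree_tracks=np.empty(0),
        n_nodes=n,
        subject_id=graph.subject_id,
        weight_mode=graph.weight_mode,
        incident_sorted=rows,
    )
    profile.degree_tracks = profile.degree_tracks_on(grid)
    return profile


def group_average_curve(
    profiles: list[PercolationProfile],
    grid: np.ndarray | None = None,
    metric: str = "n_components",
):
    """Pointwise mean curve and 95% CI band across subjects.

    Each subject's right-continuous step function is evaluated on the shared
    grid (previous-value interpolation); the band is mean +/- 1.96 * SE.

    Returns ``(grid, mean, lower, upper)``.
    """
    if len(profiles) < 2:
        raise DataError("group average needs >= 2 profiles")
    n_nodes = {p.n_nodes for p in profiles}
    if len(n_nodes) != 1:
        raise DataError(f"profiles have differing node counts: {sorted(n_nodes)}")
    if metric not in ("n_components", "gc_size"):
        raise DataError(f"unknown metric {metric!r}")
    if grid is None:
        t_max = max(float(p.thresholds[-1]) for p in profiles)
        grid = np.linspace(0.0, t_max, DEFAULT_GRID_SIZE)
    grid = np.asarray(grid, dtype=float)
    evaluate = (
        (lambda p: p.components_at(grid))
        if metric == "n_components"
        else (lambda p: p.gc_at(grid))
    )
    curves = np.stack([evaluate(p) for p in profiles]).astype(float)
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / math.sqrt(curves.shape[0])
    return grid, mean, mean - 1.96 * se, mean + 1.96 * se


def reduction_thresholds(
    profile: PercolationProfile, fractions=DEFAULT_FRACTIONS
) -> np.ndarray:
    """Threshold at which the GC first shrinks to (1 - f) of the node count.

    ``t_f`` is the smallest removed weight with gc_size <= ceil((1 - f) * N);
    the returned array is non-decreasing in f.
    """
    n = profile.n_nodes
    out = np.empty(len(fractions))
    for k, f in enumerate(fractions):
        if not 0.0 < f < 1.0:
            raise DataError(f"reduction fractions must lie in (0, 1), got {f}")
        target = math.ceil((1.0 - f) * n)
        hit = profile.gc_size <= target
        if not hit.any():  # pragma: no cover - impossible after full percolation
            raise DataError(f"giant component never reached {target} nodes")
        out[k] = profile.thresholds[int(np.argmax(hit))]
    return out


def _curve_area(values: np.ndarray) -> float:
    """Trapezoidal area of subject-indexed values, normalised to a mean level."""
    values = np.asarray(values, dtype=float)
    if values.size == 1:
        return float(values[0])
    return float(np.trapezoid(values) / (values.size - 1))


def auc_reduction_analysis(
    profiles: list[PercolationProfile], fractions=DEFAULT_FRACTIONS
) -> ReductionAnalysis:
    """Lines-of-reduction AUC analysis across a group of subjects.

    For each reduction rung f (and for f = 0, defined by the first GC split)
    the "curve" is the per-subject threshold t_f in manifest order; its
    normalised trapezoidal area AUC(f) is a mean threshold level.  The series
    dAUC(k) / AUC_MaxGCSize of consecutive area differences is fitted to
    ``a * exp(-k / SoD)`` over rung index k = 1..len(fractions).
    """
    if len(profiles) < 1:
        raise DataError("reduction analysis needs at least one profile")
    fractions = tuple(fractions)
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise DataError("fractions must be strictly increasing")
    t0 = np.array([p.first_split_threshold() for p in profiles])
    t_f = np.stack([reduction_thresholds(p, fractions) for p in profiles])
    auc_max = _curve_area(t0)
    auc_f = np.array([_curve_area(t_f[:, k]) for k in range(len(fractions))])
    delta = np.diff(np.concatenate([[auc_max], auc_f]))
    series = delta / auc_max
    k = np.arange(1, len(fractions) + 1, dtype=float)
    a, sod, _, sod_err = fit_exponential_decay(k, series)
    return ReductionAnalysis(
        fractions=fractions,
        auc_per_fraction=auc_f,
        auc_max_gc=auc_max,
        delta_auc_normalized=series,
        sod=float(sod),
        sod_stderr=float(sod_err),
        amplitude=float(a),
    )


def degree_variation_coefficient(profile: PercolationProfile) -> np.ndarray:
    """Per-node Degree Variation Coefficient.

    For node R with degree track d_t over the uniform threshold grid,
    DVC_R = sqrt( sum_t (d_{t+1} - d_t)^2 ).  Zero iff the track is constant;
    a node losing its degree in few large steps scores higher than one losing
    the same total degree gradually.
    """
    if profile.degree_grid.size < 2:
        raise DataError("degree grid with a single threshold: DVC undefined")
    diffs = np.diff(profile.degree_tracks.astype(float), axis=1)
    return np.sqrt((diffs**2).sum(axis=1))


def _profiles_of(group, grid_size: int = DEFAULT_GRID_SIZE) -> list[PercolationProfile]:
    if isinstance(group, Cohort):
        return [percolation_profile(g, grid_size=grid_size) for g in group.graphs]
    return list(group)


def compare_dvc_distributions(group_a, group_b, fit_method: str = "mle") -> DVCComparison:
    """Pooled DVC comparison between two groups.

    Accepts cohorts or precomputed profile lists.  Per-node, per-subject DVC
    values are pooled within each group, each pool is fitted to a log-normal,
    and the pools are compared with the signed-Z MWW test.
    """
    prof_a = _profiles_of(group_a)
    prof_b = _profiles_of(group_b)
    both = prof_a + prof_b
    grids = {(p.degree_grid[0], p.degree_grid[-1], p.degree_grid.size) for p in both}
    if len(grids) > 1:
        # unbounded weight modes: re-evaluate every subject on one shared grid
        top = max(p.degree_grid[-1] for p in both)
        size = max(p.degree_grid.size for p in both)
        grid = np.linspace(0.0, top, size)
        dvc = [
            np.sqrt((np.diff(p.degree_tracks_on(grid).astype(float), axis=1) ** 2).sum(axis=1))
            for p in both
        ]
    else:
        dvc = [degree_variation_coefficient(p) for p in both]
    vals_a = np.concatenate(dvc[: len(prof_a)])
    vals_b = np.concatenate(dvc[len(prof_a) :])
    fit_a = fit_lognormal(vals_a[vals_a > 0], method=fit_method)
    fit_b = fit_lognormal(vals_b[vals_b > 0], method=fit_method)
    mww = mww_compare(vals_a, vals_b)
    return DVCComparison(fit_a=fit_a, fit_b=fit_b, mww=mww,
                         values_a=vals_a, values_b=vals_b)
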