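"""Synthetic two-group cohorts of correlation networks.

The generator emulates the statistical structure that the downstream
percolation / spanning-tree / allometry analysis is sensitive to, so the
whole pipeline is testable without any imaging data:

* a hierarchically modular ground-truth correlation matrix: nested equal-size
  blocks whose pairwise correlation levels decrease with block depth, with a
  per-block-pair multiplicative spread (different modules are coherent at
  slightly different levels) plus a small element-wise jitter;
* a three-tier per-node coupling profile drawn once per cohort: a rich-club
  tier of strongly coupled hub nodes, a mid-coupled bulk, and a tier of
  weakly coupled nodes whose edges are uniformly weak -- this concentrates
  the weakest edge weights around identifiable nodes, the control-like
  signature the group contrast rests on;
* subject-level variability injected both as multiplicative jitter on the
  couplings and as finite-length sampling noise of the Gaussian time-series;
* a patient-like "weak-link homogenisation": the weakest fraction of edge
  weights is swapped with the weights at uniformly random edge positions,
  breaking node-level concentration of weak weights while preserving the
  weight multiset exactly.

All randomness descends deterministically from ``CohortSpec.seed`` via
``numpy.random.SeedSequence`` spawn keys, so a spec identifies a cohort
bit-for-bit.  Population-level draws (block values, couplings) use streams
that do not depend on the archetype, so a control-like and a patient-like
cohort from the same spec describe the same underlying population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .networks import Cohort, WeightedBrainGraph, correlation_matrix, to_weights

ARCHETYPES = ("control-like", "patient-like")

# spawn-key stream ids (population streams must not depend on archetype)
_STREAM_BASE = 0
_STREAM_COUPLING = 1
_STREAM_SUBJECT = 2

_MIN_EIG = 1e-6


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults are the study conditions the pipeline is meant to emulate:
    116 ROIs, 20 subjects per group, 240 time points per subject, a
    three-level modular hierarchy, and a patient-like archetype that
    reshuffles the weakest half of the edge weights.
    """

    n_nodes: int = 116
    n_subjects: int = 20
    n_timepoints: int = 240
    hierarchy_depth: int = 3
    block_correlation_levels: tuple = (0.62, 0.40, 0.22)
    branching: int = 2
    block_value_spread: float = 0.2
    covariance_jitter_sd: float = 0.005
    n_hub_nodes: int | None = None  # default: ~31% of nodes (36 of 116)
    hub_coupling: tuple = (0.92, 0.99)
    n_weak_nodes: int | None = None  # default: ~26% of nodes (30 of 116)
    weak_coupling: tuple = (0.10, 0.35)
    mid_coupling: tuple = (0.72, 0.78)
    subject_noise_sd: float = 0.05
    homogenize_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 4:
            raise ConfigurationError(f"n_nodes must be >= 4, got {self.n_nodes}")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_timepoints < 3:
            raise ConfigurationError("n_timepoints must be >= 3")
        if not 0.0 <= self.homogenize_fraction <= 1.0:
            raise ConfigurationError(
                f"homogenize_fraction must lie in [0, 1], got {self.homogenize_fraction}"
            )
        levels = tuple(self.block_correlation_levels)
        if len(levels) != self.hierarchy_depth:
            raise ConfigurationError(
                f"need one correlation level per hierarchy level: "
                f"{len(levels)} levels for depth {self.hierarchy_depth}"
            )
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ConfigurationError(
                "block_correlation_levels must be strictly decreasing "
                "(deepest blocks first)"
            )
        if not all(0.0 <= c < 1.0 for c in levels):
            raise ConfigurationError("correlation levels must lie in [0, 1)")
        if not 0.0 <= self.block_value_spread < 1.0:
            raise ConfigurationError("block_value_spread must lie in [0, 1)")
        s = self.block_value_spread
        if s > 0 and any(
            a * (1 - s) <= b * (1 + s) for a, b in zip(levels, levels[1:])
        ):
            raise ConfigurationError(
                "block_value_spread too large: jittered level bands overlap, "
                "breaking 'deeper shared block => larger correlation'"
            )
        if self.branching < 2:
            raise ConfigurationError("branching must be >= 2")
        if self.subject_noise_sd < 0:
            raise ConfigurationError("subject_noise_sd must be >= 0")
        if self.n_hub_nodes is None:
            self.n_hub_nodes = round(36 / 116 * self.n_nodes)
        if self.n_weak_nodes is None:
            self.n_weak_nodes = round(30 / 116 * self.n_nodes)
        n_special = self.n_hub_nodes + self.n_weak_nodes
        if n_special > self.n_nodes:
            raise ConfigurationError(
                f"hub + weak node counts ({n_special}) exceed n_nodes ({self.n_nodes})"
            )
        for name in ("hub_coupling", "weak_coupling", "mid_coupling"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} must satisfy 0 < lo <= hi <= 1")
        self.block_correlation_levels = levels

    @property
    def n_blocks_finest(self) -> int:
        return self.branching ** (self.hierarchy_depth - 1)

    def node_labels(self) -> list[str]:
        return [f"ROI-{i + 1:03d}" for i in range(self.n_nodes)]

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d


def _seed(spec_seed: int, *key) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=spec_seed, spawn_key=tuple(key))


def _project_to_correlation(corr: np.ndarray) -> np.ndarray:
    """Clip the spectrum to positive values and renormalise the diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals[0] > 0:
        return corr
    vals = np.clip(vals, _MIN_EIG, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    if np.linalg.eigvalsh(out)[0] <= 0:
        raise ConfigurationError(
            "covariance not positive-definite even after projection; "
            "reduce covariance_jitter_sd"
        )
    return out


def _finest_block_ids(spec: CohortSpec) -> np.ndarray:
    size = spec.n_nodes // spec.n_blocks_finest
    return np.arange(spec.n_nodes) // size


def _shared_level(bi: int, bj: int, depth: int, branching: int) -> int:
    """Index into block_correlation_levels for two finest-block ids.

    0 = the two nodes share a finest (deepest) block; depth-1 = they share
    only the whole node set.
    """
    lvl = 0
    while bi != bj:
        bi //= branching
        bj //= branching
        lvl += 1
    return lvl


def build_hierarchical_covariance(spec: CohortSpec) -> np.ndarray:
    """Ground-truth correlation matrix with nested block structure.

    A pair's correlation is the level value of the deepest block the pair
    shares.  Each (finest-block, finest-block) combination gets its own
    multiplicative factor in ``1 +/- block_value_spread`` -- modules cohere
    at slightly different strengths -- and a small element-wise symmetric
    jitter is added on top.  Deeper shared blocks always mean larger
    correlation (enforced at spec validation).  The result is projected to
    the nearest positive-definite correlation matrix if the jitter pushes an
    eigenvalue below zero.
    """
    n, depth = spec.n_nodes, spec.hierarchy_depth
    if n % spec.n_blocks_finest != 0:
        raise ConfigurationError(
            f"{n} nodes cannot be split into {spec.n_blocks_finest} equal blocks "
            f"(branching {spec.branching}, depth {depth}); choose divisible n_nodes"
        )
    levels = spec.block_correlation_levels
    nb = spec.n_blocks_finest
    fb = _finest_block_ids(spec)
    rng = np.random.default_rng(_seed(spec.seed, _STREAM_BASE))
    s = spec.block_value_spread
    values = np.zeros((nb, nb))
    for bi in range(nb):
        for bj in range(bi, nb):
            lvl = _shared_level(bi, bj, depth, spec.branching)
            u = rng.uniform(1.0 - s, 1.0 + s) if s > 0 else 1.0
            values[bi, bj] = values[bj, bi] = levels[lvl] * u
    corr = values[fb[:, None], fb[None, :]].copy()
    jit = rng.normal(0.0, spec.covariance_jitter_sd, size=(n, n))
    corr = corr + (jit + jit.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return _project_to_correlation(corr)


def node_couplings(spec: CohortSpec) -> np.ndarray:
    """Population coupling strength per node (three-tier profile).

    Hub and weak tiers are assigned to uniformly random nodes; the rest form
    the mid tier.  The draw is keyed by ``spec.seed`` only, so both
    archetypes of a study share one population.
    """
    rng = np.random.default_rng(_seed(spec.seed, _STREAM_COUPLING))
    alpha = rng.uniform(*spec.mid_coupling, size=spec.n_nodes)
    roles = rng.permutation(spec.n_nodes)
    hubs = roles[: spec.n_hub_nodes]
    weak = roles[spec.n_hub_nodes : spec.n_hub_nodes + spec.n_weak_nodes]
    alpha[hubs] = rng.uniform(*spec.hub_coupling, size=spec.n_hub_nodes)
    alpha[weak] = rng.uniform(*spec.weak_coupling, size=spec.n_weak_nodes)
    return alpha


def sample_subject_timeseries(cov: np.ndarray, n_timepoints: int, seed) -> np.ndarray:
    """Draw an (n_nodes, n_timepoints) zero-mean Gaussian time-series.

    ``seed`` may be an int or a ``SeedSequence``; identical seeds give
    bit-identical output.
    """
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DataError("covariance matrix is not positive-definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((cov.shape[0], n_timepoints))
    return chol @ z


def homogenize_weak_links(weights: np.ndarray, fraction: float, seed) -> np.ndarray:
    """Reshuffle the weakest ``fraction`` of edge weights across the graph.

    The values held by the lowest-weight quantile of edges are swapped, one
    by one, with the values at edge positions drawn uniformly (without
    replacement) over the whole graph.  The multiset of weights is preserved
    exactly; only their placement changes, which destroys any node-level
    concentration of weak weights.  ``fraction = 0`` is the identity (a copy
    is returned).
    """
    w = np.asarray(weights, dtype=float)
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError(f"fraction must lie in [0, 1], got {fraction}")
    if not np.allclose(w, w.T, atol=1e-10):
        raise DataError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise DataError("weights must be nonnegative")
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    vals = w[iu].copy()
    m = vals.size
    k = int(round(fraction * m))
    if k > 0:
        rng = np.random.default_rng(seed)
        weak = np.argsort(vals, kind="stable")[:k]
        targets = rng.choice(m, size=k, replace=False)
        for a, b in zip(weak, targets):
            va = vals[a]
            vals[a] = vals[b]
            vals[b] = va
    out = np.zeros_like(w)
    out[iu] = vals
    out = out + out.T
    return out


def generate_cohort(spec: CohortSpec, archetype: str) -> Cohort:
    """Generate one cohort of weighted (squared-correlation) networks.

    Per subject: couplings are jittered log-normally
    (``subject_noise_sd``), the subject covariance is the coupling outer
    product times the ground-truth block matrix (unit diagonal), a Gaussian
    time-series of ``n_timepoints`` volumes is sampled, Pearson correlations
    are computed and squared.  The patient-like archetype then applies
    :func:`homogenize_weak_links` with ``spec.homogenize_fraction``.
    """
    if archetype not in ARCHETYPES:
        raise ConfigurationError(
            f"archetype must be one of {ARCHETYPES}, got {archetype!r}"
        )
    base = build_hierarchical_covariance(spec)
    alpha = node_couplings(spec)
    labels = spec.node_labels()
    group_id = ARCHETYPES.index(archetype)
    graphs = []
    for s in range(spec.n_subjects):
        rng_subj = np.random.default_rng(_seed(spec.seed, _STREAM_SUBJECT, group_id, s, 0))
        a_s = alpha * np.exp(spec.subject_noise_sd * rng_subj.standard_normal(spec.n_nodes))
        a_s = np.clip(a_s, 0.05, 0.995)
        cov = np.outer(a_s, a_s) * base
        np.fill_diagonal(cov, 1.0)
        ts = sample_subject_timeseries(
            cov, spec.n_timepoints, _seed(spec.seed, _STREAM_SUBJECT, group_id, s, 1)
        )
        corr = correlation_matrix(ts, node_labels=labels)
        graph = to_weights(
            corr, mode="r2", node_labels=labels, subject_id=f"{archetype}-{s:03d}"
        )
        if archetype == "patient-like" and spec.homogenize_fraction > 0:
            shuffled = homogenize_weak_links(
                graph.weights, spec.homogenize_fraction,
                _seed(spec.seed, _STREAM_SUBJECT, group_id, s, 2),
            )
            graph = WeightedBrainGraph(
                weights=shuffled, node_labels=labels,
                subject_id=graph.subject_id, weight_mode=graph.weight_mode,
            )
        graphs.append(graph)
    return Cohort(group_label=archetype, graphs=graphs, node_labels=labels)
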