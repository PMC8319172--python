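"""Weighted functional-network construction.

A subject's functional network is built from ROI-level BOLD-like time-series
in two steps: pairwise Pearson correlation, then a squaring transform that
discards the sign of the correlation (negative couplings enter only through
their magnitude).  Two weight conventions are supported:

``r2``
    w = r**2 (bounded in [0, 1]).
``fisher-z2``
    w = arctanh(r)**2, the squared Fisher z-transform (unbounded; correlations
    at |r| = 1 are clamped to 1 - 1e-6 with a warning).

The resulting :class:`WeightedBrainGraph` is a fully connected, symmetric,
nonnegative weight matrix with a zero diagonal (no self-loops).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

WEIGHT_MODES = ("r2", "fisher-z2")

_FISHER_CLAMP = 1.0 - 1e-6


@dataclass
class WeightedBrainGraph:
    """One subject's weighted functional network.

    Attributes
    ----------
    weights : (n, n) ndarray
        Symmetric nonnegative connectivity strengths, zero diagonal.
    node_labels : list of str
        One opaque label per ROI.
    subject_id : str
    weight_mode : str
        Which transform produced the weights (``r2`` or ``fisher-z2``).
    """

    weights: np.ndarray
    node_labels: list[str]
    subject_id: str = ""
    weight_mode: str = "r2"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DataError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] != len(self.node_labels):
            raise DataError(
                f"{len(self.node_labels)} node labels for a {w.shape[0]}-node matrix"
            )
        if np.isnan(w).any():
            raise DataError("weight matrix contains NaN")
        if not np.allclose(w, w.T, rtol=0.0, atol=1e-10):
            raise DataError("weight matrix is not symmetric")
        if np.any(np.diag(w) != 0.0):
            raise DataError("weight matrix diagonal must be zero (no self-loops)")
        if np.any(w < 0):
            raise DataError("weights must be nonnegative")
        if self.weight_mode not in WEIGHT_MODES:
            raise DataError(f"unknown weight_mode {self.weight_mode!r}")

    def upper_weights(self) -> np.ndarray:
        """Weights of the strict upper triangle, row-major order."""
        iu = np.triu_indices(self.n_nodes, 1)
        return self.weights[iu]


@dataclass
class Cohort:
    """A named group of subjects sharing one node set."""

    group_label: str
    graphs: list[WeightedBrainGraph]
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.node_labels and self.graphs:
            self.node_labels = list(self.graphs[0].node_labels)
        for g in self.graphs:
            if list(g.node_labels) != list(self.node_labels):
                raise DataError(
                    f"subject {g.subject_id!r} node labels differ from cohort labels"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.graphs)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def weight_stack(self) -> np.ndarray:
        """(n_subjects, n, n) array of all weight matrices."""
        return np.stack([g.weights for g in self.graphs])


def correlation_matrix(timeseries: np.ndarray, node_labels=None) -> np.ndarray:
    """Full symmetric matrix of pairwise Pearson correlations between rows.

    Parameters
    ----------
    timeseries : (n_nodes, n_timepoints) array
        One row per ROI; at least 3 time points and no constant rows.
    node_labels : optional
        Used only to name the offending node in error messages.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise DataError(f"time-series must be 2-D (nodes x time), got shape {ts.shape}")
    if ts.shape[1] < 3:
        raise DataError(f"need >= 3 timepoints, got {ts.shape[1]}")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        idx = int(np.flatnonzero(sd == 0)[0])
        name = node_labels[idx] if node_labels is not None else f"index {idx}"
        raise DataError(f"constant time-series for node {name}: correlation undefined")
    r = np.corrcoef(ts)
    np.fill_diagonal(r, 1.0)
    return r


def to_weights(
    corr: np.ndarray,
    mode: str = "r2",
    node_labels=None,
    subject_id: str = "",
) -> WeightedBrainGraph:
    """Transform a correlation matrix into a weighted graph.

    The transform is even in r (the sign of a correlation carries no weight)
    and monotone in |r|.  The diagonal is forced to zero.
    """
    if mode not in WEIGHT_MODES:
        raise DataError(f"unknown weight mode {mode!r}; expected one of {WEIGHT_MODES}")
    r = np.asarray(corr, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise DataError(f"correlation matrix must be square, got shape {r.shape}")
    if np.isnan(r).any():
        raise DataError("correlation matrix contains NaN")
    if np.any(np.abs(r) > 1.0 + 1e-12):
        bad = float(np.max(np.abs(r)))
        raise DataError(f"correlation entries must lie in [-1, 1]; max |r| = {bad}")
    r = np.clip(r, -1.0, 1.0)
    if mode == "r2":
        w = r * r
    else:
        off = ~np.eye(r.shape[0], dtype=bool)
        if np.any(np.abs(r[off]) >= _FISHER_CLAMP):
            warnings.warn(
                "off-diagonal |r| >= 1 - 1e-6 clamped before Fisher z-transform",
                stacklevel=2,
            )
        rc = np.clip(r, -_FISHER_CLAMP, _FISHER_CLAMP)
        w = np.arctanh(rc) ** 2
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0  # remove float asymmetry from corrcoef round-off
    if node_labels is None:
        node_labels = [f"node-{i:03d}" for i in range(r.shape[0])]
    return WeightedBrainGraph(
        weights=w, node_labels=list(node_labels), subject_id=subject_id, weight_mode=mode
    )
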