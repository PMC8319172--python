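"""Cohort and report I/O: per-subject TSV matrices plus a JSON manifest.

A cohort on disk is a directory with one tab-separated matrix per subject
(node labels as header row and index column) and a ``manifest.json`` listing
the group label, the node labels, the subject files with their kind
(``weights``, ``correlation`` or ``timeseries``), and an echo of the
generating spec when the cohort is synthetic.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .networks import Cohort, WeightedBrainGraph, correlation_matrix, to_weights

MANIFEST_SCHEMA_VERSION = 1
_SYMMETRY_TOL = 1e-8

MATRIX_KINDS = ("weights", "correlation", "timeseries")


def write_cohort(cohort: Cohort, outdir, spec=None) -> Path:
    """Write a cohort as per-subject TSVs plus a manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for g in cohort.graphs:
        fname = f"{g.subject_id or 'subject'}.tsv"
        df = pd.DataFrame(g.weights, index=cohort.node_labels, columns=cohort.node_labels)
        df.to_csv(outdir / fname, sep="\t")
        entries.append(
            {"subject_id": g.subject_id, "path": fname, "kind": "weights",
             "weight_mode": g.weight_mode}
        )
    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "group_label": cohort.group_label,
        "node_labels": list(cohort.node_labels),
        "entries": entries,
    }
    if spec is not None:
        manifest["spec"] = spec.to_dict() if hasattr(spec, "to_dict") else dict(spec)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _load_matrix(path: Path, labels: list[str]) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != labels or list(df.columns) != labels:
        raise DataError(f"{path}: node labels do not match the manifest")
    m = df.to_numpy(dtype=float)
    if np.isnan(m).any():
        r, c = np.argwhere(np.isnan(m))[0]
        raise DataError(f"{path}: NaN at row {labels[r]!r}, column {labels[c]!r}")
    return m


def _as_symmetric(m: np.ndarray, path: Path) -> np.ndarray:
    asym = np.abs(m - m.T).max()
    if asym > _SYMMETRY_TOL:
        r, c = np.unravel_index(np.argmax(np.abs(m - m.T)), m.shape)
        raise DataError(
            f"{path}: matrix asymmetric beyond {_SYMMETRY_TOL} "
            f"(|A - A.T| = {asym:.3g} at cell ({r}, {c}))"
        )
    if asym > 0:
        warnings.warn(f"{path}: symmetrised matrix (max asymmetry {asym:.2g})", stacklevel=2)
        m = (m + m.T) / 2.0
    return m


def read_cohort(manifest_path, weight_mode: str = "r2") -> Cohort:
    """Load a cohort from a manifest, validating before any computation.

    Time-series entries are converted to weights with ``weight_mode``;
    correlation entries are squared (or Fisher-z squared) likewise; weight
    entries are taken as-is.  All referenced files are checked for existence
    first so a broken manifest fails before any work is done.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    labels = list(manifest["node_labels"])
    base = manifest_path.parent
    paths = []
    for entry in manifest["entries"]:
        p = base / entry["path"]
        if not p.exists():
            raise DataError(f"manifest references missing file: {p}")
        kind = entry.get("kind", "weights")
        if kind not in MATRIX_KINDS:
            raise DataError(f"unknown matrix kind {kind!r} for {p}")
        paths.append((p, entry))
    graphs = []
    for p, entry in paths:
        kind = entry.get("kind", "weights")
        subject = entry.get("subject_id", p.stem)
        m = _load_matrix(p, labels) if kind != "timeseries" else None
        if kind == "timeseries":
            df = pd.read_csv(p, sep="\t", index_col=0)
            if list(df.index) != labels:
                raise DataError(f"{p}: node labels do not match the manifest")
            ts = df.to_numpy(dtype=float)
            if np.isnan(ts).any():
                raise DataError(f"{p}: NaN in time-series")
            graphs.append(
                to_weights(correlation_matrix(ts, labels), weight_mode, labels, subject)
            )
            continue
        m = _as_symmetric(m, p)
        if kind == "correlation":
            graphs.append(to_weights(m, weight_mode, labels, subject))
        else:
            np.fill_diagonal(m, 0.0)
            if np.any(m < 0):
                raise DataError(f"{p}: negative entries in a weight matrix")
            graphs.append(
                WeightedBrainGraph(
                    weights=m, node_labels=labels, subject_id=subject,
                    weight_mode=entry.get("weight_mode", weight_mode),
                )
            )
    return Cohort(
        group_label=manifest.get("group_label", manifest_path.parent.name),
        graphs=graphs, node_labels=labels,
    )


def write_report(report: dict, outdir) -> Path:
    """Write the analysis report as deterministic JSON; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return path
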