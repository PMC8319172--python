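"""End-to-end two-group analysis: orchestration, reporting, group contrast.

``run_group_analysis`` executes network construction, inter-subject
variability, percolation (curves, reduction AUC analysis, degree variation),
spanning-tree filtration and allometric rank profiling for two cohorts, and
writes TSV artifacts plus one deterministic JSON report.  All randomness
flows from the single config seed; identical config + seed gives a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import rank_decay_fit, rank_exponents
from .errors import ConfigurationError, NeuropercError
from .io import read_cohort, write_cohort, write_report
from .networks import Cohort
from .percolation import (
    auc_reduction_analysis,
    compare_dvc_distributions,
    group_average_curve,
    percolation_profile,
)
from .synthetic import ARCHETYPES, CohortSpec, generate_cohort
from .variability import coefficient_of_variation, fit_lognormal, mww_compare, offdiagonal_values

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Everything one analysis run depends on.

    Either both manifests are given (observed data) or ``synthetic`` is true
    and cohorts are generated from ``spec_overrides`` + ``seed``.
    """

    seed: int = 0
    synthetic: bool = True
    control_manifest: str | None = None
    patient_manifest: str | None = None
    spec_overrides: dict = field(default_factory=dict)
    weight_mode: str = "r2"
    grid_size: int = 201
    reduction_fractions: tuple = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
    n_ranks: int = 4
    fit_mode: str = "intercept"
    outdir: str | None = None
    write_cohorts: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.synthetic:
            for name in ("control_manifest", "patient_manifest"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigurationError(f"{name} required when synthetic is false")
                if not Path(path).exists():
                    raise ConfigurationError(f"{name} does not exist: {path}")
        if self.grid_size < 2:
            raise ConfigurationError("grid_size must be >= 2")
        if self.n_ranks < 1:
            raise ConfigurationError("n_ranks must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reduction_fractions"] = [float(f) for f in self.reduction_fractions]
        return d

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=self.seed, **self.spec_overrides)


class _Stage:
    """Context manager adding stage names to errors and timing to the log."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            logger.error("stage %s: failed after %.1fs: %s", self.name, dt, exc)
            if isinstance(exc, NeuropercError):
                exc.args = (f"[stage {self.name}] {exc.args[0]}",) + exc.args[1:]
            return False
        logger.info("stage %s: done in %.1fs", self.name, dt)
        return False


def _load_cohorts(config: AnalysisConfig) -> tuple[Cohort, Cohort]:
    if config.synthetic:
        spec = config.cohort_spec()
        return (
            generate_cohort(spec, "control-like"),
            generate_cohort(spec, "patient-like"),
        )
    return (
        read_cohort(config.control_manifest, config.weight_mode),
        read_cohort(config.patient_manifest, config.weight_mode),
    )


def _variability_block(cohort: Cohort) -> tuple[np.ndarray, dict]:
    cv = coefficient_of_variation(cohort)
    values = offdiagonal_values(cv)
    fit = fit_lognormal(values)
    return cv, {"lognormal": fit.to_dict(), "n_edges": int(values.size)}


def run_group_analysis(config: AnalysisConfig) -> dict:
    """Run the full two-group analysis; returns (and optionally writes) the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir) if config.outdir else None

    with _Stage("load-cohorts"):
        control, patient = _load_cohorts(config)
    cohorts = {"control": control, "patient": patient}

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "config": config.to_dict(),
            "seed": config.seed,
            "software": "neuroperc",
            "version": __version__,
        },
        "groups": {},
    }
    artifacts: dict[str, pd.DataFrame] = {}

    with _Stage("intersubject-variability"):
        cv_values = {}
        for name, cohort in cohorts.items():
            cv, block = _variability_block(cohort)
            cv_values[name] = offdiagonal_values(cv)
            report["groups"].setdefault(name, {})["variability"] = block
            artifacts[f"cv_{name}.tsv"] = pd.DataFrame(
                cv, index=cohort.node_labels, columns=cohort.node_labels
            )
        mww = mww_compare(cv_values["control"], cv_values["patient"])
        report["cv_comparison"] = mww.to_dict()

    with _Stage("percolation"):
        profiles = {
            name: [percolation_profile(g, config.grid_size) for g in cohort.graphs]
            for name, cohort in cohorts.items()
        }
        t_max = max(p.thresholds[-1] for ps in profiles.values() for p in ps)
        grid = np.linspace(0.0, float(t_max), config.grid_size)
        rows = []
        for name, ps in profiles.items():
            _, mean, lo, hi = group_average_curve(ps, grid, "n_components")
            _, gmean, glo, ghi = group_average_curve(ps, grid, "gc_size")
            report["groups"][name]["percolation_curve"] = {
                "grid": grid.tolist(),
                "n_components_mean": mean.tolist(),
                "n_components_ci": [lo.tolist(), hi.tolist()],
                "gc_size_mean": gmean.tolist(),
                "gc_size_ci": [glo.tolist(), ghi.tolist()],
            }
            red = auc_reduction_analysis(ps, config.reduction_fractions)
            report["groups"][name]["reduction"] = red.to_dict()
            for p in ps:
                for t, nc, gc in zip(p.thresholds, p.n_components, p.gc_size):
                    rows.append(
                        {"group": name, "subject": p.subject_id, "threshold": t,
                         "n_components": int(nc), "gc_size": int(gc)}
                    )
        artifacts["percolation.tsv"] = pd.DataFrame(rows)

    with _Stage("degree-variation"):
        dvc = compare_dvc_distributions(profiles["control"], profiles["patient"])
        report["dvc_comparison"] = dvc.to_dict()

    with _Stage("allometry"):
        rank_rows = []
        for name, cohort in cohorts.items():
            exponents = rank_exponents(cohort, config.n_ranks, config.fit_mode)
            fit = rank_decay_fit(exponents)
            report["groups"][name]["rank_decay"] = fit.to_dict()
            report["groups"][name]["fit_mode"] = config.fit_mode
            per_root = exponents.mean(axis=0)  # (n_ranks, n_nodes), over subjects
            per_root_se = exponents.std(axis=0, ddof=1) / np.sqrt(max(cohort.n_subjects, 1))
            for r in range(config.n_ranks):
                for i, label in enumerate(cohort.node_labels):
                    rank_rows.append(
                        {"group": name, "rank": r + 1, "root": label,
                         "eta_mean": per_root[r, i],
                         "eta_ci_halfwidth": 1.96 * per_root_se[r, i]}
                    )
        artifacts["eta_by_root.tsv"] = pd.DataFrame(rank_rows)

    if outdir is not None:
        with _Stage("write-artifacts"):
            outdir.mkdir(parents=True, exist_ok=True)
            for fname, df in artifacts.items():
                df.to_csv(outdir / fname, sep="\t", index=fname.startswith("cv_"),
                          float_format="%.10g")
            if config.write_cohorts and config.synthetic:
                spec = config.cohort_spec()
                for name, cohort in cohorts.items():
                    write_cohort(cohort, outdir / f"cohort_{name}", spec=spec)
            write_report(report, outdir)
    return report


def archetype_contrast(spec: CohortSpec, n_ranks: int = 4) -> dict:
    """One replicate of the control-like vs patient-like comparison.

    Returns the group-contrast quantities the generator is designed to
    reproduce: the maximum-giant-component AUC of both groups, the pooled
    Degree Variation Coefficient comparison, the rank-decay constants, the
    edge-wise CV comparison, and subject-level comparisons (per-subject
    first-split thresholds, per-subject mean DVC, per-subject decay
    constants) whose MWW tests are calibrated under the null.
    """
    from ._fit import fit_saturating_exponential
    from .percolation import degree_variation_coefficient

    control = generate_cohort(spec, "control-like")
    patient = generate_cohort(spec, "patient-like")
    prof = {
        "control": [percolation_profile(g) for g in control.graphs],
        "patient": [percolation_profile(g) for g in patient.graphs],
    }
    red = {k: auc_reduction_analysis(v) for k, v in prof.items()}
    dvc = compare_dvc_distributions(prof["control"], prof["patient"])
    dvc_subject = {
        k: [float(degree_variation_coefficient(p).mean()) for p in v]
        for k, v in prof.items()
    }
    t0 = {k: [p.first_split_threshold() for p in v] for k, v in prof.items()}
    exponents = {
        "control": rank_exponents(control, n_ranks),
        "patient": rank_exponents(patient, n_ranks),
    }
    fits = {k: rank_decay_fit(v) for k, v in exponents.items()}
    ranks = np.arange(1, n_ranks + 1)

    def per_subject_sr(ex):
        out = []
        for s in range(ex.shape[0]):
            try:
                out.append(fit_saturating_exponential(ranks, ex[s].mean(axis=1))[2])
            except NeuropercError:
                out.append(np.nan)
        return [v for v in out if np.isfinite(v)]

    sr_subj = {k: per_subject_sr(v) for k, v in exponents.items()}
    cv = {
        k: offdiagonal_values(coefficient_of_variation(c))
        for k, c in (("control", control), ("patient", patient))
    }
    return {
        "auc_max_gc": {k: red[k].auc_max_gc for k in red},
        "sod": {k: red[k].sod for k in red},
        "dvc_pooled_mww": dvc.mww.to_dict(),
        "dvc_subject_mww": mww_compare(dvc_subject["control"], dvc_subject["patient"]).to_dict(),
        "first_split_mww": mww_compare(t0["control"], t0["patient"]).to_dict(),
        "sr": {k: fits[k].sr for k in fits},
        "eta_by_rank": {k: fits[k].eta_mean.tolist() for k in fits},
        "sr_subject_mww": mww_compare(sr_subj["control"], sr_subj["patient"]).to_dict(),
        "cv_mww": mww_compare(cv["control"], cv["patient"]).to_dict(),
    }
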