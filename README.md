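# neuroperc

Weighted-network analysis of resting-state functional connectomes:
percolation robustness profiling, maximum-spanning-tree (MST) filtration,
and allometric scaling of rooted trees, applied to two groups of subjects,
with a synthetic cohort generator so the full pipeline is testable end to
end without imaging data.

## Who this is for

Researchers comparing the robustness and backbone organisation of weighted
brain networks between groups (e.g. patients vs controls), starting from
ROI-level BOLD time-series or precomputed correlation matrices.

## What it computes

Given per-subject ROI × ROI weight matrices `w = r²` (squared Pearson
correlation; the squared Fisher z-transform `w = arctanh(r)²` is also
supported):

- **Percolation**: edges are removed one at a time in ascending weight
  order while the number of connected components and the giant-component
  (GC) size are tracked. Group curves are averaged with 95% CI bands.
- **Lines of reduction**: thresholds `t_f` at which each subject's GC has
  lost a fraction f ∈ {5%, …, 50%} of its nodes; the areas under the
  subject-indexed `t_f` curves (AUC) and the speed of decay (SoD) of the
  normalised consecutive-area differences, fitted to `a·exp(−k/SoD)`.
- **Degree Variation Coefficient (DVC)**: per node,
  `Δd = sqrt(Σ_t (d_{t+1} − d_t)²)` over a uniform threshold grid; pooled
  group distributions are fitted to a log-normal and compared with a
  Mann–Whitney–Wilcoxon (MWW) test.
- **Ranked MSTs**: the rank-n MST is the maximum spanning tree of the graph
  after the edges of ranks 1..n−1 are deleted (edge-disjoint backbones).
- **Allometric scaling**: each tree, rooted at every node in turn, yields
  per-node subtree masses `A_i` (subtree size) and `C_i = Σ_{k∈subtree(i)} A_k`;
  the exponent η of `C ∝ A^η` (log–log least squares) measures tree shape —
  η → 1 for a star, η = 2 for a chain, and the through-origin fit is
  provably confined to [1, 2]. The decay of mean η across MST ranks is
  fitted to `η(rank) = (η₀ − η∞)·exp(−rank/SR) + η∞`, whose constant SR is
  the speed of reduction.

## Worked example

```python
from neuroperc import CohortSpec, generate_cohort
from neuroperc.percolation import percolation_profile, auc_reduction_analysis
from neuroperc.allometry import rank_exponents, rank_decay_fit

spec = CohortSpec(n_subjects=20, seed=1)           # 116 nodes, 240 volumes
control = generate_cohort(spec, "control-like")
patient = generate_cohort(spec, "patient-like")    # weakest half reshuffled

for cohort in (control, patient):
    profiles = [percolation_profile(g) for g in cohort.graphs]
    red = auc_reduction_analysis(profiles)
    fit = rank_decay_fit(rank_exponents(cohort, n_ranks=4))
    print(f"{cohort.group_label}: AUC_MaxGCSize={red.auc_max_gc:.4f} "
          f"eta(rank)={[round(float(e), 3) for e in fit.eta_mean]} SR={fit.sr:.3f}")
```

Output:

```
control-like: AUC_MaxGCSize=0.0199 eta(rank)=[1.409, 1.441, 1.45, 1.471] SR=0.003
patient-like: AUC_MaxGCSize=0.2103 eta(rank)=[1.475, 1.468, 1.489, 1.487] SR=0.017
```

The patient-like group resists the initial GC fragmentation about three
times longer (larger `AUC_MaxGCSize`: no node holds only weak links once
the weak weights are spread uniformly), and its mean allometric exponent
changes less across MST ranks (larger SR): successive backbones of the
homogenised networks are topologically interchangeable.

The same analysis is available from the shell:

```bash
neuroperc simulate --subjects 20 --seed 1 --out cohorts/
neuroperc run-all --seed 1 --out results/   # writes report.json + TSV tables
```

## Layout

- `neuroperc.synthetic` — two-group synthetic cohort generator
- `neuroperc.networks` — correlation → weighted-graph construction
- `neuroperc.variability` — edge-wise CV, log-normal fits, MWW tests
- `neuroperc.percolation` — percolation profiles, reduction AUC/SoD, DVC
- `neuroperc.trees` — MST and edge-disjoint rank decomposition
- `neuroperc.allometry` — subtree masses, η fits, rank-decay (SR)
- `neuroperc.pipeline` / `neuroperc.cli` — orchestration, reports, CLI

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
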