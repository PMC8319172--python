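# Methods

This note documents the models, estimators and numerical conventions
implemented in `neuroperc`, the design choices made where several
formulations were defensible, and the limits of what the synthetic-cohort
tests demonstrate.

## Network construction

A subject's functional network starts from an ROI × time matrix (116 ROIs,
240 volumes by default). Pairwise Pearson correlations give a full
symmetric matrix; weights discard the correlation sign, which carries no
meaning for the robustness questions asked here. Two conventions are
implemented and every output records which one was used:

- `r2` (default): `w = r²`, bounded in [0, 1]. Chosen as the default
  because bounded weights give all subjects a common threshold domain.
- `fisher-z2`: `w = arctanh(r)²`, the squared Fisher z-transform,
  unbounded; correlations at |r| ≥ 1 − 10⁻⁶ are clamped with a warning.

The diagonal is forced to zero (no self-loops). Both transforms are even
in r and monotone in |r|, so they induce the same edge ranking — every
rank-based downstream quantity (percolation order, MSTs) is identical
under either; only threshold *values* and the DVC grid differ.

## Percolation

Edges are deleted one at a time in ascending weight order, ties broken by
lexicographic node pair so results are reproducible without a seed. After
each deletion the component count (singletons included) and the
giant-component (GC) size are recorded. Internally the sweep runs in
reverse — edges are *added* strongest-first into a union-find structure —
which gives the whole trajectory in O(m α(n)).

Threshold semantics live in one place: the graph at threshold t keeps
exactly the edges with weight **strictly greater** than t, making both
step functions right-continuous. Group-average curves evaluate each
subject's step function on a shared grid by previous-value interpolation
and report mean ± 1.96·SE.

**Lines of reduction.** For a fraction f, `t_f` is the smallest removed
weight at which the GC has at most `ceil((1−f)·N)` nodes; `t₀` marks the
first GC split. The "curve" for each rung is the per-subject `t_f` in
cohort order; its trapezoidal area divided by (n_subjects − 1) is a mean
threshold level, so for identical subjects AUC(f) = t_f exactly. The
series ΔAUC(k)/AUC_MaxGCSize over rung index k is fitted to
`a·exp(−k/SoD)`. The construction of these per-rung curves admits other
readings (e.g. sorting subjects, integrating over thresholds); it is
isolated behind `ReductionAnalysis` so an alternative can be swapped in
without touching the rest.

**Degree Variation Coefficient.** Per node,
`Δd = sqrt(Σ_{t=1}^{N_t−1} (d_{t+1} − d_t)²)` over a uniform grid of 201
thresholds (a config knob; results should always be quoted with the grid).
For `r2` weights the grid spans the full weight domain [0, 1] rather than
the subject's own maximum: a per-subject grid would make Δd depend on each
subject's strongest edge, adding a shared per-subject binning scale that
both inflates between-subject variance and makes values incomparable
across subjects. For unbounded `fisher-z2` weights the grid falls back to
the observed maximum, and group comparisons re-evaluate all subjects on
one shared grid. The displayed summation runs over consecutive grid
pairs; zero Δd occurs exactly for a constant track, and for equal total
degree loss, fewer larger steps score higher than gradual loss.

Group DVC comparison pools all per-node, per-subject values by group,
fits a log-normal to each pool and applies the MWW test. Pooled values
within a cohort share subjects and are not independent; the pooled test is
therefore anticonservative and is reported as a descriptive effect-size
summary. Subject-level summaries (per-subject mean DVC, per-subject
first-split threshold, per-subject rank-decay constant), whose MWW tests
are calibrated, are computed alongside in `pipeline.archetype_contrast`
and are what the null-configuration checks rely on.

## Statistics

- Edge-wise coefficient of variation: sample (n−1) standard deviation over
  subjects divided by the mean; invariant to global weight rescaling;
  zero-mean edges are flagged NaN and logged. It can be computed on
  weights (default, matching the matrices actually analysed) or on any
  matrix stack the caller provides (e.g. raw correlations).
- Log-normal fits: maximum likelihood by default (μ, σ = mean and sample
  sd of log values; standard errors σ/√n and σ/√(2n)); a
  Freedman–Diaconis-binned least-squares mode exists for workflows that
  report curve-fit errors.
- MWW: normal approximation with tie correction, no continuity
  correction, reported as a signed Z (positive when the first sample is
  stochastically larger) with p = 2Φ(−|Z|). Cross-checked against
  `scipy.stats.mannwhitneyu` in the tests.

## Spanning-tree filtration

The maximum spanning tree is built by greedy descent over edges sorted by
(descending weight, ascending node pair) with union-find cycle detection;
the lexicographic tie-break yields one canonical tree on equal-weight
input. The rank-n MST is the MST of the graph minus the edges of ranks
1..n−1. If the residual graph disconnects before the requested rank the
operation raises with the achieved rank rather than silently returning a
forest, because the allometric analysis is defined on trees only. For the
complete 116-node graphs analysed here, four ranks use 460 of 6670 edges
and never exhaust connectivity; the greedy decomposition *can* fail on
small dense graphs well before the Nash–Williams packing bound (e.g. three
trees on K₈), which is a property of greedy rank filtration, not a defect.

## Allometric scaling

Rooting a tree at node r orients every edge away from r; then
`A_i = 1 + Σ_children A` and `C_i = A_i + Σ_children C` in one post-order
pass. Invariants asserted on every call: `A_root = n`, `C_root = Σ A_i`,
and `A ≤ C ≤ A²` node-wise. A and C depend only on the rooted topology,
not on the traversal that produced the orientation (asserted by comparing
BFS and DFS orientations).

The exponent η is the least-squares slope of log C on log A over all
nodes, leaves included at (0, 0):

- `intercept` (default): slope plus intercept. A proportionality constant
  is allowed by C ∝ A^η, and the chain's exact C = A(A+1)/2 then gives a
  slope cleanly approaching 2.
- `origin`: slope only, which inherits the provable bound η ∈ [1, 2] from
  `A ≤ C ≤ A²`.

`exponent_by_root` evaluates η for all n roots in O(n) total: A and C of a
node depend only on which neighbour lies toward the root, so each
undirected edge carries two (A, C) pairs, the set of pairs used by a root
is the set of edges oriented away from it, and moving the root across an
edge flips exactly one orientation — all regression sums follow by a
two-pass re-rooting dynamic program. The naive per-root composition is
kept and the two are asserted equal in the tests.

Per cohort, η is averaged over roots within subject, then over subjects
per rank (95% CI from the between-subject SE), and the per-rank means at
ranks 1..4 are fitted to `η(rank) = (η₀ − η∞)·exp(−rank/SR) + η∞`.

## Exponential fits

Both decay fits use `scipy.optimize.curve_fit` (trust-region reflective)
with tolerances 10⁻¹², so noiseless synthetic series are recovered to
better than 10⁻⁶. The plain decay is parametrised internally as
`y = y₁·exp(−(x − x₁)/τ)` — the amplitude at the first abscissa stays well
conditioned when a series collapses to zero after its first point, where
the textbook `a·exp(−x/τ)` parametrisation diverges. The saturating fit
uses (η∞, δ = η₀ − η∞, SR) with box bounds η∞ ≥ 1, δ ≥ 0, SR > 0 and
initialisation η∞ = 1, δ = η(1) − 1, SR = 1. With four ranks and three
parameters the fit is exactly identified only when the series genuinely
decays; on flat or rising series δ is driven to ~0 and the fitted SR is
small and weakly identified — the per-rank means and CIs are always
reported alongside so a degenerate fit is visible.

## Synthetic cohorts

The generator produces the statistical structure the analysis is sensitive
to, not BOLD physics. A cohort is defined by:

- **Hierarchical modularity**: three nested levels of equal blocks
  (branching 2; 116 = 2 × 2 × 29), with pairwise correlation levels
  (0.62, 0.40, 0.22) from deepest to shallowest. Each block-pair gets a
  multiplicative factor in 1 ± 0.2 (modules cohere at slightly different
  strengths); spec validation guarantees the jittered bands cannot overlap,
  preserving "deeper shared block ⇒ larger correlation". A small
  element-wise jitter (sd 0.005) is added and the matrix is projected to
  the nearest positive-definite correlation matrix if needed.
- **Three-tier node coupling** α_i, drawn once per cohort: ~31% hub nodes
  (α ∈ 0.92–0.99, a rich-club-like core), ~26% weakly coupled nodes
  (α ∈ 0.10–0.35) and a mid bulk (α ∈ 0.72–0.78). A node's correlations
  are scaled by α_i·α_j (plus a unit-diagonal completion, which keeps the
  matrix positive-definite), so weak edges concentrate around the
  weak-coupling tier — the control-like signature.
- **Subject variability**: per-node log-normal jitter on α
  (`subject_noise_sd` = 0.05) plus finite-sample noise from drawing 240
  Gaussian volumes and computing empirical correlations. At 240 volumes
  the sampling noise on r (≈ 0.065 sd) dominates most structural detail;
  this floor, not the generator, limits how sharp any per-node weight
  structure can be.
- **Patient-like archetype**: the weakest 50% of the subject's squared
  correlations are swapped with the values at uniformly random edge
  positions. The weight multiset is preserved exactly; the node-level
  concentration of weak (and, through displacement, strong) weights is
  destroyed.

Tier sizes and coupling ranges were chosen so that the three group
signatures the pipeline measures are unambiguous at 20 subjects per group:
weak nodes make the control GC split early (AUC_MaxGCSize contrast), the
weak tier's monopoly on bottom-half weights makes homogenisation shift the
bulk of the pooled DVC distribution (DVC contrast), and the hub tier makes
control rank-1 MSTs star-contaminated while homogenisation re-randomises
patient backbones at every rank (SR contrast, below).

**What the synthetic contrast does and does not show.** In these cohorts
the control group's mean η *rises* slightly with MST rank (rank-1 trees
are depressed by hub-star contamination that later ranks dilute), so its
fitted SR is pinned near zero, while the patient group's flat-to-gently-
decaying profile yields a larger fitted SR. The SR ordering
(patient > control) is therefore reproduced, but through an absent decay
on the control side rather than a fast one; real cohorts in which both
groups show genuine decay are *not* emulated by these defaults. Uniform
reshuffling of half the weights makes patient-like MSTs close to MSTs of
exchangeable random weights at every rank, whose expected shape is
rank-independent — a genuinely slow multi-rank patient decay cannot be
produced by this operator, only a shallower one. Passing group-contrast
tests show that the pipeline detects the designed differences at realistic
noise levels; they are not evidence about effect sizes in real data, and
none of the clinical headline numbers (log-normal CV parameters, Z values,
AUC ratios, SoD or SR values) are reproduced quantitatively — those depend
on data that are not redistributable.

Other acknowledged departures from real data: Gaussian stationary signals
(no autocorrelation, hemodynamics, motion or physiological confounds), a
weight distribution more structured than empirical ones, exchangeable
subjects within group, and no negative-correlation semantics beyond the
squaring transform.

All randomness descends from `CohortSpec.seed` through
`numpy.random.SeedSequence` spawn keys: population draws (block factors,
couplings) use archetype-independent streams so both groups of a study
share one population; each subject's coupling jitter, time-series and
homogenisation use streams keyed by (archetype, subject index). Identical
specs give bit-identical cohorts.

## Pipeline

`run_group_analysis` chains the stages for two cohorts (synthetic or read
from TSV manifests), writes per-edge CV matrices, long-format percolation
tables and per-root η tables as TSV, and a single JSON report carrying the
config echo, seed and package version. Reports contain no timestamps, so
identical config + seed gives a byte-identical report. Matrices read from
disk are validated fail-fast: files checked before computation, NaNs named
by row/column label, asymmetries beyond 10⁻⁸ rejected (smaller ones
symmetrised with a warning).

Default problem sizes (116 nodes, 20 subjects per group, 240 volumes,
4 MST ranks, 201-point grids) keep a full two-group run around a second
and the replicate-based test batteries within minutes; they are the scale
at which the group contrasts above were calibrated.
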