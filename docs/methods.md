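# Methods

## Scientific setting

The package analyses a paired-session resting-state fMRI design: the same
cohort is scanned before and after an intervention (here, cataract
extraction with intraocular-lens implantation) and the question is whether
the topology of the brain's functional network differs between sessions,
and whether any topological change tracks behavioral change — psychomotor
vigilance task (PVT) reaction times and the change in blue-light
transmittance produced by the implanted lens.

The analysis chain is:

1. region-mean BOLD time series (116 atlas regions by default);
2. temporal cleaning — discard the first 10 volumes, ordinary-least-squares
   nuisance regression, 0.01–0.08 Hz band-pass;
3. Pearson correlation between every pair of regions;
4. proportional (sparsity) thresholding at densities 0.10–0.50 in steps of
   0.05, binarizing each matrix into an undirected graph with exactly
   round(s·R(R−1)/2) edges;
5. per-graph metrics: per-region clustering coefficient and eigenvector
   centrality; global mean clustering and degree assortativity;
6. per-(metric, threshold, region) sign-flip permutation paired t-tests
   (default 5000 flips) with Benjamini–Hochberg FDR at q = 0.05 within each
   (metric, threshold) family;
7. Pearson correlation of per-subject metric deltas (post − pre) for the
   significant results against behavioral deltas, reported uncorrected and
   BH-adjusted within each behavior family.

## Models and assumptions

**Connectivity.** Functional connectivity is the Pearson correlation of
cleaned region time series. Zero-variance regions are an error, never
silently dropped: a dead region indicates an upstream extraction problem.

**Proportional thresholding.** Edges are ranked by signed correlation —
"strongest" means most positive — with magnitude ranking available behind
the `absolute` flag. The retained edge count is round-half-away-from-zero
of s·R(R−1)/2 (667 edges for R = 116 at s = 0.10). Ties at the cut are
broken by lexicographic (row, column) order so repeated runs are
bit-identical. Because the ranking is fixed per matrix, edge sets are
nested across the grid.

**Graph metrics.** Clustering for a node of degree k with t triangles is
2t/(k(k−1)), defined as 0 for k < 2 and included in the mean (excluding
low-degree nodes would make the mean depend on density in an opaque way).
Eigenvector centrality is the non-negative principal eigenvector of the
adjacency matrix, unit L2 norm, computed by power iteration on A + I (the
shift suppresses the ±λ oscillation of bipartite spectra without changing
eigenvectors) with a dense symmetric eigensolver as fallback; on a
disconnected graph the mass concentrates on the dominant component, which
is the documented behavior — no per-component renormalisation is done.
Assortativity is the Pearson correlation of endpoint degrees with each
undirected edge counted in both orientations; when endpoint degrees have
zero variance (regular graphs) it is undefined and propagates as NaN, and
group statistics then drop the affected subjects pairwise rather than
imputing 0.

**Group inference.** For paired sessions the exchangeability null is that
each subject's pre/post difference is symmetric around zero, so the null
distribution of the paired t statistic is built by random ±1 sign flips of
the difference vector. Two-sided p-values use (b + 1)/(B + 1), so the
smallest attainable p is 1/(B + 1) and no p is ever zero. With n subjects
only 2ⁿ distinct sign patterns exist; below about n = 12 the attainable
p-values are too coarse for FDR-corrected discovery, which is why the
study-scale simulations use n = 34. FDR families are the regions within
one (metric, threshold) pair, matching how per-threshold results are
reported; pooling across thresholds is available via `pool_thresholds`.
Rejection uses strict p_adj < q.

**PVT analytics.** Reaction times are modelled ex-Gaussian
(normal(μ, σ) + exponential(τ)), the standard description of vigilance RT
distributions. Outcomes are mean RT, median RT, and the means of the
fastest and slowest deciles, computed after discarding the first three
(warm-up) trials by index and excluding false starts and >1 s ("too slow")
responses; too-slow inclusion is a flag. The decile size is
max(1, round(0.1·n_valid)); no rounding rule is standard, so the
conventional half-up rule is used. Session comparisons are classical
paired t-tests, mirroring how such behavioral outcomes are analysed.

**Transmittance delta.** Per subject, the eye with the higher transmittance
is selected independently pre and post, and delta = selected post −
selected pre. A missing eye falls back to the available eye (recorded in
the output); a missing session is an error — no imputation from age or
population data is attempted because no defensible formula exists for it.

## Synthetic cohorts: what they emulate and what they do not

`CohortSpec` defaults encode the study conditions: 34 subjects, 116
regions, 290 retained timepoints (300 acquired minus 10 discarded), TR 2 s.
Series are zero-mean multivariate normal draws from a block-modular
correlation matrix (8 communities; within-community correlation 0.35,
between 0.05 — values typical of cleaned region-level BOLD correlation
structure). The post-session effect is planted on the correlation scale:
off-diagonal entries involving the designated effect regions are shifted
by `effect_delta_corr`, then the matrix is projected to the nearest
positive-definite correlation matrix by eigenvalue clipping and diagonal
re-standardisation. This keeps the ground truth in the same units the
pipeline estimates. Two consequences worth knowing:

- the projection and the relative nature of centrality mean a planted
  shift perturbs non-planted regions too, so a strong effect legitimately
  yields discoveries beyond the planted set — recovery is therefore
  measured on the planted regions only, and specificity on null cohorts;
- sessions are exchangeable apart from the planted effect: no scanner
  drift, motion, physiological noise spectra, or autocorrelated BOLD
  dynamics are simulated. Passing tests demonstrate the statistical
  machinery is correct and calibrated, not that real acquisitions meet the
  generator's assumptions.

PVT logs accumulate uniform inter-trial intervals until the 5-minute task
ends (a degenerate fixed ITI of 7.14 s yields exactly 42 trials); with the
default 2–10 s range the expected count is duration divided by the mean
ITI, slightly above the ~42 stimuli a real administration yields once
response and feedback time are included — immaterial for the outcome
statistics, which are per-trial. Transmittance posts are exactly 68% or
95% by lens class; real optical measurements would scatter around the
nominal class values.

## Numerical choices

- Band-pass: order-2 Butterworth applied forward and backward
  (zero-phase, magnitude response squared). At TR = 2 s the 0.04 Hz
  passband tone is preserved to within 5% and a 0.2 Hz tone attenuated by
  >98%.
- Confound regression always includes an intercept; the design must be
  full column rank. The global signal is *not* regressed by default
  (`regress_global_signal` flag), since region-level analyses differ on
  this and the choice materially changes negative correlations.
- Motion QC is strict exceedance: exactly 3 mm or 3° passes.
- Power iteration tolerance 1e-10 on the iterate difference, 10⁴ iteration
  cap before the dense fallback.
- Eigenvalue clipping floor for the positive-definite projection: 1e-6.
- All RNG flows through `numpy.random.Generator` seeded per stage from a
  `SeedSequence` spawn of the run seed; no global RNG state.

## Problem sizes in the test and acceptance runs

Unit tests use cohorts of 6–14 subjects and 8–30 regions. The study-scale
checks use the full 34 × 116 × 290 design: 20 planted-effect and 20 null
replicate cohorts (2000 sign flips per test) for recovery/specificity,
1000 simulated datasets for permutation calibration, and 100 replicate
cohorts for PVT power. The acceptance script reports the same quantities
from 10 replicates per condition and 50 PVT replicates.

## Known limitations

- No weighted-graph or path-based metrics (efficiency, betweenness,
  small-world indices); only the four measures above are computed.
- Spatial preprocessing and CompCor component estimation are out of scope;
  inputs must be cleaned images or extracted series plus confound tables.
- Disconnected-graph eigenvector centrality is global, not per-component.
- The permutation test assumes exchangeable signs of paired differences;
  heavy-tailed but asymmetric difference distributions can bias it.
- The behavioral correlation stage conditions on FDR-significant graph
  results, inheriting the selection effects of that conditioning (as in
  the reporting convention it mirrors).
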