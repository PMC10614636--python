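# Methods

## The analysis in one paragraph

Structural covariance networks (SCNs) treat the correlation of a morphometric
measure — here gray-matter volume (GMV) of atlas regions of interest — across
the subjects of a group as the edge weight of a brain graph. scnkit builds one
such network per diagnostic group as a covariate-adjusted partial-correlation
matrix, compares every pair of groups edge-by-edge with a subject-relabeling
permutation test on Fisher-z correlation differences, collects the regions
touched by any significant edge, scores each region's influence in each
comparison's significant-difference graph by eigenvector centrality, and
finally clusters regions by their centrality profile across the six pairwise
comparisons with elbow-selected k-means. The intended cohort shape is a
4-group transdiagnostic sample (healthy controls, schizophrenia, bipolar
disorder, major depression; 54/17/25/68 subjects).

## Group networks: partial correlation given covariates

For a group with volumes `V` (n subjects x p regions) and covariates age and
sex, every region column is replaced by its least-squares residual against
`[1, age, sex]`, and the network is the Pearson correlation matrix of the
residuals. This is the "pairwise correlation given covariates" reading of
partial correlation. The alternative — inverse-covariance partialling over
all p regions simultaneously — is not estimable here: with p = 61 regions and
groups as small as n = 17 the sample covariance is singular, so the
covariate-residualization form is the only feasible one at these sample
sizes. The two readings coincide for p = 2 regions plus covariates, which is
what the test-suite oracle checks.

Residualization always includes an intercept; a rank-deficient design (e.g. a
constant covariate) is an error, not a silent drop. Zero-variance residual
columns are errors naming the region. The output is exactly symmetric with
unit diagonal, and `n - c - 1` residual degrees of freedom are stored for any
downstream analytic use.

No total-intracranial-volume normalisation or covariance shrinkage is
applied; inputs are taken as the ROI volume table provides them.

## Pairwise comparison: permutation test on Fisher-z differences

The edge statistic for groups A and B is `z(r_A) - z(r_B)` with
`z = atanh` (values clipped at `1 - 1e-7` before transforming). The null
distribution is built by pooling the two groups' subjects and re-splitting
them at random into pseudo-groups of the original sizes `n_perm` times. The
full chain — residualize on age/sex, correlate, Fisher-z, difference — is
recomputed inside every permutation, so the covariate fit is refit under each
relabeling rather than permuting residuals. Two-sided p-values use the
add-one estimator `(1 + #{|perm| >= |obs|}) / (n_perm + 1)`, so the smallest
attainable p-value is `1/(n_perm + 1)`; significance is `p < alpha` strictly.
Consequently `alpha = 0.001` requires `n_perm >= 1000`; the pipeline default
is `n_perm = 10000` and a configuration where `1/(n_perm+1) >= alpha` is
executed but flagged with a warning, since no edge can then be significant.

The computation is internally oriented so that swapping the group arguments
negates the observed difference matrix and leaves p-values and mask
unchanged for the same seed. Diagonals are excluded throughout. No
multiple-comparison correction is applied beyond the stringent default
`alpha = 0.001`; the test suite verifies type-I-error calibration directly
(null rejection rate at alpha = 0.05 inside the binomial 99% band over 528
null edges).

Region-level significance is the *endpoint union*: a region is significant if
it is an endpoint of at least one masked edge in at least one comparison.

Comparison labels follow the convention of the motivating cohort: each
unordered pair is written with the later-alphabetical group first and pairs
are sorted by label, which for HC/SCH/BD/MDD yields
HC-BD, MDD-BD, MDD-HC, SCH-BD, SCH-HC, SCH-MDD.

## Eigencentrality with a uniform 1/N baseline

Each comparison's weight matrix is `|delta_z|` on masked edges, zero
elsewhere, restricted to the significant-region union (weights must be
nonnegative for a Perron eigenvector to exist, and influence is treated
unsignedly). Centrality is the dominant eigenvector of the largest connected
component (most edges; ties by total weight), computed by power iteration on
`W + sI` with `s` = max row sum — the shift leaves eigenvectors unchanged but
guarantees convergence on bipartite components (a bare edge, a star), where
unshifted power iteration oscillates. The vector is L1-normalized to sum 1
over the component. Every node outside the dominant component, including
isolated nodes, is assigned the uniform baseline `1/N` with N the union
size.

The baseline convention is a deliberate interpretation: in the packaged
61-region reference table the value 0.0164 = 1/61 recurs across many cells,
which is exactly the uniform value for N = 61; assigning `1/N` to nodes
outside the dominant difference component is the only convention we found
consistent with that table. Power iteration uses tolerance 1e-10 on the L1
change and at most 10,000 iterations; non-convergence is an error reporting
the residual. The implementation is checked against a dense
eigendecomposition oracle and networkx up to N = 50 (1e-8).

HITS hub/authority scores (the standard coupled `a <- W'h`, `h <- Wa`
iteration, L1-normalized) are available for directed or asymmetric-weight
variants; on the symmetric matrices of this pipeline hubs equal authorities.

## Clustering regions by centrality profile

Profiles are the raw per-comparison eigencentrality vectors — six columns,
Average excluded (it is a summary of the features, not a feature), no
standardisation (all columns already share the eigencentrality scale, and
z-scoring would distort the uniform-baseline structure). K-means is Euclidean
best-of-`n_init` restarts (default 100) with a required seed. The elbow is
operationalised automatically as the k with maximum discrete curvature
(second difference) of the inertia curve over a contiguous scan range
(default 1..10), ties to the smaller k.

Two properties of this criterion are worth knowing. First, it favours k = 2
whenever the k=1 to k=2 inertia drop dominates — e.g. three blobs whose
between-blob distances are strongly unequal get k = 2, while equidistant
blobs get k = 3; the automatic elbow is a blunt instrument on curves without
a sharp angle. Second, on the packaged reference matrix it selects k = 2
(curvature 0.0114 at k=2 vs 0.0010 at k=4), not the k = 4 the reference
analysis reports; kneedle-style chord distance gives k = 3. The published
k = 4 evidently reflects a curve computed from unrounded centralities and/or
visual inspection and is not recoverable from the 4-dp-rounded table by any
automatic criterion we tried (curvature, kneedle, silhouette,
Calinski-Harabasz, Davies-Bouldin, gap statistic, under several
normalisations).

Relatedly, the reference table's printed 4-cluster partition is an exact
Lloyd fixed point of k-means on the printed values (every region is nearest
its own printed-cluster centroid) but not the inertia-optimal one: its
within-cluster sum of squares is 0.02378 versus 0.02283 for the
best-of-100-restarts solution, and roughly 0.4% of random single
initialisations converge to it. Best-of-restarts k-means therefore lands
elsewhere (ARI ~ 0.33 against the printed labels), which is why cluster
reports should always record seed and restart count — this package refuses
to default the seed.

Reports renumber clusters so cluster 1 has the highest mean Average and sort
within clusters by Average descending, matching the reference table's
layout; all values print at 4 decimals.

Degenerate cases: a union of only 1-2 regions leaves the curvature
undefined, and each region becomes its own cluster; duplicate profile rows
can collapse clusters, in which case the effective number of distinct
clusters is recorded as k.

## Synthetic cohorts and what they do (not) emulate

The generator produces `v_ij = mu_j + beta_age * age_i + beta_sex * sex_i +
noise_sd * u_ij`, with ages uniform on [18, 65] (the cohort's eligibility
bounds), sex Bernoulli with the cohort's overall female proportion (0.69),
and `u` a unit-variance Gaussian with block-structured correlation: region j
in block b loads `sqrt(rho)` on a latent block factor; a planted edge
(i, j, delta) adds a pairwise shared factor with loadings `sqrt(|delta|)`
and `sign(delta) * sqrt(|delta|)`; an optional per-(group, block) rho
override expresses dense within-block group differences that pairwise
factors cannot (their |delta| contributions would exceed a region's unit
variance budget). Idiosyncratic variance tops each region up to exactly 1,
so the implied correlation matrix is positive semi-definite by construction;
budget violations are configuration errors naming the region, and the
assembled matrix is eigenvalue-checked as a guard.

Defaults mirror the motivating cohort: group sizes 54/17/25/68, 61 regions
named after the packaged atlas labels, six covariance blocks, baseline
within-block correlation 0.5, `beta_age = -0.02` per year (about one
residual SD of decline across the 47-year age range, a realistic GMV aging
effect on this scale), `beta_sex = 0.5`, `noise_sd = 1` (volumes are in
arbitrary units; only the correlation structure matters downstream).

What the generator does *not* emulate: measurement noise correlated with
head size or scanner, non-Gaussian volume distributions, nonlinear age
effects, site effects, or realistic morphometric means — only the
covariance structure the analysis consumes, plus linear covariate effects.
Passing recovery tests therefore show that the pipeline correctly inverts
its own generative assumptions at realistic sample sizes, not that those
assumptions hold for real MRI data.

## Study designs used by the recovery tests

Problem sizes were chosen by a priori power and false-positive arithmetic
and confirmed by small pilots, to give sharp expected outcomes at the
motivating cohort's group sizes:

* **Union recovery** — 12 regions, 5 disjoint edges covering 10 regions
  planted at rho 0.85 in HC only, alpha = 5e-4, n_perm = 3999, 100 replicate
  cohorts. The expected count of false-positive edges touching the 2
  unplanted regions is ~0.06 per cohort, while every planted edge is
  near-certainly detected in the well-powered HC-MDD comparison; exact union
  recovery is required in >= 90/100 cohorts.
* **Cluster recovery** — 12 regions in 3 blocks of 4, each block's
  within-correlation raised to 0.9 in one designated group (MDD, BD, HC),
  alpha = 0.05 for dense masks, n_perm = 999, 10 replicate cohorts;
  adjusted Rand index 1.0 against the planted partition is required in >= 8
  of 10 with median 1.0.
* **Calibration** — one homogeneous cohort split into pseudo-groups of 60,
  33 independent regions (528 null edges), alpha = 0.05, n_perm = 999;
  the rejection count must lie in the binomial 99% band.

The demonstration study driven by the `analysis/` scripts runs the full
61-region pipeline at the cohort's real sizes (alpha 0.001, n_perm 4999,
planted block contrasts of Fisher-z ~1.27) and reports the honest outcome:
high edge-detection power in the large-group contrasts, weak power where
schizophrenia's n = 17 is involved, and correspondingly partial
profile-cluster recovery. Exact recovery under uniformly powered designs is
established by the test suite, not by the demonstration.

## Numerical choices

* Fisher-z clip at `|r| = 1 - 1e-7` (z ~ 8.3) keeps duplicated-region edges
  finite without materially affecting any realistic statistic.
* Least squares via QR/lstsq; the permutation inner loop uses a QR
  projection that is machine-precision-identical to the validated public
  path, and the observed statistic used for counting comes from the same
  fast path so boundary ties are bitwise consistent.
* Permutation p-values use the add-one estimator; masks use strict `p <
  alpha`.
* Power iteration and HITS: uniform start, L1 tolerance 1e-10, max 10,000
  iterations; dominant-component ties broken by edge count, then total
  weight, then first index.
* K-means: scikit-learn `KMeans`, seed required, `n_init` best-of restarts;
  elbow ties to the smaller k.
* All written matrices default to 4 decimals; volume tables round-trip at 6
  significant digits.

## Known limitations

* The covariate-residualization reading of partial correlation does not
  remove indirect region-mediated dependencies (that reading is infeasible
  at these sample sizes; see above).
* The automatic second-difference elbow is geometry-sensitive (see above)
  and should be read alongside the full inertia curve, which every report
  includes.
* Permutation tests assume exchangeability of subjects across groups under
  the null given the covariates; strong group differences in covariate
  distributions would weaken this.
* The 1/N baseline convention for nodes outside the dominant component is a
  reverse-engineered interpretation of the reference table, documented
  rather than established.
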