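# scnkit

Structural covariance network (SCN) comparison for ROI gray-matter
volumetrics: per-group covariate-adjusted partial-correlation networks,
permutation-based pairwise group comparison, eigencentrality profiling of the
significant difference networks, and k-means clustering of regions by
centrality profile.

## Who this is for

Neuroimaging groups with a multi-group morphometry cohort — subject metadata
(group, age, sex) plus a subjects x regions table of atlas ROI gray-matter
volumes — who want to ask: *which brain regions' covariance structure
distinguishes which diagnoses, and which regions behave alike across
contrasts?* The package starts from plain TSV/CSV tables; image
preprocessing and parcellation are out of scope.

## The method

For each group g, the network is the partial-correlation matrix

    r_g[i, j] = corr( resid(V_i | 1, age, sex), resid(V_j | 1, age, sex) )

over region volumes V, removing linear age/sex effects. (Full
inverse-covariance partialling over all p regions is singular when p exceeds
the group size — here p = 61 vs groups as small as n = 17 — so the
covariate-residualization reading is used.) For every pair of groups (A, B)
the edge statistic is the Fisher-z difference `atanh(r_A) - atanh(r_B)`, with
a null distribution built by pooling the two groups' subjects and re-splitting
them `n_perm` times, refitting the covariate adjustment inside every
permutation; two-sided p-values use the add-one estimator and edges with
`p < alpha` (default 0.001) form the significance mask. Regions touched by
any significant edge form the region union; each comparison's masked
`|delta z|` graph is scored by eigenvector centrality (dominant connected
component, L1-normalized; nodes outside it sit at the uniform baseline 1/N),
giving a regions x comparisons profile matrix whose rows are clustered by
best-of-restarts k-means with elbow-selected k. A synthetic cohort generator
with planted, provably-PSD covariance structure supports end-to-end
parameter-recovery testing. Details and design rationale: `docs/methods.md`.

## Worked example

The numbered scripts under `analysis/` run the whole method on a synthetic
164-subject, 4-group cohort (54 HC / 17 SCH / 25 BD / 68 MDD, 61 regions)
with three covariance blocks elevated to rho 0.9 in one group each:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_build_networks.py
python analysis/03_compare_and_profile.py
python analysis/04_cluster_regions.py
python analysis/05_reference_matrix_checks.py
```

Script 03 prints, for alpha = 0.001 and n_perm = 4999:

```
  HC-BD      72 significant edges
  MDD-BD     83 significant edges
  MDD-HC    102 significant edges
  SCH-BD      2 significant edges
  SCH-HC     30 significant edges
  SCH-MDD    19 significant edges
significant-region union: 35 of 61 regions
   pair  n_true  tp  fp   tpr   fpr
  HC-BD      90  71   1 0.789 0.001
 MDD-BD     100  82   1 0.820 0.001
 MDD-HC     100 100   2 1.000 0.001
 SCH-BD      45   2   0 0.044 0.000
 SCH-HC      45  29   1 0.644 0.001
SCH-MDD      55  19   0 0.345 0.000
```

Read: each planted block difference is detected nearly completely in the
well-powered contrasts (true-positive rate 0.79–1.00 with false-positive
rate at the nominal 0.001), while contrasts hinging on the 17-subject
schizophrenia group are underpowered — the same sample-size asymmetry the
motivating cohort carries. Script 04 then clusters the 35 profiled regions
and reports agreement with the planted blocks (partial at these sizes,
0.59 ARI at k = 4; the test suite demonstrates exact recovery under
uniformly powered designs). Script 05 desk-checks the packaged 61-region
reference eigencentrality matrix:

```
Average column recomputation over 61 rows: max |error| 6.7e-05
uniform baseline for an empty 61-region network: 0.0164 (reference filler value 0.0164)
max-curvature elbow selects k = 2 (reference reports k = 4; ...)
printed partition is a Lloyd fixed point: True; its WSS 0.02378 vs best-of-restarts 0.02283
```

The last two lines are findings, not failures: on the published
(4-dp-rounded) matrix no automatic elbow criterion yields k = 4, and the
published 4-cluster partition is a genuine k-means fixed point that
best-of-restarts k-means improves upon — see `docs/methods.md`.

The same pipeline is available as a CLI for real tables:

```sh
scn run --config my_study.yaml          # full pipeline from a YAML config
scn build-scn --participants p.tsv --volumes v.tsv --out nets/
scn compare --participants p.tsv --volumes v.tsv --out comps/ \
    --alpha 0.001 --n-perm 10000 --seed 7
scn profile --masks comps/ --out profiles.tsv --hits
scn cluster --profiles profiles.tsv --out clusters/ --seed 7
```

Inputs: a participants table with columns `subject_id, group, age, sex`
(sex as M/F or 0/1) and a volumes table whose first column is `subject_id`
and whose remaining columns are atlas region names. `.tsv`/`.csv` extensions
select the delimiter.

## Layout

```
src/scnkit/          library: tabular_io, synthetic_cohort, scn_build,
                     network_compare, centrality_profile, node_clustering,
                     pipeline, cli (+ packaged reference matrix in data/)
analysis/            numbered narrative drivers writing to results/
tests/               pytest suite incl. acceptance criteria
docs/methods.md      model, conventions, numerical choices, limitations
scripts/acceptance.py
```
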