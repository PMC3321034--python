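# mesrec

Association of a mesenchymal-transition gene-expression signature with time
to tumor recurrence in glioblastoma, as a tested, reusable pipeline.

A 64-gene signature of coordinated epithelial–mesenchymal-transition (EMT)
markers — Slug (SNAI2), collagens, FN1, POSTN, and related extracellular-
matrix genes — is summarized per tumor sample as a **metagene**: the
unweighted mean of the genes' log2 normalized expression. The package asks
whether patients with exceptionally long time to recurrence after therapy
have *low* metagene levels, using a rank-sum statistic with an exact
combinatorial null:

- rank the n responders by metagene score (rank 1 = lowest);
- sum the ranks R of the k patients whose tumors recurred more than three
  years after treatment;
- evaluate P(R ≤ r_obs) exactly as
  `#{k-subsets of {1..n} with sum ≤ r_obs} / C(n, k)`, counted by integer
  dynamic programming, with a seeded 10⁷-permutation estimator as a
  cross-check.

Around that core the package provides: a genome-wide single-gene rank-sum
scan, Kaplan–Meier / log-rank comparison of a median metagene split, Cox
proportional-hazards regression (univariate, and multivariate with the four
glioblastoma subtypes in sum-to-zero coding), ten-nearest-neighbor subtype
imputation, mutual-information and fold-change gene rankings, hypergeometric
signature enrichment, and a synthetic cohort generator (latent-activity
factor model with Weibull recurrence times) that supplies ground truth for
every statistical claim in the test suite.

It is written for computational biologists analyzing expression matrices
(TSV or GCT 1.2) with clinical time-to-event annotations, and for anyone who
wants an exact, reproducible reference implementation of the bounded-sum
distinct-rank null distribution.

## Worked example

Simulate a GBM-sized cohort (545 samples, ~99 responders, 64 signature
genes + 2,000 background genes) and run the full pipeline:

```bash
cat > config.yaml <<EOF
seed: 7
out_dir: demo_out
simulate:
  n_samples: 545
  n_background_genes: 2000
threshold_days: 1095
n_perm: 1000000
scan: true
EOF
mesrec run --config config.yaml
cat demo_out/ranksum.tsv
```

```
n	90
k	7
member_ranks	1,2,3,4,8,10,13
rank_sum	41
p_exact	4.39009e-08
p_mc	0
mc_se	0
```

Of the 90 simulated responders, the 7 with recurrence beyond 1,095 days sit
at ranks 1,2,3,4,8,10,13 of the metagene ranking — a rank sum of 41, with
an exact null probability of 4.4×10⁻⁸ (the 10⁶-permutation estimate is 0:
at this depth the expected hit count is below one, which is exactly why the
exact DP value is the one to report). The accompanying `scan.tsv` shows the
best *single* gene in the same cohort reaches only rank sum 43
(`head -3 demo_out/scan.tsv` → `CRISPLD2 43`, `THY1 44`): averaging the
signature beats every individual component, the synergy property the
statistic is designed to expose. `logrank.tsv` reports the median-split
Kaplan–Meier comparison (chi² = 93.07, p = 5.0×10⁻²²) and
`cox_univariate.tsv` the continuous-metagene Cox fit; `km.png` and
`manifest.json` (seed, versions, config hash) complete the run.

Every stage is also a standalone subcommand (`mesrec simulate | metagene |
ranksum | scan | survival | impute-subtypes | mi-rank | foldchange |
enrich`) and a plain library call (`mesrec.rank_sum_test`,
`mesrec.exact_null_pvalue`, `mesrec.cox_multivariate_deviation`, ...).

## Layout

```
src/mesrec/
  core_types.py      expression matrices, clinical tables, signatures, IO
  synthetic_data.py  latent-factor cohort generator with ground truth
  metagene.py        metagene scoring, centroid-difference signatures
  rank_association.py  rank sum, exact DP null, permutation null, scan
  survival.py        KM/log-rank, Cox (lifelines, Efron ties)
  subtype_impute.py  kNN subtype imputation
  gene_association.py  Pearson, mutual information, fold change, enrichment
  cli.py             click CLI and pipeline orchestration
  data/emt_signature_64.txt  the 64-gene EMT signature
docs/methods.md      model, estimators, numerical choices, limitations
```
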