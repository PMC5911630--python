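# survscreen

Median-split survival screening of gene-expression biomarkers, with a
composite hazard-ratio score for prioritizing therapeutic targets.

## The problem

In prognostic-biomarker studies of gastric cancer (and solid tumors
generally), a candidate gene is evaluated by splitting a patient cohort
at the median of the gene's expression and asking whether the
high-expression half dies faster over a 5-year window. Each gene in each
clinical subgroup (disease stage, Lauren histology, HER2 status,
treatment arm) yields a hazard ratio and a log-rank p-value; comparing
dozens of such pairs across gene sets by eye is error-prone.
`survscreen` implements that screen end to end as a tested library:

1. **Stratify** — dichotomize a gene's expression at the cohort median
   (high iff value > median; ties at the median go low), recomputed
   inside each clinical subgroup.
2. **Survival fit** — Kaplan–Meier curves, the log-rank test, and a
   univariate Cox proportional-hazards fit for the high/low indicator
   (Newton–Raphson, Efron tie correction), restricted to a 60-month
   horizon (5-year overall survival).
3. **Score** — the composite HR score for a gene set of size *n*:

   ```
   score = 100/n · Σᵢ (HRᵢ − 1) · (−log₁₀ pᵢ)
   ```

   Signed: a protective marker (HR < 1) contributes negatively. Scores
   strictly above 300 are classified as significant targeting value.
4. **Prioritize** — tumor-vs-normal expression comparison (paired or
   pooled-variance Student t-test) and a ranking rule: genes significant
   in more subgroups rank first, ties broken by mean score; genes whose
   tumor expression is not elevated are demoted.

A synthetic-cohort generator with known planted effect sizes (log-normal
expression, exponential event times whose hazard depends on the
median-split indicator, exponential dropout plus administrative
censoring at 60 months) makes every stage testable without patient data.
A small IUPAC consensus-motif counter covers the downstream promoter
analysis (counting C/EBP- and PPARα-style binding elements in a
TSS−1500 bp window).

## Worked example

```python
import numpy as np
import survscreen as ss

cfg = ss.SimulationConfig(n_patients=800, n_genes=3,
                          log_hr_by_gene={"ACSS3": np.log(2.0)}, seed=17)
cohort = ss.simulate_cohort(cfg)
table = ss.run_screen(cohort, ["ACSS3", "G1", "G2"],
                      [ss.SubgroupSpec("all"), ss.SubgroupSpec("stage", "3")])
print(table[["gene", "subgroup", "n", "n_events", "hr",
             "logrank_p", "score", "significant"]].to_string(index=False))
```

```
 gene subgroup   n  n_events     hr  logrank_p    score  significant
ACSS3      all 800       516  2.207  3.762e-19     2223         True
ACSS3  stage=3 326       211   2.06  1.626e-07    719.6         True
   G1      all 800       516 0.9902     0.9105 -0.04007        False
   G1  stage=3 326       211  1.166     0.2656    9.535        False
   G2      all 800       516 0.9182     0.3329   -3.907        False
   G2  stage=3 326       211 0.7562    0.04325   -33.26        False
```

The planted gene (true HR 2.0) is recovered with HR ≈ 2.2 and a score
far above the 300 threshold in both cohorts; the two null genes hover
near score 0. Adding a paired tumor/normal comparison and ranking:

```python
paired = ss.simulate_paired_expression(
    ss.PairedConfig(n_pairs=34, log_fold_change=0.8, noise_sd=0.4, seed=17))
comp = ss.compare_expression(paired["normal"], paired["tumor"], "paired",
                             gene="ACSS3")
print(ss.rank_targets(table, [comp]).to_string(index=False))
```

```
 rank  gene  n_significant  mean_score expression_support
    1 ACSS3              2      1471.4          supported
    2    G1              0         4.7 no-expression-data
    3    G2              0       -18.6 no-expression-data
```

Single published (HR, p) pairs can be scored directly:

```sh
$ survscreen score --hr 2.11 --p 2.8e-12
HR score = 1282.4 (significant)
```

The same CLI exposes `simulate cohort|paired|promoter`, `screen`,
`compare`, `rank`, and `motifs` subcommands; see `survscreen --help`.

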