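# Methods

## The screening model

`survscreen` treats each candidate gene as a dichotomous prognostic
marker. Within a cohort (or clinical subgroup), the gene's expression
vector is split at its sample median; the survival experience of the
high group (expression strictly above the median) is compared with the
low group under a proportional-hazards assumption:

    h_high(t) = HR · h_low(t)

The screen reports, per (gene, subgroup) cell: the Cox estimate of HR
with a 95% Wald interval, the log-rank p-value, and the composite score

    score = 100/n · Σᵢ (HRᵢ − 1) · (−log₁₀ pᵢ)

over the n genes of a set (n = 1 for per-gene screening). The score is
the product of an effect-size term (HR − 1) and an evidence term
(−log₁₀ p), averaged over the set and scaled by 100; scores strictly
above 300 are classified as significant targeting value, 300 or below
as not. The signed form is used: protective markers (HR < 1)
contribute negatively, which is what makes negative scores for
favorable genes representable. An `absolute=True` switch rectifies the
effect term for users who want magnitude-only screening.

The p-value entering the score is the **log-rank** p, not the Wald p;
both are computed and stored. Within the screen, p-values are clamped
at 1e-300 so that chi-square tail underflow on extreme markers produces
a finite (huge) score rather than an error; the standalone scoring
function instead rejects p below that floor unless the caller passes an
explicit `p_floor`.

## Survival estimation

* **Kaplan–Meier**: the standard product-limit estimator; censored
  observations reduce risk sets only. With no censoring it equals
  1 − ECDF at every event time (asserted in tests).
* **Log-rank test**: observed-minus-hypergeometric-expected events in
  the high group accumulated over pooled event times, with the usual
  variance term; the statistic is referred to chi-square with 1 df.
* **Cox fit**: the partial likelihood for the single binary covariate is
  maximized by Newton–Raphson from β = 0 with the **Efron** correction
  for tied event times. Median-split markers on coarsely recorded
  follow-up produce heavy ties, for which Efron is substantially more
  accurate than Breslow. Convergence requires |score function| < 1e-9
  (max 50 iterations); step-halving guards against likelihood
  decreases, with a relative slack of 1e-9·(|ℓ| + 1) in the comparison
  so that floating-point noise in a partial log-likelihood summed over
  thousands of events cannot reject the final quadratic-convergence
  steps. Risk-set sums are computed from suffix cumulative sums over
  the time-sorted sample, so one evaluation costs O(n log n).
* **Monotone likelihood** (complete separation) is detected as |β|
  exceeding 15 (HR beyond e¹⁵); such fits return `converged = False`
  with a (0, ∞) confidence interval rather than a silently absurd
  estimate, and the screen records the cell as failed with reason
  `nonconvergence`.
* **5-year restriction**: follow-up is clipped at a 60-month horizon,
  with later events recoded censored-at-60. This is the screen's
  default (`horizon=60`), togglable or disabled with `horizon=None`.
* The 95% interval uses z = 1.95996.

## Dichotomization conventions

The sample median is the midpoint of the two central order statistics
for even n. Ties at the exact median are assigned **low**; the
convention is arbitrary but fixed and stated, because with heavily tied
expression values it changes group sizes. A marker that is constant, or
whose median equals its maximum (empty high group under ties-go-low),
is rejected as degenerate — in the screen this becomes a failed cell
with reason `constant_marker`. Subgroup analyses **recompute** the
median inside each subgroup rather than inheriting the full-cohort
split, matching the practice of running a survival analyzer separately
per sub-cohort.

## Synthetic cohorts

The generator emulates the structure of a web-scale gastric-cancer
microarray survival cohort:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 876 | cohort size (the all-patients meta-cohort size) |
| `baseline_hazard` | 0.015 /month | exponential event rate for all-low patients (≈59% 5-year event fraction) |
| `log_hr_by_gene` | `{}` | true log HR of each prognostic gene's high group |
| `censor_horizon` | 60 months | administrative cut (5-year OS) |
| `random_censor_rate` | 0.005 /month | independent exponential dropout |
| `expression_meanlog`, `expression_sdlog` | 6.0, 1.0 | log-normal marker intensity |

Event times are exponential — a constant baseline hazard — because no
baseline shape is implied by the screen itself and the exponential
makes closed-form and parameter-recovery oracles possible. The true
hazard covariate is the **median-split indicator**, not continuous
expression, so recovery experiments measure estimation error rather
than deliberate misspecification. Subgroup labels are drawn
independently per patient: HER2 (neg 532/876, pos 344/876) and
treatment arm (surgery 380/876, 5FU+surgery 153/876, other the
remainder) follow the printed sub-cohort sizes of the meta-cohort being
emulated; stage (15/25/40/20%) and Lauren histology (55% intestinal /
45% diffuse) are field-typical values chosen once, since no sub-cohort
sizes are printed for them. The censoring scheme (exponential dropout
plus a fixed horizon) is an assumption: the real cohorts' censoring
distribution is unknown.

What the generator does **not** emulate: correlated expression blocks
(co-regulated pathways), non-proportional hazards, informative
censoring, batch effects, or any coupling between subgroup labels and
expression. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated model, not robustness to these
real-data features.

Paired tumor/normal tables use a shared per-pair baseline
(Normal(8, 1), a log2-microarray-like scale) plus independent
measurement noise on each arm and a constant tumor log-fold shift; 34
pairs is the default, matching the matched-pair count of the TCGA
gastric set the comparison step targets.

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical configs are bit-reproducible.

## Expression comparison and ranking

Matched designs use a one-sample t-test on paired differences (exactly
zero differences give t = 0, p = 1; constant nonzero differences are a
degeneracy error, not an infinite statistic). Unmatched designs use the
classical pooled-variance Student t, with Welch behind a flag. Ranking
orders genes by the count of subgroups with a significant score, then
by mean score; genes whose tumor mean is not above their normal mean or
whose comparison p ≥ 0.05 are demoted below all supported genes. Genes
lacking a comparison are flagged `no-expression-data` and placed
between supported and unsupported genes — the rule only pins
unsupported genes below supported ones, and absence of evidence is
treated as weaker than evidence of absence. Absolute expression
intensity (a practical criterion for druggability) is deliberately not
formalized: no intensity floor is defensible from the screen's inputs
alone.

## Promoter motif counting

Binding elements are counted as IUPAC consensus matches, overlapping
occurrences included, on the forward strand plus (by default) positions
where the pattern's reverse complement matches. Consensus matching
keeps the operation deterministic and oracle-testable;
position-weight-matrix scanning is an extension point, and published
binding-element counts that depend on unstated matrices and thresholds
are treated as context rather than validation targets. A sequence `N`
matches nothing except a pattern `N`. The planted-motif simulator
places non-overlapping copies uniformly over all valid placements via
the gap bijection, so plant-and-recover tests are exact.

## Problem sizes used in validation

Validation simulations use: 50 random small datasets (n 15–40, with
ties) for the cross-library Cox/log-rank agreement check at 1e-6
relative; 200 seeds at n = 600 for parameter recovery (mean log-HR
within 0.05 of log 2, CI coverage within [0.90, 0.98]); 100 seeds × 10
null genes at n = 300 for the global-null screen false-significance
rate (< 5%); and 1000 seeds for paired-t null uniformity. These sizes
give binomial/Monte-Carlo error well inside the asserted margins while
keeping the suite fast on one CPU.

## Known limitations

* Univariate only: no multivariate adjustment, stratified baselines, or
  time-dependent covariates.
* No multiple-testing correction across genes — the composite score's
  fixed threshold is the screen's only significance gate, by design.
* The >300 threshold is a screening convention, not a calibrated error
  rate; its null behavior depends on cohort size (the global-null test
  characterizes it at n = 300 only).
* Optimal-cutpoint scanning and tertile/quartile splits are out of
  scope; the median split is the screen's definition.
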