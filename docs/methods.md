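# Methods

This note records the statistical procedures implemented in `sigeval`, the
conventions chosen where several were defensible, and what the synthetic
generators do and do not establish.

## Summary scores

A signature score collapses the expression of a signature's genes in one
sample into one number. Ten scores are functions of the gene-value vector
alone; four place each gene relative to the other samples first.

| score | definition | notes |
|---|---|---|
| mean, median | arithmetic mean; midpoint-convention median | |
| mode | half-sample mode | iterative halving to the densest half; final midpoint; ties toward the median |
| midrange | (min + max)/2 | |
| midhinge | (Q1 + Q3)/2 | |
| trimean | (Q1 + 2·Q2 + Q3)/4 | equals (midhinge + median)/2 |
| IQR | Q3 − Q1 | dispersion |
| IQM | mean of values v with Q1 ≤ v ≤ Q3 | needs ≥ 4 values; fewer raises a dedicated insufficient-genes error |
| MAD | median of \|v − median\| | unscaled |
| AAD | mean of \|v − mean\| | |
| z-score | mean of per-gene z (gene standardized across samples, n−1 sd) | zero-variance genes excluded with a warning |
| NCS | mean of per-gene min-max scaled values | always in [0, 1]; zero-range genes excluded |
| ssGSEA | sum of the running difference between the rank-weighted in-set CDF (weight \|rank\|^α, α = 0.25) and the uniform out-of-set CDF | single-sample variant (sum, not maximum); depends only on within-sample ranks |
| GSVA | gene-wise kernel CDF across samples (gaussian, bandwidth sd/4, or empirical), per-sample ranking symmetrized about the center, KS-like walk with weight exponent τ = 1 | enrichment = max positive deviation + min negative deviation ("difference of extrema") |

Conventions shared by all quartile-based scores: quartiles by linear
interpolation of order statistics at 1 + (n−1)p (numpy's default, "type
7"). The literature that motivates this inventory names "Mean Absolute
Deviation" and "Average Absolute Deviation" without formulas and uses MAD
ambiguously; both variants are exposed under the definitions above. The
NCS formula is likewise not pinned publicly; min-max-mean is the
documented substitute. The z-score aggregates as a mean (not sum/√k) so
scores are comparable across signature lengths, which the accuracy
comparisons require. Missing signature genes are intersected away with a
warning and a recorded `n_genes_used`; nothing is imputed. Scores are
computed on the matrix as provided (log or linear) — no automatic
transformation. First-principal-component-style scores (PC1, PLAGE) are
deliberately absent: their sign is arbitrary, so the directional
comparison against random sets is undefined for them.

## The random-gene-signature (RGS) null

For a signature of effective length k (genes matched in the measured
universe), n_RGS = 1000 gene sets of length k are drawn uniformly without
replacement from the measured universe (not the whole genome). Draws may
include the signature's own genes by default — a random set legitimately
can — with an exclusion flag available. Sets are drawn once per
(signature, dataset, method) and reused across pairs, which keeps accuracy
indices comparable across pairs and is cheaper; a per-pair mode exists
behind a flag.

The permutation p-value is p = 1 − percentile/100 + ε, where the
percentile counts null statistics *strictly* below the observed one and
ε = 1/(n_RGS + 1) truncated to four decimals (0.0009 at 1000) keeps p away
from zero; p is clamped at 1 (the raw formula can reach 1 + ε). A
direction gate forces p = 1 when the effect points the wrong way: strictly
greater hypoxic score (bulk), strictly greater hypoxic median (single-cell,
gate on by default and configurable), strictly greater tumor mean
(clinical). Note an internal tension in the source framework's own
threshold rationale: "five outperforming RGS" corresponds to 5/1001 =
0.0049, but the p formula at percentile 99.5 yields 0.0059 > 0.005, so in
practice only ≤ 4 outperformers pass at the 0.005 threshold. The formula is
implemented as printed; the inconsistency is documented, not repaired.

Bulk significance uses p ≤ 0.005 (inclusive); single-cell uses p < 0.005
(strict) — both exactly as the conventions they reproduce. Pairs whose
score is undefined (e.g. IQM under four matched genes) are excluded from
accuracy denominators with a reported count, never treated as failures.

Platform coverage filter: a platform is excluded when strictly more than
20% of signatures are each missing strictly more than 20% of their genes
from the platform's measured universe.

## Wasserstein distance (single-cell)

The order-2 Wasserstein distance between the two empirical cell-score
distributions is computed as the exact integral of (Qx − Qy)² between the
merged ECDF breakpoints (the quantile functions are step functions, so the
integral is a finite sum). For equal sample sizes this reduces exactly to
the root-mean-square of sorted pairwise differences, which is also the
independent oracle used in tests. The distance, not its square, is the
statistic; under the permutation null the two are monotone-equivalent.

## Clinical testing

One-sided Mann-Whitney U ("tumor stochastically greater"), exact when the
combined sample size is ≤ 16 and tie-free, otherwise the normal
approximation with tie and continuity correction (delegated to scipy; the
exact branch is cross-checked against full rank enumeration in tests). The
gate compares group means, as the evaluation rule it mirrors prescribes —
note that rule's prose describes "stochastically greater" with the CDF
inequality written in the wrong direction; the named hypothesis is the one
implemented. The SPI counts RGS p-values *strictly* greater than the
signature's ("higher"; ties do not count), with every RGS evaluated on the
same group sizes and through the same gated procedure as the signature
(symmetric treatment — whether the original procedure gated the RGS
p-values is not stated). Bonferroni threshold: 0.05/(S × C); 7.14e−5 at
S = 70, C = 10.

## Survival

Follow-up is administratively censored at the 60-month horizon (events
after it become censorings at the horizon). Kaplan-Meier estimation and
the log-rank test delegate to lifelines; the log-rank test is verified
against a hand-worked six-subject observed/expected table (χ² = 32/433).
The percentile scan dichotomizes the score at each of the ten percentiles
50, 55, …, 95 (same type-7 quantile convention as the scores), with
"high" = score strictly above the threshold so ties go low and the high
group is at most (100 − q)% of the cohort; a split leaving a group empty
is reported as undefined for that percentile. A percentile is significant
at p ≤ 0.005 = 0.05/10.

## Synthetic generators

The generators realize exactly the structure each evaluator assumes — no
more. Bulk: per-gene baseline μ_g ~ U(1, 8) on the natural-log scale,
per-sample noise N(0, sd), an additive log-scale effect on signature genes
in hypoxic samples, exponentiated to a linear-scale matrix; series of
2 + 2 samples; optional per-platform gene removal to exercise the coverage
filter. Defaults (2000 genes, 20 signature genes, effect 2.0, noise sd
0.3, 25 series = 100 pairs) are the validation conditions. Single-cell:
negative-binomial counts (gamma-distributed gene means, dispersion 0.5),
independent dropout (default 0.3), multiplicative fold-change (default
4.0) on signature genes in hypoxic cells, 150 cells per condition.
Clinical: tumor samples carry a 1.5 log-unit shift on signature genes
across 10 cohorts of 50 tumor + 30 NAT; tumor survival is exponential
(baseline hazard 0.01/month), multiplied by 3 for the top 20% of tumors by
realized planted-signature score, with independent exponential censoring
calibrated to ~30% and no records for NAT samples.

What passing tests on these data do **not** show: robustness to gene-gene
correlation, batch effects, library-size variation, doublets or ambient
RNA, non-exponential hazards, or informative censoring — none of which the
generators model. The framework's statistical calibration (null accuracy
below 1%, scan false-positive rate ~4% over seeds) and its power under the
stated planted effects are what they establish.

## Registry statistics

The packaged registry holds the metadata of the 70 published hypoxia
signatures surveyed in the field: name, derivation class (clinical /
in-vitro / both), a clinical-derived flag (35 of 70), tissue, and two size
columns — the originally published gene count and the post-reannotation
count. Statistics can be computed on either basis because the printed
headline numbers mix them: the maximum (759, Starmans) and the medians
(24 overall, 14 clinical-derived) hold on the original counts, while the
mean of 55 reproduces only on the post-reannotation counts
(3838/70 = 54.83, rounded half-up); the original-count mean is 56.19. The
registry exposes both columns so either basis can be queried rather than
assumed. Median uses the midpoint convention for even counts; integer
reporting rounds half-up.

## Numerical and reproducibility choices

- One seed per run; the CLI derives per-signature RGS seeds by fixed
  offsets, and simulate→evaluate reruns with the same seed are
  byte-identical.
- Batch scoring of many gene sets is vectorized for the common methods and
  falls back to the reference per-set implementations otherwise; the two
  paths are cross-checked in tests.
- Undefined scores propagate as NaN and are counted, never silently zeroed.
- Problem sizes in the validation suite (2000-gene universes, 100–500
  pairs, 300-subject cohorts, 50–100 seeds) were chosen as the smallest
  that make the binomial tolerances of the calibration and power checks
  meaningful.
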