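# Methods

This note documents the models, estimators, and design choices behind
`sepstrat`, and what the synthetic-cohort tests do and do not establish.

## Synthetic cohort model

Counts follow the standard bulk RNA-seq generative model

    K_ij ~ NegBinom(mean = s_j · μ_i · 2^{β_ij},  variance = m + φ_i m²)

with per-gene baselines μ_i ~ LogNormal(3.0, 1.5) (median ≈ 20 counts),
per-gene dispersions φ_i ~ Uniform(0.05, 0.5) — the overdispersion range
typical of whole-blood bulk RNA-seq — and per-sample library-size factors
s_j ~ LogNormal(0, 0.2) rescaled to geometric mean 1.

The planted effect β_ij is nonzero when:

- gene i is a marker of sample j's endotype: β ~ Uniform(1.0, 2.5) log2
  units, drawn once per gene. Five endotypes carry 220 markers each,
  pairwise disjoint. 220 was chosen so that capping recovered signatures at
  200 genes (the signature-size convention) still leaves headroom; the true
  per-endotype marker count in real cohorts is unknown.
- gene i is a severity gene (150 genes): full effect (β = 1.0) in
  High-severity samples, half effect in Intermediate, none in Low. The
  graded structure is the minimal one under which training on extreme
  phenotypes (High vs Low) and evaluating on the merged comparison
  (High + Intermediate vs Low) is a meaningful test.
- gene i is a mortality gene (100 genes) and the sample died in hospital
  (β = 1.0).

Healthy controls carry no planted effects. Marker, severity, and mortality
gene sets are disjoint by construction.

Clinical variables are drawn per endotype. Defaults reproduce the severity
*ordering* of the emulated study design: 24 h SOFA means
(2.5, 2.2, 1.4, 1.8, 1.7) for the five endotypes in ER cohorts, scaled to
(7.6, 8.2, 3.5, 3.7, 3.5) in the ICU; blood-culture positivity
(28.4 %, 28.9 %, 14.8 %, 8.9 %, 4.2 %); endotype proportions
(83, 45, 55, 58, 25)/266. SOFA is a truncated-normal draw rounded to
integers in [0, 24]. Deceased patients receive an event time ~
Uniform(1, 28) days; survivors are censored at their hospital-stay day
(lognormal, endotype-specific mean), capped at 28. This supports
Kaplan–Meier and log-rank testing without modeling hazards.

What the generator does **not** emulate: batch or site effects, demographic
confounding, gene–gene correlation beyond the planted block structure,
count-level technical artifacts, and partially overlapping endotype
programs. Passing the recovery tests therefore demonstrates that the
pipeline's machinery is correct and calibrated — not that real cohorts
would yield the same effect sizes or error rates. In particular, planted
effects of 2–5.7 fold on disjoint marker blocks produce near-perfect
recovery (ARI ≈ 1, CV accuracy ≈ 1); real endotypes overlap and the
published analogues of these figures are lower.

## Differential expression

The two-group test is a plain negative-binomial Wald test:

1. Per-gene dispersion by the method of moments on size-factor-normalized
   counts, pooled across the two groups and floored at 1e-8. No shrinkage
   toward a mean–dispersion trend, no outlier replacement, no independent
   filtering — this is a deliberate simplification of the full DESeq2-style
   machinery; it is self-contained and, at the cohort sizes used here,
   calibrated (measured type-I error 0.052 at nominal 0.05 under the null).
2. Per-group means by maximum likelihood with library-size offsets
   (vectorized Newton iterations on log-mean; mean floor 1e-6).
3. Wald statistic log2fc / se against the standard normal, with se from the
   Fisher information of both group fits; BH adjustment across tested
   genes. Genes with all-zero counts in both groups are dropped and
   reported.

Size factors are median-of-ratios: the median across all-positive genes of
the count over the gene's geometric mean, rescaled to geometric mean one.
Fold-change filters are inclusive (a gene at exactly 1.25-fold with
adjusted p exactly 0.05 is retained).

## Consensus endotype discovery

Features are the 2000 genes with the largest median absolute deviation of
normalized log2 expression (the feature set is not dictated by the study
design; MAD on normalized expression is the standard unsupervised choice and
is configurable). Distances are Manhattan, chosen for robustness to heavy
tails. PAM is implemented directly: greedy BUILD initialization, then
best-improvement SWAP passes until no single medoid/non-medoid exchange
lowers the cost; ties break toward lower sample indices, making the
procedure deterministic. On fixtures with n ≤ 8 the SWAP optimum matches
exhaustive medoid enumeration.

Consensus clustering draws 250 subsamples of 80 % of the cohort per
candidate k (2–8), clusters each with PAM, and records
consensus(a, b) = co-clustered / co-sampled. These parameters stabilize the
consensus at n ≈ 182; any pair never co-sampled is an error instructing more
resamples. Final labels per k come from PAM on 1 − consensus. Per-resample
randomness derives from a per-k counter substream of the master seed, so
changing the k range never perturbs another k's draws.

k is selected by mean rank over four validity metrics — mean silhouette
(higher better), PAC (lower), Calinski–Harabasz (higher), Davies–Bouldin
(lower) — with ties broken toward smaller k. PAC is the fraction of
consensus entries in (0.1, 0.9). Note a structural property of this
definition: under a pure-noise cohort, co-clustering frequencies concentrate
near 1/k, so for k ≥ 5 many entries sit below 0.1 and null PAC lands around
0.35–0.5 rather than near 1. The meaningful null signature is that PAC never
approaches the ≈ 0 value that genuine structure produces at its true k, and
that recovered labels carry no information (ARI ≈ 0); the null-calibration
tests assert exactly that.

## Signatures

Unique endotype markers: one-vs-rest DE per endotype, upregulated genes at
≥ 1.5-fold and adjusted p ≤ 0.05, genes significant in two or more
endotypes removed everywhere, survivors ranked by descending log2
fold change and truncated at 200. Uniqueness is enforced before capping, so
the final sets are guaranteed pairwise disjoint (and may fall short of 200).
Ranking by fold change rather than p-value follows the "most upregulated"
reading; ranking by Wald statistic is a configurable alternative.

Severity and mortality signatures: L1-penalized logistic regression on
standardized log2 expression of the DE candidate genes (±1.25-fold,
adjusted p ≤ 0.05), penalty chosen by 10-fold cross-validated deviance with
the 1-SE rule (the sparsest model within one standard error of the best).
Standardization statistics are computed inside each training fold to avoid
leakage; final weights are rescaled to the original expression scale so the
stored model applies directly to new cohorts. Severity training uses the
extreme phenotypes (High vs Low) and is then evaluated on
High + Intermediate vs Low; a transfer label map that reassigns samples
across the training extremes is rejected as leakage. Reduced signatures
keep the top quartile of significant genes by |log2fc| (ceiling rule,
boundary ties kept).

## Endotype classifier and gene pairs

The classifier is L1 multinomial logistic regression (saga) over the union
of the unique marker sets, standardized. The penalty is searched — coarse
log grid, then bisection on log C — for the largest selected-gene union not
exceeding budget + 5 (default budget 40); if the exact budget is
unattainable the nearest achievable count is used with a warning. The
budget-targeting search is rerun inside every cross-validation training
fold; reported CV metrics (macro one-vs-rest AUC, accuracy, macro
sensitivity/specificity) therefore contain no tuning leakage. Stratified
5-fold CV is the default scheme; the pipeline uses one repeat and the
standalone API defaults to five.

Gene pairs: for every class and every unordered pair from the budgeted
genes, a two-feature logistic model (intercept + both genes, fit by a
batched Newton solver with a 1e-4 ridge for separable folds — AUCs are
rank-based and unaffected) is cross-validated one-vs-rest; pairs with mean
CV AUC ≥ 0.85 are retained. The batched solver matches per-pair scikit-learn
fits on the same folds to within CV noise (asserted in tests). The retained
pair count is a reportable output, not a target.

## Enrichment

The single-sample score follows the GSVA construction: per gene, a
Gaussian-kernel CDF estimate across samples (bandwidth = per-gene SD ×
n^(−1/5)); per sample, genes are ranked by that statistic and given
symmetric rank scores |G/2 − r + 1/2|; a weighted KS random walk down the
ranked list (weights = rank score^tau inside the set, tau = 1; constant
decrement outside) yields score = max positive deviation + min negative
deviation, which is bounded in [−1, 1] and antisymmetric under reversal of
every gene's cross-sample ordering. Kernel choice, tau, and the score form
are configurable; the implementation is validated against a literal
step-by-step transcription of the statistic on small fixtures.

ORA is the hypergeometric upper tail P(X ≥ overlap) with BH adjustment
across sets. The universe defaults to the genes present in the expression
matrix, not the genome, to avoid background inflation.

Endotype transfer to validation cohorts uses the multinomial classifier for
assignment and enrichment of the five marker signatures for confirmation;
ties in the per-sample argmax break deterministically by signature name and
are flagged.

## Clinical statistics

Kruskal–Wallis (tie-corrected, chi-squared reference) and Pearson
chi-squared without continuity correction are used for numerical and
categorical endotype comparisons; no Fisher fallback is applied by default
even with small cells (Fisher's exact test is available behind a flag for
2×2 tables). Dunn's post-hoc z uses pooled-rank mean differences with
tie-corrected variance; the default is unadjusted two-sided p-values with BH
optional. Kaplan–Meier and the log-rank test come from lifelines behind the
package's interface. The combined survival comparison groups the two
endotypes with the highest mean SOFA against the rest — the higher-powered
prognosis grouping. The organ-failure-free-days style endpoint is encoded
generically as a 28-day time-to-event problem with censoring at discharge.

## Pipeline

Stages run in order: normalize → severity/mortality DE + LASSO → consensus
discovery (ER discovery cohort only) → unique markers → multinomial fit →
pair derivation → prediction on ER-validation and ICU → enrichment
confirmation → clinical statistics. Validation cohorts never influence
clustering, marker selection, or penalty tuning. All randomness flows from
one master seed through named substreams. The recovery report matches
discovered clusters to planted endotypes with the Hungarian algorithm on
the label contingency table and reports ARI, per-endotype marker Jaccard,
classifier CV metrics, transfer accuracies, and enrichment/classifier
agreement. Configuration is YAML; unknown keys are rejected and a resolved
copy is written with every run.

## Problem sizes and numerical conventions

- Default recovery runs use the full default cohort (8000 genes,
  182 + 84 + 82 + 39 samples, 250 consensus resamples); one pipeline run
  takes ~35 s on one CPU. Unit tests use a structurally identical cohort at
  2000 genes / 165 samples.
- Null-calibration replicates use 60-sample, 1500-gene null cohorts
  (20 replicates in tests, 10 in the acceptance script).
- Dispersion floor 1e-8, mean floor 1e-6, pseudocount 1 for the log2
  transform; zero-variance genes are dropped with warnings wherever they
  would break standardization or ranking.
- PAM, the consensus procedure, label tie-breaks, and argmax rules are all
  deterministic given the seed; reruns produce byte-identical reports.

## Known limitations

- The NB Wald test is anti-conservative for very small groups (< 10 per
  arm) since moment dispersion estimates are noisy there; the pipeline's
  group sizes are well above that.
- The gene-budget search assumes selection size is monotone in the penalty,
  which L1 paths occasionally violate locally; the bisection then returns
  the nearest achievable size with a warning.
- Enrichment scoring is O(genes × samples²) in the kernel step; it is
  chunked but intended for cohort-scale (≤ a few hundred samples) matrices.
- Multiclass sensitivity/specificity are macro averages; other conventions
  (micro, prevalence-weighted) would give different numbers on imbalanced
  cohorts.
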