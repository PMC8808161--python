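# sepstrat

Transcriptomic endotype discovery and severity stratification for early
sepsis cohorts.

Sepsis patients arriving at the emergency room are clinically heterogeneous:
some resolve with minimal support while others progress to organ failure and
death, and bedside scores measured at presentation separate them poorly. One
productive way to handle this heterogeneity is to stratify patients into
*endotypes* — subgroups defined by distinct underlying immune programs in
whole-blood gene expression — and to derive compact gene signatures that
predict severity, mortality, and endotype membership early enough to guide
triage.

`sepstrat` implements that full analysis path as a tested, reusable library:

- **Synthetic cohort generator** (`sepstrat.sim`) — negative-binomial RNA-seq
  counts for an ER discovery cohort (182 patients), a held-out ER validation
  cohort (84), an ICU cohort (82), and healthy controls (39), with five
  planted endotypes (each carrying ~220 uniquely upregulated marker genes),
  graded severity and mortality gene programs, and endotype-dependent SOFA
  scores, mortality, blood-culture positivity, and survival times. Every
  downstream stage is testable against this planted ground truth.
- **Normalization and differential expression** (`sepstrat.de`) —
  median-of-ratios size factors, log2 normalization, SOFA-based severity
  strata (High ≥ 5, Intermediate ≥ 2 and < 5, Low < 2), and a
  negative-binomial Wald test with per-gene moment dispersion estimates and
  Benjamini–Hochberg adjustment.
- **Consensus endotype discovery** (`sepstrat.consensus`) — PAM (k-medoids,
  BUILD + SWAP) on Manhattan distances over the most variable genes,
  subsampled consensus clustering, and cluster-number selection by a
  committee of validity metrics (mean silhouette, PAC, Calinski–Harabasz,
  Davies–Bouldin).
- **Gene signatures** (`sepstrat.signatures`) — unique upregulated marker
  sets per endotype (one-vs-rest DE, shared genes removed, top 200 by fold
  change), L1-penalized logistic severity/mortality signatures trained on
  extreme phenotypes with the penalty chosen by the cross-validated 1-SE
  rule, fold-change-reduced signatures, and fixed-signature evaluation
  (L1 logistic or random forest).
- **Endotype classifier** (`sepstrat.classifier`) — L1 multinomial logistic
  regression with the penalty tuned to a 40-gene budget, repeated stratified
  cross-validation with all tuning inside training folds, and exhaustive
  two-gene-pair rules for assay-sized classification.
- **Enrichment** (`sepstrat.enrichment`) — single-sample gene-set scores via
  a kernel-CDF + weighted Kolmogorov–Smirnov random-walk statistic (the GSVA
  construction) for endotype transfer, and hypergeometric
  over-representation analysis for pathway characterization.
- **Clinical statistics** (`sepstrat.clinstats`) — Kruskal–Wallis with
  Dunn's post-hoc, Pearson chi-squared (Fisher optional), pooled proportion
  ratios, Kaplan–Meier curves, and log-rank tests.
- **Pipeline + CLI** (`sepstrat.pipeline`, `sepstrat` command) — seeded,
  configuration-driven orchestration with a recovery report against ground
  truth.

## Worked example

```python
from sepstrat import PipelineConfig, SimConfig, run_pipeline

config = PipelineConfig(outdir="run", seed=1, simulate=SimConfig(seed=1))
report = run_pipeline(config)
print("selected k:", report.k_selected)
print("ARI vs planted endotypes:", round(report.ari, 3))
print("classifier genes CV accuracy:", round(report.classifier_cv["accuracy"], 3))
print("validation transfer accuracy:", round(report.transfer_accuracy, 3))
print("GSVA / classifier agreement (ICU):", round(report.gsva_agreement, 3))
```

Output on the default synthetic cohort:

```
selected k: 5
ARI vs planted endotypes: 1.0
classifier genes CV accuracy: 1.0
validation transfer accuracy: 1.0
GSVA / classifier agreement (ICU): 1.0
```

Reading the numbers: consensus k-medoids on the discovery cohort selects
five clusters and reproduces the planted endotype partition exactly
(adjusted Rand index 1.0); the 40-gene multinomial classifier separates them
under cross-validation; the model carries over to the held-out validation
cohort; and single-sample enrichment of the five marker signatures assigns
ICU samples to the same endotypes as the classifier. The run directory
contains every intermediate artifact (size factors, DE tables, consensus
matrices and metrics, marker GMT, classifier JSON, gene-pair table,
per-cohort predictions, enrichment scores, clinical statistics).

The same pipeline runs from the shell:

```bash
sepstrat simulate --seed 1 --outdir data/
sepstrat discover --counts data/counts.tsv --metadata data/metadata.tsv \
    --k-range 2:8 --seed 1 --out consensus.json
sepstrat pipeline --config config.yaml
```

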