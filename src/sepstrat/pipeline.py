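"""End-to-end orchestration: discovery -> signatures -> classifier -> transfer
-> clinical statistics, with seeded stages and a recovery report against
planted ground truth when running on a synthetic cohort.

Stage order and cohort roles mirror the study design: unsupervised endotype
discovery uses the ER discovery cohort only; the trained classifier is then
applied to the held-out ER validation and ICU cohorts, with single-sample
enrichment of the endotype signatures as confirmation. Severity and
mortality signatures are trained on the pooled septic ER + ICU samples.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from . import io as sio
from .classifier import (
    ClassifierSpec,
    cross_validate,
    derive_gene_pairs,
    fit_multinomial_lasso,
    pair_table,
    predict_endotype,
)
from .clinstats import chi_squared, dunn_posthoc, kruskal_wallis, log_rank, proportion_ratio
from .consensus import consensus_cluster
from .de import assign_severity, filter_de, nb_wald_de, normalize_log2, size_factors
from .enrichment import classify_by_enrichment, gsva_scores
from .model import CVReport
from .signatures import (
    evaluate_signature_transfer,
    lasso_signature,
    per_endotype_de,
    unique_upregulated_markers,
)
from .sim import GroundTruth, SimConfig, generate_cohort, read_fixture

logger = logging.getLogger("sepstrat")

__all__ = ["PipelineConfig", "RecoveryReport", "run_pipeline"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Exactly one of ``simulate`` (generative parameters) or the three input
    paths (``counts``, ``metadata``, ``gmt``) must be provided.
    """

    outdir: str = "sepstrat_run"
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimConfig | None = None
    counts: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    de: dict = field(
        default_factory=lambda: {"min_fold": 1.25, "max_adj_p": 0.05}
    )
    consensus: dict = field(
        default_factory=lambda: {
            "k_range": [2, 3, 4, 5, 6, 7, 8],
            "n_resamples": 250,
            "subsample_fraction": 0.8,
            "n_var_genes": 2000,
        }
    )
    markers: dict = field(
        default_factory=lambda: {"min_fold": 1.5, "max_adj_p": 0.05, "cap": 200}
    )
    classifier: dict = field(
        default_factory=lambda: {
            "gene_budget": 40,
            "budget_tolerance": 5,
            "cv_folds": 5,
            "cv_repeats": 1,
        }
    )
    pairs: dict = field(default_factory=lambda: {"min_auc": 0.85, "cv_folds": 5})
    signatures: dict = field(default_factory=lambda: {"cv_folds": 10, "eval_folds": 5, "eval_repeats": 1})
    gsva: dict = field(default_factory=lambda: {"tau": 1.0})

    def validate(self) -> None:
        has_sim = self.simulate is not None
        has_paths = all(p is not None for p in (self.counts, self.metadata))
        if has_sim == has_paths:
            raise ConfigError("provide exactly one of a simulate block or input paths")
        if has_paths:
            for p in (self.counts, self.metadata):
                if not Path(p).exists():
                    raise ConfigError(f"input file does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if raw.get("simulate") is not None:
            sim_raw = {
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["simulate"].items()
            }
            raw["simulate"] = SimConfig(**sim_raw)
        base = cls()
        for key in ("de", "consensus", "markers", "classifier", "pairs", "signatures", "gsva"):
            if key in raw:
                merged = dict(getattr(base, key))
                merged.update(raw[key])
                raw[key] = merged
        return cls(**raw)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(dataclasses.asdict(self))


@dataclass
class RecoveryReport:
    """Synthetic-twin summary of how well each stage recovered the truth."""

    k_selected: int
    ari: float | None
    marker_jaccard: dict[str, float]
    classifier_cv: dict
    transfer_accuracy: float | None
    icu_accuracy: float | None
    gsva_agreement: float | None
    severity_cv: dict | None
    mortality_cv: dict | None
    best_pair_auc: dict[str, float]
    n_pairs: int
    clinical: dict
    runtime_seconds: float
    seed: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _match_clusters(pred: pd.Series, truth: pd.Series) -> dict[str, str]:
    """Map predicted cluster names to true endotype names by maximizing the
    assignment overlap (Hungarian algorithm on the contingency table)."""
    tab = pd.crosstab(pred, truth)
    rows, cols = linear_sum_assignment(-tab.to_numpy())
    return {str(tab.index[r]): str(tab.columns[c]) for r, c in zip(rows, cols)}


def _jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def run_pipeline(config: PipelineConfig) -> RecoveryReport:
    """Execute every stage in order and write artifacts under ``config.outdir``."""
    t0 = time.time()
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    truth: GroundTruth | None = None
    stage = "load_data"
    try:
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.simulate.seed or config.seed)
            counts, meta, truth = generate_cohort(sim_cfg)
        else:
            counts = sio.read_counts(config.counts)
            meta = sio.read_metadata(config.metadata)
            truth = None
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("data: %d genes x %d samples", *counts.shape)

    try:
        stage = "normalize"
        factors = size_factors(counts)
        expr = normalize_log2(counts, factors)
        factors.to_csv(outdir / "size_factors.tsv", sep="\t")

        stage = "severity_mortality_signatures"
        septic = meta.index[(meta["cohort"] != "healthy") & meta["sofa24"].notna()]
        sev = pd.Series(
            [assign_severity(meta.loc[s, "sofa24"]) for s in septic], index=septic
        ).dropna()
        extremes = sev[sev.isin(["High", "Low"])]
        sev_de = nb_wald_de(
            counts,
            list(extremes.index[extremes == "High"]),
            list(extremes.index[extremes == "Low"]),
            factors=factors,
        )
        sev_de.table.to_csv(outdir / "de_high_vs_low.tsv", sep="\t", index=False)
        sev_candidates = filter_de(sev_de.table, config.de["min_fold"], config.de["max_adj_p"], "both")
        severity_cv = None
        if sev_candidates:
            sev_model = lasso_signature(
                expr[extremes.index],
                extremes,
                sev_candidates,
                cv_folds=config.signatures["cv_folds"],
                seed=config.seed,
                name="severity",
            )
            sev_model.to_json(outdir / "severity_signature.json")
            merged = sev.replace({"Intermediate": "High"})
            severity_cv = evaluate_signature_transfer(
                sev_model,
                expr[merged.index],
                merged,
                cv_folds=config.signatures["eval_folds"],
                repeats=config.signatures["eval_repeats"],
                seed=config.seed,
            ).as_dict()

        died = meta.loc[septic, "died_in_hospital"].astype(bool)
        mort_labels = died.map({True: "Died", False: "Survived"})
        mortality_cv = None
        if died.sum() >= 10:
            mort_de = nb_wald_de(
                counts, list(died.index[died]), list(died.index[~died]), factors=factors
            )
            mort_de.table.to_csv(outdir / "de_died_vs_survived.tsv", sep="\t", index=False)
            mort_candidates = filter_de(
                mort_de.table, config.de["min_fold"], config.de["max_adj_p"], "both"
            )
            if mort_candidates:
                mort_model = lasso_signature(
                    expr[septic],
                    mort_labels,
                    mort_candidates,
                    cv_folds=config.signatures["cv_folds"],
                    seed=config.seed,
                    name="mortality",
                )
                mort_model.to_json(outdir / "mortality_signature.json")
                mortality_cv = evaluate_signature_transfer(
                    mort_model,
                    expr[septic],
                    mort_labels,
                    cv_folds=config.signatures["eval_folds"],
                    repeats=config.signatures["eval_repeats"],
                    seed=config.seed,
                ).as_dict()

        stage = "consensus_discovery"
        disc = meta.index[meta["cohort"] == "ER_discovery"]
        cons = consensus_cluster(
            expr[disc],
            k_range=config.consensus["k_range"],
            n_resamples=config.consensus["n_resamples"],
            subsample_fraction=config.consensus["subsample_fraction"],
            n_var_genes=config.consensus["n_var_genes"],
            seed=config.seed,
        )
        cons.metrics.to_csv(outdir / "consensus_metrics.tsv", sep="\t")
        disc_labels = pd.Series(
            [f"C{l}" for l in cons.final_labels], index=disc, name="endotype"
        )
        pd.DataFrame(
            cons.consensus[cons.k_selected], index=disc, columns=disc
        ).to_csv(outdir / "consensus_matrix_selected_k.tsv", sep="\t")
        disc_labels.to_csv(outdir / "discovery_labels.tsv", sep="\t")
        logger.info("consensus: selected k=%d", cons.k_selected)

        stage = "unique_markers"
        endo_de = per_endotype_de(counts, disc_labels, factors=factors)
        markers = unique_upregulated_markers(
            endo_de,
            min_fold=config.markers["min_fold"],
            max_adj_p=config.markers["max_adj_p"],
            cap=config.markers["cap"],
        )
        sio.write_gmt(
            {name: gs.genes for name, gs in markers.items()},
            outdir / "endotype_signatures.gmt",
            description="unique upregulated endotype markers",
        )

        stage = "multinomial_classifier"
        candidates = sorted({g for gs in markers.values() for g in gs.genes})
        spec = ClassifierSpec(
            candidate_genes=candidates,
            gene_budget=config.classifier["gene_budget"],
            budget_tolerance=config.classifier["budget_tolerance"],
            cv_folds=config.classifier["cv_folds"],
            repeats=config.classifier["cv_repeats"],
            seed=config.seed,
        )
        model = fit_multinomial_lasso(expr[disc], disc_labels, spec)
        model.to_json(outdir / "endotype_classifier.json")
        logger.info("classifier: %d genes selected", len(model.genes))

        def trainer(e_tr, y_tr):
            inner = dataclasses.replace(spec, candidate_genes=[g for g in candidates if g in e_tr.index])
            return fit_multinomial_lasso(e_tr, y_tr, inner)

        classifier_cv = cross_validate(
            expr[disc],
            disc_labels,
            trainer,
            folds=spec.cv_folds,
            repeats=spec.repeats,
            seed=config.seed,
        )

        stage = "gene_pairs"
        rules = derive_gene_pairs(
            expr[disc],
            disc_labels,
            model.genes,
            min_auc=config.pairs["min_auc"],
            cv_folds=config.pairs["cv_folds"],
            seed=config.seed,
        )
        pair_table(rules).to_csv(outdir / "gene_pairs.tsv", sep="\t", index=False)
        best_pair = {}
        for r in rules:
            best_pair.setdefault(r.class_label, r.cv_auc)

        stage = "transfer_prediction"
        preds = {}
        for cohort in ("ER_validation", "ICU"):
            cols = meta.index[meta["cohort"] == cohort]
            if len(cols) == 0:
                continue
            labels_c, proba_c = predict_endotype(model, expr[cols])
            preds[cohort] = labels_c
            proba_c.to_csv(outdir / f"predicted_proba_{cohort}.tsv", sep="\t")

        stage = "gsva_confirmation"
        gsva_agreement = None
        gene_sets = {name: gs.genes for name, gs in markers.items() if gs.genes}
        icu_cols = meta.index[meta["cohort"] == "ICU"]
        if len(icu_cols) >= 3 and len(gene_sets) >= 2:
            scores = gsva_scores(expr[icu_cols], gene_sets, tau=config.gsva["tau"])
            scores.to_csv(outdir / "gsva_scores_ICU.tsv", sep="\t")
            enr = classify_by_enrichment(scores)
            if "ICU" in preds:
                gsva_agreement = float((enr["label"] == preds["ICU"]).mean())

        stage = "clinical_statistics"
        er_cols = meta.index[meta["cohort"].isin(["ER_discovery", "ER_validation"])]
        all_labels = pd.concat([disc_labels] + [preds[c] for c in preds]).reindex(er_cols).dropna()
        clin = _clinical_stats(meta, all_labels)
        sio.write_json(clin, outdir / "clinical_stats.json")

        stage = "recovery_report"
        report = _recovery_report(
            truth=truth,
            meta=meta,
            disc_labels=disc_labels,
            preds=preds,
            markers=markers,
            cons_k=cons.k_selected,
            classifier_cv=classifier_cv,
            severity_cv=severity_cv,
            mortality_cv=mortality_cv,
            best_pair=best_pair,
            n_pairs=len(rules),
            gsva_agreement=gsva_agreement,
            clinical=clin,
            runtime=time.time() - t0,
            seed=config.seed,
        )
        sio.write_json(report.as_dict(), outdir / "recovery_report.json")
        return report
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def _clinical_stats(meta: pd.DataFrame, labels: pd.Series) -> dict:
    """Endotype-level clinical comparisons on the labeled ER samples."""
    sub = meta.loc[labels.index].copy()
    sub["endotype"] = labels
    out: dict = {}
    groups = sorted(pd.unique(labels))
    sofa_groups = [
        sub.loc[sub["endotype"] == g, "sofa24"].dropna().to_numpy() for g in groups
    ]
    if len(groups) >= 2 and all(len(g) for g in sofa_groups):
        h, p = kruskal_wallis(sofa_groups)
        out["sofa24_kruskal"] = {"H": h, "p": p}
        if len(groups) >= 3:
            out["sofa24_dunn"] = dunn_posthoc(sofa_groups).to_dict(orient="records")

    for column, key in (
        ("blood_culture_positive", "blood_culture_chisq"),
        ("died_in_hospital", "mortality_chisq"),
    ):
        tab = []
        for g in groups:
            v = sub.loc[sub["endotype"] == g, column].astype(bool)
            tab.append([int(v.sum()), int((~v).sum())])
        tab = np.asarray(tab)
        if (tab.sum(axis=0) > 0).all() and tab.sum() > 0:
            x2, dof, p = chi_squared(tab)
            out[key] = {"X2": x2, "df": dof, "p": p}

    # combined-severity survival comparison: the two highest-SOFA endotypes
    # against the rest, the higher-powered grouping used for prognosis
    mean_sofa = sub.groupby("endotype")["sofa24"].mean().sort_values(ascending=False)
    if len(mean_sofa) >= 3:
        severe = list(mean_sofa.index[:2])
        sev_mask = sub["endotype"].isin(severe)
        t1 = sub.loc[sev_mask, "survival_time_days"].to_numpy()
        e1 = sub.loc[sev_mask, "event"].astype(int).to_numpy()
        t2 = sub.loc[~sev_mask, "survival_time_days"].to_numpy()
        e2 = sub.loc[~sev_mask, "event"].astype(int).to_numpy()
        if e1.sum() + e2.sum() > 0 and len(t1) and len(t2):
            x2, p = log_rank(t1, e1, t2, e2)
            out["combined_logrank"] = {"groups": severe, "X2": x2, "p": p}
        bc = sub["blood_culture_positive"].astype(bool)
        pos_a = int(bc[sev_mask].sum())
        pos_b = int(bc[~sev_mask].sum())
        if pos_b > 0:
            out["blood_culture_ratio_severe_vs_rest"] = proportion_ratio(
                pos_a, int(sev_mask.sum()), pos_b, int((~sev_mask).sum())
            )
    return out


def _recovery_report(
    truth: GroundTruth | None,
    meta: pd.DataFrame,
    disc_labels: pd.Series,
    preds: dict[str, pd.Series],
    markers,
    cons_k: int,
    classifier_cv: CVReport,
    severity_cv,
    mortality_cv,
    best_pair: dict[str, float],
    n_pairs: int,
    gsva_agreement,
    clinical: dict,
    runtime: float,
    seed: int,
) -> RecoveryReport:
    ari = None
    jaccard: dict[str, float] = {}
    transfer_acc = None
    icu_acc = None
    if truth is not None:
        true_disc = truth.endotype_label.reindex(disc_labels.index).dropna()
        ari = float(adjusted_rand_score(true_disc, disc_labels.loc[true_disc.index]))
        mapping = _match_clusters(disc_labels.loc[true_disc.index], true_disc)
        for cluster, endo in mapping.items():
            if cluster in markers and endo in truth.marker_genes:
                jaccard[endo] = _jaccard(markers[cluster].genes, truth.marker_genes[endo])
        if "ER_validation" in preds:
            pv = preds["ER_validation"].map(mapping)
            tv = truth.endotype_label.reindex(pv.index).dropna()
            transfer_acc = float((pv.loc[tv.index] == tv).mean())
        if "ICU" in preds:
            pi = preds["ICU"].map(mapping)
            ti = truth.endotype_label.reindex(pi.index).dropna()
            icu_acc = float((pi.loc[ti.index] == ti).mean())
    return RecoveryReport(
        k_selected=cons_k,
        ari=ari,
        marker_jaccard=jaccard,
        classifier_cv=classifier_cv.as_dict(),
        transfer_accuracy=transfer_acc,
        icu_accuracy=icu_acc,
        gsva_agreement=gsva_agreement,
        severity_cv=severity_cv,
        mortality_cv=mortality_cv,
        best_pair_auc=best_pair,
        n_pairs=n_pairs,
        clinical=clinical,
        runtime_seconds=runtime,
        seed=seed,
    )
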