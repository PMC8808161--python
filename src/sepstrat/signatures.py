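"""Gene-signature construction: unique per-endotype marker sets and
LASSO-selected severity/mortality signatures.

Severity signatures are trained on the extreme phenotypes (High vs Low
SOFA strata) and then assessed on the merged High + Intermediate vs Low
comparison, the design that yields the most robust severity markers when
the intermediate group is noisy. Unique endotype signatures are the most
upregulated differentially expressed genes found in exactly one endotype's
one-vs-rest comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .de import DEResult, filter_de, nb_wald_de
from .model import CVReport, SignatureModel, SklearnOnGenes
from .classifier import cross_validate

__all__ = [
    "GeneSet",
    "per_endotype_de",
    "unique_upregulated_markers",
    "lasso_signature",
    "reduce_candidates_by_fc",
    "evaluate_signature_transfer",
    "evaluate_fixed_signature",
]


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    log2fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")


def per_endotype_de(
    counts: pd.DataFrame, labels: pd.Series, factors: pd.Series | None = None
) -> dict[str, DEResult]:
    """One-vs-rest differential expression for every endotype.

    ``labels`` indexes a subset of the count columns (the clustered cohort);
    each table is oriented endotype over pooled rest.
    """
    labels = pd.Series(labels)
    sizes = labels.value_counts()
    small = sizes[sizes < 3]
    if not small.empty:
        raise ValueError(f"endotypes with fewer than 3 samples: {list(small.index)}")
    samples = list(labels.index)
    sub = counts[samples]
    out: dict[str, DEResult] = {}
    for endo in sorted(pd.unique(labels)):
        grp = [s for s in samples if labels[s] == endo]
        rest = [s for s in samples if labels[s] != endo]
        out[str(endo)] = nb_wald_de(sub, grp, rest, factors=factors)
    return out


def unique_upregulated_markers(
    de_tables: dict[str, DEResult | pd.DataFrame],
    min_fold: float = 1.5,
    max_adj_p: float = 0.05,
    cap: int = 200,
) -> dict[str, GeneSet]:
    """Per-endotype unique upregulated marker sets.

    Significant upregulated genes are taken per endotype; any gene
    significant-upregulated in two or more endotypes is removed everywhere;
    survivors are ranked by descending log2 fold change and truncated at
    ``cap``. The resulting sets are pairwise disjoint by construction.
    """
    tables = {
        name: (res.table if isinstance(res, DEResult) else res) for name, res in de_tables.items()
    }
    up_lists = {
        name: filter_de(tab, min_fold=min_fold, max_adj_p=max_adj_p, direction="up")
        for name, tab in tables.items()
    }
    counts: dict[str, int] = {}
    for genes in up_lists.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    out: dict[str, GeneSet] = {}
    for name, genes in up_lists.items():
        unique = [g for g in genes if counts[g] == 1]
        tab = tables[name].set_index("gene_id") if "gene_id" in tables[name].columns else tables[name]
        fc = tab.loc[unique, "log2fc"]
        order = fc.sort_values(ascending=False).index[:cap]
        if len(order) == 0:
            warnings.warn(f"endotype {name!r} has no unique upregulated markers")
        out[name] = GeneSet(
            name=name, genes=list(order), log2fc={g: float(fc[g]) for g in order}
        )
    return out


def _cv_deviance(est, x, y, folds, seed) -> tuple[float, float]:
    """Mean and SE across folds of the validation deviance (-2 mean loglik)."""
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    devs = []
    for tr, te in splitter.split(x, y):
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        est.fit((x[tr] - mu) / sd, y[tr])
        p = est.predict_proba((x[te] - mu) / sd)[:, 1]
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = np.where(y[te] == 1, np.log(p), np.log(1 - p))
        devs.append(-2.0 * ll.mean())
    devs = np.asarray(devs)
    return float(devs.mean()), float(devs.std(ddof=1) / math.sqrt(len(devs)))


def lasso_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    candidate_genes: list[str],
    cv_folds: int = 10,
    seed: int = 0,
    name: str = "lasso_signature",
    c_grid: np.ndarray | None = None,
) -> SignatureModel:
    """L1-penalized logistic signature with the penalty chosen by the 1-SE rule.

    Expression is standardized inside each CV fold for penalty selection and
    on the full data for the final fit; stored weights are rescaled to the
    original log2-expression scale. ``labels`` must be binary.
    """
    labels = pd.Series(labels).reindex(expr.columns)
    classes = sorted(pd.unique(labels.dropna()))
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got {classes}")
    genes = [g for g in candidate_genes if g in expr.index]
    missing = set(candidate_genes) - set(genes)
    if missing:
        raise KeyError(f"candidate genes absent from expression: {sorted(missing)[:5]}")
    y = (labels.to_numpy() == classes[1]).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < cv_folds:
        raise ValueError("each class needs at least cv_folds samples")
    x_raw = expr.loc[genes].to_numpy(dtype=float).T
    sd0 = x_raw.std(axis=0)
    if (sd0 == 0).any():
        warnings.warn(f"removed {int((sd0 == 0).sum())} constant candidate genes")
        genes = [g for g, s in zip(genes, sd0 > 0) if s]
        x_raw = x_raw[:, sd0 > 0]

    if c_grid is None:
        c_grid = np.logspace(-3, 2, 16)
    est = LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=5000, random_state=seed)
    stats = []
    for c in c_grid:
        est.C = float(c)
        stats.append(_cv_deviance(est, x_raw, y, cv_folds, seed))
    means = np.array([m for m, _ in stats])
    ses = np.array([s for _, s in stats])
    i_min = int(np.argmin(means))
    threshold = means[i_min] + ses[i_min]
    # 1-SE rule: the sparsest model (smallest C) within one SE of the best
    i_sel = int(np.flatnonzero(means <= threshold)[0])
    c_sel = float(c_grid[i_sel])

    mu = x_raw.mean(axis=0)
    sd = np.where(x_raw.std(axis=0) > 0, x_raw.std(axis=0), 1.0)
    est.C = c_sel
    est.fit((x_raw - mu) / sd, y)
    nz = np.flatnonzero(np.abs(est.coef_[0]) > 1e-10)
    sel_genes = [genes[i] for i in nz]
    w_std = est.coef_[0]
    w_orig = (w_std / sd)[nz]
    b_orig = float(est.intercept_[0] - np.sum(w_std * mu / sd))
    return SignatureModel(
        name=name,
        genes=sel_genes,
        classes=[str(classes[0]), str(classes[1])],
        weights=np.vstack([np.zeros(len(nz)), w_orig]),
        intercepts=np.array([0.0, b_orig]),
        training={
            "comparison": f"{classes[1]} vs {classes[0]}",
            "penalty": "l1",
            "C": c_sel,
            "cv_folds": cv_folds,
            "seed": seed,
            "positive_class": str(classes[1]),
            "train_labels": {s: str(v) for s, v in labels.dropna().items()},
        },
    )


def reduce_candidates_by_fc(
    det: pd.DataFrame,
    top_fraction: float = 0.25,
    min_fold: float = 1.25,
    max_adj_p: float = 0.05,
) -> list[str]:
    """Significant genes in the top fraction of absolute log2 fold changes.

    The cut keeps ceil(n_significant * top_fraction) genes; ties at the
    boundary value are all retained. Output is ordered by descending |log2fc|.
    """
    if det.empty:
        raise ValueError("empty DE table")
    sig = filter_de(det, min_fold=min_fold, max_adj_p=max_adj_p, direction="both")
    if not sig:
        return []
    tab = det.set_index("gene_id") if "gene_id" in det.columns else det
    absfc = tab.loc[sig, "log2fc"].abs().sort_values(ascending=False)
    n_keep = math.ceil(len(absfc) * top_fraction)
    boundary = absfc.iloc[n_keep - 1]
    kept = absfc[absfc >= boundary]
    return list(kept.index)


def evaluate_signature_transfer(
    model: SignatureModel,
    expr: pd.DataFrame,
    labels: pd.Series,
    cv_folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> CVReport:
    """Refit the signature's genes on a merged comparison and cross-validate.

    The signature gene set is fixed; an L1 logistic model at the stored
    penalty is refit inside each fold. Samples shared with the training
    comparison must keep a consistent class (a flipped class indicates
    leakage through a redefined group map and is rejected).
    """
    labels = pd.Series(labels).reindex(expr.columns).dropna()
    train_labels = model.training.get("train_labels", {})
    pos = model.training.get("positive_class")
    if train_labels and pos is not None:
        classes = sorted(pd.unique(labels))
        if len(classes) != 2:
            raise ValueError("transfer labels must be binary")
        shared = [(train_labels[s] == pos, str(v)) for s, v in labels.items() if s in train_labels]
        if shared:
            # some orientation of the transfer classes must agree with the
            # training extremes on every shared sample
            ok_a = all((str(classes[1]) == v) == was_pos for was_pos, v in shared)
            ok_b = all((str(classes[0]) == v) == was_pos for was_pos, v in shared)
            if not (ok_a or ok_b):
                raise ValueError(
                    "label leakage: the transfer group map reassigns samples across "
                    "the training extremes"
                )
    if not model.genes:
        raise ValueError("signature has no genes to evaluate")
    c = float(model.training.get("C", 1.0))

    def trainer(e_tr, y_tr):
        est = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c, max_iter=5000, random_state=seed)
        return SklearnOnGenes(model.genes, est, standardize=True).fit(e_tr, y_tr)

    return cross_validate(expr[labels.index], labels, trainer, folds=cv_folds, repeats=repeats, seed=seed)


LEARNERS = ("l1_logistic", "random_forest")


def evaluate_fixed_signature(
    genes: list[str],
    expr: pd.DataFrame,
    labels: pd.Series,
    learner: str = "random_forest",
    cv_folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> CVReport:
    """Cross-validated performance of a fixed gene set under a chosen learner.

    No feature selection happens inside folds — the gene set is taken as
    given (e.g. a previously published signature).
    """
    if not genes:
        raise ValueError("gene set is empty")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression: {missing[:5]}")
    if learner == "l1_logistic":
        def make():
            return LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0, max_iter=5000, random_state=seed)
        standardize = True
    elif learner == "random_forest":
        def make():
            return RandomForestClassifier(n_estimators=300, random_state=seed)
        standardize = False
    else:
        raise ValueError(f"unknown learner {learner!r}; expected one of {LEARNERS}")
    labels = pd.Series(labels).reindex(expr.columns).dropna()

    def trainer(e_tr, y_tr):
        return SklearnOnGenes(genes, make(), standardize=standardize).fit(e_tr, y_tr)

    return cross_validate(expr[labels.index], labels, trainer, folds=cv_folds, repeats=repeats, seed=seed)
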