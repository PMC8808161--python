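"""Gene-budgeted multinomial endotype classifier and gene-pair reduction.

The classifier is an L1-penalized multinomial logistic regression over the
union of the per-endotype marker signatures. The penalty is tuned so the
union of genes with any nonzero class weight lands as close as possible to
a fixed gene budget (default 40) without exceeding budget + 5. Gene pairs
are then derived by fitting a plain two-gene logistic model, one-vs-rest,
for every unordered pair from the budgeted set, retaining pairs whose
cross-validated AUC clears a threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .model import CVReport, SignatureModel

__all__ = [
    "ClassifierSpec",
    "PairRule",
    "fit_multinomial_lasso",
    "predict_endotype",
    "cross_validate",
    "derive_gene_pairs",
]


@dataclass
class ClassifierSpec:
    candidate_genes: list[str]
    gene_budget: int = 40
    budget_tolerance: int = 5
    cv_folds: int = 5
    repeats: int = 5
    seed: int = 0
    max_iter: int = 2000
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.gene_budget > len(self.candidate_genes):
            raise ValueError("gene_budget exceeds number of candidate genes")


@dataclass
class PairRule:
    class_label: str
    gene_a: str
    gene_b: str
    weights: np.ndarray  # (intercept, w_a, w_b) on standardized training scale
    cv_auc: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a gene pair needs two distinct genes")


def _standardize(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    return (x[:, keep] - mu[keep]) / sd[keep], mu, sd, keep


def _selected_union(coef: np.ndarray) -> np.ndarray:
    return np.any(np.abs(coef) > 1e-10, axis=0)


def fit_multinomial_lasso(
    expr: pd.DataFrame, labels: pd.Series, spec: ClassifierSpec
) -> SignatureModel:
    """L1 multinomial logistic regression tuned to a gene budget.

    ``expr`` is normalized log2 expression (genes x samples); ``labels`` maps
    the same samples to endotype names. The penalty C is searched (coarse
    log-spaced grid, then bisection) for the largest selected-gene union not
    exceeding ``gene_budget + budget_tolerance``; weights are returned on the
    original expression scale.
    """
    labels = pd.Series(labels).reindex(expr.columns)
    classes, counts = np.unique(labels.to_numpy(), return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if (counts < spec.cv_folds).any():
        small = classes[counts < spec.cv_folds]
        raise ValueError(f"classes smaller than cv_folds: {list(small)}")
    genes = [g for g in spec.candidate_genes if g in expr.index]
    if len(genes) < len(spec.candidate_genes):
        missing = set(spec.candidate_genes) - set(genes)
        raise KeyError(f"candidate genes absent from expression matrix: {sorted(missing)[:5]}")
    x_raw = expr.loc[genes].to_numpy(dtype=float).T
    x, mu, sd, keep = _standardize(x_raw)
    if not keep.all():
        warnings.warn(f"removed {int((~keep).sum())} constant candidate genes")
        genes = [g for g, k in zip(genes, keep) if k]
    y = labels.to_numpy()

    est = LogisticRegression(
        l1_ratio=1.0,
        solver="saga",
        max_iter=spec.max_iter,
        tol=spec.tol,
        warm_start=True,
        random_state=spec.seed,
    )

    def n_selected(c: float) -> int:
        est.C = c
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x, y)
        return int(_selected_union(est.coef_).sum())

    budget_hi = spec.gene_budget + spec.budget_tolerance
    grid = np.logspace(-2.5, 0.5, 7)
    counts_path = []
    for c in grid:
        m = n_selected(c)
        counts_path.append((c, m))
        if m > budget_hi:
            break
    # bisect the bracketing interval on log C; stop once on budget
    feasible = [(c, m) for c, m in counts_path if m <= budget_hi]
    above = [(c, m) for c, m in counts_path if m > budget_hi]
    if feasible and above and not any(m == spec.gene_budget for _, m in feasible):
        lo = max(c for c, _ in feasible)
        hi = min(c for c, _ in above)
        for _ in range(8):
            mid = float(np.sqrt(lo * hi))
            m = n_selected(mid)
            counts_path.append((mid, m))
            if abs(m - spec.gene_budget) <= 1 and m <= budget_hi:
                break
            if m <= budget_hi:
                lo = mid
            else:
                hi = mid
    achievable = [(c, m) for c, m in counts_path if m <= budget_hi]
    if achievable:
        # prefer counts closest to the budget from the achievable side
        c_best, m_best = min(achievable, key=lambda cm: (abs(cm[1] - spec.gene_budget), -cm[0]))
    else:
        c_best, m_best = min(counts_path, key=lambda cm: cm[1])
        warnings.warn(
            f"gene budget {spec.gene_budget} unattainable on the penalty grid; "
            f"nearest achievable selection has {m_best} genes"
        )
    est.C = c_best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(x, y)

    sel = _selected_union(est.coef_)
    sel_genes = [g for g, s in zip(genes, sel) if s]
    sd_kept = sd[keep]
    mu_kept = mu[keep]
    coef, intercept = est.coef_, est.intercept_
    if coef.shape[0] == 1 and len(est.classes_) == 2:
        # sklearn stores one row for binary problems; expand to per-class rows
        coef = np.vstack([np.zeros_like(coef[0]), coef[0]])
        intercept = np.array([0.0, intercept[0]])
    w_std = coef[:, sel]
    w_orig = w_std / sd_kept[sel]
    b_orig = intercept - (coef * (mu_kept / sd_kept)).sum(axis=1)
    return SignatureModel(
        name="endotype_multinomial",
        genes=sel_genes,
        classes=[str(c) for c in est.classes_],
        weights=w_orig,
        intercepts=b_orig,
        training={
            "comparison": "multinomial endotype",
            "penalty": "l1",
            "C": float(c_best),
            "gene_budget": spec.gene_budget,
            "budget_tolerance": spec.budget_tolerance,
            "cv_folds": spec.cv_folds,
            "seed": spec.seed,
            "n_selected": int(m_best),
        },
    )


def predict_endotype(model: SignatureModel, expr: pd.DataFrame):
    """Apply a fitted endotype model: (labels, class probabilities)."""
    proba = model.predict_proba(expr)
    labels = model.predict(expr)
    return labels, proba


def _macro_specificity(y_true, y_pred, classes) -> float:
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    total = cm.sum()
    spec = []
    for i in range(len(classes)):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = total - tp - fp - fn
        spec.append(tn / (tn + fp) if (tn + fp) else np.nan)
    return float(np.nanmean(spec))


def cross_validate(
    expr: pd.DataFrame,
    labels: pd.Series,
    trainer,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified CV of a trainer callable.

    ``trainer(expr_train, labels_train)`` must return an object with
    ``predict`` and ``predict_proba`` over a genes x samples frame. All
    tuning and standardization happen inside the trainer, i.e. inside the
    training folds.
    """
    labels = pd.Series(labels).reindex(expr.columns)
    y = labels.to_numpy()
    classes = list(np.unique(y))
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(f"classes smaller than fold count: {list(counts[counts < folds].index)}")
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    rows = []
    sample_idx = np.arange(len(y))
    for fold_no, (tr, te) in enumerate(splitter.split(sample_idx, y)):
        cols_tr = expr.columns[tr]
        cols_te = expr.columns[te]
        model = trainer(expr[cols_tr], labels.loc[cols_tr])
        proba = model.predict_proba(expr[cols_te])
        pred = proba.columns[np.argmax(proba.to_numpy(), axis=1)]
        y_te = y[te]
        if len(classes) == 2:
            auc = roc_auc_score((y_te == proba.columns[1]).astype(int), proba.iloc[:, 1])
        else:
            auc = roc_auc_score(
                y_te, proba[classes].to_numpy(), multi_class="ovr", average="macro", labels=classes
            )
        cm = confusion_matrix(y_te, pred, labels=classes)
        recalls = np.diag(cm) / np.maximum(cm.sum(axis=1), 1)
        rows.append(
            {
                "fold": fold_no,
                "auc": float(auc),
                "accuracy": float((pred == y_te).mean()),
                "sensitivity": float(np.mean(recalls[cm.sum(axis=1) > 0])),
                "specificity": _macro_specificity(y_te, pred, classes),
            }
        )
    per_fold = pd.DataFrame(rows)
    return CVReport(
        auc=float(per_fold["auc"].mean()),
        accuracy=float(per_fold["accuracy"].mean()),
        sensitivity=float(per_fold["sensitivity"].mean()),
        specificity=float(per_fold["specificity"].mean()),
        per_fold=per_fold,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


def _fit_logistic_batch(xb: np.ndarray, y: np.ndarray, ridge: float = 1e-4, n_iter: int = 25):
    """Newton/IRLS fit of P parallel small logistic regressions.

    ``xb`` has shape (P, n, d) including the intercept column; returns betas
    of shape (P, d). A small ridge keeps separable problems finite; rankings
    (hence AUCs) are unaffected.
    """
    p_, n, d = xb.shape
    beta = np.zeros((p_, d))
    eye = ridge * np.eye(d)
    for _ in range(n_iter):
        eta = np.clip(np.einsum("pnd,pd->pn", xb, beta), -30, 30)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-8)
        grad = np.einsum("pnd,pn->pd", xb, y[None, :] - mu) - ridge * beta
        hess = np.einsum("pnd,pn,pne->pde", xb, w, xb) + eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _auc_batch(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank-based AUC for each row of ``scores`` against binary ``y``."""
    npos = int(y.sum())
    nneg = len(y) - npos
    if npos == 0 or nneg == 0:
        return np.full(scores.shape[0], np.nan)
    ranks = rankdata(scores, axis=1)
    pos_rank_sum = ranks[:, y.astype(bool)].sum(axis=1)
    return (pos_rank_sum - npos * (npos + 1) / 2) / (npos * nneg)


def derive_gene_pairs(
    expr: pd.DataFrame,
    labels: pd.Series,
    genes: list[str],
    min_auc: float = 0.85,
    cv_folds: int = 5,
    seed: int = 0,
) -> list[PairRule]:
    """Two-gene one-vs-rest logistic rules from the budgeted gene set.

    Every unordered pair is fit per class; pairs with mean cross-validated
    AUC >= ``min_auc`` are retained, sorted by class then descending AUC.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 budgeted genes")
    labels = pd.Series(labels).reindex(expr.columns)
    x_raw = expr.loc[genes].to_numpy(dtype=float).T
    sd = x_raw.std(axis=0)
    x = (x_raw - x_raw.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = x.shape[0]
    pairs = np.array(list(itertools.combinations(range(len(genes)), 2)))
    ia, ib = pairs[:, 0], pairs[:, 1]
    p_ = len(pairs)
    xb = np.empty((p_, n, 3))
    xb[:, :, 0] = 1.0
    xb[:, :, 1] = x[:, ia].T
    xb[:, :, 2] = x[:, ib].T

    rules: list[PairRule] = []
    for cls in sorted(pd.unique(labels)):
        y = (labels.to_numpy() == cls).astype(float)
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        fold_aucs = np.zeros((cv_folds, p_))
        for f, (tr, te) in enumerate(splitter.split(np.arange(n), y)):
            beta = _fit_logistic_batch(xb[:, tr, :], y[tr])
            scores = np.einsum("pnd,pd->pn", xb[:, te, :], beta)
            fold_aucs[f] = _auc_batch(scores, y[te])
        cv_auc = fold_aucs.mean(axis=0)
        keep = np.flatnonzero(cv_auc >= min_auc)
        if keep.size:
            beta_full = _fit_logistic_batch(xb[keep], y)
            for row, bi in enumerate(keep):
                rules.append(
                    PairRule(
                        class_label=str(cls),
                        gene_a=genes[ia[bi]],
                        gene_b=genes[ib[bi]],
                        weights=beta_full[row],
                        cv_auc=float(cv_auc[bi]),
                    )
                )
    rules.sort(key=lambda r: (r.class_label, -r.cv_auc))
    return rules


def pair_table(rules: list[PairRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": r.class_label,
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "cv_auc": r.cv_auc,
            }
            for r in rules
        ]
    )
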