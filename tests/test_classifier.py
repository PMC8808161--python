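"""Gene-budgeted multinomial classifier, cross-validation, and gene pairs."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from sepstrat import (
    ClassifierSpec,
    PairRule,
    cross_validate,
    derive_gene_pairs,
    fit_multinomial_lasso,
    predict_endotype,
)
from sepstrat.model import SklearnOnGenes


def _separable_fixture(rng, n_per=20, k=3, n_genes=30, sep=4.0):
    """k classes, each with a private block of shifted genes."""
    blocks = []
    for c in range(k):
        x = rng.normal(size=(n_genes, n_per))
        x[c * 2 : c * 2 + 2] += sep
        blocks.append(x)
    expr = pd.DataFrame(
        np.hstack(blocks),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_per * k)],
    )
    labels = pd.Series(np.repeat([f"E{c + 1}" for c in range(k)], n_per), index=expr.columns)
    return expr, labels


class TestMultinomialLasso:
    def test_separable_classes_small_budget(self, rng):
        expr, labels = _separable_fixture(rng)
        spec = ClassifierSpec(candidate_genes=list(expr.index), gene_budget=6, cv_folds=5, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = fit_multinomial_lasso(expr, labels, spec)
        assert len(model.genes) <= 11
        pred = model.predict(expr)
        assert (pred == labels).all()

    def test_probabilities_sum_to_one(self, rng):
        expr, labels = _separable_fixture(rng)
        spec = ClassifierSpec(candidate_genes=list(expr.index), gene_budget=6, cv_folds=5, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = fit_multinomial_lasso(expr, labels, spec)
        proba = model.predict_proba(expr)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_budget_recovered_on_default_cohort(self, default_cohort):
        counts, meta, truth = default_cohort
        from sepstrat import normalize_log2, size_factors

        expr = normalize_log2(counts, size_factors(counts))
        disc = meta.index[meta["cohort"] == "ER_discovery"]
        labels = truth.endotype_label.reindex(disc)
        candidates = sorted({g for gs in truth.marker_genes.values() for g in gs})
        spec = ClassifierSpec(candidate_genes=candidates, gene_budget=40, cv_folds=5, seed=0)
        model = fit_multinomial_lasso(expr[disc], labels, spec)
        assert 35 <= len(model.genes) <= 45

    def test_class_smaller_than_folds_rejected(self, rng):
        expr, labels = _separable_fixture(rng, n_per=4)
        spec = ClassifierSpec(candidate_genes=list(expr.index), gene_budget=6, cv_folds=5)
        with pytest.raises(ValueError, match="smaller than cv_folds"):
            fit_multinomial_lasso(expr, labels, spec)


class TestPredict:
    @pytest.fixture()
    def fitted(self, rng):
        expr, labels = _separable_fixture(rng)
        spec = ClassifierSpec(candidate_genes=list(expr.index), gene_budget=6, cv_folds=5, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = fit_multinomial_lasso(expr, labels, spec)
        return model, expr, labels

    def test_self_consistent_on_separable_fixture(self, fitted):
        model, expr, labels = fitted
        pred, proba = predict_endotype(model, expr)
        assert (pred == labels).all()

    def test_duplicated_sample_identical_prediction(self, fitted):
        model, expr, _ = fitted
        dup = pd.concat([expr.iloc[:, [0]], expr.iloc[:, [0]].rename(columns={expr.columns[0]: "copy"})], axis=1)
        _, proba = predict_endotype(model, dup)
        assert np.allclose(proba.iloc[0], proba.iloc[1])

    def test_missing_gene_error_names_gene(self, fitted):
        model, expr, _ = fitted
        gone = model.genes[0]
        with pytest.raises(KeyError, match=gone):
            predict_endotype(model, expr.drop(index=gone))

    def test_nonfinite_expression_rejected(self, fitted):
        model, expr, _ = fitted
        bad = expr.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            predict_endotype(model, bad)


def _l1_trainer(c=1.0, seed=0):
    def trainer(e_tr, y_tr):
        est = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c, random_state=seed, max_iter=2000)
        return SklearnOnGenes(list(e_tr.index), est, standardize=True).fit(e_tr, y_tr)

    return trainer


class TestCrossValidate:
    def test_permuted_labels_near_chance(self, rng):
        expr, labels = _separable_fixture(rng, n_per=25, k=2)
        aucs, accs = [], []
        for rep in range(5):
            shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            rep_cv = cross_validate(expr, shuffled, _l1_trainer(), folds=5, repeats=1, seed=rep)
            aucs.append(rep_cv.auc)
            accs.append(rep_cv.accuracy)
        assert abs(np.mean(aucs) - 0.5) < 0.1
        assert abs(np.mean(accs) - 0.5) < 0.12  # max class prevalence = 0.5

    def test_deterministic_under_fixed_seed(self, rng):
        expr, labels = _separable_fixture(rng, k=2)
        r1 = cross_validate(expr, labels, _l1_trainer(), folds=5, repeats=2, seed=9)
        r2 = cross_validate(expr, labels, _l1_trainer(), folds=5, repeats=2, seed=9)
        assert r1.per_fold.equals(r2.per_fold)

    def test_agrees_with_manual_leave_one_out(self, rng):
        """5-fold CV accuracy must track a hand-coded LOO loop on a small
        two-class fixture (same learner, same standardization rule)."""
        expr, labels = _separable_fixture(rng, n_per=15, k=2, sep=1.5)
        rep = cross_validate(expr, labels, _l1_trainer(), folds=5, repeats=5, seed=0)
        x = expr.to_numpy().T
        y = (labels == "E2").to_numpy().astype(int)
        correct = []
        for i in range(len(y)):
            tr = np.arange(len(y)) != i
            mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            est = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0, random_state=0, max_iter=2000)
            est.fit((x[tr] - mu) / sd, y[tr])
            correct.append(est.predict((x[[i]] - mu) / sd)[0] == y[i])
        loo_acc = np.mean(correct)
        assert abs(rep.accuracy - loo_acc) <= 0.05

    def test_class_smaller_than_folds_rejected(self, rng):
        expr, labels = _separable_fixture(rng, n_per=3)
        with pytest.raises(ValueError, match="smaller than fold count"):
            cross_validate(expr, labels, _l1_trainer(), folds=5, repeats=1, seed=0)


class TestGenePairs:
    def test_perfectly_separating_pair_retained_with_unit_auc(self, rng):
        n = 40
        labels = pd.Series(np.repeat(["A", "B"], n // 2), index=[f"S{i}" for i in range(n)])
        x = rng.normal(size=(4, n)) * 0.1
        # the difference G0 - G1 separates class A perfectly
        x[0] += np.where(labels == "A", 2.0, -2.0)
        expr = pd.DataFrame(x, index=[f"G{i}" for i in range(4)], columns=labels.index)
        rules = derive_gene_pairs(expr, labels, list(expr.index), min_auc=0.95, cv_folds=5, seed=0)
        assert any({r.gene_a, r.gene_b} == {"G0", "G1"} and r.cv_auc == 1.0 for r in rules)

    def test_matches_sklearn_per_pair_enumeration(self, rng):
        """Retained set and AUCs must match an independent per-pair loop using
        sklearn logistic fits on the same folds."""
        n, n_genes = 60, 8
        x = rng.normal(size=(n_genes, n))
        labels = pd.Series(rng.choice(["A", "B"], n, p=[0.4, 0.6]), index=[f"S{i}" for i in range(n)])
        x[0] += np.where(labels == "A", 1.5, 0.0)
        x[3] += np.where(labels == "B", 1.0, 0.0)
        expr = pd.DataFrame(x, index=[f"G{i}" for i in range(n_genes)], columns=labels.index)
        genes = list(expr.index)
        min_auc = 0.6
        rules = derive_gene_pairs(expr, labels, genes, min_auc=min_auc, cv_folds=4, seed=2)

        xs = expr.to_numpy().T
        xs = (xs - xs.mean(axis=0)) / xs.std(axis=0)
        expected = {}
        for cls in ["A", "B"]:
            y = (labels == cls).to_numpy().astype(int)
            folds = list(StratifiedKFold(4, shuffle=True, random_state=2).split(xs, y))
            for ia, ib in itertools.combinations(range(n_genes), 2):
                aucs = []
                for tr, te in folds:
                    est = LogisticRegression(C=1e4, max_iter=5000)
                    est.fit(xs[tr][:, [ia, ib]], y[tr])
                    s = est.decision_function(xs[te][:, [ia, ib]])
                    aucs.append(roc_auc_score(y[te], s))
                auc = float(np.mean(aucs))
                if auc >= min_auc:
                    expected[(cls, genes[ia], genes[ib])] = auc
        got = {(r.class_label, r.gene_a, r.gene_b): r.cv_auc for r in rules}
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=0.02)

    def test_sorted_by_class_then_descending_auc(self, rng):
        expr, labels = _separable_fixture(rng, n_per=15, k=2, n_genes=8)
        rules = derive_gene_pairs(expr, labels, list(expr.index), min_auc=0.5, cv_folds=5, seed=0)
        keys = [(r.class_label, -r.cv_auc) for r in rules]
        assert keys == sorted(keys)

    def test_pair_needs_two_distinct_genes(self):
        with pytest.raises(ValueError, match="distinct"):
            PairRule(class_label="A", gene_a="g", gene_b="g", weights=np.zeros(3), cv_auc=1.0)
        with pytest.raises(ValueError, match="at least 2"):
            derive_gene_pairs(pd.DataFrame([[1.0]]), pd.Series(["A"]), ["g"])

    def test_best_pair_never_beats_full_model_by_much(self, rng):
        expr, labels = _separable_fixture(rng, n_per=20, k=3, n_genes=20, sep=1.2)
        spec = ClassifierSpec(candidate_genes=list(expr.index), gene_budget=10, cv_folds=5, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = fit_multinomial_lasso(expr, labels, spec)
        rules = derive_gene_pairs(expr, labels, model.genes or list(expr.index), min_auc=0.0, cv_folds=5, seed=0)
        proba = model.predict_proba(expr)
        for cls in proba.columns:
            y = (labels == cls).astype(int)
            full_auc = roc_auc_score(y, proba[cls])
            best = max(r.cv_auc for r in rules if r.class_label == cls)
            assert best <= full_auc + 0.02
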