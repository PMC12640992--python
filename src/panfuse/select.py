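"""Dual machine-learning hub-gene selection.

Two feature selectors are run independently on the same labelled expression
matrix — an L1-regularised (multinomial) logistic model with a
cross-validated penalty path, and a random forest scored by permutation
importance — and their gene lists are intersected. The intersection is the
hub-gene set; genes stable under both a sparse linear view and a non-linear
tree view of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .io import ExpressionMatrix


@dataclass
class LassoSelection:
    genes: list                 # ordered by descending |coefficient|
    coefficients: dict          # gene -> max |coef| across classes
    lambda_choice: float        # selected penalty (1/C)
    path: pd.DataFrame          # lambda, mean CV log-loss, se, n_selected


@dataclass
class RFSelection:
    genes: list                 # top_n, decreasing importance
    importances: dict           # gene -> permutation importance (all genes)


@dataclass
class SelectionResult:
    lasso: LassoSelection
    rf: RFSelection
    intersection: list          # ordered by rf importance

    @property
    def lasso_genes(self):
        return self.lasso.genes

    @property
    def rf_genes(self):
        return self.rf.genes

    def to_frame(self, gene_universe: Sequence[str]) -> pd.DataFrame:
        inter = set(self.intersection)
        return pd.DataFrame(
            {
                "gene": list(gene_universe),
                "lasso_coef": [self.lasso.coefficients.get(g, 0.0) for g in gene_universe],
                "rf_importance": [self.rf.importances.get(g, 0.0) for g in gene_universe],
                "in_intersection": [g in inter for g in gene_universe],
            }
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Dual hub-gene selection (L1 logistic ∩ random-forest importance)",
                f"  lasso-selected genes: {len(self.lasso.genes)}"
                f"  (lambda = {self.lasso.lambda_choice:.4g}, one-standard-error rule)",
                f"  rf top genes: {len(self.rf.genes)}",
                f"  intersection (hub genes): {len(self.intersection)}"
                + (f" -> {', '.join(self.intersection[:10])}" if self.intersection else ""),
            ]
        )


def _cv_logloss(X, y, C, n_folds, seed):
    """Stratified K-fold mean/SE log-loss for one penalty value."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    losses = []
    for tr, te in skf.split(X, y):
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="saga", max_iter=1500, tol=1e-3, random_state=seed
        )
        clf.fit(X[tr], y[tr])
        p = np.clip(clf.predict_proba(X[te]), 1e-12, 1)
        classes = clf.classes_
        idx = np.searchsorted(classes, y[te])
        losses.append(float(-np.mean(np.log(p[np.arange(te.size), idx]))))
    losses = np.asarray(losses)
    return losses.mean(), losses.std(ddof=1) / np.sqrt(n_folds)


def lasso_select(
    X: ExpressionMatrix,
    y,
    n_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 16,
    rule: str = "1se",
) -> LassoSelection:
    """L1-penalised gene selection with a cross-validated penalty path.

    The penalty grid is logarithmic; the chosen lambda follows the
    one-standard-error rule by default (the sparsest model whose CV loss is
    within one SE of the minimum; ``rule="min"`` takes the minimiser). A gene
    is selected if its coefficient is nonzero for any class.
    """
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("lasso_select needs at least 2 classes")
    if X.n_samples < n_folds:
        raise ValueError("fewer samples than CV folds")
    M = StandardScaler().fit_transform(X.samples_matrix())

    lambdas = np.logspace(-2, 1.2, n_lambdas)  # penalty = 1/C
    records = []
    for lam in lambdas:
        mean, se = _cv_logloss(M, y, 1.0 / lam, n_folds, seed)
        records.append({"lambda": lam, "cv_logloss": mean, "se": se})
    path = pd.DataFrame(records)

    i_min = int(path["cv_logloss"].idxmin())
    if rule == "1se":
        threshold = path.loc[i_min, "cv_logloss"] + path.loc[i_min, "se"]
        admissible = path.index[path["cv_logloss"] <= threshold]
        choice = int(max(admissible))  # largest penalty => sparsest
    else:
        choice = i_min
    lam = float(path.loc[choice, "lambda"])

    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / lam, solver="saga", max_iter=3000, tol=1e-4, random_state=seed
    )
    clf.fit(M, y)
    coef = np.atleast_2d(clf.coef_)
    max_abs = np.abs(coef).max(axis=0)
    selected = np.where(max_abs > 1e-10)[0]
    order = selected[np.argsort(-max_abs[selected], kind="stable")]
    genes = [X.gene_ids[i] for i in order]
    coefficients = {X.gene_ids[i]: float(max_abs[i]) for i in range(X.n_genes)}

    return LassoSelection(genes=genes, coefficients=coefficients, lambda_choice=lam, path=path)


def lasso_path_counts(X: ExpressionMatrix, y, lambdas: Sequence[float], seed: int = 0) -> list:
    """Number of selected genes at each penalty (for monotonicity checks)."""
    y = np.asarray(y, dtype=int)
    M = StandardScaler().fit_transform(X.samples_matrix())
    counts = []
    for lam in lambdas:
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="saga", max_iter=3000, tol=1e-4, random_state=seed
        )
        clf.fit(M, y)
        counts.append(int((np.abs(np.atleast_2d(clf.coef_)).max(axis=0) > 1e-10).sum()))
    return counts


def rf_select(
    X: ExpressionMatrix,
    y,
    n_trees: int = 1000,
    top_n: int = 30,
    seed: int = 0,
    n_permutations: int = 3,
) -> RFSelection:
    """Random-forest gene ranking by permutation importance."""
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100")
    if top_n > X.n_genes:
        raise ValueError(f"top_n={top_n} exceeds n_genes={X.n_genes}")
    y = np.asarray(y, dtype=int)
    M = X.samples_matrix()
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(M, y)
    imp = permutation_importance(
        rf, M, y, n_repeats=n_permutations, random_state=seed, n_jobs=1
    )
    importances = imp.importances_mean
    order = np.argsort(-importances, kind="stable")[:top_n]
    genes = [X.gene_ids[i] for i in order]
    return RFSelection(
        genes=genes,
        importances={X.gene_ids[i]: float(importances[i]) for i in range(X.n_genes)},
    )


def intersect(lasso: LassoSelection, rf: RFSelection) -> SelectionResult:
    """Hub genes = LASSO ∩ RF, ordered by decreasing RF importance."""
    common = set(lasso.genes) & set(rf.genes)
    if not common:
        warnings.warn("LASSO and random-forest selections do not overlap", UserWarning)
    intersection = [g for g in rf.genes if g in common]
    return SelectionResult(lasso=lasso, rf=rf, intersection=intersection)


class HubGeneSelector:
    """Model wrapper: run both selectors on a labelled cohort and intersect.

    Parameters mirror :func:`lasso_select` and :func:`rf_select`.
    """

    def __init__(
        self,
        X: ExpressionMatrix,
        labels,
        n_folds: int = 5,
        n_trees: int = 1000,
        top_n: int = 30,
        lambda_rule: str = "1se",
        seed: int = 0,
    ):
        self.X = X
        self.labels = np.asarray(labels, dtype=int)
        self.n_folds = n_folds
        self.n_trees = n_trees
        self.top_n = min(top_n, X.n_genes)
        self.lambda_rule = lambda_rule
        self.seed = seed

    def fit(self) -> SelectionResult:
        lasso = lasso_select(
            self.X, self.labels, n_folds=self.n_folds, seed=self.seed, rule=self.lambda_rule
        )
        rf = rf_select(
            self.X, self.labels, n_trees=self.n_trees, top_n=self.top_n, seed=self.seed
        )
        return intersect(lasso, rf)
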