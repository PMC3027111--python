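"""Taxonomic classification from unigram composition.

Multinomial logistic regression with a single predictor per model — one
amino acid's percentage frequency, or the score on the first principal
component of the full 20-dimensional composition — evaluated with
stratified 10-fold cross-validation at genus, class, and phylum level.
With q categories the model has q-1 logit equations relative to a
baseline category; the prediction is the highest-probability category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .io import TaxonomyRecord

logger = logging.getLogger(__name__)

LEVELS = ("genus", "class", "phylum")


def select_training_subset(
    taxonomy: Sequence[TaxonomyRecord], min_species: int = 9
) -> List[str]:
    """Ids of organisms belonging to genera with >= ``min_species`` members."""
    if not taxonomy:
        raise ValueError("taxonomy is empty")
    sizes: Dict[str, int] = {}
    for rec in taxonomy:
        sizes[rec.genus] = sizes.get(rec.genus, 0) + 1
    keep = {g for g, c in sizes.items() if c >= min_species}
    ids = [r.organism_id for r in taxonomy if r.genus in keep]
    if not ids:
        raise ValueError(f"no genus has >= {min_species} species")
    return ids


class UnigramTaxonomyClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial logistic regression on compositional features.

    A small L2 ridge penalty (``ridge``, default 1e-6) guards against
    perfect separation, which single-feature fits on small genera reach
    easily and which would otherwise send coefficients to infinity.

    Attributes (after ``fit``)
    --------------------------
    classes_ : category labels, sklearn order
    baseline_ : the baseline (reference) category — most frequent label
        unless given explicitly
    intercept_baseline_, coef_baseline_ : coefficients of the q-1 logit
        equations log(P(j)/P(baseline)), rows aligned with
        ``nonbaseline_classes_``.  Predictions do not depend on the choice
        of baseline; only this report does.
    """

    def __init__(self, ridge: float = 1e-6, baseline: Optional[str] = None,
                 max_iter: int = 1000):
        self.ridge = ridge
        self.baseline = baseline
        self.max_iter = max_iter

    def fit(self, X, y) -> "UnigramTaxonomyClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        y = np.asarray(y)
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) < 2:
            raise ValueError("need >= 2 categories")
        if self.ridge <= 0:
            raise ValueError("ridge must be > 0")
        self._lr = LogisticRegression(
            C=1.0 / self.ridge, solver="lbfgs", max_iter=self.max_iter
        ).fit(X, y)
        self.classes_ = self._lr.classes_
        self.n_features_in_ = X.shape[1]
        baseline = self.baseline
        if baseline is None:
            baseline = labels[np.argmax(counts)]
        elif baseline not in labels:
            raise ValueError(f"baseline {baseline!r} not among labels")
        self.baseline_ = baseline
        # sklearn's multinomial parametrisation is symmetric; subtracting the
        # baseline row yields the q-1 baseline-relative logit equations
        coef, intercept = self._lr.coef_, self._lr.intercept_
        if len(self.classes_) == 2:
            # sklearn stores a single row w for log(P(classes_[1])/P(classes_[0]))
            coef = np.vstack([-coef[0] / 2, coef[0] / 2])
            intercept = np.array([-intercept[0] / 2, intercept[0] / 2])
        b = int(np.where(self.classes_ == baseline)[0][0])
        keep = np.arange(len(self.classes_)) != b
        self.nonbaseline_classes_ = self.classes_[keep]
        self.coef_baseline_ = coef[keep] - coef[b]
        self.intercept_baseline_ = intercept[keep] - intercept[b]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "_lr")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        return self._lr.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_lr")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        return self._lr.predict(X)


def fit_mlr(features, labels, baseline: Optional[str] = None,
            ridge: float = 1e-6) -> UnigramTaxonomyClassifier:
    """Thin functional wrapper over :class:`UnigramTaxonomyClassifier`."""
    return UnigramTaxonomyClassifier(ridge=ridge, baseline=baseline).fit(
        features, labels
    )


def first_principal_component(features) -> np.ndarray:
    """Per-organism score on the leading principal component of the
    (column-centered) organism x unigram-frequency matrix.

    Sign convention: the loading vector's largest-magnitude entry is
    positive, making the score deterministic across runs and libraries.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    if np.allclose(X, X[0]):
        raise ValueError("zero-variance matrix: PC1 undefined")
    pca = PCA(n_components=1, svd_solver="full").fit(X)
    loading = pca.components_[0]
    sign = np.sign(loading[np.argmax(np.abs(loading))]) or 1.0
    return (pca.transform(X)[:, 0] * sign).astype(float)


@dataclass
class CVResult:
    level: str
    predictor_spec: str
    fold_accuracies: List[float]
    mean_accuracy: float
    sd: float
    n_folds: int
    seed: int


def cross_validate(
    features,
    labels,
    level: str = "genus",
    folds: int = 10,
    seed: int = 0,
    ridge: float = 1e-6,
    predictor_spec: str = "",
) -> CVResult:
    """Stratified seeded k-fold cross-validation of the single-predictor
    model; per-fold accuracy is the fraction of held-out organisms whose
    argmax category equals the truth."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(labels)
    min_class = np.min(np.unique(y, return_counts=True)[1])
    eff_folds = int(min(folds, min_class))
    if eff_folds < folds:
        logger.warning(
            "smallest category has %d members; using %d folds", min_class,
            eff_folds,
        )
    if eff_folds < 2:
        raise ValueError("smallest category too small for cross-validation")
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        train_labels = np.unique(y[train_idx])
        if len(train_labels) < 2:
            logger.warning("fold skipped: <2 categories present in training")
            continue
        clf = UnigramTaxonomyClassifier(ridge=ridge).fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
    return CVResult(
        level=level,
        predictor_spec=predictor_spec,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        n_folds=len(accs),
        seed=seed,
    )


def accuracy_table(
    freq_matrix: pd.DataFrame,
    taxonomy: Sequence[TaxonomyRecord],
    levels: Sequence[str] = LEVELS,
    min_species: int = 9,
    folds: int = 10,
    seed: int = 0,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Per-predictor, per-level CV accuracies: 20 single-unigram models
    plus the PC1 model, on organisms from genera with >= ``min_species``
    members.

    ``freq_matrix`` is organisms x unigram percentage frequencies, indexed
    by organism_id.
    """
    ids = select_training_subset(taxonomy, min_species=min_species)
    ids = [i for i in ids if i in freq_matrix.index]
    tax = {r.organism_id: r for r in taxonomy}
    X = freq_matrix.loc[ids]
    label_of = {
        "genus": lambda r: r.genus,
        "class": lambda r: r.taxon_class,
        "phylum": lambda r: r.phylum,
    }
    predictors = {col: X[col].to_numpy() for col in X.columns}
    predictors["PC1"] = first_principal_component(X.to_numpy())
    rows = []
    for level in levels:
        y = np.array([label_of[level](tax[i]) for i in ids])
        if len(np.unique(y)) < 2:
            logger.warning("level %s has a single category; skipped", level)
            continue
        for name, x in predictors.items():
            cv = cross_validate(x, y, level=level, folds=folds, seed=seed,
                                ridge=ridge, predictor_spec=name)
            rows.append(
                {
                    "level": level,
                    "predictor": name,
                    "mean_accuracy": cv.mean_accuracy,
                    "sd": cv.sd,
                    "n_organisms": len(ids),
                    "n_categories": len(np.unique(y)),
                }
            )
    return pd.DataFrame(rows)
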