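"""Stratified 10-fold comparison of the fixed classifier zoo.

Eleven classifiers are compared with stratified k-fold cross-validation
(k = 10 by default) on identical fold assignments, so differences between
rows are paired. Hyperparameters follow the comparison protocol: linear SVC
with l2 penalty, 200-tree random forest, RBF-kernel SVC, K = 15 nearest
neighbours, a two-hidden-layer 40 + 40 logistic-activation network with
regularization 0.001, a larger 271/180/280 logistic network trained with an
Adam-family optimizer (eta = 0.002, beta1 = 0.9, beta2 = 0.999), a fully
grown decision tree, an RBF Gaussian process, Gaussian naive Bayes,
l1-penalized logistic regression with C = 1, and AdaBoost over decision
stumps. Feature standardization and (optionally) coefficient-ranked feature
selection are fitted inside each training fold; the leakage-prone
whole-dataset selection variant is available behind an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .selection import SelectionModel, apply_selection, fit_selector


@dataclass
class ClassifierSpec:
    """One zoo entry: a named estimator factory with its hyperparameters."""

    name: str
    build: callable  # seed -> unfitted estimator
    hyperparameters: dict = field(default_factory=dict)
    source_table: str = ""
    grid: dict = field(default_factory=dict)  # small documented grid-search grid


@dataclass
class CVReport:
    """Cross-validation result for one classifier on one target skill."""

    classifier: str
    hyperparameters: dict
    fold_accuracies: tuple
    seed: int
    skill: str = ""
    feature_set: str = "combined"
    data_variant: str = "nodc"

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def default_zoo(seed: int = 0) -> list:
    """The eleven comparison classifiers with their fixed hyperparameters."""
    return [
        ClassifierSpec(
            # joint multiclass hinge (Crammer-Singer): with an ordered
            # three-level target the middle class need not be linearly
            # separable from the union of the outer two, which breaks
            # one-vs-rest linear SVMs when the discriminative signal is
            # low-rank; the joint formulation partitions the discriminant
            # axis into intervals instead
            "LinSVC",
            lambda s: LinearSVC(
                penalty="l2", multi_class="crammer_singer", random_state=s, max_iter=20000
            ),
            {"penalty": "l2", "multi_class": "crammer_singer"}, "combined",
            {"C": [0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0]},
        ),
        ClassifierSpec(
            "RF", lambda s: RandomForestClassifier(n_estimators=200, random_state=s),
            {"n_estimators": 200}, "combined", {"max_depth": [None, 5, 10]},
        ),
        ClassifierSpec(
            "SVC", lambda s: SVC(kernel="rbf", random_state=s),
            {"kernel": "rbf"}, "combined", {"C": [0.1, 1.0, 10.0, 100.0]},
        ),
        ClassifierSpec(
            "KNN", lambda s: KNeighborsClassifier(n_neighbors=15),
            {"n_neighbors": 15}, "combined", {"n_neighbors": [5, 10, 15]},
        ),
        ClassifierSpec(
            "NN",
            lambda s: MLPClassifier(
                hidden_layer_sizes=(40, 40), activation="logistic", alpha=0.001,
                max_iter=500, random_state=s,
            ),
            {"hidden_layer_sizes": (40, 40), "activation": "logistic", "alpha": 0.001},
            "combined", {"alpha": [1e-4, 1e-3, 1e-2]},
        ),
        ClassifierSpec(
            "NN-dropout",
            # 271/180/280 logistic architecture; sklearn has no dropout layer,
            # so its regularizing role is played by the l2 term (early stopping
            # is unreliable with the tiny validation splits of 90-subject folds)
            lambda s: MLPClassifier(
                hidden_layer_sizes=(271, 180, 280), activation="logistic",
                solver="adam", learning_rate_init=0.002, beta_1=0.9, beta_2=0.999,
                alpha=0.01, max_iter=400, random_state=s,
            ),
            {"hidden_layer_sizes": (271, 180, 280), "activation": "logistic",
             "learning_rate_init": 0.002, "beta_1": 0.9, "beta_2": 0.999},
            "combined",
        ),
        ClassifierSpec(
            "DT",
            lambda s: DecisionTreeClassifier(
                min_samples_split=2, min_samples_leaf=1, random_state=s
            ),
            {"min_samples_split": 2, "min_samples_leaf": 1}, "combined",
        ),
        ClassifierSpec(
            "GP",
            lambda s: GaussianProcessClassifier(kernel=1.0 * RBF(1.0), random_state=s),
            {"kernel": "RBF"}, "combined",
        ),
        ClassifierSpec("GNB", lambda s: GaussianNB(), {}, "combined"),
        ClassifierSpec(
            "LR",
            # l1 penalty, C = 1; one-vs-rest over liblinear for 3 classes
            lambda s: OneVsRestClassifier(
                LogisticRegression(
                    l1_ratio=1.0, C=1.0, solver="liblinear", random_state=s, max_iter=2000
                )
            ),
            {"penalty": "l1", "C": 1.0}, "combined",
        ),
        ClassifierSpec(
            "AB", lambda s: AdaBoostClassifier(random_state=s),
            {"base_estimator": "decision stump"}, "combined",
        ),
    ]


class CoefficientSelector(BaseEstimator, TransformerMixin):
    """Fold-internal wrapper around :func:`fit_selector` for sklearn pipelines."""

    def __init__(self, penalty="l1", lam=1.0, seed=0):
        self.penalty = penalty
        self.lam = lam
        self.seed = seed

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.model_ = fit_selector(X, y, self.penalty, self.lam, self.seed)
        return self

    def transform(self, X):
        return apply_selection(pd.DataFrame(X, columns=self.model_.feature_names), self.model_)


class RandomUnderSamplingBoost(BaseEstimator):
    """AdaBoost over decision stumps trained on a class-balanced undersample.

    Before fitting, every class is randomly undersampled to the minority
    class size; an option for skewed targets, not part of the default zoo.
    """

    def __init__(self, seed=0, n_estimators=50):
        self.seed = seed
        self.n_estimators = n_estimators

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        classes, counts = np.unique(y, return_counts=True)
        m = counts.min()
        idx = np.concatenate(
            [rng.choice(np.flatnonzero(y == c), size=m, replace=False) for c in classes]
        )
        self.model_ = AdaBoostClassifier(
            n_estimators=self.n_estimators, random_state=self.seed
        ).fit(X[idx], y[idx])
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X))


def _build_pipeline(spec: ClassifierSpec, seed: int, selection: dict | None, grid_search: bool):
    steps = [("scale", StandardScaler())]
    if selection is not None:
        steps.append(
            (
                "select",
                CoefficientSelector(
                    penalty=selection.get("penalty", "l1"),
                    lam=selection.get("lam", 1.0),
                    seed=seed,
                ),
            )
        )
    clf = spec.build(seed)
    if grid_search and spec.grid:
        # tune only the classifier on the already-selected training features:
        # the selector is label-driven but its fit does not depend on the
        # classifier's hyperparameters, so it needs fitting once per fold
        clf = GridSearchCV(clf, spec.grid, cv=5, scoring="accuracy", n_jobs=1)
    steps.append(("clf", clf))
    return Pipeline(steps)


def run_comparison(
    X: pd.DataFrame,
    y,
    zoo: list | None = None,
    k: int = 10,
    seed: int = 0,
    selection: dict | None = None,
    leaky_selection: bool = False,
    grid_search: bool = False,
    skill: str = "",
    feature_set: str = "combined",
    data_variant: str = "nodc",
) -> list:
    """Stratified k-fold comparison of every classifier in the zoo.

    ``selection`` (e.g. ``{"penalty": "l1", "lam": 1.0}``) enables
    coefficient-ranked feature selection, fitted inside each training fold by
    default; ``leaky_selection`` instead fits it once on the full table
    before cross-validation (reproducing the protocol whose fold placement
    is ambiguous — statistically optimistic, off by default). With
    ``grid_search`` each classifier's small documented grid is searched in an
    inner stratified 3-fold loop. Fold assignments are shared across
    classifiers for paired comparison.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    zoo = zoo if zoo is not None else default_zoo(seed)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than k={k} folds; "
            f"reduce k to at most {counts.min()}"
        )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    inner_selection = selection
    if selection is not None and leaky_selection:
        model = fit_selector(
            X, y, selection.get("penalty", "l1"), selection.get("lam", 1.0), seed
        )
        X = apply_selection(X, model)
        inner_selection = None
    reports = []
    for spec in zoo:
        est = _build_pipeline(spec, seed, inner_selection, grid_search)
        folds = cross_val_score(est, X, y, cv=cv, scoring="accuracy", n_jobs=1)
        reports.append(
            CVReport(
                classifier=spec.name,
                hyperparameters=dict(spec.hyperparameters),
                fold_accuracies=tuple(float(a) for a in folds),
                seed=seed,
                skill=skill,
                feature_set=feature_set,
                data_variant=data_variant,
            )
        )
    return reports


def report_table(reports: list) -> pd.DataFrame:
    """Mean-accuracy table: rows = classifiers, columns = target skills."""
    if not reports:
        raise ValueError("no reports to tabulate")
    rows = {}
    for r in reports:
        rows.setdefault(r.classifier, {})[r.skill or "accuracy"] = r.mean_accuracy
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "classifier"
    return df


def format_table(df: pd.DataFrame) -> str:
    """Human-readable rendering; the best cell per column is starred."""
    out = df.copy().astype(object)
    for col in df.columns:
        best = df[col].idxmax()
        for idx in df.index:
            mark = "*" if idx == best else " "
            out.loc[idx, col] = f"{df.loc[idx, col]:.3f}{mark}"
    return out.to_string()
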