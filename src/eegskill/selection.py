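"""Score encoding and coefficient-ranked regularized feature selection.

Cognitive scores on the 0-800 scale are encoded into three levels at the
200/400 thresholds. Feature selection fits a regularized multiclass
logistic regression (objective: cross-entropy loss plus an l1 or l2 penalty
lambda * ||w|| on the coefficient vector) to standardized features and
retains the features whose coefficients are large: weak predictors shrink
toward zero under the penalty, so coefficient magnitude ranks importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler

LEVELS = ("low", "moderate", "high")


def encode_score(score: float) -> str:
    """Map a 0-800 cognitive score to its level: low < 200 <= moderate < 400 <= high."""
    if not 0 <= score <= 800:
        raise ValueError(f"score {score} outside the 0-800 scale")
    if score < 200:
        return "low"
    if score < 400:
        return "moderate"
    return "high"


@dataclass
class SelectionModel:
    """Fitted selector: per-class coefficients and the retained-feature mask.

    ``coefficients`` is a classes x features frame from a one-vs-rest fit on
    standardized features; a feature's importance is its maximum absolute
    coefficient across classes, and features at or above the mean importance
    are retained (the common default threshold for model-based selection).
    """

    penalty: str
    lam: float
    feature_names: tuple
    coefficients: pd.DataFrame
    retained_mask: np.ndarray
    threshold_rule: str = "max-|coef| over classes >= mean over features"
    classes: tuple = field(default_factory=tuple)

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    def retained_features(self) -> list:
        return [n for n, m in zip(self.feature_names, self.retained_mask) if m]


def fit_selector(
    X: pd.DataFrame, y, penalty: str = "l1", lam: float = 1.0, seed: int = 0
) -> SelectionModel:
    """Fit the regularized-logistic selector on a feature table.

    Features are standardized (zero mean, unit variance) before fitting, so
    coefficient magnitudes are comparable across mixed units (uV^2, dB,
    p-values). ``lam`` is the penalty weight (sklearn's ``C = 1/lam``).
    Raises if the labels contain a single class or if the penalty drives
    every coefficient to zero (nothing left to retain).
    """
    X = pd.DataFrame(X)
    if X.isna().any().any():
        raise ValueError("feature table contains missing values")
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes to fit the selector")
    if penalty not in ("l1", "l2"):
        raise ValueError("penalty must be 'l1' or 'l2'")
    if lam <= 0:
        raise ValueError("lam must be positive")
    Xs = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    base = LogisticRegression(
        l1_ratio=1.0 if penalty == "l1" else 0.0,
        C=1.0 / lam, solver="liblinear", max_iter=2000, random_state=seed,
    )
    model = OneVsRestClassifier(base).fit(Xs, y)
    coef = np.vstack([est.coef_[0] for est in model.estimators_])
    importance = np.abs(coef).max(axis=0)
    if not np.any(importance > 0):
        raise ValueError(
            "all coefficients are zero under the requested penalty; "
            "no features can be retained (reduce lam)"
        )
    mask = importance >= importance.mean()
    return SelectionModel(
        penalty=penalty,
        lam=lam,
        feature_names=tuple(X.columns),
        coefficients=pd.DataFrame(coef, index=list(model.classes_), columns=X.columns),
        retained_mask=mask,
        classes=tuple(model.classes_),
    )


def apply_selection(X: pd.DataFrame, model: SelectionModel) -> pd.DataFrame:
    """Restrict a feature table to the selector's retained columns, order kept."""
    X = pd.DataFrame(X)
    expected = list(model.feature_names)
    if list(X.columns) != expected:
        missing = sorted(set(expected) - set(X.columns))
        extra = sorted(set(X.columns) - set(expected))
        raise ValueError(
            f"feature table does not match the selector: missing {missing}, unexpected {extra}"
        )
    return X.loc[:, model.retained_mask]
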