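"""SVM and extra-trees classifiers with sensitivity-scored grid search.

Hyperparameters are chosen by stratified cross-validated grid search scored
by sensitivity (recall on the bleeding-present class), matching the
sensitivity-first evaluation stance, then the best configuration is refit on
all provided data.  Fold count defaults to 10 and is reduced to the
minority-class count on corpora too small for stratified 10-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.feature_selection import SelectKBest
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

__all__ = ["ModelSpec", "TrainedModel", "train_classic", "CLASSIC_GRIDS"]

FAMILIES = ("svm", "extra_trees", "cnn")
SAMPLES = ("full", "down_sampled")

#: Declared hyperparameter grids; returned parameters always belong here.
CLASSIC_GRIDS: Dict[str, Dict[str, list]] = {
    "svm": {"clf__C": [0.1, 1, 10, 100], "clf__kernel": ["linear", "rbf"]},
    "extra_trees": {
        "clf__n_estimators": [100, 300, 500],
        "clf__max_depth": [None, 10, 30],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the six supervised model variants (family x sampling)."""

    family: str
    sample: str = "full"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.sample not in SAMPLES:
            raise ValueError(f"unknown sample mode {self.sample!r}")

    @property
    def name(self) -> str:
        suffix = "ds" if self.sample == "down_sampled" else "fs"
        return f"{self.family}_{suffix}"


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    best_params: dict
    cv_sensitivity: float

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=int)


def _base_estimator(family: str, seed: int):
    if family == "svm":
        return SVC(random_state=seed)
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed)
    raise ValueError(f"train_classic does not handle family {family!r}")


def train_classic(
    spec: ModelSpec,
    X,
    gold: Sequence[int],
    grid: Optional[Dict[str, list]] = None,
    cv_folds: int = 10,
    select_k: Optional[int] = None,
) -> TrainedModel:
    """Grid-search and fit an SVM or extra-trees classifier.

    ``X`` is a note-by-feature matrix (sparse or dense).  When ``select_k``
    is given, chi-square selection to ``select_k`` features is performed
    inside each cross-validation fold (avoiding selection leakage) and in
    the final refit; otherwise ``X`` is used as-is.
    """
    if spec.family not in ("svm", "extra_trees"):
        raise ValueError("train_classic handles svm and extra_trees only")
    y = np.asarray(gold, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels must contain both classes")
    if y.size < 20:
        raise ValueError("need at least 20 labeled notes to train")
    n_splits = min(cv_folds, int(counts.min()))
    if n_splits < 2:
        raise ValueError("stratified folding impossible: minority class too small")

    steps = []
    if select_k is not None:
        k = min(select_k, X.shape[1])
        steps.append(("select", SelectKBest(sk_chi2, k=k)))
    steps.append(("clf", _base_estimator(spec.family, spec.seed)))
    pipe = Pipeline(steps)

    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        pipe,
        param_grid=grid if grid is not None else CLASSIC_GRIDS[spec.family],
        scoring="recall",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    Xs = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X)
    search.fit(Xs, y)
    best = {
        key.removeprefix("clf__"): val for key, val in search.best_params_.items()
    }
    return TrainedModel(
        spec=spec,
        estimator=search.best_estimator_,
        best_params=best,
        cv_sensitivity=float(search.best_score_),
    )
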