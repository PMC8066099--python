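"""Classifier zoo, repeated cross-validated AUC model selection, final refit.

Fifteen classifier configurations are compared: three random-forest variants
(fixed defaults, grid-tuned mtry, random-search mtry) and twelve other
standard learners (trees, boosted trees, discriminant analyses, nearest
centroids/neighbours, naive Bayes, logistic regression, a one-hidden-layer
neural network, PLS and a polynomial-kernel SVM). Each is scored by the mean
of 24 held-out ROC AUCs from 3 repeats of stratified 8-fold cross-validation
(a fresh randomised split per repeat); the highest mean AUC wins (ties:
lower SD, then roster order). The winner is refitted on the whole cohort to
produce the final per-case pCR probabilities.

The random-forest default configuration follows the convention
ntree = 500, mtry = floor(sqrt(p)) for p selected features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import auc as roc_auc
from .table import FeatureTable

__all__ = [
    "ROSTER",
    "ClassifierSpec",
    "ModelSelectionReport",
    "rf_default_hyperparams",
    "make_classifier",
    "repeated_cv_auc",
    "summarize_and_rank",
    "evaluate_roster",
    "fit_final",
]

#: roster order is also the last tie-break in model ranking
ROSTER = (
    "C5TREE",
    "DT",
    "HDDA",
    "KNN",
    "LOGREG",
    "NB",
    "NN",
    "PAM",
    "PDA",
    "PLS",
    "RF_DEF",
    "RF_GRID",
    "RF_RAND",
    "SDA",
    "SVM",
)


def rf_default_hyperparams(p: int) -> dict:
    """Default random-forest settings: 500 trees, mtry = floor(sqrt(p))."""
    if p < 1:
        raise ValueError("need at least one selected feature")
    return {"n_estimators": 500, "max_features": max(int(math.floor(math.sqrt(p))), 1)}


@dataclass(frozen=True)
class ClassifierSpec:
    key: str
    tuning_mode: str = "default"  # default | grid | random
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.key not in ROSTER:
            raise ValueError(f"unknown classifier key: {self.key!r}")


class PLSClassifier(BaseEstimator, ClassifierMixin):
    """Partial-least-squares classifier: PLS regression on the 0/1 outcome.

    The continuous PLS prediction, clipped to [0, 1], serves as the class-1
    probability (any monotone map preserves ROC ordering).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.classes_ = np.unique(y).astype(int)
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pls_ = PLSRegression(n_components=max(k, 1))
        self.pls_.fit(X, y)
        return self

    def predict_proba(self, X):
        p1 = np.clip(self.pls_.predict(np.asarray(X, dtype=float)).ravel(), 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class CentroidScoreClassifier(BaseEstimator, ClassifierMixin):
    """Shrunken nearest-centroid with a continuous decision function.

    ``decision_function`` is the difference of distances to the two class
    centroids, so the model can be wrapped with a sigmoid calibration to
    yield probabilities (centroid models natively emit only hard labels).
    """

    def __init__(self, shrink_threshold: float = 0.2):
        self.shrink_threshold = shrink_threshold

    def fit(self, X, y):
        self.nc_ = NearestCentroid(shrink_threshold=self.shrink_threshold)
        self.nc_.fit(X, y)
        self.classes_ = self.nc_.classes_
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self.nc_.centroids_[None, :, :], axis=2)
        return d[:, 0] - d[:, 1]  # positive when closer to class 1

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class OobMtryRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest with mtry tuned on the training data via out-of-bag AUC.

    Each candidate ``max_features`` value is scored by the ROC AUC of the
    forest's out-of-bag class-1 votes (the standard way mtry is tuned in the
    R random-forest ecosystem); the best candidate's forest is kept. Ties go
    to the smaller mtry. Tuning therefore never sees the held-out fold.
    """

    def __init__(self, candidates=(2,), n_estimators=500, random_state=0):
        self.candidates = candidates
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        best = None
        for mtry in self.candidates:
            rf = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=int(mtry),
                oob_score=True,
                random_state=self.random_state,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rf.fit(X, y)
            oob = rf.oob_decision_function_[:, list(rf.classes_).index(1)]
            seen = ~np.isnan(oob)
            if len(np.unique(y[seen])) < 2:
                score = 0.5
            else:
                score = roc_auc(oob[seen], y[seen])
            if best is None or score > best[0]:
                best = (score, int(mtry), rf)
        self.oob_auc_, self.max_features_, self.forest_ = best
        self.classes_ = self.forest_.classes_
        return self

    def predict_proba(self, X):
        return self.forest_.predict_proba(X)

    def predict(self, X):
        return self.forest_.predict(X)


def _scaled(clf) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _mtry_grid(p: int, budget: int = 10) -> list[int]:
    cand = sorted(set(np.linspace(1, p, num=min(budget, p)).round().astype(int)))
    return [int(c) for c in cand]


def make_classifier(key: str, n_features: int, seed: int = 0):
    """Instantiate the roster classifier ``key`` for ``n_features`` inputs.

    Every returned estimator exposes ``predict_proba`` (score-only models are
    wrapped with a sigmoid calibration fitted on the training folds).
    """
    p = max(int(n_features), 1)
    inner_cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    if key == "C5TREE":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    if key == "DT":  # boosted decision trees
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3, criterion="entropy"),
            n_estimators=50,
            random_state=seed,
        )
    if key == "HDDA":  # regularised quadratic discriminant analysis
        return _scaled(QuadraticDiscriminantAnalysis(reg_param=0.5))
    if key == "KNN":
        return _scaled(KNeighborsClassifier(n_neighbors=7, weights="distance"))
    if key == "LOGREG":
        return _scaled(LogisticRegression(penalty=None, max_iter=2000))
    if key == "NB":
        return GaussianNB()
    if key == "NN":
        return _scaled(
            MLPClassifier(
                hidden_layer_sizes=(5,), alpha=1e-2, max_iter=2000, random_state=seed
            )
        )
    if key == "PAM":  # nearest shrunken centroids + sigmoid calibration
        return _scaled(
            CalibratedClassifierCV(
                CentroidScoreClassifier(shrink_threshold=0.2),
                method="sigmoid",
                cv=inner_cv,
            )
        )
    if key == "PDA":  # discriminant analysis with a fixed ridge penalty
        return _scaled(LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.5))
    if key == "PLS":
        return _scaled(PLSClassifier(n_components=min(2, p)))
    if key == "RF_DEF":
        hp = rf_default_hyperparams(p)
        return RandomForestClassifier(random_state=seed, **hp)
    if key == "RF_GRID":
        return OobMtryRandomForest(
            candidates=tuple(_mtry_grid(p)), n_estimators=500, random_state=seed
        )
    if key == "RF_RAND":
        rng = np.random.default_rng(seed)
        n_cand = min(10, p)
        cand = tuple(
            int(c) for c in rng.choice(np.arange(1, p + 1), size=n_cand, replace=False)
        )
        return OobMtryRandomForest(
            candidates=cand, n_estimators=500, random_state=seed
        )
    if key == "SDA":  # shrinkage discriminant analysis (Ledoit-Wolf)
        return _scaled(LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"))
    if key == "SVM":
        return _scaled(
            SVC(kernel="poly", degree=3, probability=True, random_state=seed)
        )
    raise ValueError(f"unknown classifier key: {key!r}")


def _scores(model, X) -> np.ndarray:
    proba = model.predict_proba(X)
    cls = list(np.asarray(model.classes_).astype(int))
    return proba[:, cls.index(1)]


@dataclass
class ModelSelectionReport:
    """24 held-out AUCs per classifier, their mean/SD, and the winner."""

    aucs: dict[str, list[float]]
    repeat_seeds: list[int]
    k: int
    repeats: int

    @property
    def mean_auc(self) -> dict[str, float]:
        return {k: float(np.nanmean(v)) for k, v in self.aucs.items()}

    @property
    def sd_auc(self) -> dict[str, float]:
        return {k: float(np.nanstd(v, ddof=1)) for k, v in self.aucs.items()}

    @property
    def winner(self) -> str:
        means, sds = self.mean_auc, self.sd_auc
        valid = [k for k in self.aucs if np.isfinite(means[k])]
        if not valid:
            raise RuntimeError("every classifier failed model selection")
        return min(valid, key=lambda k: (-means[k], sds[k], ROSTER.index(k)))

    def ranking(self) -> pd.DataFrame:
        """Ranked mean/SD AUC table (two decimals, best first)."""
        df = pd.DataFrame(
            {
                "Model": list(self.aucs),
                "Mean AUC": [round(self.mean_auc[k], 2) for k in self.aucs],
                "SD (AUC)": [round(self.sd_auc[k], 2) for k in self.aucs],
            }
        )
        order = sorted(
            range(len(df)),
            key=lambda i: (
                -self.mean_auc[df["Model"][i]],
                self.sd_auc[df["Model"][i]],
                ROSTER.index(df["Model"][i]),
            ),
        )
        return df.iloc[order].reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "aucs": {k: list(map(float, v)) for k, v in self.aucs.items()},
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "winner": self.winner,
            "repeat_seeds": self.repeat_seeds,
            "k": self.k,
            "repeats": self.repeats,
        }


def repeated_cv_auc(
    table: FeatureTable,
    key: str,
    k: int = 8,
    repeats: int = 3,
    seed: int = 0,
) -> list[float]:
    """Held-out AUCs from ``repeats`` x stratified ``k``-fold CV (24 by default).

    Each repeat draws a fresh randomised stratified split. A classifier
    failure on a fold is recorded as NaN with a warning, never imputed.
    Values are returned in (repeat, fold) order.
    """
    X, y = table.values, table.labels
    rng = np.random.default_rng(seed)
    repeat_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=repeats)]
    out: list[float] = []
    for rep_seed in repeat_seeds:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        for fold, (train, test) in enumerate(skf.split(X, y)):
            model = make_classifier(key, X.shape[1], seed=rep_seed + fold)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X[train], y[train])
                    out.append(roc_auc(_scores(model, X[test]), y[test]))
            except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
                warnings.warn(f"{key} failed on repeat fold {fold}: {exc}")
                out.append(float("nan"))
    return out


def summarize_and_rank(
    aucs: dict[str, list[float]], repeat_seeds: list[int], k: int = 8, repeats: int = 3
) -> ModelSelectionReport:
    """Bundle per-classifier AUC lists into a ranked report."""
    if not aucs:
        raise ValueError("at least one classifier must be evaluated")
    return ModelSelectionReport(aucs=aucs, repeat_seeds=repeat_seeds, k=k, repeats=repeats)


def evaluate_roster(
    table: FeatureTable,
    roster: tuple[str, ...] = ROSTER,
    k: int = 8,
    repeats: int = 3,
    seed: int = 0,
) -> ModelSelectionReport:
    """Run repeated-CV model selection for every roster key on one table."""
    rng = np.random.default_rng(seed)
    repeat_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=repeats)]
    aucs = {
        key: repeated_cv_auc(table, key, k=k, repeats=repeats, seed=seed)
        for key in roster
    }
    return summarize_and_rank(aucs, repeat_seeds, k=k, repeats=repeats)


def fit_final(table: FeatureTable, key: str, seed: int = 0):
    """Fit the winning classifier on the whole cohort.

    Returns the fitted model and its per-case class-1 probability scores
    (in [0, 1]), ready for operating-point evaluation.
    """
    if len(np.unique(table.labels)) < 2:
        raise ValueError("cannot fit on a single-class cohort")
    model = make_classifier(key, table.n_features, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(table.values, table.labels)
        scores = _scores(model, table.values)
    return model, scores
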