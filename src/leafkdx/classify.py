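"""Diagnosis classifiers and evaluation.

Three classifier families, each at the fixed hyperparameters used for the
diagnosis task: an RBF support vector machine (C=10, γ=0.1 with
k(u,v) = exp(−γ‖u−v‖²)), k-nearest neighbors (k=6, Manhattan distance,
class-vote ties resolved toward the deficient class), and a depth-5
Gini decision tree.  Class 1 is potassium-deficient and is the positive
class for recall/precision/F1; class 2 is normal.

:class:`KDeficiencyDiagnoser` is the sklearn-style end-to-end tabular
model: z-score → influence screening → Fisher LDA → classifier.  It fits
on a FeatureTable (22 canonical columns) and predicts labels in {1, 2}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES
from .reduction import FisherLDA
from .screening import InfluenceScreen

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "KDeficiencyDiagnoser",
    "split_dataset",
    "train",
    "diagnose",
    "evaluate",
    "make_classifier",
    "save_model",
    "load_model",
    "kfold_tune",
]

DEFICIENT, NORMAL = 1, 2


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family to use and its fixed hyperparameters."""

    kind: str = "svm"  # svm | knn | dt
    svm_C: float = 10.0
    svm_gamma: float = 0.1
    knn_k: int = 6
    knn_metric: str = "manhattan"
    dt_max_depth: int = 5
    dt_criterion: str = "gini"
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("svm", "knn", "dt"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if min(self.svm_C, self.svm_gamma, self.knn_k, self.dt_max_depth) <= 0:
            raise ValueError("hyperparameters must be positive")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn estimator behind a :class:`ClassifierSpec`."""
    spec.validate()
    if spec.kind == "svm":
        return SVC(C=spec.svm_C, kernel="rbf", gamma=spec.svm_gamma, random_state=spec.seed)
    if spec.kind == "knn":
        # sklearn resolves 3–3 vote ties toward the first entry of classes_,
        # which is class 1 (deficient) — the fail-safe direction
        return KNeighborsClassifier(n_neighbors=spec.knn_k, metric=spec.knn_metric)
    return DecisionTreeClassifier(
        max_depth=spec.dt_max_depth, criterion=spec.dt_criterion, random_state=spec.seed
    )


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    table: pd.DataFrame,
    train_frac: float = 0.7,
    seed: int = 0,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 70/30-style split; 1700 samples give 1190 train / 510 test.

    Splits are disjoint, exhaustive and reproducible under the seed; an
    error is raised if either side loses a class entirely.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    y = table[label_col]
    train, test = train_test_split(
        table, train_size=train_frac, stratify=y, random_state=seed, shuffle=True
    )
    for part, name in ((train, "train"), (test, "test")):
        if set(part[label_col].unique()) != set(y.unique()):
            raise ValueError(f"class missing from the {name} split; dataset too small")
    return train, test


# ---------------------------------------------------------------------------
# the end-to-end tabular model


class KDeficiencyDiagnoser(ClassifierMixin, BaseEstimator):
    """Standardize → influence-screen → Fisher LDA → classifier.

    Parameters
    ----------
    classifier : str, default "svm"
        One of "svm", "knn", "dt".
    spec : ClassifierSpec or None
        Full hyperparameter bundle; overrides ``classifier`` when given.
    screening : bool, default True
        Disable to keep all 22 features (the screen is bypassed).
    threshold : float or None
        Fixed influence-factor cutoff (None = mean rule).
    response : str, default "k_content"
        Column used as the screening regression response when fitting on a
        FeatureTable; falls back to the class labels if absent.
    lda_dims : int, default 2
        Discriminant-space dimensionality fed to the classifier.
    """

    def __init__(
        self,
        classifier: str = "svm",
        spec: ClassifierSpec | None = None,
        screening: bool = True,
        threshold: float | None = None,
        response: str = "k_content",
        lda_dims: int = 2,
        seed: int = 0,
    ):
        self.classifier = classifier
        self.spec = spec
        self.screening = screening
        self.threshold = threshold
        self.response = response
        self.lda_dims = lda_dims
        self.seed = seed

    def _resolved_spec(self) -> ClassifierSpec:
        return self.spec if self.spec is not None else ClassifierSpec(kind=self.classifier, seed=self.seed)

    def fit(self, X: pd.DataFrame, y=None):
        X = self._feature_frame(X)
        if y is None:
            raise ValueError("y (labels in {1, 2}) is required")
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes present to fit")

        response = self._response_vector(X, y)
        feats = X[FEATURE_NAMES]
        self.scaler_ = StandardScaler().fit(feats)
        Z = pd.DataFrame(self.scaler_.transform(feats), columns=FEATURE_NAMES, index=feats.index)

        if self.screening:
            self.screen_ = InfluenceScreen(threshold=self.threshold).fit(Z, response)
            Zr = self.screen_.transform(Z)
            self.retained_ = list(self.screen_.retained_)
        else:
            self.screen_ = None
            Zr = Z
            self.retained_ = list(FEATURE_NAMES)

        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # rank-1 S_B padding warning is expected
            self.lda_ = FisherLDA(n_components=self.lda_dims).fit(Zr, y)
        # z-score the discriminant scores: the classifier hyperparameters
        # (RBF gamma, Manhattan KNN) assume inputs of unit scale, while the
        # raw projection scale depends on the within-class structure
        self.score_scaler_ = StandardScaler().fit(self.lda_.transform(Zr))
        P = self.score_scaler_.transform(self.lda_.transform(Zr))
        self.clf_ = make_classifier(self._resolved_spec()).fit(P, y)
        self.classes_ = self.clf_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "clf_")
        X = self._feature_frame(X)
        feats = X[FEATURE_NAMES]
        Z = pd.DataFrame(self.scaler_.transform(feats), columns=FEATURE_NAMES, index=feats.index)
        Zr = self.screen_.transform(Z) if self.screen_ is not None else Z
        return self.clf_.predict(self.score_scaler_.transform(self.lda_.transform(Zr)))

    def transform(self, X) -> np.ndarray:
        """Discriminant-space scores (the 2-D scatter coordinates)."""
        check_is_fitted(self, "lda_")
        X = self._feature_frame(X)
        feats = X[FEATURE_NAMES]
        Z = pd.DataFrame(self.scaler_.transform(feats), columns=FEATURE_NAMES, index=feats.index)
        Zr = self.screen_.transform(Z) if self.screen_ is not None else Z
        return self.score_scaler_.transform(self.lda_.transform(Zr))

    def _feature_frame(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=FEATURE_NAMES)
        missing = [c for c in FEATURE_NAMES if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        return X

    def _response_vector(self, X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
        if self.response in X.columns:
            return X[self.response].to_numpy(dtype=float)
        return y.astype(float)


# ---------------------------------------------------------------------------
# functional wrappers


def train(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    label_col: str = "label",
    **kwargs,
) -> KDeficiencyDiagnoser:
    """Fit the end-to-end diagnoser on a FeatureTable."""
    model = KDeficiencyDiagnoser(spec=spec, seed=spec.seed, **kwargs)
    return model.fit(table, table[label_col].to_numpy())


def diagnose(model: KDeficiencyDiagnoser, X) -> np.ndarray:
    """Predicted labels in {1, 2}; pure function of (model, X)."""
    return model.predict(X)


def save_model(model: KDeficiencyDiagnoser, path: str | Path) -> None:
    """Persist the fitted model (joblib) plus a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    meta = {
        "classifier": model._resolved_spec().kind,
        "retained_features": getattr(model, "retained_", None),
        "lda": model.lda_.projection_.to_dict() if hasattr(model, "lda_") else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> KDeficiencyDiagnoser:
    return joblib.load(path)


def kfold_tune(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    param: str,
    grid: list[float],
    n_folds: int = 5,
    seed: int = 0,
    label_col: str = "label",
) -> tuple[float, dict[float, float]]:
    """Stratified k-fold accuracy over a one-parameter grid.

    A tuning utility only — the defaults stay at the fixed study values.
    Returns (best value, {value: mean accuracy}).
    """
    y = table[label_col].to_numpy()
    scores: dict[float, float] = {}
    for val in grid:
        s = dataclass_replace(spec, **{param: val})
        model = KDeficiencyDiagnoser(spec=s, seed=seed)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        accs = []
        for tr_idx, te_idx in cv.split(table, y):
            m = clone(model)
            m.fit(table.iloc[tr_idx], y[tr_idx])
            accs.append(float((m.predict(table.iloc[te_idx]) == y[te_idx]).mean()))
        scores[val] = float(np.mean(accs))
    best = max(scores, key=scores.get)
    return best, scores


def dataclass_replace(spec: ClassifierSpec, **kw) -> ClassifierSpec:
    import dataclasses

    return dataclasses.replace(spec, **kw)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationReport:
    """2×2 confusion (rows: true 1, 2; cols: predicted 1, 2) and metrics."""

    confusion: np.ndarray
    Acc: float
    Rec: float
    Pre: float
    F1: float
    n: int
    period: str = ""

    def to_dict(self) -> dict:
        return {
            "confusion": np.asarray(self.confusion).tolist(),
            "Acc": self.Acc,
            "Rec": self.Rec,
            "Pre": self.Pre,
            "F1": self.F1,
            "n": self.n,
            "period": self.period,
        }


def evaluate(y_true, y_pred, period: str = "") -> EvaluationReport:
    """Confusion matrix and Acc/Rec/Pre/F1 with class 1 (deficient) positive.

    F1 is defined as 0 when precision·recall = 0 (the 0/0 convention).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    bad = set(np.unique(np.concatenate([y_true, y_pred]))) - {DEFICIENT, NORMAL}
    if bad:
        raise ValueError(f"labels must be in {{1, 2}}, got extras {sorted(bad)}")
    tp = int(np.sum((y_true == DEFICIENT) & (y_pred == DEFICIENT)))
    fn = int(np.sum((y_true == DEFICIENT) & (y_pred == NORMAL)))
    fp = int(np.sum((y_true == NORMAL) & (y_pred == DEFICIENT)))
    tn = int(np.sum((y_true == NORMAL) & (y_pred == NORMAL)))
    n = len(y_true)
    acc = (tp + tn) / n
    rec = tp / (tp + fn) if tp + fn else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return EvaluationReport(
        confusion=np.array([[tp, fn], [fp, tn]]),
        Acc=acc,
        Rec=rec,
        Pre=pre,
        F1=f1,
        n=n,
        period=period,
    )
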