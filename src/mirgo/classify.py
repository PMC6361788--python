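"""Per-GO-term binary classifiers on embedding vectors.

One RBF-kernel SVM is trained per GO term on protein embedding vectors
(positives: proteins annotated to the term after propagation; negatives:
balanced descendant-excluding sample).  C and the kernel width gamma are
selected by stratified 10-fold cross-validated accuracy over a log2 grid.
Decision values are turned into [0, 1] confidence scores by Platt-style
sigmoid calibration fitted on cross-validated decision values (scikit-learn's
``SVC(probability=True)``).  At prediction time every miRNA embedding vector
is scored against every trained term independently (one-vs-rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .embedding import EmbeddingMatrix
from .ontology import TermTrainingSet

logger = logging.getLogger(__name__)

# log2 grids; the exponent ranges follow common RBF-SVM search practice
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SVMParams:
    """RBF-SVM hyper-parameters: penalty C and kernel width gamma."""

    C: float
    kernel_gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.kernel_gamma <= 0:
            raise ValueError("C and kernel_gamma must be positive")


def grid_search_cv(
    features: np.ndarray,
    labels: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    g_grid=DEFAULT_GAMMA_GRID,
    folds: int = 10,
    seed: int = 0,
) -> tuple[SVMParams, float]:
    """Pick (C, gamma) by stratified k-fold mean accuracy.

    Ties are broken toward smaller C, then smaller gamma (the grid is scanned
    in ascending order and only a strictly better mean accuracy replaces the
    incumbent).  Returns the selected params and their mean CV accuracy.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes for cross-validation")
    if counts.min() < folds:
        raise ValueError(
            f"a class has only {counts.min()} members; lower folds (={folds}) or min_pos"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best: tuple[SVMParams, float] | None = None
    for C in sorted(c_grid):
        for gamma in sorted(g_grid):
            clf = SVC(C=C, kernel="rbf", gamma=gamma)
            acc = float(np.mean(cross_val_score(clf, features, labels, cv=cv)))
            if best is None or acc > best[1] + 1e-12:
                best = (SVMParams(C=C, kernel_gamma=gamma), acc)
    assert best is not None
    return best


class _SigmoidDecisionSVC:
    """Fallback scorer for degenerate class sizes (<2 per class).

    No cross-validated calibration is possible; scores are the logistic of
    the raw SVM decision value, which still lies in (0, 1) and is 0.5 on the
    decision boundary.
    """

    def __init__(self, svc: SVC):
        self.svc = svc

    def fit(self, X, y):
        self.svc.fit(X, y)
        self.classes_ = self.svc.classes_
        self.n_features_in_ = self.svc.n_features_in_
        return self

    def predict(self, X):
        return self.svc.predict(X)

    def predict_proba(self, X):
        d = self.svc.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-d))
        return np.column_stack([1.0 - p1, p1])


@dataclass
class TermClassifier:
    """A fitted, calibrated one-vs-rest classifier for a single GO term."""

    term: str
    params: SVMParams
    model: object  # fitted calibrated classifier with predict_proba
    n_pos: int
    n_neg: int
    cv_accuracy: float = float("nan")

    def score(self, vectors: np.ndarray) -> np.ndarray:
        """Calibrated probability of the positive class, in [0, 1]."""
        vectors = np.atleast_2d(vectors)
        if vectors.shape[1] != self.model.n_features_in_:
            raise ValueError(
                f"dimension mismatch: got {vectors.shape[1]}, "
                f"model expects {self.model.n_features_in_}"
            )
        pos_col = int(np.where(self.model.classes_ == 1)[0][0])
        return self.model.predict_proba(vectors)[:, pos_col]


class TermSVM(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator for one term: optional grid search + calibration.

    With ``C``/``gamma`` set to None, ``fit`` grid-searches them by stratified
    ``folds``-fold CV accuracy; otherwise the given values are used.  Fitted
    attributes: ``params_``, ``cv_accuracy_``, ``svc_``.
    """

    def __init__(
        self,
        C: float | None = None,
        gamma: float | None = None,
        c_grid=DEFAULT_C_GRID,
        g_grid=DEFAULT_GAMMA_GRID,
        folds: int = 10,
        seed: int = 0,
    ):
        self.C = C
        self.gamma = gamma
        self.c_grid = c_grid
        self.g_grid = g_grid
        self.folds = folds
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.C is not None and self.gamma is not None:
            self.params_ = SVMParams(C=self.C, kernel_gamma=self.gamma)
            self.cv_accuracy_ = float("nan")
        else:
            self.params_, self.cv_accuracy_ = grid_search_cv(
                X, y, self.c_grid, self.g_grid, folds=self.folds, seed=self.seed
            )
        svc = SVC(C=self.params_.C, kernel="rbf", gamma=self.params_.kernel_gamma)
        _, counts = np.unique(y, return_counts=True)
        n_min = int(counts.min())
        if n_min >= 2:
            # Platt-style sigmoid fitted on out-of-fold decision values
            cal_cv = StratifiedKFold(n_splits=min(5, n_min))
            self.model_ = CalibratedClassifierCV(
                svc, method="sigmoid", cv=cal_cv, ensemble=False
            )
            self.model_.fit(X, y)
        else:
            # degenerate class sizes: sigmoid of the raw decision value
            self.model_ = _SigmoidDecisionSVC(svc).fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))


def train_term_classifier(
    embeddings: EmbeddingMatrix,
    ts: TermTrainingSet,
    params: SVMParams | None = None,
    folds: int = 10,
    seed: int = 0,
    c_grid=DEFAULT_C_GRID,
    g_grid=DEFAULT_GAMMA_GRID,
) -> TermClassifier:
    """Fit the calibrated RBF-SVM for one term's training set.

    Every training entity must have an embedding vector; missing ids raise
    with the offending list.
    """
    entities = list(ts.positives) + list(ts.negatives)
    missing = [e for e in entities if e not in embeddings]
    if missing:
        raise KeyError(f"entities absent from embedding vocabulary: {missing[:10]}")
    X = embeddings.subset(entities).vectors
    y = np.array([1] * len(ts.positives) + [0] * len(ts.negatives))
    est = TermSVM(
        C=params.C if params else None,
        gamma=params.kernel_gamma if params else None,
        c_grid=c_grid,
        g_grid=g_grid,
        folds=folds,
        seed=seed,
    ).fit(X, y)
    return TermClassifier(
        term=ts.term,
        params=est.params_,
        model=est.model_,
        n_pos=len(ts.positives),
        n_neg=len(ts.negatives),
        cv_accuracy=est.cv_accuracy_,
    )


@dataclass
class PredictionSet:
    """Scores in [0, 1] per (miRNA, GO term) pair."""

    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def mirnas(self) -> list[str]:
        return sorted({m for m, _ in self.scores})

    def scores_for(self, mirna: str) -> dict[str, float]:
        return {t: s for (m, t), s in self.scores.items() if m == mirna}

    def write_tsv(self, path) -> None:
        """(mirna_id, go_term, score) with 4-decimal scores, sorted by miRNA
        then descending score (ties by term id)."""
        rows = sorted(
            ((m, t, s) for (m, t), s in self.scores.items()),
            key=lambda r: (r[0], -r[2], r[1]),
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("mirna_id\tgo_term\tscore\n")
            for m, t, s in rows:
                fh.write(f"{m}\t{t}\t{s:.4f}\n")

    @classmethod
    def read_tsv(cls, path) -> "PredictionSet":
        out: dict[tuple[str, str], float] = {}
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                m, t, s = line.rstrip("\n").split("\t")
                out[(m, t)] = float(s)
        return cls(scores=out)


def predict_go_scores(
    mirna_vectors: EmbeddingMatrix, classifiers: list[TermClassifier]
) -> PredictionSet:
    """Score every miRNA vector against every trained term classifier."""
    pred = PredictionSet()
    if not classifiers:
        return pred
    X = mirna_vectors.vectors
    for clf in classifiers:
        s = clf.score(X)
        if np.any(s < -1e-9) or np.any(s > 1 + 1e-9):
            raise ValueError(f"scores out of [0,1] for term {clf.term}")
        s = np.clip(s, 0.0, 1.0)
        for mirna, val in zip(mirna_vectors.node_ids, s):
            pred.scores[(mirna, clf.term)] = float(val)
    return pred
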