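"""Per-episode classification and per-person cognitive screening.

The screening task is heavily imbalanced (cognitively healthy residents far
outnumber persons with dementia), so minority-class feature vectors are
augmented with SMOTE: a synthetic vector is a convex combination
``a + lambda * (b - a)`` of a random minority instance ``a`` and one of its
k = 5 nearest minority neighbours ``b``, with ``lambda ~ U[0, 1]``.

Five short-term classifiers label individual locomotion episodes as walked
by a cognitively healthy (CH) subject or a person with dementia (PwD):
Gaussian naive Bayes, 5-nearest-neighbours, a decision tree, an RBF-kernel
SVM with C = 0.7, and a single-hidden-layer (100 ReLU units) network trained
with Adam for up to 1000 epochs at batch size 200.  Evaluation is
leave-one-person-out (LOPO): each subject's episodes form one held-out test
fold, and standardisation, SMOTE and any fold-specific feature fitting use
only that fold's training subjects.  The long-term diagnosis per subject is
the majority vote over its episode predictions (arg-max over classes; ties
resolve to PwD, the screening-sensitive choice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

LABEL_CH = "CH"
LABEL_PWD = "PwD"
#: PwD is the positive ("abnormal") class in per-class reporting.
POSITIVE_LABEL = LABEL_PWD

MODEL_KINDS = ("nb", "knn", "dt", "svm", "nn")


# --------------------------------------------------------------------------
# dataset container


@dataclass
class LabeledDataset:
    """Episode feature matrix with per-episode subject ids and labels."""

    X: np.ndarray  # (N, d)
    y: np.ndarray  # (N,) of {CH, PwD}
    subjects: np.ndarray  # (N,) subject ids

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise ValueError("X, y and subjects must have equal length")
        for s in np.unique(self.subjects):
            labels = np.unique(self.y[self.subjects == s])
            if len(labels) > 1:
                raise ValueError(f"subject {s!r} carries contradictory labels {labels}")

    @property
    def subject_labels(self) -> dict[str, str]:
        return {str(s): str(self.y[self.subjects == s][0]) for s in np.unique(self.subjects)}

    def __len__(self) -> int:
        return len(self.X)


# --------------------------------------------------------------------------
# SMOTE


def smote_oversample(
    minority: np.ndarray, majority_count: int, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Synthetic minority vectors by convex combination of nearest neighbours.

    Generates exactly ``majority_count - len(minority)`` vectors.  For each:
    pick a random minority instance ``a``, pick ``b`` uniformly among the k
    nearest minority neighbours of ``a`` (Euclidean, excluding ``a``), and
    emit ``a + lambda * (b - a)`` with ``lambda ~ U[0, 1]``.  Deterministic
    under a fixed seed.  ``k`` is clamped to ``len(minority) - 1`` when the
    minority class is small; fewer than 2 minority instances is fatal.
    """
    minority = np.asarray(minority, dtype=float)
    n_min = len(minority)
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority instances")
    n_new = majority_count - n_min
    if n_new <= 0:
        return np.empty((0, minority.shape[1]))
    if k > n_min - 1:
        logger.warning("clamping SMOTE k from %d to %d (minority size %d)", k, n_min - 1, n_min)
        k = n_min - 1

    # pairwise neighbour table: for each a, indices of its k nearest others
    d2 = ((minority[:, None, :] - minority[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbours = np.argsort(d2, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(seed)
    out = np.empty((n_new, minority.shape[1]))
    for i in range(n_new):
        ai = rng.integers(n_min)
        b = minority[neighbours[ai, rng.integers(k)]]
        lam = rng.uniform()
        out[i] = minority[ai] + lam * (b - minority[ai])
    return out


def balance_with_smote(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity with the majority class."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE balancing expects exactly 2 classes")
    minority_label = classes[np.argmin(counts)]
    majority_count = counts.max()
    if counts.min() == majority_count:
        return X, y
    synth = smote_oversample(X[y == minority_label], majority_count, k=k, seed=seed)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(len(synth), minority_label, dtype=y.dtype)])
    return X_out, y_out


# --------------------------------------------------------------------------
# short-term models


@dataclass
class ModelSpec:
    """A short-term classifier choice plus its hyperparameters."""

    kind: str = "svm"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def build(self):
        kind = self.kind.lower()
        params = dict(self.params)
        if kind == "nb":
            return GaussianNB(**params)
        if kind == "knn":
            return KNeighborsClassifier(n_neighbors=params.pop("n_neighbors", 5), **params)
        if kind == "dt":
            return DecisionTreeClassifier(random_state=self.seed, **params)
        if kind == "svm":
            return SVC(kernel="rbf", C=params.pop("C", 0.7), random_state=self.seed, **params)
        if kind == "nn":
            return MLPClassifier(
                hidden_layer_sizes=params.pop("hidden_layer_sizes", (100,)),
                activation="relu",
                solver="adam",
                max_iter=params.pop("max_iter", 1000),
                batch_size=params.pop("batch_size", 200),
                random_state=self.seed,
                **params,
            )
        raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")


class ShortTermModel:
    """Standardise -> (optionally SMOTE) -> fit; the per-episode classifier.

    ``scale_head`` restricts z-scoring to the first ``scale_head`` feature
    columns.  Heterogeneously scaled shape features need standardisation,
    but an L2-normalised visual-word histogram block is already on a common
    scale; z-scoring its sparse bins would inflate rare-word quantisation
    noise to unit variance, so that block is passed through untouched.
    ``None`` standardises every column.
    """

    def __init__(
        self,
        spec: ModelSpec,
        use_smote: bool = True,
        smote_k: int = 5,
        scale_head: int | None = None,
    ):
        self.spec = spec
        self.use_smote = use_smote
        self.smote_k = smote_k
        self.scale_head = scale_head
        self.scaler = StandardScaler()
        self.model = None

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = X.shape[1] if self.scale_head is None else min(self.scale_head, X.shape[1])
        return X[:, :h], X[:, h:]

    def _transform(self, X: np.ndarray) -> np.ndarray:
        head, tail = self._split(X)
        return np.hstack([self.scaler.transform(head), tail])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShortTermModel":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contain a single class")
        head, _ = self._split(X)
        self.scaler.fit(head)
        Xs = self._transform(X)
        if self.use_smote:
            Xs, y = balance_with_smote(Xs, y, k=self.smote_k, seed=self.spec.seed)
        self.model = self.spec.build()
        self.model.fit(Xs, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("model is not fitted")
        return self.model.predict(self._transform(X))


# --------------------------------------------------------------------------
# metrics


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    tp: int
    fp: int
    fn: int


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
            "per_class": {
                c: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "support": m.support,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                }
                for c, m in self.per_class.items()
            },
        }


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        logger.debug("0/0 metric defined as 0")
        return 0.0
    return num / den


def compute_metrics(y_true, y_pred, classes=None) -> MetricsReport:
    """Precision, recall and F1 per class with macro and weighted averages.

    ``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``,
    ``F1 = 2PR/(P+R)``; 0/0 is defined as 0.  Macro averages are unweighted
    means over classes, weighted averages are support-weighted.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("cannot score an empty prediction set")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))

    per_class: dict[str, ClassMetrics] = {}
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        f1 = _safe_div(2.0 * precision * recall, precision + recall)
        per_class[str(c)] = ClassMetrics(
            precision=precision,
            recall=recall,
            f1=f1,
            support=int(np.sum(y_true == c)),
            tp=tp,
            fp=fp,
            fn=fn,
        )

    supports = np.array([m.support for m in per_class.values()], dtype=float)
    weights = supports / supports.sum() if supports.sum() else np.zeros_like(supports)

    def agg(attr):
        vals = np.array([getattr(m, attr) for m in per_class.values()])
        return float(vals.mean()), float((vals * weights).sum())

    macro_p, weighted_p = agg("precision")
    macro_r, weighted_r = agg("recall")
    macro_f, weighted_f = agg("f1")
    return MetricsReport(
        per_class=per_class,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f,
        weighted_precision=weighted_p,
        weighted_recall=weighted_r,
        weighted_f1=weighted_f,
        accuracy=float(np.mean(y_true == y_pred)),
    )


# --------------------------------------------------------------------------
# leave-one-person-out evaluation


def lopo_folds(subjects: np.ndarray):
    """Yield (subject, train_mask, test_mask) with one fold per subject."""
    subjects = np.asarray(subjects)
    for s in np.unique(subjects):
        test = subjects == s
        yield str(s), ~test, test


def lopo_evaluate(
    dataset: LabeledDataset,
    spec: ModelSpec,
    use_smote: bool = True,
    smote_k: int = 5,
    featurizer=None,
    scale_head: int | None = None,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Leave-one-person-out evaluation of a short-term classifier.

    One fold per subject: that subject's episodes are the test set, and all
    fitting (standardisation, SMOTE, and — via ``featurizer`` — any feature
    construction such as a per-fold visual vocabulary) sees only training
    subjects.  ``featurizer(train_mask) -> X_full`` must return the feature
    matrix for all episodes built using only training information; when
    omitted, ``dataset.X`` is used as-is.

    Returns pooled out-of-fold metrics and a per-episode prediction frame
    with columns ``subject_id, episode, true, pred``.
    """
    if len(np.unique(dataset.subjects)) < 2:
        raise ValueError("LOPO needs at least 2 subjects")
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("LOPO needs both classes present")

    rows = []
    for subject, train_mask, test_mask in lopo_folds(dataset.subjects):
        X = featurizer(train_mask) if featurizer is not None else dataset.X
        if len(np.unique(dataset.y[train_mask])) < 2:
            raise ValueError(f"training fold for subject {subject} has a single class")
        model = ShortTermModel(spec, use_smote=use_smote, smote_k=smote_k, scale_head=scale_head)
        model.fit(X[train_mask], dataset.y[train_mask])
        preds = model.predict(X[test_mask])
        for ep, (true, pred) in enumerate(zip(dataset.y[test_mask], preds)):
            rows.append(
                {"subject_id": subject, "episode": ep, "true": str(true), "pred": str(pred)}
            )
    pred_df = pd.DataFrame(rows)
    report = compute_metrics(pred_df["true"].to_numpy(), pred_df["pred"].to_numpy())
    return report, pred_df


# --------------------------------------------------------------------------
# long-term diagnosis


@dataclass
class DiagnosticHypothesis:
    subject_id: str
    predicted: str
    votes: dict[str, int]
    n_episodes: int


def long_term_assess(predictions, subject_id: str = "", tie_break: str = POSITIVE_LABEL) -> DiagnosticHypothesis:
    """Per-person diagnosis: the class most frequently predicted per episode.

    Ties resolve to ``tie_break`` (default PwD — a screening system prefers a
    false alarm over a miss).  An empty prediction history is fatal.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("cannot assess a subject with no episode predictions")
    votes = {LABEL_CH: 0, LABEL_PWD: 0}
    for p in predictions:
        votes[str(p)] = votes.get(str(p), 0) + 1
    top = max(votes.values())
    winners = [c for c, v in votes.items() if v == top]
    predicted = tie_break if tie_break in winners else winners[0]
    return DiagnosticHypothesis(
        subject_id=subject_id, predicted=predicted, votes=votes, n_episodes=len(predictions)
    )


def long_term_evaluate(
    pred_df: pd.DataFrame, tie_break: str = POSITIVE_LABEL
) -> tuple[MetricsReport, pd.DataFrame]:
    """Aggregate per-episode predictions into per-subject diagnoses and score them."""
    rows = []
    for subject, group in pred_df.groupby("subject_id", sort=True):
        hyp = long_term_assess(group["pred"], subject_id=str(subject), tie_break=tie_break)
        rows.append(
            {
                "subject_id": str(subject),
                "true": group["true"].iloc[0],
                "pred": hyp.predicted,
                "votes_ch": hyp.votes.get(LABEL_CH, 0),
                "votes_pwd": hyp.votes.get(LABEL_PWD, 0),
            }
        )
    diag = pd.DataFrame(rows)
    report = compute_metrics(diag["true"].to_numpy(), diag["pred"].to_numpy())
    return report, diag
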