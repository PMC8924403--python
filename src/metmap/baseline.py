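"""Single-report TF-IDF ranked soft-voting ensemble (the baseline).

Four base learners — logistic regression (inverse-regularization constant
15.0, balanced class weights, Newton-CG solver), a linear SVM with
Platt-calibrated probabilities, a 2,000-tree random forest (sqrt feature
subsampling, bootstrapping), and gradient-boosted trees at library
defaults — each see TF-IDF features of the *target report alone* (no
history).  The ensemble soft-votes: each model's positive-class
probability is averaged with a weight derived from its training-set
accuracy, precision and recall, so the best-performing base model counts
most.  Weights are fitted per organ.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .evaluate import ConfusionCounts, compute_metrics
from .preprocess import HistoryDocument

MODEL_KINDS = ("logistic_regression", "linear_svm", "random_forest", "gradient_boosting")


def fit_tfidf(training_texts: Sequence[str]) -> TfidfVectorizer:
    """Fit a TF-IDF vectorizer (smoothed idf, sklearn dialect) on train text.

    The vocabulary comes from the training split only; unseen words in
    later transforms map to zero columns.
    """
    if not training_texts:
        raise ValueError("cannot fit TF-IDF on an empty training corpus")
    vec = TfidfVectorizer()  # smooth_idf=True, l2 norm, lowercase
    vec.fit(training_texts)
    return vec


@dataclasses.dataclass
class EnsembleWeights:
    """Per-base-model ranked soft-voting weights.

    ``scores[m] = (accuracy + precision + recall) / 3`` on the training
    split; ``weights`` are scores normalized to sum to 1, so weight order
    matches score order.
    """

    kinds: tuple[str, ...]
    scores: np.ndarray
    weights: np.ndarray
    metrics: dict[str, dict[str, float]]


def compute_model_weights(
    training_metrics: dict[str, dict[str, float]]
) -> EnsembleWeights:
    """Ranked weights from per-model training accuracy/precision/recall.

    All-zero scores (pathological) fall back to uniform weights with a
    warning.
    """
    kinds = tuple(training_metrics)
    scores = []
    for kind in kinds:
        m = training_metrics[kind]
        for name in ("accuracy", "precision", "recall"):
            if not 0.0 <= m[name] <= 1.0:
                raise ValueError(f"{kind} {name} out of [0,1]: {m[name]}")
        scores.append((m["accuracy"] + m["precision"] + m["recall"]) / 3.0)
    scores = np.asarray(scores, dtype=float)
    total = scores.sum()
    if total == 0.0:
        warnings.warn("all base-model scores are zero; using uniform weights")
        weights = np.full(len(kinds), 1.0 / len(kinds))
    else:
        weights = scores / total
    return EnsembleWeights(
        kinds=kinds, scores=scores, weights=weights, metrics=dict(training_metrics)
    )


def predict_soft_vote(
    weights: np.ndarray, probabilities: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Soft vote: confidence = Σ_m w_m p_m; label 1 iff confidence ≥ 0.5.

    ``probabilities`` has shape (n_models,) or (n_docs, n_models).  The tie
    at exactly 0.5 resolves positive (favor sensitivity).
    """
    weights = np.asarray(weights, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    single = probabilities.ndim == 1
    P = probabilities[None, :] if single else probabilities
    if P.shape[1] != weights.shape[0]:
        raise ValueError(
            f"got {P.shape[1]} model probabilities for {weights.shape[0]} weights"
        )
    if np.any((P < 0) | (P > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    confidence = P @ weights
    labels = (confidence >= 0.5).astype(int)
    if single:
        return confidence[0], labels[0]
    return confidence, labels


def _make_base_models(seed: int) -> dict[str, object]:
    return {
        "logistic_regression": LogisticRegression(
            C=15.0, class_weight="balanced", solver="newton-cg", max_iter=1000
        ),
        "linear_svm": CalibratedClassifierCV(
            LinearSVC(random_state=seed), method="sigmoid", cv=5
        ),
        "random_forest": RandomForestClassifier(
            n_estimators=2000,
            bootstrap=True,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        ),
        "gradient_boosting": XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss"
        ),
    }


class BaselineEnsemble:
    """Fitted single-report ensemble for one organ."""

    uses_history = False

    def __init__(self, organ=None, seed: int = 0) -> None:
        self.organ = organ
        self.seed = seed
        self.vectorizer: TfidfVectorizer | None = None
        self.models: dict[str, object] = {}
        self.weights: EnsembleWeights | None = None

    def fit(self, texts: Sequence[str], labels: Sequence[int]) -> "BaselineEnsemble":
        y = np.asarray(labels, dtype=int)
        if len(set(y.tolist())) < 2:
            raise ValueError("training labels contain a single class")
        self.vectorizer = fit_tfidf(list(texts))
        X = self.vectorizer.transform(texts)
        self.models = _make_base_models(self.seed)
        metrics: dict[str, dict[str, float]] = {}
        for kind, model in self.models.items():
            model.fit(X, y)
            pred = model.predict(X)
            rep = compute_metrics(ConfusionCounts.from_predictions(y, pred))
            metrics[kind] = {
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
            }
        self.weights = compute_model_weights(metrics)
        return self

    def base_probabilities(self, texts: Sequence[str]) -> np.ndarray:
        """(n_docs, n_models) positive-class probabilities."""
        X = self.vectorizer.transform(texts)
        cols = []
        for kind in self.weights.kinds:
            model = self.models[kind]
            proba = model.predict_proba(X)
            pos_col = list(model.classes_).index(1)
            cols.append(proba[:, pos_col])
        return np.column_stack(cols)

    def predict_texts(self, texts: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        P = self.base_probabilities(texts)
        return predict_soft_vote(self.weights.weights, P)

    def predict_docs(self, docs: Sequence[HistoryDocument]):
        return self.predict_texts([d.text for d in docs])

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Persist as a versioned directory: vocabulary + weights as JSON,
        base models via joblib."""
        import joblib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "meta.json").write_text(
            json.dumps(
                {
                    "format": "metmap-baseline-v1",
                    "organ": self.organ.value if self.organ else None,
                    "seed": self.seed,
                }
            )
        )
        vocab = {t: int(i) for t, i in self.vectorizer.vocabulary_.items()}
        (directory / "tfidf_vocabulary.json").write_text(json.dumps(vocab))
        (directory / "ensemble_weights.json").write_text(
            json.dumps(
                {
                    "kinds": list(self.weights.kinds),
                    "scores": self.weights.scores.tolist(),
                    "weights": self.weights.weights.tolist(),
                    "metrics": self.weights.metrics,
                }
            )
        )
        joblib.dump(self.vectorizer, directory / "vectorizer.joblib")
        for kind, model in self.models.items():
            joblib.dump(model, directory / f"{kind}.joblib")

    @classmethod
    def load(cls, directory) -> "BaselineEnsemble":
        import joblib

        from .organs import OrganSite

        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        obj = cls(
            organ=OrganSite(meta["organ"]) if meta["organ"] else None,
            seed=meta["seed"],
        )
        obj.vectorizer = joblib.load(directory / "vectorizer.joblib")
        w = json.loads((directory / "ensemble_weights.json").read_text())
        obj.weights = EnsembleWeights(
            kinds=tuple(w["kinds"]),
            scores=np.asarray(w["scores"]),
            weights=np.asarray(w["weights"]),
            metrics=w["metrics"],
        )
        obj.models = {
            kind: joblib.load(directory / f"{kind}.joblib") for kind in w["kinds"]
        }
        return obj


def train_baseline(
    organ, texts: Sequence[str], labels: Sequence[int], seed: int = 0
) -> BaselineEnsemble:
    """Fit the four base models and per-organ ranked weights."""
    return BaselineEnsemble(organ=organ, seed=seed).fit(texts, labels)
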