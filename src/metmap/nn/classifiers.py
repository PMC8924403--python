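"""History-document classifiers wrapping the numpy networks.

Each classifier owns its vocabulary scheme, sequence-length policy and
network, and exposes ``fit`` / ``predict_texts`` / ``predict_docs`` plus
directory persistence (vocabulary as JSON, weights as npz, spec as JSON).

Sequence length for the CNNs is the 95th percentile of training document
lengths; longer documents are truncated from the *front*, dropping the
oldest history tokens so the target (newest) report is always retained.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from ..preprocess import HistoryDocument
from .models import (
    AttentionSpec,
    BilstmSpec,
    CnnSpec,
    TrainConfig,
    build_model,
    sigmoid,
    train_model,
)
from .tokenize import AlphaVocab, Tokenizer, pad_batch


@dataclasses.dataclass
class Predictions:
    probabilities: np.ndarray
    labels: np.ndarray
    empty_input: np.ndarray  # True where the encoded sequence was empty

    def __iter__(self):  # (probs, labels) unpacking convenience
        return iter((self.probabilities, self.labels))


class _NeuralClassifier:
    """Shared fit/predict scaffolding for the three neural models."""

    uses_history = True
    name = "neural"

    def __init__(self, seed: int = 0) -> None:
        self.seed = seed
        self.net = None
        self.history: dict | None = None

    # subclass hooks -------------------------------------------------------
    def _fit_vocab(self, texts: Sequence[str]) -> None:
        raise NotImplementedError

    def _encode_all(self, texts: Sequence[str]):
        raise NotImplementedError

    def _build_net(self):
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def fit(
        self,
        texts: Sequence[str],
        labels: Sequence[int],
        val_texts: Sequence[str],
        val_labels: Sequence[int],
        config: TrainConfig | None = None,
    ):
        config = config or TrainConfig(seed=self.seed)
        self._fit_vocab(texts)
        X_train = self._encode_all(texts)
        X_val = self._encode_all(val_texts)
        self.net = self._build_net()
        self.history = train_model(
            self.net, X_train, np.asarray(labels), X_val, np.asarray(val_labels), config
        )
        return self

    def predict_texts(self, texts: Sequence[str]) -> Predictions:
        raise NotImplementedError

    def predict_docs(self, docs: Sequence[HistoryDocument]):
        pred = self.predict_texts([d.text for d in docs])
        return pred.probabilities, pred.labels


class SimpleCNNClassifier(_NeuralClassifier):
    name = "simple_cnn"

    def __init__(self, seed: int = 0, spec: CnnSpec | None = None) -> None:
        super().__init__(seed)
        self.spec = spec or CnnSpec()
        self.tokenizer = Tokenizer()
        self._attention: AttentionSpec | None = None

    def _fit_vocab(self, texts: Sequence[str]) -> None:
        self.tokenizer.fit(texts)
        lengths = [len(self.tokenizer.encode(t)) for t in texts]
        p95 = int(np.percentile(lengths, 95)) if lengths else self.spec.kernel_size
        self.spec.max_len = max(self.spec.kernel_size, p95)

    def _encode_one(self, text: str) -> tuple[np.ndarray, bool]:
        seq = self.tokenizer.encode(text)
        empty = len(seq) == 0
        seq = seq[-self.spec.max_len :]  # drop oldest tokens
        row = np.zeros(self.spec.max_len, dtype=np.int64)
        row[: len(seq)] = seq
        return row, empty

    def _encode_all(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack([self._encode_one(t)[0] for t in texts])

    def _build_net(self):
        return build_model(
            self.spec,
            self.tokenizer.vocab_size,
            attention=self._attention,
            seed=self.seed,
        )

    def predict_texts(self, texts: Sequence[str]) -> Predictions:
        rows, empties = zip(*(self._encode_one(t) for t in texts))
        X = np.stack(rows)
        probs = np.concatenate(
            [self.net.predict_proba(X[i : i + 256]) for i in range(0, len(X), 256)]
        )
        return Predictions(
            probabilities=probs,
            labels=(probs >= 0.5).astype(int),
            empty_input=np.asarray(empties, dtype=bool),
        )

    # persistence ----------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "meta.json").write_text(
            json.dumps(
                {
                    "kind": self.name,
                    "seed": self.seed,
                    "spec": dataclasses.asdict(self.spec),
                    "attention": (
                        dataclasses.asdict(self._attention) if self._attention else None
                    ),
                }
            )
        )
        (directory / "vocabulary.json").write_text(json.dumps(self.tokenizer.word_index))
        np.savez(directory / "weights.npz", **self.net.params)

    @classmethod
    def load(cls, directory):
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        obj = cls(seed=meta["seed"], spec=CnnSpec(**meta["spec"]))
        if meta.get("attention"):
            obj._attention = AttentionSpec(**meta["attention"])
        obj.tokenizer.word_index = {
            k: int(v)
            for k, v in json.loads((directory / "vocabulary.json").read_text()).items()
        }
        obj.net = obj._build_net()
        with np.load(directory / "weights.npz") as data:
            obj.net.params = {k: data[k] for k in data.files}
        return obj


class AugmentedCNNClassifier(SimpleCNNClassifier):
    name = "augmented_cnn"

    def __init__(
        self,
        seed: int = 0,
        spec: CnnSpec | None = None,
        attention: AttentionSpec | None = None,
    ) -> None:
        super().__init__(seed, spec)
        self._attention = attention or AttentionSpec()

    @classmethod
    def load(cls, directory):
        obj = super().load(directory)
        if obj._attention is None:
            obj._attention = AttentionSpec()
        return obj


class BiLSTMClassifier(_NeuralClassifier):
    name = "bilstm"

    def __init__(self, seed: int = 0, spec: BilstmSpec | None = None) -> None:
        super().__init__(seed)
        self.spec = spec or BilstmSpec()
        self.vocab = AlphaVocab()

    def _fit_vocab(self, texts: Sequence[str]) -> None:
        self.vocab.fit(texts)

    def _encode_all(self, texts: Sequence[str]) -> list[list[int]]:
        # empty encodings become a single padding index, flagged at predict
        return [self.vocab.encode(t) or [AlphaVocab.PAD] for t in texts]

    def _build_net(self):
        return build_model(self.spec, self.vocab.vocab_size, seed=self.seed)

    def predict_texts(self, texts: Sequence[str]) -> Predictions:
        seqs = [self.vocab.encode(t) for t in texts]
        empties = np.array([len(s) == 0 for s in seqs], dtype=bool)
        seqs = [s or [AlphaVocab.PAD] for s in seqs]
        probs = np.empty(len(seqs))
        for start in range(0, len(seqs), 64):
            X, mask = pad_batch(seqs[start : start + 64])
            probs[start : start + 64] = sigmoid(self.net.forward(X, mask))
        return Predictions(
            probabilities=probs,
            labels=(probs >= 0.5).astype(int),
            empty_input=empties,
        )

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "meta.json").write_text(
            json.dumps(
                {
                    "kind": self.name,
                    "seed": self.seed,
                    "spec": dataclasses.asdict(self.spec),
                }
            )
        )
        (directory / "vocabulary.json").write_text(json.dumps(self.vocab.word_index))
        np.savez(directory / "weights.npz", **self.net.params)

    @classmethod
    def load(cls, directory):
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        obj = cls(seed=meta["seed"], spec=BilstmSpec(**meta["spec"]))
        obj.vocab.word_index = {
            k: int(v)
            for k, v in json.loads((directory / "vocabulary.json").read_text()).items()
        }
        obj.net = obj._build_net()
        with np.load(directory / "weights.npz") as data:
            obj.net.params = {k: data[k] for k in data.files}
        return obj


CLASSIFIER_KINDS = {
    "cnn": SimpleCNNClassifier,
    "acnn": AugmentedCNNClassifier,
    "bilstm": BiLSTMClassifier,
}


def load_classifier(directory):
    """Load any saved classifier bundle by its recorded kind."""
    meta = json.loads((Path(directory) / "meta.json").read_text())
    kinds = {
        "simple_cnn": SimpleCNNClassifier,
        "augmented_cnn": AugmentedCNNClassifier,
        "bilstm": BiLSTMClassifier,
    }
    return kinds[meta["kind"]].load(directory)
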