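"""Word-index schemes and batch padding for the neural models.

Two vocabularies coexist deliberately:

* :class:`Tokenizer` (CNN models): indices by descending training-corpus
  frequency starting at 1; unknown words are *dropped* on encode; 0 is the
  padding index.
* :class:`AlphaVocab` (Bi-LSTM): words sorted alphabetically with indices
  from 2, reserving 0 for padding and 1 for unknown; unknown words are
  *kept* as index 1, so encoded length equals token count.
"""

from __future__ import annotations

import string
from collections import Counter
from typing import Sequence

import numpy as np

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def words_of(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return text.lower().translate(_PUNCT_TABLE).split()


class Tokenizer:
    """Frequency-ranked word→index mapping; unknown words dropped."""

    def __init__(self) -> None:
        self.word_index: dict[str, int] = {}

    def fit(self, training_texts: Sequence[str]) -> "Tokenizer":
        if not training_texts:
            raise ValueError("cannot fit a tokenizer on an empty corpus")
        counts: Counter = Counter()
        first_seen: dict[str, int] = {}
        pos = 0
        for text in training_texts:
            for w in words_of(text):
                counts[w] += 1
                if w not in first_seen:
                    first_seen[w] = pos
                    pos += 1
        ordered = sorted(counts, key=lambda w: (-counts[w], first_seen[w]))
        self.word_index = {w: i + 1 for i, w in enumerate(ordered)}
        return self

    @property
    def vocab_size(self) -> int:
        return len(self.word_index)

    def encode(self, text: str) -> list[int]:
        wi = self.word_index
        return [wi[w] for w in words_of(text) if w in wi]


class AlphaVocab:
    """Alphabetical word→index mapping with pad=0 and unknown=1."""

    PAD = 0
    UNK = 1

    def __init__(self) -> None:
        self.word_index: dict[str, int] = {}

    def fit(self, training_texts: Sequence[str]) -> "AlphaVocab":
        if not training_texts:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        words = set()
        for text in training_texts:
            words.update(words_of(text))
        self.word_index = {w: i + 2 for i, w in enumerate(sorted(words))}
        return self

    @property
    def vocab_size(self) -> int:
        """Number of indices including the two reserved ones."""
        return len(self.word_index) + 2

    def encode(self, text: str) -> list[int]:
        wi = self.word_index
        return [wi.get(w, self.UNK) for w in words_of(text)]


def pad_batch(sequences: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad a batch with 0 to its own max length; return (array, mask).

    The mask marks real tokens with 1.  Raises on an empty batch or a batch
    whose sequences are all empty.
    """
    if len(sequences) == 0:
        raise ValueError("empty batch")
    maxlen = max(len(s) for s in sequences)
    if maxlen == 0:
        raise ValueError("batch contains only empty sequences")
    X = np.zeros((len(sequences), maxlen), dtype=np.int64)
    mask = np.zeros((len(sequences), maxlen), dtype=np.float64)
    for i, seq in enumerate(sequences):
        X[i, : len(seq)] = seq
        mask[i, : len(seq)] = 1.0
    return X, mask
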