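"""Sequence encodings for the binding/affinity classifiers.

Two feature families: overlapping k-mer count/frequency vectors (4^k
columns, lexicographic order) for the tabular models, and 30x4 one-hot
matrices (column order A, C, G, T; one-hot over positions) for the
sequence models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..library import all_kmers
from ..sequences import ALPHABET, INSERT_LENGTH, require_insert

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class EncodedDataset:
    """Feature matrix + labels + ids with encoding metadata.

    features: (n, 4^k) for k-mer mode, (n, 30, 4) for one-hot mode.
    """

    features: np.ndarray
    labels: np.ndarray
    ids: list[str]
    mode: str  # "kmer" | "onehot"
    k: int | None = None
    normalized: bool = False
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")


def encode_kmer(
    seqs: Sequence[str], k: int, normalize: bool = False
) -> np.ndarray:
    """Overlapping k-mer counts per sequence; 4^k lexicographic columns.

    Row sums are 31-k for counts over 30-mers, or 1 after normalization.
    """
    if not 1 <= k <= 5:
        raise ValueError("k must be in 1..5")
    kmers = {m: i for i, m in enumerate(all_kmers(k))}
    X = np.zeros((len(seqs), len(kmers)))
    for r, seq in enumerate(seqs):
        require_insert(seq)
        for i in range(len(seq) - k + 1):
            X[r, kmers[seq[i : i + k]]] += 1.0
    if normalize:
        X /= X.sum(axis=1, keepdims=True)
    return X


def encode_onehot(seqs: Sequence[str] | str) -> np.ndarray:
    """One-hot encode 30-mers to (n, 30, 4); a single string gives (30, 4)."""
    single = isinstance(seqs, str)
    seq_list = [seqs] if single else list(seqs)
    X = np.zeros((len(seq_list), INSERT_LENGTH, 4))
    for r, seq in enumerate(seq_list):
        require_insert(seq)
        for p, b in enumerate(seq):
            X[r, p, _BASE_INDEX[b]] = 1.0
    return X[0] if single else X


def decode_onehot(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode_onehot` for a single (30, 4) matrix."""
    idx = np.argmax(np.asarray(matrix), axis=-1)
    return "".join(ALPHABET[i] for i in idx)


def make_encoded_dataset(
    seqs: Sequence[str],
    labels: Sequence[int],
    mode: str,
    k: int = 2,
    normalize: bool = False,
    ids: Sequence[str] | None = None,
) -> EncodedDataset:
    if mode == "kmer":
        X = encode_kmer(seqs, k=k, normalize=normalize)
    elif mode == "onehot":
        X = encode_onehot(seqs)
    else:
        raise ValueError(f"unknown encoding mode {mode!r}")
    if ids is None:
        ids = [f"s{i}" for i in range(len(seqs))]
    return EncodedDataset(
        features=X,
        labels=np.asarray(labels),
        ids=list(ids),
        mode=mode,
        k=k if mode == "kmer" else None,
        normalized=normalize,
        sequences=list(seqs),
    )


def shuffle_preserving_composition(
    seq: str, rng: np.random.Generator
) -> str:
    """Random permutation of a sequence's bases (composition unchanged)."""
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)
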