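"""Overlapping k-mer frequency encoding and token streams.

Each window of ``n`` nucleotides yields ``n - K + 1`` overlapping K-mers.
With the default K = 3 (codon-scale context) a sequence is summarized by a
64-dimensional frequency vector over the 3-mers in fixed lexicographic order
(A < C < G < U: AAA, AAC, ..., UUU), normalized to sum to one.  The same
lexicographic index defines the integer token stream consumed by the
Transformer encoder.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .sequences import RnaSequence

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = ["kmer_labels", "kmer_encode", "tokenize", "kmer_matrix", "token_matrix"]


def kmer_labels(K: int = 3) -> list[str]:
    """The 4**K k-mer strings in lexicographic order (A < C < G < U)."""
    return ["".join(p) for p in product(BASES, repeat=K)]


def _residues(seq: RnaSequence | str) -> str:
    return seq.residues if isinstance(seq, RnaSequence) else seq


def tokenize(seq: RnaSequence | str, K: int = 3) -> np.ndarray:
    """Integer codes of the overlapping K-mers at offsets 0 .. n-K.

    The code of a K-mer is its base-4 value with A=0, C=1, G=2, U=3, which
    coincides with its rank in lexicographic order.
    """
    residues = _residues(seq)
    n = len(residues)
    if n < K:
        raise ValueError(f"sequence of length {n} is shorter than K={K}")
    codes = np.array([BASE_INDEX[b] for b in residues], dtype=np.int64)
    tokens = np.zeros(n - K + 1, dtype=np.int64)
    for j in range(K):
        tokens = tokens * 4 + codes[j:n - K + 1 + j]
    return tokens


def kmer_encode(seq: RnaSequence | str, K: int = 3) -> np.ndarray:
    """Normalized K-mer frequency vector of length 4**K (sums to one)."""
    tokens = tokenize(seq, K)
    counts = np.bincount(tokens, minlength=4 ** K).astype(np.float64)
    return counts / counts.sum()


def kmer_matrix(seqs: list[RnaSequence], K: int = 3) -> np.ndarray:
    """Stack of kmer_encode rows, shape (m, 4**K)."""
    return np.stack([kmer_encode(s, K) for s in seqs])


def token_matrix(seqs: list[RnaSequence], K: int = 3) -> np.ndarray:
    """Stack of token streams, shape (m, n-K+1); lengths must agree."""
    streams = [tokenize(s, K) for s in seqs]
    lengths = {len(t) for t in streams}
    if len(lengths) > 1:
        raise ValueError(f"heterogeneous token-stream lengths {sorted(lengths)}")
    return np.stack(streams)
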