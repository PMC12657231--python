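"""Evaluation mathematics: random-match model, recall curves, compression.

The random-match model asks how many of n samples a random query is
expected to share at least one k-mer with, under sampling without
replacement (hypergeometric): with a k-mer space of size M, a sample of S
distinct k-mers and a query of q distinct k-mers,

    P(at least one shared) = 1 - C(M - S, q) / C(M, q),

and the expectation over n independent samples is n times that.

Recall curves follow the re-query protocol: reads with known source labels
are mapped back to the index, and recall at identity cutoff c is the
fraction of reads whose true label is retrieved with sequence identity at
least c; realignability is the area under that curve over [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RandomMatchModel:
    kmer_space: int  # M
    sample_kmers: int  # S
    query_kmers: int  # q
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.sample_kmers > self.kmer_space:
            raise ValueError("sample_kmers must not exceed the k-mer space")
        if self.query_kmers > self.kmer_space:
            raise ValueError("query_kmers must not exceed the k-mer space")
        if min(self.kmer_space, self.sample_kmers, self.query_kmers, self.n_samples) < 0:
            raise ValueError("model parameters must be non-negative")


def dna_kmer_space(k: int, canonical: bool = False) -> int:
    """Size of the DNA k-mer space; with ``canonical=True`` the number of
    reverse-complement equivalence classes."""
    if not canonical:
        return 4**k
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


def p_at_least_one_match(model: RandomMatchModel) -> float:
    """Hypergeometric P(query shares >= 1 k-mer with the sample)."""
    M, S, q = model.kmer_space, model.sample_kmers, model.query_kmers
    if S == 0 or q == 0:
        return 0.0
    if q > M - S:
        return 1.0
    # C(M-S, q)/C(M, q) = prod_t (M-S-t)/(M-t), stable in log space
    log_p0 = 0.0
    for t in range(q):
        log_p0 += math.log(M - S - t) - math.log(M - t)
    return -math.expm1(log_p0)


def expected_random_matches(model: RandomMatchModel) -> float:
    """Expected number of samples sharing >= 1 k-mer with a random query."""
    return model.n_samples * p_at_least_one_match(model)


def simulate_random_matches(model: RandomMatchModel, trials: int,
                            rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo estimate of the expectation, with its standard error.

    Each trial draws the sample and the query without replacement from the
    k-mer space and counts an overlap event; the expectation is
    n_samples * P(overlap).
    """
    M, S, q = model.kmer_space, model.sample_kmers, model.query_kmers
    hits = 0
    for _ in range(trials):
        sample = rng.choice(M, size=S, replace=False)
        query = rng.choice(M, size=q, replace=False)
        if np.intersect1d(sample, query, assume_unique=True).size:
            hits += 1
    p = hits / trials
    se = math.sqrt(max(p * (1 - p), 1e-12) / trials)
    return model.n_samples * p, model.n_samples * se


@dataclass
class RecallCurve:
    cutoffs: np.ndarray
    recall: np.ndarray

    @property
    def realignability(self) -> float:
        """Area under recall over the identity cutoff in [0, 1]."""
        return float(np.trapezoid(self.recall, self.cutoffs))


def recall_curve(
    truth: dict[str, str],
    mappings: dict[str, tuple[str, float]],
    cutoffs=None,
) -> RecallCurve:
    """Recall of true labels as a function of the identity cutoff.

    ``truth`` maps read id -> source label; ``mappings`` maps read id ->
    (retrieved label, identity in [0, 1]).  Reads absent from ``mappings``
    count as unretrieved at every cutoff; a mapping for an unknown read is
    an error.
    """
    unknown = set(mappings) - set(truth)
    if unknown:
        raise ValueError(f"mappings contain unknown reads: {sorted(unknown)[:3]}")
    if cutoffs is None:
        cutoffs = np.linspace(0.0, 1.0, 101)
    cutoffs = np.asarray(cutoffs, dtype=float)
    n = len(truth)
    recall = np.zeros(len(cutoffs))
    if n:
        identities = np.array(
            [
                mappings[read][1] if read in mappings and mappings[read][0] == label else -1.0
                for read, label in truth.items()
            ]
        )
        for i, c in enumerate(cutoffs):
            recall[i] = np.count_nonzero(identities >= c) / n
    return RecallCurve(cutoffs, recall)


@dataclass
class CompressionStats:
    input_chars: int
    index_bytes: int
    relations: int

    def __post_init__(self) -> None:
        if min(self.input_chars, self.index_bytes, self.relations) <= 0:
            raise ValueError("all compression inputs must be positive")

    @property
    def ratio(self) -> float:
        """Input characters per index byte."""
        return self.input_chars / self.index_bytes

    @property
    def redundancy(self) -> float:
        """Input characters per annotation relation (within-sample duplication)."""
        return self.input_chars / self.relations

    @property
    def efficiency(self) -> float:
        """Annotation relations per index byte (cross-sample duplication)."""
        return self.relations / self.index_bytes


def compression_stats(input_chars: int, index_bytes: int, relations: int) -> CompressionStats:
    """Decompose a compression ratio as ratio = redundancy x efficiency."""
    return CompressionStats(input_chars, index_bytes, relations)
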