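"""Aptamer sequence encoders: cumulative k-mer and reverse-complement
canonical k-mer window frequencies.

Both encoders concatenate one block per k = 1..kmax. Within block k every
entry is (number of length-k windows equal to that k-mer) / (L - k + 1), so
each block is a probability vector over its k-mer universe. The plain
encoder enumerates all 4^k k-mers; the reverse-complement variant merges
each k-mer with its reverse complement and keeps the lexicographically
smaller representative, giving 2^(2k-1) classes for odd k and
2^(2k-1) + 2^(k-1) for even k.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .seqio import NucleotideSequence

NUCLEOTIDES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class EncodingError(ValueError):
    """Sequence cannot be encoded under the requested spec."""


@dataclass(frozen=True)
class KmerSpec:
    """Aptamer encoding parameters: k range upper bound and k-mer mode."""

    kmax: int = 3
    mode: str = "plain"  # or "revc"

    def __post_init__(self) -> None:
        if self.kmax < 1:
            raise ValueError(f"kmax must be >= 1, got {self.kmax}")
        if self.mode not in ("plain", "revc"):
            raise ValueError(f"mode must be 'plain' or 'revc', got {self.mode!r}")

    @property
    def n_features(self) -> int:
        if self.mode == "plain":
            return sum(4**k for k in range(1, self.kmax + 1))
        return sum(count_canonical(k) for k in range(1, self.kmax + 1))

    def encode(self, seq: NucleotideSequence | str) -> "FeatureVector":
        if self.mode == "plain":
            return kmer_vector(seq, self.kmax)
        return revc_kmer_vector(seq, self.kmax)


@dataclass(frozen=True)
class FeatureVector:
    """Named real-valued features; names unique, values finite."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.names)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, reversed)."""
    if not set(seq) <= set(NUCLEOTIDES):
        raise EncodingError(f"invalid DNA residues in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    return min(kmer, revcomp(kmer))


def count_canonical(k: int) -> int:
    """Number of reverse-complement equivalence classes of k-mers.

    2^(2k-1) for odd k; 2^(2k-1) + 2^(k-1) for even k (self-complementary
    k-mers exist only for even k).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k % 2 == 1:
        return 2 ** (2 * k - 1)
    return 2 ** (2 * k - 1) + 2 ** (k - 1)


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order."""
    return ["".join(p) for p in product(NUCLEOTIDES, repeat=k)]


def canonical_kmers(k: int) -> list[str]:
    """Canonical representatives in lexicographic order."""
    return sorted({canonical_kmer(m) for m in all_kmers(k)})


def _residues(seq: NucleotideSequence | str) -> tuple[str, str]:
    if isinstance(seq, NucleotideSequence):
        return seq.id, seq.residues
    return "<anonymous>", seq


def kmer_vector(seq: NucleotideSequence | str, kmax: int = 3) -> FeatureVector:
    """Cumulative k-mer window frequencies for k = 1..kmax.

    Dimension is sum over k of 4^k: 84 for kmax=3, 340 for kmax=4.
    """
    seq_id, residues = _residues(seq)
    if not set(residues) <= set(NUCLEOTIDES):
        raise EncodingError(f"sequence {seq_id!r}: residues outside ACGT")
    if len(residues) < kmax:
        raise EncodingError(
            f"sequence {seq_id!r}: length {len(residues)} < kmax {kmax}"
        )
    names: list[str] = []
    values: list[float] = []
    for k in range(1, kmax + 1):
        kmers = all_kmers(k)
        index = {m: i for i, m in enumerate(kmers)}
        counts = np.zeros(len(kmers))
        n_windows = len(residues) - k + 1
        for i in range(n_windows):
            counts[index[residues[i : i + k]]] += 1
        names.extend(f"k{k}_{m}" for m in kmers)
        values.extend(counts / n_windows)
    return FeatureVector(names=tuple(names), values=np.asarray(values))


def revc_kmer_vector(seq: NucleotideSequence | str, kmax: int = 3) -> FeatureVector:
    """Cumulative reverse-complement canonical k-mer frequencies, k = 1..kmax.

    Dimension is sum over k of count_canonical(k): 44 for kmax=3, 180 for
    kmax=4. Invariant under reverse complement of the input sequence.
    """
    seq_id, residues = _residues(seq)
    if not set(residues) <= set(NUCLEOTIDES):
        raise EncodingError(f"sequence {seq_id!r}: residues outside ACGT")
    if len(residues) < kmax:
        raise EncodingError(
            f"sequence {seq_id!r}: length {len(residues)} < kmax {kmax}"
        )
    names: list[str] = []
    values: list[float] = []
    for k in range(1, kmax + 1):
        reps = canonical_kmers(k)
        index = {m: i for i, m in enumerate(reps)}
        counts = np.zeros(len(reps))
        n_windows = len(residues) - k + 1
        for i in range(n_windows):
            counts[index[canonical_kmer(residues[i : i + k])]] += 1
        names.extend(f"rc{k}_{m}" for m in reps)
        values.extend(counts / n_windows)
    return FeatureVector(names=tuple(names), values=np.asarray(values))
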