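"""Canonical k-mer feature space and normalized profile matrices.

The feature representation is the frequency vector of canonical k-mers
(k = 4 or 5). A canonical k-mer is the lexicographic minimum of a k-mer and
its reverse complement, which makes the profile independent of the strand a
contig happens to be reported on. Collapsing gives 136 features for k=4
(16 palindromes + 120 reverse-complement pairs) and 512 for k=5 (odd k has
no palindromes). Each profile row is normalized by the number of valid
windows so it sums to one; windows containing N are skipped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_io import SequenceRecord

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# base -> 2-bit code; N (and anything else) -> 4 marks an invalid position
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerIndex:
    """Column layout of the canonical k-mer feature space.

    Columns are the canonical k-mers in lexicographic order, so the layout
    is deterministic for a given k.
    """

    k: int
    kmer_to_col: dict[str, int]
    code_to_col: np.ndarray  # 4**k entries: integer k-mer code -> column

    @property
    def n_features(self) -> int:
        return len(self.kmer_to_col)

    @property
    def columns(self) -> list[str]:
        return sorted(self.kmer_to_col, key=self.kmer_to_col.get)


def build_kmer_index(k: int) -> KmerIndex:
    """Enumerate canonical k-mers for k in {4, 5}.

    Other k values are out of scope for this feature representation.
    """
    if k not in (4, 5):
        raise ValueError(f"k must be 4 or 5, got {k}")
    all_kmers = ["".join(p) for p in itertools.product(_BASES, repeat=k)]
    canon = sorted({canonical(km) for km in all_kmers})
    kmer_to_col = {km: i for i, km in enumerate(canon)}
    code_to_col = np.empty(4**k, dtype=np.int64)
    for code, km in enumerate(all_kmers):
        code_to_col[code] = kmer_to_col[canonical(km)]
    return KmerIndex(k=k, kmer_to_col=kmer_to_col, code_to_col=code_to_col)


class ProfileError(ValueError):
    """A sequence cannot yield a k-mer profile (too short or all-N windows)."""


def kmer_profile(
    record: SequenceRecord, index: KmerIndex
) -> tuple[np.ndarray, int]:
    """Normalized canonical k-mer frequency vector for one sequence.

    Slides a window of length k (step 1); windows containing N are skipped.
    Returns ``(row, valid_kmer_count)`` where ``row`` sums to 1. Raises
    :class:`ProfileError` if the sequence is shorter than k or no window is
    free of N.
    """
    k = index.k
    if record.length < k:
        raise ProfileError(
            f"sequence {record.id!r} is shorter than k={k} ({record.length} bp)"
        )
    enc = _ENCODE[np.frombuffer(record.seq.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    valid = (windows < 4).all(axis=1)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ProfileError(
            f"sequence {record.id!r} has no k-mer window free of N"
        )
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = windows[valid].astype(np.int64) @ powers
    counts = np.bincount(index.code_to_col[codes], minlength=index.n_features)
    return counts / n_valid, n_valid


@dataclass
class ProfileMatrix:
    """Sequences x canonical k-mers normalized frequency matrix."""

    ids: list[str]
    k: int
    values: np.ndarray  # (n_sequences, n_features), rows sum to 1
    valid_kmer_counts: np.ndarray  # (n_sequences,) ints

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        return self.values[self.ids.index(seq_id)]

    def to_tsv(self, path, index: KmerIndex) -> None:
        df = pd.DataFrame(self.values, columns=index.columns)
        df.insert(0, "sequence_id", self.ids)
        df.to_csv(path, sep="\t", index=False)


def profile_matrix(records: list[SequenceRecord], k: int) -> ProfileMatrix:
    """Stack per-sequence profiles into a matrix, rows in input order."""
    if not records:
        raise ValueError("no records to profile")
    index = build_kmer_index(k)
    rows = np.empty((len(records), index.n_features), dtype=np.float64)
    counts = np.empty(len(records), dtype=np.int64)
    for i, rec in enumerate(records):
        rows[i], counts[i] = kmer_profile(rec, index)
    return ProfileMatrix(
        ids=[r.id for r in records], k=k, values=rows, valid_kmer_counts=counts
    )
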