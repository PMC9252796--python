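"""FASTA input/output, length filtering and per-sequence statistics.

Input sequences are assembled contigs or long reads. Sequences are stored
uppercase over the alphabet {A, C, G, T, N}; GC fraction is computed over
unambiguous (non-N) positions only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_BASES = frozenset("ACGTN")


class FastaError(ValueError):
    """Raised for malformed or unusable FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence with derived statistics.

    Attributes
    ----------
    id : str
        Header token before the first whitespace; unique within one input.
    seq : str
        Uppercase residues over {A, C, G, T, N}.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence id must be non-empty")
        if not self.seq:
            raise FastaError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FastaError(
                f"sequence {self.id!r} contains invalid character(s): "
                f"{', '.join(sorted(bad))}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        """GC fraction over A/C/G/T positions; N positions are excluded
        from the denominator. 0.0 for an all-N sequence."""
        acgt = sum(1 for b in self.seq if b != "N")
        if acgt == 0:
            return 0.0
        gc = self.seq.count("G") + self.seq.count("C")
        return gc / acgt


@dataclass
class LengthFilterResult:
    kept: list[SequenceRecord]
    discarded: list[tuple[str, int]] = field(default_factory=list)
    min_length: int = 1


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Sequences are uppercased; the record id is the header token before the
    first whitespace. Raises :class:`FastaError` on an empty file, a
    duplicate id, or characters outside {A, C, G, T, N} (case-insensitive).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        raise FastaError(f"no sequences found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA, preserving input order."""
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def filter_by_length(
    records: list[SequenceRecord], min_length: int
) -> LengthFilterResult:
    """Keep records with length >= ``min_length`` (inclusive), order preserved.

    Raises ``ValueError`` if ``min_length < 1`` or if no record survives
    (the downstream pipeline cannot proceed on an empty set).
    """
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    kept = [r for r in records if r.length >= min_length]
    discarded = [(r.id, r.length) for r in records if r.length < min_length]
    if not kept:
        raise ValueError(
            f"no sequences pass length filter (min_length={min_length} bp)"
        )
    return LengthFilterResult(kept=kept, discarded=discarded, min_length=min_length)


def write_discarded_tsv(result: LengthFilterResult, path: str | Path) -> None:
    """Report filtered-out sequences as TSV: sequence_id, length, reason."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence_id", "length", "reason"])
        for sid, length in result.discarded:
            w.writerow([sid, length, f"length<{result.min_length}"])
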