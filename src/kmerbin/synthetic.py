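"""Ground-truthed synthetic communities for end-to-end testing.

Each source genome is an order-m Markov chain over {A, C, G, T} whose
transition rows are drawn from a Dirichlet with a small concentration
parameter, so different genomes have distinct k-mer signatures by
construction (smaller ``distinctness_alpha`` means more distinct genomes).
Fragments emulate assembled contigs / long reads: lognormal lengths,
uniform start positions. A two-class differential design plants a
class-exclusive genome as a known differential-density signal.

All generators are pure functions of (spec, seed): reruns are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .seq_io import SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic mixed community.

    ``distinctness_alpha`` is the Dirichlet concentration for the per-genome
    Markov transition rows; 0.1 gives clearly separated compositional
    signatures, larger values blur them. Fragment lengths are lognormal with
    the given median (bp) and log-scale sigma, clipped to
    [500, genome_length].
    """

    n_genomes: int = 5
    genome_length: int = 200_000
    markov_order: int = 3
    distinctness_alpha: float = 0.1
    fragments_per_genome: int = 200
    fragment_length_median: int = 5_000
    fragment_length_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.markov_order > 4 or self.markov_order < 1:
            raise ValueError("markov_order must be in [1, 4]")
        for name in (
            "genome_length",
            "fragments_per_genome",
            "fragment_length_median",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.distinctness_alpha <= 0:
            raise ValueError("distinctness_alpha must be positive")
        if self.fragment_length_sigma <= 0:
            raise ValueError("fragment_length_sigma must be positive")


def _rng(spec_seed: int, *stream: int) -> np.random.Generator:
    """Independent, reproducible substream for one generator stage."""
    return np.random.default_rng([spec_seed, *stream])


def sample_genome(spec: CommunitySpec, genome_index: int) -> str:
    """Generate one genome from its own Markov chain.

    The transition matrix (4**markov_order contexts x 4 bases) is drawn
    row-wise from Dirichlet(distinctness_alpha) using the genome's own
    substream of the seed, so each (seed, genome_index) pair maps to exactly
    one sequence.
    """
    m = spec.markov_order
    rng = _rng(spec.seed, 1, genome_index)
    n_ctx = 4**m
    trans = rng.dirichlet([spec.distinctness_alpha] * 4, size=n_ctx)
    cum = np.cumsum(trans, axis=1)
    L = spec.genome_length
    out = np.empty(L, dtype=np.int64)
    start = rng.integers(0, 4, size=min(m, L))
    out[: len(start)] = start
    u = rng.random(L)
    ctx = 0
    for b in start:
        ctx = (ctx * 4 + int(b)) % n_ctx
    for i in range(len(start), L):
        row = cum[ctx]
        b = int(np.searchsorted(row, u[i], side="right"))
        b = min(b, 3)  # guard against cumulative rounding at 1.0
        out[i] = b
        ctx = (ctx * 4 + b) % n_ctx
    return "".join(_BASES[out])


@dataclass
class TruthTable:
    """Ground truth: fragment id -> source genome (and class, if any)."""

    frame: pd.DataFrame  # columns: sequence_id, genome, class (class may be NA)

    def genome_of(self) -> dict[str, int]:
        return dict(zip(self.frame["sequence_id"], self.frame["genome"]))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _lognormal_lengths(
    rng: np.random.Generator, n: int, median: int, sigma: float, max_len: int
) -> np.ndarray:
    lengths = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    lo, hi = 500, max_len
    if lo > hi:
        raise ValueError(
            f"impossible fragment clip range [500, {max_len}]; genome too short"
        )
    return np.clip(np.round(lengths).astype(np.int64), lo, hi)


def fragment_genome(
    genome: str,
    spec: CommunitySpec,
    genome_index: int,
    n_fragments: int | None = None,
    id_prefix: str = "",
    stream: int = 2,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Cut fragments out of one genome at uniform start positions.

    Returns the fragment records and their truth rows (sequence_id, genome).
    Lengths are lognormal(median, sigma) clipped to [500, genome_length].
    """
    n = spec.fragments_per_genome if n_fragments is None else n_fragments
    rng = _rng(spec.seed, stream, genome_index)
    lengths = _lognormal_lengths(
        rng, n, spec.fragment_length_median, spec.fragment_length_sigma, len(genome)
    )
    records = []
    rows = []
    for j, flen in enumerate(lengths):
        start = int(rng.integers(0, len(genome) - flen + 1))
        sid = f"{id_prefix}g{genome_index}_f{j}"
        records.append(SequenceRecord(id=sid, seq=genome[start : start + flen]))
        rows.append({"sequence_id": sid, "genome": genome_index})
    return records, pd.DataFrame(rows, columns=["sequence_id", "genome"])


def generate_community(
    spec: CommunitySpec,
) -> tuple[list[SequenceRecord], TruthTable]:
    """A mixed community: every genome contributes fragments_per_genome
    fragments."""
    records: list[SequenceRecord] = []
    frames = []
    for g in range(spec.n_genomes):
        genome = sample_genome(spec, g)
        recs, truth = fragment_genome(genome, spec, g)
        records.extend(recs)
        frames.append(truth)
    frame = pd.concat(frames, ignore_index=True)
    frame["class"] = pd.NA
    return records, TruthTable(frame=frame)


def generate_differential_pair(
    spec: CommunitySpec,
    abundance_a: np.ndarray,
    abundance_b: np.ndarray,
) -> tuple[list[SequenceRecord], dict[str, str], TruthTable]:
    """Two-class community with per-class genome abundances.

    Per class, round(fragments_per_genome * abundance) fragments are drawn
    from each genome; a genome with abundance 0 in one class yields
    class-exclusive fragments — the planted differential signal. Returns the
    records, the id -> class table and the ground truth.
    """
    abundance_a = np.asarray(abundance_a, dtype=np.float64)
    abundance_b = np.asarray(abundance_b, dtype=np.float64)
    for name, vec in (("abundance_a", abundance_a), ("abundance_b", abundance_b)):
        if vec.shape != (spec.n_genomes,):
            raise ValueError(f"{name} must have length n_genomes={spec.n_genomes}")
        if np.any(vec < 0):
            raise ValueError(f"{name} must be non-negative")
        if not np.isclose(vec.sum(), 1.0):
            raise ValueError(f"{name} must sum to 1")
    genomes = [sample_genome(spec, g) for g in range(spec.n_genomes)]
    records: list[SequenceRecord] = []
    class_table: dict[str, str] = {}
    frames = []
    for cls, vec, stream in (("A", abundance_a, 3), ("B", abundance_b, 4)):
        for g in range(spec.n_genomes):
            n = int(round(spec.fragments_per_genome * vec[g]))
            if n == 0:
                continue
            recs, truth = fragment_genome(
                genomes[g],
                spec,
                g,
                n_fragments=n,
                id_prefix=f"{cls}_",
                stream=stream,
            )
            records.extend(recs)
            truth["class"] = cls
            frames.append(truth)
            for r in recs:
                class_table[r.id] = cls
    if not records:
        raise ValueError("abundance vectors produced zero fragments")
    frame = pd.concat(frames, ignore_index=True)
    return records, class_table, TruthTable(frame=frame)


def write_class_table(class_table: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sequence_id": list(class_table), "class": list(class_table.values())}
    ).to_csv(path, sep="\t", index=False)


def variant_spec(spec: CommunitySpec, seed: int) -> CommunitySpec:
    """The same community design under a different seed."""
    return replace(spec, seed=seed)
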