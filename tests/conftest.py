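import numpy as np
import pytest

from kmerbin.kmer import ProfileMatrix, build_kmer_index
from kmerbin.seq_io import SequenceRecord


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text: str, name: str = "in.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def two_centroid_profiles(
    n_per_group: int = 50, k: int = 4, spread: int = 2000, seed: int = 7
) -> tuple[ProfileMatrix, np.ndarray]:
    """Rows drawn tightly around two distinct profile centroids.

    Each row is a multinomial frequency vector (``spread`` draws) around one
    of two Dirichlet-sampled centroids, i.e. a valid normalized profile.
    Returns the matrix and the ground-truth group labels (0/1).
    """
    rng = np.random.default_rng(seed)
    index = build_kmer_index(k)
    centroids = rng.dirichlet(np.full(index.n_features, 0.05), size=2)
    rows, groups = [], []
    for g in range(2):
        counts = rng.multinomial(spread, centroids[g], size=n_per_group)
        rows.append(counts / spread)
        groups.extend([g] * n_per_group)
    values = np.vstack(rows)
    ids = [f"s{i}" for i in range(len(values))]
    pm = ProfileMatrix(
        ids=ids,
        k=k,
        values=values,
        valid_kmer_counts=np.full(len(values), spread),
    )
    return pm, np.array(groups)


@pytest.fixture
def two_centroid():
    return two_centroid_profiles()


def make_records(seqs: dict[str, str]) -> list[SequenceRecord]:
    return [SequenceRecord(id=k, seq=v) for k, v in seqs.items()]
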