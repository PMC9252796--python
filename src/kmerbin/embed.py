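"""Dimensionality reduction of k-mer profiles to a 2D embedding.

Profiles can optionally be compressed with PCA before the (usually
neighbor-graph based) 2D reduction, which keeps large inputs tractable.
Backends are pluggable; bundled: UMAP (default), t-SNE and a deterministic
PCA baseline. Additional methods can be registered at run time via
:func:`register_embedder`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .kmer import ProfileMatrix

# auto-compression kicks in above this many sequences
AUTO_COMPRESS_THRESHOLD = 5000


@dataclass
class EmbedConfig:
    """Embedding method, its hyperparameters and the compression switch.

    ``params`` is passed through to the backend (e.g. ``n_neighbors`` and
    ``min_dist`` for UMAP, ``perplexity`` for t-SNE); unset keys fall back
    to the backend's published defaults. ``compress=None`` means automatic:
    on above ``AUTO_COMPRESS_THRESHOLD`` sequences, off below.
    """

    method: str = "umap"
    params: dict = field(default_factory=dict)
    compress: bool | None = None
    compress_dims: int = 50
    seed: int = 0


@dataclass
class Embedding2D:
    ids: list[str]
    coords: np.ndarray  # (n_sequences, 2)
    config: EmbedConfig

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sequence_id": self.ids, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        ).to_csv(path, sep="\t", index=False)


def compress_profiles(
    matrix: ProfileMatrix | np.ndarray, dims: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """PCA compression of the profile rows (mean-centered, variance maximizing).

    Returns ``(reduced, explained_variance_ratio)``. Deterministic: the full
    SVD solver is used, so the same input always yields the same projection.
    """
    X = matrix.values if isinstance(matrix, ProfileMatrix) else np.asarray(matrix)
    n, p = X.shape
    if not 2 <= dims < p:
        raise ValueError(f"dims must be in [2, {p - 1}], got {dims}")
    if n < dims:
        raise ValueError(f"need at least dims={dims} rows, got {n}")
    pca = PCA(n_components=dims, svd_solver="full", random_state=seed)
    reduced = pca.fit_transform(X)
    return reduced, pca.explained_variance_ratio_


def _embed_pca(X: np.ndarray, config: EmbedConfig) -> np.ndarray:
    reduced, _ = compress_profiles(X, 2, config.seed)
    return reduced


def _embed_tsne(X: np.ndarray, config: EmbedConfig) -> np.ndarray:
    from sklearn.manifold import TSNE

    n = X.shape[0]
    perplexity = config.params.get("perplexity", 30.0)
    # t-SNE requires perplexity < n; clamp for small inputs
    perplexity = min(perplexity, (n - 1) / 3)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=config.seed,
    )
    return tsne.fit_transform(X)


def _embed_umap(X: np.ndarray, config: EmbedConfig) -> np.ndarray:
    import umap

    n = X.shape[0]
    # genome binning cares about macro-structure: a wide neighborhood keeps
    # each genome's fragment cloud in one piece instead of shredding it
    n_neighbors = min(config.params.get("n_neighbors", 50), n - 1)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=config.params.get("min_dist", 0.1),
        random_state=config.seed,
    )
    return reducer.fit_transform(X)


_EMBEDDERS: dict[str, Callable[[np.ndarray, EmbedConfig], np.ndarray]] = {
    "umap": _embed_umap,
    "tsne": _embed_tsne,
    "pca": _embed_pca,
}


def register_embedder(
    name: str, fn: Callable[[np.ndarray, EmbedConfig], np.ndarray]
) -> None:
    """Register an additional embedding backend (plugin hook)."""
    _EMBEDDERS[name] = fn


def supported_embedders() -> list[str]:
    return sorted(_EMBEDDERS)


def embed_2d(
    matrix: ProfileMatrix | np.ndarray,
    config: EmbedConfig,
    ids: list[str] | None = None,
) -> Embedding2D:
    """Reduce profiles (or an already-compressed matrix) to 2D coordinates.

    Applies PCA compression first when ``config.compress`` is on (or when it
    is None and the input exceeds ``AUTO_COMPRESS_THRESHOLD`` rows). The same
    seed and input always give identical coordinates.
    """
    if isinstance(matrix, ProfileMatrix):
        X, ids = matrix.values, list(matrix.ids)
    else:
        X = np.asarray(matrix, dtype=np.float64)
        if ids is None:
            ids = [str(i) for i in range(X.shape[0])]
    if X.shape[0] < 10:
        raise ValueError(
            f"need at least 10 sequences to embed, got {X.shape[0]}"
        )
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in embedding input")
    if config.method not in _EMBEDDERS:
        raise ValueError(
            f"unknown embedding method {config.method!r}; "
            f"supported: {', '.join(supported_embedders())}"
        )
    compress = config.compress
    if compress is None:
        compress = X.shape[0] > AUTO_COMPRESS_THRESHOLD
    if compress and X.shape[1] > config.compress_dims:
        X, _ = compress_profiles(X, config.compress_dims, config.seed)
    coords = np.asarray(_EMBEDDERS[config.method](X, config), dtype=np.float64)
    return Embedding2D(ids=ids, coords=coords, config=config)
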