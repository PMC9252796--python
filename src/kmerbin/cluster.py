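"""Clustering of the 2D embedding into candidate bins.

Methods: dbscan, hdbscan, kmeans, spectral. Labels are renumbered to
1..n_clusters by decreasing cluster size (ties broken by the smallest member
id); 0 marks noise, which only density-based methods produce. To make the
result invariant to input row order, rows are sorted by sequence id before
the backend runs and mapped back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, HDBSCAN, KMeans, SpectralClustering

from .embed import Embedding2D

_METHODS = ("dbscan", "hdbscan", "kmeans", "spectral")


@dataclass
class ClusterLabels:
    ids: list[str]
    labels: np.ndarray  # int per sequence; >=1 member, 0 noise
    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))

    def sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"sequence_id": self.ids, "cluster": self.labels}).to_csv(
            path, sep="\t", index=False
        )


def _run_backend(
    X: np.ndarray, method: str, params: dict, seed: int
) -> np.ndarray:
    """Raw backend labels; -1 (or sklearn's noise convention) means noise."""
    if method == "dbscan":
        model = DBSCAN(
            eps=params.get("eps", 0.5), min_samples=params.get("min_samples", 5)
        )
    elif method == "hdbscan":
        model = HDBSCAN(
            min_cluster_size=params.get("min_cluster_size", 10),
            min_samples=params.get("min_samples", None),
            copy=True,
        )
    elif method == "kmeans":
        if "k" not in params:
            raise ValueError("kmeans requires a 'k' parameter")
        model = KMeans(n_clusters=int(params["k"]), n_init=10, random_state=seed)
    elif method == "spectral":
        if "k" not in params:
            raise ValueError("spectral requires a 'k' parameter")
        model = SpectralClustering(
            n_clusters=int(params["k"]),
            random_state=seed,
            assign_labels="discretize",
        )
    else:
        raise ValueError(
            f"unknown clustering method {method!r}; supported: {', '.join(_METHODS)}"
        )
    return model.fit_predict(X)


def _renumber(raw: np.ndarray, ids: list[str]) -> np.ndarray:
    """Map raw labels to 1..n by decreasing size, ties by smallest member id;
    noise (-1) maps to 0."""
    out = np.zeros(len(raw), dtype=np.int64)
    clusters = [c for c in np.unique(raw) if c != -1]
    keyed = []
    for c in clusters:
        members = np.flatnonzero(raw == c)
        smallest_id = min(ids[i] for i in members)
        keyed.append((-len(members), smallest_id, c))
    for new_label, (_, _, c) in enumerate(sorted(keyed), start=1):
        out[raw == c] = new_label
    return out


def cluster_embedding(
    embedding: Embedding2D,
    method: str = "hdbscan",
    params: dict | None = None,
    seed: int = 0,
) -> ClusterLabels:
    """Cluster 2D coordinates into candidate bins.

    Raises if the method is unknown, a required parameter (``k`` for
    kmeans/spectral) is missing, or every point ends up as noise.
    """
    params = dict(params or {})
    # canonical row order by id so results do not depend on input order
    order = np.argsort(np.array(embedding.ids, dtype=object))
    X = embedding.coords[order]
    sorted_ids = [embedding.ids[i] for i in order]
    raw = _run_backend(X, method, params, seed)
    labels_sorted = _renumber(raw, sorted_ids)
    if labels_sorted.max(initial=0) == 0:
        raise ValueError(
            "clustering produced no clusters (all points noise); "
            "try a larger eps / smaller min_cluster_size"
        )
    labels = np.empty_like(labels_sorted)
    labels[order] = labels_sorted
    return ClusterLabels(
        ids=list(embedding.ids), labels=labels, method=method,
        params=params, seed=seed,
    )
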