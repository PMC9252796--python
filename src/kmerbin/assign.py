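"""Semi-supervised bin assignment: train a classifier on the clustered
subset, then assign every remaining sequence to a bin.

The confident subset is the set of clustered (non-noise) sequences; clusters
with fewer than 5 members are dropped from training and their members are
routed back to classifier assignment. The classifier is a regularized
multinomial logistic regression over the k-mer profiles (not the 2D
coordinates), so new sequences can be assigned without re-embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cluster import ClusterLabels
from .kmer import ProfileMatrix

MIN_CLUSTER_TRAIN_SIZE = 5


@dataclass
class BinClassifier:
    model: LogisticRegression
    classes: list[int]
    training_accuracy: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)


@dataclass
class BinAssignment:
    """Final per-sequence bin labels with provenance.

    ``source`` is 'cluster' for sequences keeping their cluster label,
    'classifier' for sequences assigned by the trained model at or above the
    confidence threshold, and 'unassigned' (bin 0) otherwise. ``confidence``
    is the classifier's max posterior for every classifier-evaluated row
    (including ones below the threshold) and NaN for cluster-kept rows.
    """

    ids: list[str]
    bins: np.ndarray  # int, 0 = unassigned
    sources: list[str]
    confidences: np.ndarray  # float, NaN where not classifier-assigned

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence_id": self.ids,
                "bin": self.bins,
                "source": self.sources,
                "confidence": self.confidences,
            }
        )


def select_training_subset(labels: ClusterLabels) -> tuple[list[str], np.ndarray]:
    """Clustered sequences in clusters with >= 5 members, as training data.

    Returns ``(train_ids, train_labels)``. Raises if fewer than two clusters
    are large enough to train on.
    """
    sizes = labels.sizes()
    trainable = {c for c, n in sizes.items() if n >= MIN_CLUSTER_TRAIN_SIZE}
    if len(trainable) < 2:
        raise ValueError(
            "insufficient cluster structure for classification: need >= 2 "
            f"clusters with >= {MIN_CLUSTER_TRAIN_SIZE} members, "
            f"found {len(trainable)}"
        )
    mask = np.isin(labels.labels, list(trainable))
    train_ids = [sid for sid, m in zip(labels.ids, mask) if m]
    return train_ids, labels.labels[mask]


def train_bin_classifier(
    profiles: np.ndarray,
    train_labels: np.ndarray,
    seed: int = 0,
) -> BinClassifier:
    """Fit the multiclass probabilistic bin classifier on profile rows."""
    classes = np.unique(train_labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to train a bin classifier")
    if len(np.unique(profiles, axis=0)) == 1:
        raise ValueError(
            "degenerate features: all training profiles identical across classes"
        )
    model = LogisticRegression(C=100.0, max_iter=2000, random_state=seed)
    model.fit(profiles, train_labels)
    acc = float(np.mean(model.predict(profiles) == train_labels))
    return BinClassifier(
        model=model, classes=[int(c) for c in classes], training_accuracy=acc
    )


def assign_bins(
    classifier: BinClassifier,
    all_profiles: ProfileMatrix,
    labels: ClusterLabels,
    confidence_threshold: float = 0.5,
    extra_unassigned_ids: list[str] | None = None,
) -> BinAssignment:
    """Produce the final bin label for every sequence.

    Sequences in a trainable cluster keep their cluster label
    (source='cluster'). Everything else with a profile — noise points,
    members of dropped small clusters, sequences below the length filter —
    receives the classifier's argmax bin if its probability clears the
    threshold, else bin 0. ``extra_unassigned_ids`` (sequences too short to
    profile at all) are appended as unassigned.
    """
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ValueError("confidence_threshold must be in [0, 1]")
    trainable = set(classifier.classes)
    cluster_of = dict(zip(labels.ids, labels.labels.tolist()))

    n = len(all_profiles.ids)
    bins = np.zeros(n, dtype=np.int64)
    sources = ["unassigned"] * n
    confidences = np.full(n, np.nan)

    candidate_rows = [
        i
        for i, sid in enumerate(all_profiles.ids)
        if cluster_of.get(sid, 0) not in trainable
    ]
    for i, sid in enumerate(all_profiles.ids):
        c = cluster_of.get(sid, 0)
        if c in trainable:
            bins[i] = c
            sources[i] = "cluster"
    if candidate_rows:
        proba = classifier.predict_proba(all_profiles.values[candidate_rows])
        arg = np.argmax(proba, axis=1)
        best = proba[np.arange(len(candidate_rows)), arg]
        pred = np.asarray(classifier.model.classes_)[arg]
        for j, i in enumerate(candidate_rows):
            confidences[i] = best[j]
            if best[j] >= confidence_threshold:
                bins[i] = int(pred[j])
                sources[i] = "classifier"

    ids = list(all_profiles.ids)
    extra = list(extra_unassigned_ids or [])
    return BinAssignment(
        ids=ids + extra,
        bins=np.concatenate([bins, np.zeros(len(extra), dtype=np.int64)]),
        sources=sources + ["unassigned"] * len(extra),
        confidences=np.concatenate([confidences, np.full(len(extra), np.nan)]),
    )
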