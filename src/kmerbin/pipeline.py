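"""End-to-end pipeline: read -> filter -> profile -> embed -> cluster ->
classify -> summarize, with a JSON run manifest for reproducibility.

Every output is a TSV with a header row (or JSON for the manifest), written
atomically into the output directory. A rerun with the same inputs, config
and seed reproduces every table byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import (
    BinAssignment,
    assign_bins,
    select_training_subset,
    train_bin_classifier,
)
from .cluster import ClusterLabels, cluster_embedding
from .diffdensity import (
    DEFAULT_GRID_SIZE,
    density_difference,
    plot_density_difference,
    read_class_table,
)
from .embed import EmbedConfig, Embedding2D, embed_2d
from .kmer import ProfileError, build_kmer_index, kmer_profile, ProfileMatrix
from .seq_io import (
    SequenceRecord,
    filter_by_length,
    read_fasta,
    write_discarded_tsv,
)

logger = logging.getLogger("kmerbin")

DEFAULT_MIN_LENGTH = 500
MINOR_BIN_FRACTION = 0.01


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    k: int = 5
    min_length: int = DEFAULT_MIN_LENGTH
    embed_method: str = "umap"
    embed_params: dict = field(default_factory=dict)
    compress: bool | None = None
    compress_dims: int = 50
    cluster_method: str = "hdbscan"
    cluster_params: dict = field(default_factory=dict)
    confidence_threshold: float = 0.5
    bandwidth: float | None = None  # None = Scott's rule
    grid_size: int = DEFAULT_GRID_SIZE
    seed: int = 0


@dataclass
class PipelineResult:
    records: list[SequenceRecord]
    profiles: ProfileMatrix
    embedding: Embedding2D
    clusters: ClusterLabels
    assignment: BinAssignment
    summary: pd.DataFrame
    manifest: dict


def n50(lengths) -> int:
    """Largest L such that members of length >= L hold >= half the bases."""
    lengths = sorted(int(x) for x in lengths)
    if not lengths:
        return 0
    half = sum(lengths) / 2.0
    acc = 0
    for L in reversed(lengths):
        acc += L
        if acc >= half:
            return L
    return lengths[0]


def summarize_bins(
    assignment: BinAssignment, records: list[SequenceRecord]
) -> pd.DataFrame:
    """Per-bin size, total bp, N50, mean GC, fraction of sequences and the
    minor-bin flag (fraction < 1%; minor bins may be discarded downstream).
    """
    by_id = {r.id: r for r in records}
    total = len(assignment.ids)
    rows = []
    for b in sorted(set(assignment.bins.tolist()) - {0}):
        member_ids = [
            sid for sid, bb in zip(assignment.ids, assignment.bins) if bb == b
        ]
        members = [by_id[sid] for sid in member_ids]
        lengths = [m.length for m in members]
        frac = len(members) / total
        rows.append(
            {
                "bin": int(b),
                "n_sequences": len(members),
                "total_bp": int(sum(lengths)),
                "n50": n50(lengths),
                "mean_gc": float(np.mean([m.gc for m in members])),
                "fraction_of_sequences": frac,
                "minor_flag": frac < MINOR_BIN_FRACTION,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bin",
            "n_sequences",
            "total_bp",
            "n50",
            "mean_gc",
            "fraction_of_sequences",
            "minor_flag",
        ],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def run_pipeline(
    fasta_path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
    classes_path: str | Path | None = None,
    plot: bool = False,
) -> PipelineResult:
    """Run the full binning pipeline and write all artifacts to ``out_dir``.

    Artifacts: assignment.tsv, embedding.tsv, clusters.tsv, bin_summary.tsv,
    discarded.tsv, manifest.json, plus diff_grid.tsv / diff_grid.json /
    diff_clusters.tsv (and optionally diff.png) when ``classes_path`` gives
    a two-class label table. Any stage failure raises :class:`StageError`
    naming the stage.
    """
    fasta_path = Path(fasta_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc

    records = stage("seq_io", read_fasta, fasta_path)
    logger.info("read %d sequences", len(records))
    filt = stage("seq_io", filter_by_length, records, config.min_length)
    logger.info(
        "length filter (>= %d bp): kept %d, discarded %d",
        config.min_length, len(filt.kept), len(filt.discarded),
    )

    # profiles for every sequence long enough to count k-mers, including
    # below-filter ones: those become classifier-assignment candidates
    index = build_kmer_index(config.k)
    prof_rows, prof_ids, prof_counts, unprofiled = [], [], [], []
    for rec in records:
        try:
            row, cnt = kmer_profile(rec, index)
        except ProfileError:
            unprofiled.append(rec.id)
            continue
        prof_rows.append(row)
        prof_ids.append(rec.id)
        prof_counts.append(cnt)
    if not prof_ids:
        raise StageError("kmer", ValueError("no sequence yields a k-mer profile"))
    profiles = ProfileMatrix(
        ids=prof_ids,
        k=config.k,
        values=np.vstack(prof_rows),
        valid_kmer_counts=np.asarray(prof_counts),
    )
    kept_ids = {r.id for r in filt.kept}
    kept_mask = [sid in kept_ids for sid in profiles.ids]
    kept_profiles = ProfileMatrix(
        ids=[sid for sid, m in zip(profiles.ids, kept_mask) if m],
        k=config.k,
        values=profiles.values[kept_mask],
        valid_kmer_counts=profiles.valid_kmer_counts[kept_mask],
    )
    logger.info("profiled %d sequences (k=%d)", len(profiles.ids), config.k)

    embed_cfg = EmbedConfig(
        method=config.embed_method,
        params=dict(config.embed_params),
        compress=config.compress,
        compress_dims=config.compress_dims,
        seed=seed,
    )
    embedding = stage("embed", embed_2d, kept_profiles, embed_cfg)
    logger.info("embedded %d sequences with %s", len(embedding.ids), embed_cfg.method)

    clusters = stage(
        "cluster",
        cluster_embedding,
        embedding,
        config.cluster_method,
        dict(config.cluster_params),
        seed,
    )
    logger.info(
        "clustered into %d clusters (%d noise points)",
        clusters.n_clusters, int((clusters.labels == 0).sum()),
    )

    train_ids, train_labels = stage("assign", select_training_subset, clusters)
    id_row = {sid: i for i, sid in enumerate(kept_profiles.ids)}
    train_X = kept_profiles.values[[id_row[sid] for sid in train_ids]]
    classifier = stage("assign", train_bin_classifier, train_X, train_labels, seed)
    assignment = stage(
        "assign",
        assign_bins,
        classifier,
        profiles,
        clusters,
        config.confidence_threshold,
        unprofiled,
    )
    n_cluster = assignment.sources.count("cluster")
    n_clf = assignment.sources.count("classifier")
    n_un = assignment.sources.count("unassigned")
    logger.info(
        "assigned: %d by cluster, %d by classifier, %d unassigned",
        n_cluster, n_clf, n_un,
    )

    summary = summarize_bins(assignment, records)

    diff_result = None
    if classes_path is not None:
        classes = stage("diffdensity", read_class_table, classes_path)
        classes = {sid: c for sid, c in classes.items() if sid in set(embedding.ids)}
        diff_result = stage(
            "diffdensity",
            density_difference,
            embedding,
            classes,
            clusters,
            config.bandwidth,
            config.grid_size,
        )

    by_id = {r.id: r for r in records}
    assign_df = assignment.to_frame()
    assign_df["length"] = [by_id[sid].length for sid in assignment.ids]
    assign_df["gc"] = [by_id[sid].gc for sid in assignment.ids]

    manifest = {
        "tool": "kmerbin",
        "version": __version__,
        "input": {"path": str(fasta_path), "sha256": _sha256(fasta_path)},
        "classes_input": str(classes_path) if classes_path else None,
        "parameters": {
            **asdict(config),
            "training_accuracy": classifier.training_accuracy,
        },
        "counts": {
            "read": len(records),
            "filtered": len(filt.kept),
            "embedded": len(embedding.ids),
            "clustered": int((clusters.labels > 0).sum()),
            "assigned_cluster": n_cluster,
            "assigned_classifier": n_clf,
            "unassigned": n_un,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    _atomic_write(out_dir / "assignment.tsv",
                  lambda p: assign_df.to_csv(p, sep="\t", index=False))
    _atomic_write(out_dir / "embedding.tsv", embedding.to_tsv)
    _atomic_write(out_dir / "clusters.tsv", clusters.to_tsv)
    _atomic_write(out_dir / "bin_summary.tsv",
                  lambda p: summary.to_csv(p, sep="\t", index=False))
    _atomic_write(out_dir / "discarded.tsv",
                  lambda p: write_discarded_tsv(filt, p))
    _atomic_write(
        out_dir / "manifest.json",
        lambda p: Path(p).write_text(json.dumps(manifest, indent=2) + "\n"),
    )
    if diff_result is not None:
        diff_result.to_files(
            out_dir / "diff_grid.tsv",
            out_dir / "diff_grid.json",
            out_dir / "diff_clusters.tsv",
        )
        if plot:
            plot_density_difference(diff_result, embedding, out_dir / "diff.png")

    return PipelineResult(
        records=records,
        profiles=profiles,
        embedding=embedding,
        clusters=clusters,
        assignment=assignment,
        summary=summary,
        manifest=manifest,
    )


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> PipelineResult:
    """Replay a recorded run: same input, parameters and seed."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    params = dict(manifest["parameters"])
    params.pop("training_accuracy", None)
    config = PipelineConfig(**params)
    return run_pipeline(
        manifest["input"]["path"],
        config,
        out_dir,
        classes_path=manifest.get("classes_input"),
    )
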