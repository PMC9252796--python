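"""Differential two-class kernel density comparison on the 2D embedding.

For two user-defined sample classes A and B, a Gaussian 2D kernel density
estimate is computed for each class separately on a shared grid with a
shared bandwidth, and their difference surface f_A - f_B highlights regions
of the embedding dominated by one class. Each class density integrates to
one (per-class normalization), so the difference reflects distributional
shift rather than absolute sequence counts; the per-class member counts are
reported alongside so users can rescale.

The signed difference is also aggregated per cluster by evaluating both
densities exactly (closed form, not grid interpolation) at each member
point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterLabels
from .embed import Embedding2D

GRID_SIZE_MIN = 25
GRID_SIZE_MAX = 1000
DEFAULT_GRID_SIZE = 250
# grid bounds pad the data bounding box by this many bandwidths
PAD_BANDWIDTHS = 4.0


def default_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Scott's rule per axis for a 2D KDE: h_i = sigma_i * n^(-1/6).

    Raises on fewer than two points or a zero-variance axis (give an
    explicit bandwidth in that case).
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need >= 2 points for automatic bandwidth")
    sigma = points.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        raise ValueError(
            "zero variance on an axis; supply an explicit bandwidth"
        )
    factor = n ** (-1.0 / 6.0)
    return float(sigma[0] * factor), float(sigma[1] * factor)


@dataclass
class DensityGrid:
    """A class-specific KDE sampled at the centers of a G x G grid.

    ``values[i, j]`` is the probability density at the center of the cell
    with x-interval ``x_edges[i:i+2]`` and y-interval ``y_edges[j:j+2]``.
    """

    x_edges: np.ndarray  # (G+1,)
    y_edges: np.ndarray  # (G+1,)
    values: np.ndarray  # (G, G)
    bandwidth: tuple[float, float]
    n_points: int

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def cell_area(self) -> float:
        return float(
            (self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0])
        )

    def mass(self) -> float:
        """Riemann (midpoint) integral of the density over the grid."""
        return float(self.values.sum() * self.cell_area)


def _eval_density(
    points: np.ndarray, bandwidth: tuple[float, float], at: np.ndarray
) -> np.ndarray:
    """Exact KDE f(x) = (1/n) sum_i N(x | p_i, diag(h^2)) at query points."""
    hx, hy = bandwidth
    dx = (at[:, 0, None] - points[None, :, 0]) / hx
    dy = (at[:, 1, None] - points[None, :, 1]) / hy
    kern = np.exp(-0.5 * (dx**2 + dy**2))
    return kern.sum(axis=1) / (2.0 * np.pi * hx * hy * points.shape[0])


def kde_2d(
    points: np.ndarray,
    bandwidth: tuple[float, float],
    grid_size: int = DEFAULT_GRID_SIZE,
    bounds: tuple[float, float, float, float] | None = None,
) -> DensityGrid:
    """Gaussian product-kernel density estimate on a regular grid.

    ``bounds`` is (x_min, x_max, y_min, y_max); by default the data bounding
    box padded by 4 * max(h_x, h_y), which conserves >= 99% of the
    probability mass on the grid. The kernel is separable, so the grid is
    evaluated as an outer product of axis-wise Gaussian matrices.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[0] < 1 or points.shape[1] != 2:
        raise ValueError("points must be an n x 2 array with n >= 1")
    hx, hy = bandwidth
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidth components must be positive")
    if not GRID_SIZE_MIN <= grid_size <= GRID_SIZE_MAX:
        raise ValueError(
            f"grid_size must be in [{GRID_SIZE_MIN}, {GRID_SIZE_MAX}], got {grid_size}"
        )
    if bounds is None:
        pad = PAD_BANDWIDTHS * max(hx, hy)
        bounds = (
            points[:, 0].min() - pad,
            points[:, 0].max() + pad,
            points[:, 1].min() - pad,
            points[:, 1].max() + pad,
        )
    x_min, x_max, y_min, y_max = bounds
    if np.any(points[:, 0] < x_min) or np.any(points[:, 0] > x_max) or np.any(
        points[:, 1] < y_min
    ) or np.any(points[:, 1] > y_max):
        raise ValueError("bounds do not contain all points")
    x_edges = np.linspace(x_min, x_max, grid_size + 1)
    y_edges = np.linspace(y_min, y_max, grid_size + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    gx = np.exp(-0.5 * ((xc[:, None] - points[None, :, 0]) / hx) ** 2)
    gy = np.exp(-0.5 * ((yc[:, None] - points[None, :, 1]) / hy) ** 2)
    values = (gx @ gy.T) / (2.0 * np.pi * hx * hy * points.shape[0])
    return DensityGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        values=values,
        bandwidth=(float(hx), float(hy)),
        n_points=points.shape[0],
    )


@dataclass
class DensityDiffResult:
    """Per-class KDE grids, their difference surface and per-cluster scores.

    ``diff = grid_a.values - grid_b.values``; ``per_cluster`` has one row per
    nonzero cluster with columns cluster, n_A, n_B, mean_diff, sum_diff,
    where the diff is the exact f_A - f_B evaluated at member points.
    """

    class_a: str
    class_b: str
    grid_a: DensityGrid
    grid_b: DensityGrid
    diff: np.ndarray
    per_cluster: pd.DataFrame

    def to_files(self, grid_path, sidecar_path, cluster_path) -> None:
        """Diff grid as a TSV matrix, edges/bandwidth in a JSON sidecar,
        per-cluster table as TSV."""
        import json

        np.savetxt(grid_path, self.diff, delimiter="\t")
        sidecar = {
            "class_a": self.class_a,
            "class_b": self.class_b,
            "x_edges": self.grid_a.x_edges.tolist(),
            "y_edges": self.grid_a.y_edges.tolist(),
            "bandwidth": list(self.grid_a.bandwidth),
            "n_a": self.grid_a.n_points,
            "n_b": self.grid_b.n_points,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)
            fh.write("\n")
        self.per_cluster.to_csv(cluster_path, sep="\t", index=False)


def read_class_table(path) -> dict[str, str]:
    """Read a two-column TSV (sequence_id, class) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("class table needs columns sequence_id and class")
    ids, classes = df.iloc[:, 0], df.iloc[:, 1]
    return dict(zip(ids, classes))


def density_difference(
    embedding: Embedding2D,
    classes: dict[str, str],
    labels: ClusterLabels | None = None,
    bandwidth: float | tuple[float, float] | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> DensityDiffResult:
    """Differential density between the two classes on the shared embedding.

    ``classes`` maps sequence id to one of exactly two class names; the
    difference is density(first class) - density(second class) with the
    class names ordered lexicographically. Both grids share bounds (union
    bounding box, padded) and bandwidth (Scott's rule on the pooled labeled
    points unless given explicitly). Each class needs >= 2 points with
    automatic bandwidth, >= 1 with an explicit one.
    """
    pos = {sid: i for i, sid in enumerate(embedding.ids)}
    missing = sorted(sid for sid in classes if sid not in pos)
    if missing:
        raise ValueError(
            "class table ids missing from embedding: " + ", ".join(missing[:10])
        )
    names = sorted(set(classes.values()))
    if len(names) != 2:
        raise ValueError(f"need exactly two classes, got {names}")
    cls_a, cls_b = names
    pts = {
        c: embedding.coords[[pos[sid] for sid, cl in classes.items() if cl == c]]
        for c in names
    }
    min_pts = 1 if bandwidth is not None else 2
    for c in names:
        if pts[c].shape[0] < min_pts:
            raise ValueError(f"class {c!r} has fewer than {min_pts} points")

    # pooled points in embedding row order, not class order, so bandwidth
    # and bounds are bitwise invariant under a class swap
    labeled_rows = [i for i, sid in enumerate(embedding.ids) if sid in classes]
    pooled = embedding.coords[labeled_rows]
    if bandwidth is None:
        bw = default_bandwidth(pooled)
    elif np.isscalar(bandwidth):
        bw = (float(bandwidth), float(bandwidth))
    else:
        bw = (float(bandwidth[0]), float(bandwidth[1]))
    pad = PAD_BANDWIDTHS * max(bw)
    bounds = (
        pooled[:, 0].min() - pad,
        pooled[:, 0].max() + pad,
        pooled[:, 1].min() - pad,
        pooled[:, 1].max() + pad,
    )
    grid_a = kde_2d(pts[cls_a], bw, grid_size, bounds)
    grid_b = kde_2d(pts[cls_b], bw, grid_size, bounds)
    diff = grid_a.values - grid_b.values

    rows = []
    if labels is not None:
        class_of = classes
        for c in sorted(set(labels.labels.tolist()) - {0}):
            member_ids = [
                sid for sid, lab in zip(labels.ids, labels.labels) if lab == c
            ]
            members = [sid for sid in member_ids if sid in pos]
            at = embedding.coords[[pos[sid] for sid in members]]
            f_a = _eval_density(pts[cls_a], bw, at)
            f_b = _eval_density(pts[cls_b], bw, at)
            d = f_a - f_b
            rows.append(
                {
                    "cluster": int(c),
                    "n_A": sum(class_of.get(sid) == cls_a for sid in members),
                    "n_B": sum(class_of.get(sid) == cls_b for sid in members),
                    "mean_diff": float(d.mean()) if len(d) else 0.0,
                    "sum_diff": float(d.sum()),
                }
            )
    per_cluster = pd.DataFrame(
        rows, columns=["cluster", "n_A", "n_B", "mean_diff", "sum_diff"]
    )
    return DensityDiffResult(
        class_a=cls_a,
        class_b=cls_b,
        grid_a=grid_a,
        grid_b=grid_b,
        diff=diff,
        per_cluster=per_cluster,
    )


def plot_density_difference(
    result: DensityDiffResult, embedding: Embedding2D, path
) -> None:
    """Diverging-colormap heatmap of the diff surface with the embedding
    scatter overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    vmax = float(np.abs(result.diff).max()) or 1.0
    extent = (
        result.grid_a.x_edges[0],
        result.grid_a.x_edges[-1],
        result.grid_a.y_edges[0],
        result.grid_a.y_edges[-1],
    )
    im = ax.imshow(
        result.diff.T,
        origin="lower",
        extent=extent,
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        aspect="auto",
    )
    ax.scatter(
        embedding.coords[:, 0], embedding.coords[:, 1], s=3, c="black", alpha=0.3
    )
    fig.colorbar(im, ax=ax, label=f"density {result.class_a} - {result.class_b}")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
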