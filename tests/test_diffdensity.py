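import numpy as np
import pytest

from kmerbin.cluster import ClusterLabels
from kmerbin.diffdensity import (
    DensityGrid,
    default_bandwidth,
    density_difference,
    kde_2d,
    read_class_table,
)
from kmerbin.embed import EmbedConfig, Embedding2D


def naive_kde_grid(points, bandwidth, grid: DensityGrid):
    """Independent oracle: double loop over cells x points."""
    hx, hy = bandwidth
    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    out = np.zeros((len(xc), len(yc)))
    norm = 1.0 / (2.0 * np.pi * hx * hy * len(points))
    for i, x in enumerate(xc):
        for j, y in enumerate(yc):
            s = 0.0
            for px, py in points:
                s += np.exp(
                    -((x - px) ** 2 / (2 * hx**2) + (y - py) ** 2 / (2 * hy**2))
                )
            out[i, j] = s * norm
    return out


class TestDefaultBandwidth:
    def test_scott_rule_closed_form(self):
        """64 points with unit per-axis sd give h = 64^(-1/6) = 0.5."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(64, 2))
        pts = (pts - pts.mean(0)) / pts.std(0, ddof=1)  # exact unit sd
        hx, hy = default_bandwidth(pts)
        assert hx == pytest.approx(0.5)
        assert hy == pytest.approx(0.5)

    def test_identical_points_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            default_bandwidth(np.ones((10, 2)))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 2))
        h = np.array(default_bandwidth(pts))
        h_scaled = np.array(default_bandwidth(3.5 * pts))
        np.testing.assert_allclose(h_scaled, 3.5 * h, rtol=1e-12)


class TestKde2D:
    def test_single_point_closed_form(self):
        """Density at the kernel's own center with h=1 is 1/(2*pi)."""
        grid = kde_2d(
            np.array([[0.0, 0.0]]), (1.0, 1.0), grid_size=25, bounds=(-5, 5, -5, 5)
        )
        # (-5,5) with 25 cells puts a cell center exactly at 0
        ix = np.argmin(np.abs(0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])))
        assert grid.values[ix, ix] == pytest.approx(1.0 / (2 * np.pi), rel=1e-12)

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(scale=2.0, size=(50, 2))
        bw = default_bandwidth(pts)
        grid = kde_2d(pts, bw, grid_size=100)
        expected = naive_kde_grid(pts, bw, grid)
        np.testing.assert_allclose(grid.values, expected, atol=1e-10)

    def test_mass_conservation_with_default_padding(self):
        rng = np.random.default_rng(6)
        for n in (10, 200):
            pts = rng.normal(size=(n, 2)) * [1.0, 3.0]
            grid = kde_2d(pts, default_bandwidth(pts), grid_size=250)
            assert 0.99 <= grid.mass() <= 1.0

    def test_matches_scipy_mixture_cross_check(self):
        """Independent cross-check: the KDE is a uniform mixture of
        bivariate normals, evaluated here with scipy's multivariate_normal
        pdf per point."""
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 2))
        hx, hy = 0.7, 1.3
        grid = kde_2d(pts, (hx, hy), grid_size=30)
        xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        q = np.column_stack([X.ravel(), Y.ravel()])
        expected = np.mean(
            [
                multivariate_normal(mean=p, cov=np.diag([hx**2, hy**2])).pdf(q)
                for p in pts
            ],
            axis=0,
        ).reshape(30, 30)
        np.testing.assert_allclose(grid.values, expected, rtol=1e-8)

    def test_grid_maximum_near_mode(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(1000, 2))
        grid = kde_2d(pts, default_bandwidth(pts), grid_size=100)
        ix, iy = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
        cell = grid.x_edges[1] - grid.x_edges[0]
        assert abs(xc[ix]) <= 3 * cell + 1e-9
        assert abs(yc[iy]) <= 3 * cell + 1e-9

    def test_grid_size_bounds_enforced(self):
        pts = np.random.default_rng(0).normal(size=(10, 2))
        for g in (10, 2000):
            with pytest.raises(ValueError, match=r"\[25, 1000\]"):
                kde_2d(pts, (1.0, 1.0), grid_size=g)

    def test_bounds_must_contain_points(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0]])
        with pytest.raises(ValueError, match="bounds"):
            kde_2d(pts, (1.0, 1.0), grid_size=25, bounds=(-1, 1, -1, 1))

    def test_nonpositive_bandwidth_is_error(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError, match="bandwidth"):
            kde_2d(pts, (0.0, 1.0), grid_size=25)


def _embedding_with_classes(seed=0, n=60):
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0], 1.0, size=(n, 2))
    b = rng.normal([6, 0], 1.0, size=(n, 2))
    coords = np.vstack([a, b])
    ids = [f"p{i}" for i in range(2 * n)]
    emb = Embedding2D(ids=ids, coords=coords, config=EmbedConfig(method="pca"))
    classes = {ids[i]: ("A" if i < n else "B") for i in range(2 * n)}
    labels = ClusterLabels(
        ids=ids,
        labels=np.array([1] * n + [2] * n),
        method="test", params={}, seed=0,
    )
    return emb, classes, labels


class TestDensityDifference:
    def test_identical_point_sets_give_zero_diff(self):
        emb, _, labels = _embedding_with_classes()
        # same ids in both classes is impossible (one class per id), so use
        # two ids per coordinate: duplicate coordinates across classes
        coords = np.vstack([emb.coords, emb.coords])
        ids = [f"a{i}" for i in range(len(emb.coords))] + [
            f"b{i}" for i in range(len(emb.coords))
        ]
        emb2 = Embedding2D(ids=ids, coords=coords, config=emb.config)
        classes = {f"a{i}": "A" for i in range(len(emb.coords))}
        classes.update({f"b{i}": "B" for i in range(len(emb.coords))})
        labels2 = ClusterLabels(
            ids=ids, labels=np.ones(len(ids), dtype=int),
            method="t", params={}, seed=0,
        )
        res = density_difference(emb2, classes, labels2)
        assert np.abs(res.diff).max() < 1e-12
        assert (res.per_cluster["mean_diff"] == 0).all()

    def test_class_swap_negates_exactly(self):
        emb, classes, labels = _embedding_with_classes(seed=3)
        res = density_difference(emb, classes, labels)
        swapped = {k: ("B" if v == "A" else "A") for k, v in classes.items()}
        res_swap = density_difference(emb, swapped, labels)
        assert np.array_equal(res_swap.diff, -res.diff)
        np.testing.assert_array_equal(
            res_swap.per_cluster["mean_diff"].to_numpy(),
            -res.per_cluster["mean_diff"].to_numpy(),
        )

    def test_single_point_classes_closed_form(self):
        """A={(0,0)}, B={(10,10)} with h=1: the diff at (0,0) is about
        +1/(2*pi) because B's kernel is vanishingly small there."""
        ids = ["a", "b"]
        emb = Embedding2D(
            ids=ids,
            coords=np.array([[0.0, 0.0], [10.0, 10.0]]),
            config=EmbedConfig(),
        )
        classes = {"a": "A", "b": "B"}
        res = density_difference(emb, classes, None, bandwidth=1.0, grid_size=101)
        xc = 0.5 * (res.grid_a.x_edges[:-1] + res.grid_a.x_edges[1:])
        yc = 0.5 * (res.grid_a.y_edges[:-1] + res.grid_a.y_edges[1:])
        ix, iy = np.argmin(np.abs(xc)), np.argmin(np.abs(yc))
        # nearest cell center to the origin is within half a cell
        expected = 1.0 / (2 * np.pi)
        assert res.diff[ix, iy] == pytest.approx(expected, rel=0.05)

    def test_per_cluster_counts_and_sign(self):
        emb, classes, labels = _embedding_with_classes(seed=4)
        res = density_difference(emb, classes, labels)
        tbl = res.per_cluster.set_index("cluster")
        assert tbl.loc[1, "n_A"] == 60 and tbl.loc[1, "n_B"] == 0
        assert tbl.loc[2, "n_A"] == 0 and tbl.loc[2, "n_B"] == 60
        # cluster 1 sits where class A is dense: positive mean diff
        assert tbl.loc[1, "mean_diff"] > 0 > tbl.loc[2, "mean_diff"]

    def test_per_class_grids_integrate_to_one(self):
        emb, classes, labels = _embedding_with_classes(seed=5)
        res = density_difference(emb, classes, labels)
        assert res.grid_a.mass() == pytest.approx(1.0, abs=1e-2)
        assert res.grid_b.mass() == pytest.approx(1.0, abs=1e-2)

    def test_unknown_ids_in_class_table_is_error(self):
        emb, classes, labels = _embedding_with_classes()
        classes["ghost"] = "A"
        with pytest.raises(ValueError, match="ghost"):
            density_difference(emb, classes, labels)

    def test_not_two_classes_is_error(self):
        emb, classes, labels = _embedding_with_classes()
        with pytest.raises(ValueError, match="two classes"):
            density_difference(emb, {k: "A" for k in classes}, labels)

    def test_class_below_min_points_is_error(self):
        emb, classes, labels = _embedding_with_classes()
        tiny = {emb.ids[0]: "A", emb.ids[1]: "B", emb.ids[2]: "B"}
        with pytest.raises(ValueError, match="fewer than 2"):
            density_difference(emb, tiny, labels)

    def test_file_outputs(self, tmp_path):
        emb, classes, labels = _embedding_with_classes()
        res = density_difference(emb, classes, labels, grid_size=30)
        res.to_files(
            tmp_path / "g.tsv", tmp_path / "g.json", tmp_path / "c.tsv"
        )
        grid = np.loadtxt(tmp_path / "g.tsv", delimiter="\t")
        assert grid.shape == (30, 30)
        header = (tmp_path / "c.tsv").read_text().splitlines()[0]
        assert header == "cluster\tn_A\tn_B\tmean_diff\tsum_diff"
        import json

        sidecar = json.loads((tmp_path / "g.json").read_text())
        assert len(sidecar["x_edges"]) == 31

    def test_read_class_table(self, tmp_path):
        p = tmp_path / "classes.tsv"
        p.write_text("sequence_id\tclass\ns1\tA\ns2\tB\n")
        assert read_class_table(p) == {"s1": "A", "s2": "B"}
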