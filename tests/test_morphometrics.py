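"""Node splitting, the ten morphometric properties, correlation, k-means, PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from caq.morphometrics import (
    PROPERTY_COLUMNS,
    cluster_nodes,
    extract_nodes,
    pca_nodes,
    property_correlation,
    split_nodes,
)


def disk_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_node_table(n_per_cluster=30, seed=0) -> tuple[pd.DataFrame, np.ndarray]:
    """Three well-separated log-normal clusters in 10-property space."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    scales = [1.0, 20.0, 400.0]
    for k, s in enumerate(scales):
        for _ in range(n_per_cluster):
            base = s * rng.lognormal(0, 0.05)
            rows.append({
                "node_id": len(rows), "dataset_id": "d0",
                "volume_um3": base,
                "surface_area_um2": base ** 0.8,
                "diameter_um": base ** 0.5,
                "main_axis_um": base ** 0.5 * 1.2,
                "second_axis_um": base ** 0.5 * 0.8,
                "third_axis_um": 0.0,
                "mean_intensity": 50 * s ** 0.3 * rng.lognormal(0, 0.05),
                "max_intensity": 120 * s ** 0.3,
                "min_intensity": 10.0,
                "median_distance_um": 30.0 / s ** 0.2,
            })
            truth.append(k)
    return pd.DataFrame(rows), np.array(truth)


class TestExtract:
    def test_overlapping_disks_split_into_two_nodes(self):
        mask = disk_mask((100, 100), (50, 40), 15) | disk_mask((100, 100), (50, 62), 15)
        table = extract_nodes(mask, mask * 100.0, min_size_px=50)
        assert len(table) == 2

    def test_small_blob_filtered(self):
        mask = disk_mask((64, 64), (32, 32), 5)  # ~79 px
        table = extract_nodes(mask, mask * 1.0, min_size_px=100)
        assert len(table) == 0

    def test_circle_geometry(self):
        mask = disk_mask((100, 100), (50, 50), 20)
        table = extract_nodes(mask, mask * 1.0, pixel_size_um=0.5, min_size_px=50)
        (row,) = table.itertuples()
        assert row.diameter_um == pytest.approx(40 * 0.5, rel=0.05)
        assert row.main_axis_um == pytest.approx(row.second_axis_um, rel=0.05)
        assert row.volume_um3 == pytest.approx(np.pi * 20**2 * 0.25, rel=0.05)

    def test_axis_ordering_and_intensity_bounds(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((128, 128), bool)
        for _ in range(5):
            c = rng.uniform(20, 108, 2)
            mask |= disk_mask((128, 128), c, rng.uniform(8, 14))
        intensity = rng.uniform(10, 100, (128, 128)) * mask
        table = extract_nodes(mask, intensity, min_size_px=50)
        assert len(table) >= 1
        assert (table.main_axis_um >= table.second_axis_um - 1e-9).all()
        assert (table.min_intensity <= table.mean_intensity).all()
        assert (table.mean_intensity <= table.max_intensity).all()

    def test_watershed_conserves_pixels(self, rng):
        for _ in range(10):
            mask = np.zeros((128, 128), bool)
            for _ in range(rng.integers(3, 9)):
                c = rng.uniform(10, 118, 2)
                mask |= disk_mask((128, 128), c, rng.uniform(5, 15))
            labels = split_nodes(mask)
            assert (labels > 0).sum() == mask.sum()
            # no pixel duplicated: labels are a partition by construction
            assert labels[~mask].sum() == 0

    def test_deterministic(self):
        mask = disk_mask((100, 100), (50, 40), 15) | disk_mask((100, 100), (50, 62), 15)
        a = split_nodes(mask)
        b = split_nodes(mask)
        np.testing.assert_array_equal(a, b)

    def test_empty_mask_empty_table(self):
        table = extract_nodes(np.zeros((32, 32), bool), np.zeros((32, 32)))
        assert len(table) == 0


class TestCorrelation:
    def test_duplicated_property_correlates_perfectly(self):
        table, _ = make_node_table(seed=1)
        corr = property_correlation(table)
        diag = np.diag(corr)
        assert np.allclose(diag[~np.isnan(diag)], 1.0)  # NaN marks zero variance
        assert np.allclose(corr, corr.T, equal_nan=True)
        t2 = table.copy()
        t2["max_intensity"] = t2["mean_intensity"]
        corr2 = property_correlation(t2)
        assert corr2.loc["mean_intensity", "max_intensity"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        n = 1000
        table = pd.DataFrame({c: rng.normal(10, 1, n) for c in PROPERTY_COLUMNS})
        table["node_id"] = np.arange(n)
        table["dataset_id"] = "d0"
        corr = property_correlation(table).to_numpy()
        off = corr[~np.eye(10, dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.12

    def test_volume_surface_scaling(self):
        rows = []
        for i, r in enumerate(range(5, 30, 2)):
            mask = disk_mask((80, 80), (40, 40), r)
            t = extract_nodes(mask, mask * 1.0, min_size_px=10)
            rows.append(t.assign(node_id=i))
        table = pd.concat(rows, ignore_index=True)
        r = np.corrcoef(table.volume_um3, table.surface_area_um2)[0, 1]
        assert r > 0.95

    def test_zero_variance_column_flagged_not_zeroed(self):
        table, _ = make_node_table(seed=3)
        corr = property_correlation(table)
        assert corr["third_axis_um"].isna().all()


class TestClustering:
    def test_three_planted_clusters_selected_and_recovered(self):
        table, truth = make_node_table(seed=4)
        res = cluster_nodes(table, seed=0)
        assert res.chosen_k == 3
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_identical_rows_report_no_structure(self):
        table, _ = make_node_table(n_per_cluster=5, seed=5)
        table.loc[:, PROPERTY_COLUMNS] = 1.0
        res = cluster_nodes(table, seed=0)
        assert res.chosen_k is None and res.labels is None

    def test_fixed_seed_is_deterministic(self):
        table, _ = make_node_table(seed=6)
        a = cluster_nodes(table, seed=42)
        b = cluster_nodes(table, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.silhouette_by_k == b.silhouette_by_k


class TestPCA:
    def test_collinear_data_is_rank_one(self):
        rng = np.random.default_rng(7)
        t = rng.lognormal(0, 1, 100)
        table = pd.DataFrame({c: t * (i + 1) for i, c in enumerate(PROPERTY_COLUMNS)})
        table["node_id"] = np.arange(100)
        table["dataset_id"] = "d0"
        res = pca_nodes(table)
        assert res["explained_variance_ratio"][0] > 0.999

    def test_scores_are_uncorrelated(self):
        table, _ = make_node_table(seed=8)
        res = pca_nodes(table)
        cov = np.cov(res["scores"].T)
        off = cov[~np.eye(cov.shape[0], dtype=bool)]
        assert np.all(np.abs(off) < 1e-8 * max(1.0, cov.max()))

    def test_isotropic_gaussian_spreads_variance(self):
        rng = np.random.default_rng(9)
        n = 2000
        table = pd.DataFrame(
            {c: np.exp(rng.normal(0, 0.1, n)) for c in PROPERTY_COLUMNS}
        )
        table["node_id"] = np.arange(n)
        table["dataset_id"] = "d0"
        res = pca_nodes(table)
        evr = res["explained_variance_ratio"]
        assert evr[0] < 2.0 * evr[-1]


def test_large_nodes_have_wider_intensity_range_and_sit_closer():
    """Planted large nodes: higher intensity range, smaller median distance."""
    rng = np.random.default_rng(10)
    img = np.zeros((256, 256))
    mask = np.zeros((256, 256), bool)
    # large nodes clustered centrally, small nodes on the periphery
    large_centers = [(110 + 30 * i, 110 + 25 * j) for i in range(2) for j in range(2)]
    small_centers = [(20, 20), (20, 236), (236, 20), (236, 236), (128, 15)]
    for c in large_centers:
        m = disk_mask((256, 256), c, 12)
        mask |= m
        img[m] = rng.uniform(20, 250, m.sum())
    for c in small_centers:
        m = disk_mask((256, 256), c, 6)
        mask |= m
        img[m] = rng.uniform(90, 130, m.sum())
    table = extract_nodes(mask, img, min_size_px=50)
    table["range"] = table.max_intensity - table.min_intensity
    large = table.volume_um3 > table.volume_um3.median()
    assert table[large]["range"].mean() > table[~large]["range"].mean()
    assert table[large].median_distance_um.mean() < table[~large].median_distance_um.mean()
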