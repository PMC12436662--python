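"""Node-level morphometrics of condensate:filament assemblies.

Connected components of a reconstructed network image are treated as
"nodes". Touching nodes are separated with a watershed on the negated
Euclidean distance transform seeded at h-maxima (h = 2 px by default, so
small unimodal blobs are never split); nodes below 100 px are removed. Ten
properties are extracted per node:

1.  volume (area x pixel area in 2D mode, µm²; µm³ with a z-depth),
2.  surface area (perimeter x pixel size in 2D mode, µm),
3.  diameter (maximum Feret diameter, µm),
4-6. main / second / third axis lengths from the intensity-weighted inertia
    tensor (third axis 0 in 2D mode, µm),
7-9. mean / max / min intensity,
10. median centroid-to-centroid Euclidean distance to all other nodes (µm).

The property table feeds Pearson correlation, k-means clustering with
silhouette-based model selection on log-transformed columns, and PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label, regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import watershed
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

__all__ = [
    "PROPERTY_COLUMNS",
    "split_nodes",
    "extract_nodes",
    "property_correlation",
    "cluster_nodes",
    "pca_nodes",
    "ClusterResult",
]

PROPERTY_COLUMNS = [
    "volume_um3",
    "surface_area_um2",
    "diameter_um",
    "main_axis_um",
    "second_axis_um",
    "third_axis_um",
    "mean_intensity",
    "max_intensity",
    "min_intensity",
    "median_distance_um",
]


def split_nodes(mask: np.ndarray, h_px: float = 2.0) -> np.ndarray:
    """Label a binary mask, splitting touching blobs by distance-transform watershed.

    Seeds are the h-maxima of the Euclidean distance transform, so a blob is
    split only where the distance map has two maxima separated by a saddle
    deeper than ``h_px``. Every foreground pixel keeps exactly one label
    (pixel conservation).
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    seeds = h_maxima(distance, h_px)
    markers = label(seeds, connectivity=2)
    if markers.max() == 0:
        return label(mask, connectivity=2).astype(np.int32)
    return watershed(-distance, markers, mask=mask).astype(np.int32)


def _weighted_axis_lengths(region) -> tuple[float, float]:
    """Major/minor ellipse axis lengths from intensity-weighted central moments."""
    mu = region.moments_weighted_central
    m00 = mu[0, 0]
    if m00 <= 0:
        return 0.0, 0.0
    cov = np.array([[mu[2, 0], mu[1, 1]], [mu[1, 1], mu[0, 2]]]) / m00
    eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    minor, major = 4.0 * np.sqrt(eigvals)
    return float(major), float(minor)


def extract_nodes(
    mask_or_labels: np.ndarray,
    intensity: np.ndarray,
    pixel_size_um: float = 1.0,
    min_size_px: int = 100,
    h_px: float = 2.0,
    dataset_id: str = "d0",
    z_depth_um: float | None = None,
) -> pd.DataFrame:
    """Split, filter (< ``min_size_px`` removed) and measure network nodes.

    Accepts either a binary mask (watershed splitting applied) or an
    integer label image (labels used as-is). Returns one row per node with
    the ten morphometric properties plus ``node_id`` and ``dataset_id``.
    """
    arr = np.asarray(mask_or_labels)
    intensity = np.asarray(intensity, dtype=np.float64)
    if arr.shape != intensity.shape:
        raise ValueError("mask and intensity image must share shape")
    labels = arr.astype(np.int32) if arr.dtype.kind in "iu" and arr.max() > 1 else split_nodes(arr, h_px)
    px = pixel_size_um
    depth = z_depth_um if z_depth_um is not None else 1.0  # 2D: volume == area in um^2
    rows = []
    for region in regionprops(labels, intensity_image=intensity):
        if region.area < min_size_px:
            continue
        major, minor = _weighted_axis_lengths(region)
        rows.append(
            {
                "node_id": int(region.label),
                "dataset_id": dataset_id,
                "centroid_y": region.centroid[0],
                "centroid_x": region.centroid[1],
                "volume_um3": region.area * px * px * depth,
                "surface_area_um2": region.perimeter * px,
                "diameter_um": region.feret_diameter_max * px,
                "main_axis_um": major * px,
                "second_axis_um": minor * px,
                "third_axis_um": 0.0,
                "mean_intensity": float(region.intensity_mean),
                "max_intensity": float(region.intensity_max),
                "min_intensity": float(region.intensity_min),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return pd.DataFrame(columns=["node_id", "dataset_id", "centroid_y", "centroid_x",
                                     *PROPERTY_COLUMNS])
    cy = table["centroid_y"].to_numpy()
    cx = table["centroid_x"].to_numpy()
    dist = np.hypot(cy[:, None] - cy[None, :], cx[:, None] - cx[None, :]) * px
    if len(table) > 1:
        med = np.array([np.median(np.delete(dist[i], i)) for i in range(len(table))])
    else:
        med = np.zeros(1)
    table["median_distance_um"] = med
    return table[["node_id", "dataset_id", "centroid_y", "centroid_x", *PROPERTY_COLUMNS]]


def rescale_intensities(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale intensity columns to [0, 1] per dataset.

    Makes intensity columns comparable before concatenated tables from
    different acquisitions are analysed together.
    """
    out = table.copy()
    cols = ["mean_intensity", "max_intensity", "min_intensity"]
    for _, idx in out.groupby("dataset_id").groups.items():
        block = out.loc[idx, cols]
        lo = block.min().min()
        hi = block.max().max()
        span = hi - lo
        out.loc[idx, cols] = (block - lo) / span if span > 0 else 0.0
    return out


def property_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the ten node properties.

    Intensities are min-max rescaled per dataset before the (concatenated)
    columns are correlated. Zero-variance columns yield NaN rows/columns
    rather than silent zeros; the diagonal stays 1 wherever defined.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 nodes")
    data = rescale_intensities(table)[PROPERTY_COLUMNS]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = data.corr(method="pearson")
    zero_var = data.std(ddof=0) == 0
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    np.fill_diagonal(corr.values, np.where(zero_var, np.nan, 1.0))
    return corr


def log_transform(table: pd.DataFrame, standardize: bool = True) -> np.ndarray:
    """log10(x + eps) per property column, optionally column-standardized.

    ``eps`` is 1e-6 of each column's smallest positive value (or 1e-6 when a
    column has no positive entries), which keeps zeros finite while leaving
    the scale of positive values untouched.
    """
    X = table[PROPERTY_COLUMNS].to_numpy(dtype=float)
    eps = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        pos = X[:, j][X[:, j] > 0]
        eps[j] = 1e-6 * pos.min() if pos.size else 1e-6
    X = np.log10(X + eps)
    if standardize:
        sd = X.std(axis=0)
        keep = sd > 0
        X = X[:, keep]
        X = StandardScaler().fit_transform(X)
    return X


@dataclass
class ClusterResult:
    labels: np.ndarray | None
    silhouette_by_k: dict[int, float]
    chosen_k: int | None
    seed: int


def cluster_nodes(
    table: pd.DataFrame,
    k_range: range = range(2, 9),
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """K-means over ``k_range`` on the log-transformed property matrix.

    Runs k-means with ``n_init`` restarts for each k, scores each with the
    mean silhouette, and picks the k with the best score. Degenerate inputs
    (all rows identical) report no clustering structure; k values exceeding
    the number of distinct rows are skipped with a warning.
    """
    X = log_transform(table)
    if X.size == 0 or len(np.unique(X, axis=0)) < 2:
        return ClusterResult(None, {}, None, seed)
    n_distinct = len(np.unique(X, axis=0))
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if k > n_distinct or k >= len(X):
            warnings.warn(f"skipping k={k}: not enough distinct points", stacklevel=2)
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(X, lab))
        labels_by_k[k] = lab
    if not sil:
        return ClusterResult(None, {}, None, seed)
    chosen = max(sil, key=sil.get)
    return ClusterResult(labels_by_k[chosen], sil, chosen, seed)


def pca_nodes(table: pd.DataFrame) -> dict:
    """PCA of the log-transformed, column-standardized property matrix.

    Returns scores (all components), loadings, and the explained-variance
    ratio; components beyond the matrix rank carry zero variance.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 nodes")
    X = log_transform(table, standardize=True)
    pca = PCA()
    scores = pca.fit_transform(X)
    return {
        "scores": scores,
        "loadings": pca.components_,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
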