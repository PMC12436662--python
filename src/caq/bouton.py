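"""Super-resolution bouton quantification and shared group statistics.

Covers four measurements on STED / expansion-microscopy images:

* **Bouton ROIs** — the vesicle-marker channel is converted to a mask
  (Gaussian smoothing + Otsu), optionally intersected with a GFP mask in
  rescue conditions, and split into particle ROIs; low-circularity ROIs can
  be re-split by watershed to separate fused boutons.
* **Actin enrichment** — per-ROI maximum actin intensity normalized to the
  maximum of the whole actin image, summarized as the per-image median.
* **Ring autocorrelation** — normalized autocorrelation of a line profile
  along an axon; the dominant spatial period (the ~190 nm actin ring
  spacing) is the lag of the first local maximum after the zero-lag peak.
* **Cluster density** — count of suprathreshold clusters (intensity and
  area thresholds) per axonal area.

The statistics helpers implement iterative Grubbs outlier removal, a
Shapiro–Wilk normality gate, and routing to a two-sided Mann–Whitney U test
or Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .morphometrics import split_nodes
from .segment import remove_outliers_rout

__all__ = [
    "BoutonROIs",
    "DensityResult",
    "bouton_rois",
    "actin_enrichment",
    "ring_autocorrelation",
    "cluster_density",
    "grubbs_outliers",
    "compare_groups",
]


@dataclass
class BoutonROIs:
    labels: np.ndarray
    table: pd.DataFrame  # roi_id, area_px2, circularity


@dataclass
class DensityResult:
    image_id: str
    n_objects: int
    axon_area_px2: float
    density_per_px2: float
    axon_area_um2: float | None = None
    density_per_um2: float | None = None


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0
    return min(4.0 * np.pi * area / perimeter**2, 1.0)


def bouton_rois(
    marker_channel: np.ndarray,
    gfp_channel: np.ndarray | None = None,
    min_intensity: float | None = None,
    min_intensity_gfp: float | None = None,
    split_by_circularity: bool = False,
    circularity_threshold: float = 0.5,
    smooth_sigma: float = 1.0,
    min_area_px: int = 5,
) -> BoutonROIs:
    """Particle ROIs from the vesicle-marker channel (optionally AND GFP).

    The default mask is Otsu on the lightly smoothed channel; an explicit
    ``min_intensity`` floor can be added (the expansion-microscopy variant)
    to keep background out of the mask. In rescue conditions the ROI mask is
    the intersection of the marker and GFP masks so only transfected cells
    are analysed. With ``split_by_circularity``, ROIs below the circularity
    threshold are re-split by a distance-transform watershed.
    """
    marker = np.asarray(marker_channel, dtype=np.float64)
    mask = _auto_mask(marker, smooth_sigma, min_intensity)
    if gfp_channel is not None:
        gfp = np.asarray(gfp_channel, dtype=np.float64)
        if gfp.shape != marker.shape:
            raise ValueError("channels must share shape")
        mask &= _auto_mask(gfp, smooth_sigma, min_intensity_gfp)
    labels = label(mask, connectivity=2)
    if split_by_circularity and labels.max() > 0:
        labels = _split_low_circularity(labels, circularity_threshold)
    rows = []
    out = np.zeros_like(labels)
    next_id = 0
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        next_id += 1
        out[labels == region.label] = next_id
        rows.append(
            {
                "roi_id": next_id,
                "area_px2": int(region.area),
                "circularity": _circularity(region.area, region.perimeter),
            }
        )
    cols = ["roi_id", "area_px2", "circularity"]
    return BoutonROIs(out, pd.DataFrame(rows, columns=cols))


def _auto_mask(img: np.ndarray, smooth_sigma: float, floor: float | None) -> np.ndarray:
    smooth = ndi.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    if np.ptp(smooth) == 0:
        return np.zeros(img.shape, dtype=bool)
    mask = smooth > threshold_otsu(smooth)
    if floor is not None:
        mask &= img > floor
    return mask


def _split_low_circularity(labels: np.ndarray, threshold: float) -> np.ndarray:
    out = labels.copy()
    next_label = labels.max()
    for region in regionprops(labels):
        if _circularity(region.area, region.perimeter) >= threshold:
            continue
        sub = labels == region.label
        pieces = split_nodes(sub, h_px=1.0)
        n = pieces.max()
        if n <= 1:
            continue
        out[sub] = 0
        for k in range(1, n + 1):
            next_label += 1
            out[(pieces == k)] = next_label
    return _relabel(out)


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def actin_enrichment(
    rois: BoutonROIs, actin_channel: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Normalized per-ROI actin maxima and their per-image median.

    Each ROI's maximum actin intensity is divided by the maximum of the
    whole actin image, so values lie in (0, 1] and are invariant under
    global rescaling of the actin channel.
    """
    actin = np.asarray(actin_channel, dtype=np.float64)
    if actin.shape != rois.labels.shape:
        raise ValueError("actin channel must match ROI geometry")
    if len(rois.table) == 0:
        raise ValueError("no ROIs to measure")
    global_max = actin.max()
    if global_max <= 0:
        raise ValueError("actin channel maximum is non-positive; normalization undefined")
    table = rois.table.copy()
    maxima = ndi.labeled_comprehension(
        actin, rois.labels, table["roi_id"].to_numpy(), np.max, float, np.nan
    )
    table["max_actin_raw"] = maxima
    table["max_actin_norm"] = maxima / global_max
    return table, float(table["max_actin_norm"].median())


def ring_autocorrelation(
    profile: np.ndarray, pixel_um: float, max_lag_um: float | None = None
) -> dict:
    """Normalized autocorrelation of a line profile and its dominant period.

    The profile is mean-subtracted and the autocorrelation normalized so the
    zero-lag value is 1. The dominant period is the lag of the first local
    maximum after the zero-lag peak; ``None`` when no local maximum exists.
    """
    y = np.asarray(profile, dtype=np.float64)
    if y.size < 3:
        raise ValueError("profile too short")
    y = y - y.mean()
    var = np.dot(y, y)
    if var == 0:
        raise ValueError("constant profile: zero variance")
    full = np.correlate(y, y, mode="full")
    ac = full[y.size - 1:] / var
    lags_um = np.arange(ac.size) * pixel_um
    if max_lag_um is not None:
        keep = lags_um <= max_lag_um
        ac, lags_um = ac[keep], lags_um[keep]
    period = None
    interior = np.flatnonzero(
        (ac[1:-1] > ac[:-2]) & (ac[1:-1] >= ac[2:])
    ) + 1
    if interior.size:
        period = float(lags_um[interior[0]])
    return {"lags_um": lags_um, "autocorrelation": ac, "period_um": period}


def cluster_density(
    img: np.ndarray,
    axon_mask: np.ndarray,
    theta_intensity: float = 4000.0,
    theta_area_px: int = 10,
    pixel_size_um: float | None = None,
    image_id: str = "",
) -> DensityResult:
    """Count suprathreshold clusters inside an axon mask, per mask area.

    A cluster counts when its pixels exceed ``theta_intensity`` and its area
    exceeds ``theta_area_px`` (both strict, matching ">4000 intensity
    counts, >10 pixel area" conventions).
    """
    img = np.asarray(img, dtype=np.float64)
    axon_mask = np.asarray(axon_mask) > 0
    if img.shape != axon_mask.shape:
        raise ValueError("image and axon mask must share shape")
    if not axon_mask.any():
        raise ValueError("axon mask is empty")
    binary = (img > theta_intensity) & axon_mask
    labels = label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    n = int(np.count_nonzero(counts[1:] > theta_area_px))
    area_px2 = float(axon_mask.sum())
    res = DensityResult(
        image_id=image_id,
        n_objects=n,
        axon_area_px2=area_px2,
        density_per_px2=n / area_px2,
    )
    if pixel_size_um is not None:
        res.axon_area_um2 = area_px2 * pixel_size_um**2
        res.density_per_um2 = n / res.axon_area_um2
    return res


def axon_mask_from_signal(img: np.ndarray, theta_intensity: float = 4000.0) -> np.ndarray:
    """Convex hull of suprathreshold signal, a fallback axon mask."""
    from skimage.morphology import convex_hull_image

    binary = np.asarray(img) > theta_intensity
    if not binary.any():
        raise ValueError("no suprathreshold signal to hull")
    return convex_hull_image(binary)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def grubbs_outliers(values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs test; removes one extreme per pass.

    Repeats until the most extreme remaining point no longer exceeds the
    Grubbs critical value at ``alpha``. Returns ``(kept, removed)``.
    """
    vals = list(np.asarray(values, dtype=float))
    removed: list[float] = []
    while len(vals) >= 3:
        arr = np.asarray(vals)
        mean, sd = arr.mean(), arr.std(ddof=1)
        if sd == 0:
            break
        idx = int(np.argmax(np.abs(arr - mean)))
        g = abs(arr[idx] - mean) / sd
        n = len(arr)
        t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
        if g > g_crit:
            removed.append(vals.pop(idx))
        else:
            break
    return np.asarray(vals), np.asarray(removed)


def compare_groups(
    a,
    b,
    outlier_method: str = "grubbs",
    alpha: float = 0.05,
    rout_q: float = 1.0,
) -> dict:
    """Two-group comparison with the outlier/normality/test routing.

    Outliers are removed per group (Grubbs iterative at ``alpha``, ROUT at
    ``rout_q`` percent, or none); Shapiro–Wilk tests normality of each
    group; if either group rejects at ``alpha`` the two-sided Mann–Whitney
    U test is used (exact when both groups have n <= 20 and no ties, normal
    approximation with tie correction otherwise), else Welch's t-test. The
    routing is deterministic given the inputs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    removed = {}
    if outlier_method == "grubbs":
        a, removed["a"] = grubbs_outliers(a, alpha)
        b, removed["b"] = grubbs_outliers(b, alpha)
    elif outlier_method == "rout":
        a, removed["a"] = remove_outliers_rout(a, Q=rout_q)
        b, removed["b"] = remove_outliers_rout(b, Q=rout_q)
    elif outlier_method == "none":
        removed = {"a": np.array([]), "b": np.array([])}
    else:
        raise ValueError("outlier_method must be 'grubbs', 'rout' or 'none'")
    if a.size < 3 or b.size < 3:
        raise ValueError("fewer than 3 values remain after outlier removal")

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False  # constant sample: not meaningfully normal
        return stats.shapiro(x).pvalue >= alpha

    normal = _normal(a) and _normal(b)
    if normal:
        res = stats.ttest_ind(a, b, equal_var=False)
        test = "welch_t"
    else:
        n_small = a.size <= 20 and b.size <= 20
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (n_small and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann_whitney_u"
    return {
        "test": test,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "removed_a": removed["a"].tolist(),
        "removed_b": removed["b"].tolist(),
        "normality_pass": normal,
    }
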