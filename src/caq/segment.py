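"""Condensate segmentation and dense/dilute partitioning thermodynamics.

Condensates are segmented by Otsu thresholding after Gaussian convolution.
The partition coefficient of each condensate is the ratio of its mean
fluorescence intensity to the mean intensity of the dilute phase (all pixels
outside every condensate), and the apparent transfer free energy follows as

    dG = -R * T * ln(Kp)

with the gas constant in kcal/(mol K) so that dG comes out in kcal/mol.
Kp > 1 (enrichment in the dense phase) therefore corresponds to dG < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops_table
from skimage.morphology import dilation, disk, erosion

__all__ = [
    "R_KCAL_PER_MOL_K",
    "R_AS_PRINTED",
    "SegmentationResult",
    "PartitionRecord",
    "segment_condensates",
    "partition_coefficient",
    "delta_g",
    "remove_outliers_rout",
]

#: Gas constant in kcal mol^-1 K^-1 (1.9872 cal/(mol K) converted to kcal).
R_KCAL_PER_MOL_K = 1.9872e-3
#: The literal constant 1.9872 used without the cal->kcal conversion, kept
#: for reproducing pipelines that plug it in as-is.
R_AS_PRINTED = 1.9872


@dataclass
class SegmentationResult:
    """Integer label image (0 = background) plus a per-region table."""

    labels: np.ndarray
    regions: pd.DataFrame  # region_id, centroid_y, centroid_x, area_px2, mean_intensity, max_intensity


@dataclass
class PartitionRecord:
    region_id: int
    Kp: float
    deltaG_kcal_mol: float
    T_kelvin: float
    R_const: float


def segment_condensates(
    img: np.ndarray,
    gaussian_sigma_px: float = 2.0,
    min_area_px: int = 20,
) -> SegmentationResult:
    """Otsu threshold the Gaussian-smoothed image and label condensates.

    Connected components are 8-connected; components smaller than
    ``min_area_px`` are discarded and labels renumbered consecutively.
    A constant image has no separable threshold and raises ``ValueError``.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if np.ptp(img) == 0:
        raise ValueError("no threshold separable: image is constant")
    smooth = ndi.gaussian_filter(img, gaussian_sigma_px) if gaussian_sigma_px > 0 else img
    mask = smooth > threshold_otsu(smooth)
    labels = label(mask, connectivity=2)
    if labels.max() > 0 and min_area_px > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area_px)
        labels[np.isin(labels, small[small > 0])] = 0
        labels = label(labels > 0, connectivity=2)
    if labels.max() == 0:
        regions = pd.DataFrame(
            columns=["region_id", "centroid_y", "centroid_x", "area_px2",
                     "mean_intensity", "max_intensity"]
        )
        return SegmentationResult(labels, regions)
    props = regionprops_table(
        labels, intensity_image=img,
        properties=("label", "centroid", "area", "intensity_mean", "intensity_max"),
    )
    regions = pd.DataFrame(props).rename(columns={
        "label": "region_id",
        "centroid-0": "centroid_y",
        "centroid-1": "centroid_x",
        "area": "area_px2",
        "intensity_mean": "mean_intensity",
        "intensity_max": "max_intensity",
    })
    return SegmentationResult(labels, regions)


def partition_coefficient(
    img: np.ndarray,
    seg: SegmentationResult,
    T_kelvin: float = 298.15,
    r_const: float = R_KCAL_PER_MOL_K,
    exclude_dilation_px: int = 2,
    erode_px: int = 2,
) -> list[PartitionRecord]:
    """Per-condensate partition coefficient Kp and transfer free energy.

    The dilute mean is computed once over all pixels outside every labelled
    region; a ring of ``exclude_dilation_px`` around each region is excluded
    from it to avoid counting point-spread bleed as dilute phase. For the
    same reason the dense mean of each region is taken over the region
    eroded by ``erode_px`` (falling back to the full region when erosion
    empties it). Both corrections can be disabled with 0. Each region's Kp
    shares the one dilute mean.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.shape != seg.labels.shape:
        raise ValueError("segmentation does not match image geometry")
    fg = seg.labels > 0
    excl = fg
    if exclude_dilation_px > 0:
        excl = dilation(fg, disk(exclude_dilation_px))
    outside = img[~excl]
    if outside.size == 0:
        raise ValueError("no dilute-phase pixels left outside regions")
    dilute_mean = float(outside.mean())
    if dilute_mean <= 0:
        raise ValueError(
            "dilute mean is non-positive; background offset must be handled upstream"
        )
    core = erosion(fg, disk(erode_px)) if erode_px > 0 else fg
    records = []
    for rid in np.unique(seg.labels[fg]):
        region = seg.labels == rid
        dense = region & core
        sel = dense if dense.any() else region
        kp = float(img[sel].mean() / dilute_mean)
        records.append(
            PartitionRecord(
                region_id=int(rid),
                Kp=kp,
                deltaG_kcal_mol=delta_g(kp, T_kelvin, r_const),
                T_kelvin=T_kelvin,
                R_const=r_const,
            )
        )
    return records


def delta_g(
    Kp: float | np.ndarray,
    T_kelvin: float = 298.15,
    r_const: float = R_KCAL_PER_MOL_K,
) -> float | np.ndarray:
    """Apparent transfer free energy ``-R T ln(Kp)`` in kcal/mol.

    Pass ``r_const=R_AS_PRINTED`` to use the bare 1.9872 constant (then the
    result is numerically in cal/mol despite the conventional kcal label).
    """
    Kp = np.asarray(Kp, dtype=float)
    if np.any(Kp <= 0):
        raise ValueError("Kp must be positive")
    if T_kelvin <= 0:
        raise ValueError("temperature must be positive")
    out = -r_const * T_kelvin * np.log(Kp)
    return float(out) if out.ndim == 0 else out


def remove_outliers_rout(
    values, Q: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """ROUT-style outlier removal from a single sample at FDR rate ``Q`` (%).

    Fits the robust constant model (the median), estimates the robust
    standard deviation of the residuals (RSDR) from the 68.27th percentile
    of absolute residuals with a small-sample correction, converts each
    residual to a two-sided t-tail probability, and removes the largest
    residuals selected by a Benjamini–Hochberg step at rate Q. ``Q=0``
    removes nothing.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if Q < 0 or Q > 100:
        raise ValueError("Q is a percentage in [0, 100]")
    keep = np.ones(n, dtype=bool)
    if Q == 0:
        return values[keep], values[~keep]
    resid = np.abs(values - np.median(values))
    df = n - 1
    rsdr = np.percentile(resid, 68.27) * n / df
    if rsdr == 0:
        keep = resid == 0
        return values[keep], values[~keep]
    t = resid / rsdr
    p = 2 * stats.t.sf(t, df)
    order = np.argsort(p)  # most extreme first
    thresh = Q / 100.0 * (np.arange(1, n + 1)) / n
    passing = np.flatnonzero(p[order] <= thresh)
    if passing.size:
        keep[order[: passing.max() + 1]] = False
    return values[keep], values[~keep]
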