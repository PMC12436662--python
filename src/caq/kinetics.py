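"""Enrichment kinetics: drift correction, ROI time series, Gompertz fitting.

Actin enrichment inside a condensate over time follows the Gompertz growth
law

    Y(X) = YM * (Y0/YM) ** exp(-K X)

with initial value ``Y0 = Y(0)``, plateau ``YM = Y(inf)`` and rate constant
``K`` (1/min); ``1/K`` is the characteristic enrichment time in minutes.
Movies are first corrected for rigid x-y drift by cross-correlation
registration to a reference frame, then the mean ROI intensity per frame is
background-subtracted and normalized. The module also provides the scalar
baseline subtraction used for plate-reader (pyrene/turbidity) traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from skimage.registration import phase_cross_correlation

from .synth import gompertz

__all__ = [
    "EnrichmentSeries",
    "GompertzFit",
    "FitError",
    "gompertz",
    "register_translation",
    "roi_timeseries",
    "fit_gompertz",
    "baseline_correct",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass
class EnrichmentSeries:
    times_min: np.ndarray
    values: np.ndarray
    roi_id: int | str = 0
    shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must align")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass
class GompertzFit:
    YM: float
    Y0: float
    K: float
    R2: float
    covariance: np.ndarray = field(repr=False, default=None)

    @property
    def one_over_K(self) -> float:
        return 1.0 / self.K

    def predict(self, t) -> np.ndarray:
        return gompertz(t, self.YM, self.Y0, self.K)


def register_translation(
    movie: np.ndarray, reference: int = 0, upsample: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and correct per-frame rigid x-y translation.

    Each frame's shift relative to frame ``reference`` is found by
    cross-correlation with subpixel refinement; frames are resampled (spline
    interpolation) to alignment. Featureless frames register at zero shift
    with a warning. For enrichment movies whose first frames carry almost no
    signal, pass a late, high-contrast frame (e.g. ``reference=-1``).
    Returns ``(shifts[(T, 2)], corrected_movie)``.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("expected a (T, Y, X) movie with >= 2 frames")
    reference = reference % movie.shape[0]
    ref = movie[reference]
    shifts = np.zeros((movie.shape[0], 2))
    corrected = movie.copy()
    flat_ref = np.ptp(ref) == 0
    for t in range(movie.shape[0]):
        if t == reference:
            continue
        if flat_ref or np.ptp(movie[t]) == 0:
            warnings.warn(f"frame {t} or reference is featureless; zero shift assumed",
                          stacklevel=2)
            continue
        shift, _, _ = phase_cross_correlation(ref, movie[t], upsample_factor=upsample)
        shifts[t] = shift
        corrected[t] = ndi.shift(movie[t], shift, order=1, mode="nearest")
    return shifts, corrected


def roi_timeseries(
    movie: np.ndarray,
    roi_mask: np.ndarray,
    dt_min: float = 1.0,
    times_min: np.ndarray | None = None,
    roi_id: int | str = 0,
    normalize: str = "max",
    shifts: np.ndarray | None = None,
) -> EnrichmentSeries:
    """Mean ROI intensity per frame, background-subtracted and normalized.

    The background is the mean intensity outside the ROI in the first frame;
    it is subtracted from every frame's ROI mean. ``normalize='max'``
    divides by the series maximum (so the plateau of a saturating series is
    about 1); ``'none'`` returns background-subtracted values.
    """
    movie = np.asarray(movie, dtype=np.float64)
    roi_mask = np.asarray(roi_mask) > 0
    if movie.ndim != 3:
        raise ValueError("expected a (T, Y, X) movie")
    if roi_mask.shape != movie.shape[1:]:
        raise ValueError("ROI mask must match frame shape")
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    means = movie[:, roi_mask].mean(axis=1)
    background = movie[0][~roi_mask].mean() if (~roi_mask).any() else 0.0
    values = means - background
    if normalize == "max":
        peak = values.max()
        if peak <= 0:
            raise ValueError("series maximum is non-positive; cannot normalize")
        values = values / peak
    elif normalize != "none":
        raise ValueError("normalize must be 'max' or 'none'")
    if times_min is None:
        times_min = np.arange(movie.shape[0]) * dt_min
    return EnrichmentSeries(times_min, values, roi_id=roi_id, shifts=shifts)


def fit_gompertz(
    series: EnrichmentSeries | tuple[np.ndarray, np.ndarray],
    max_nfev: int = 10000,
) -> GompertzFit:
    """Least-squares fit of the Gompertz law to an enrichment series.

    Initialization: ``YM0 = max(values)``, ``Y00 = max(first value, 1e-3)``,
    ``K0 = 1 / (time to half-plateau)``; all three parameters are bounded
    positive. Reports ``R^2 = 1 - SS_res/SS_tot``.
    """
    if isinstance(series, EnrichmentSeries):
        t, y = series.times_min, series.values
    else:
        t, y = (np.asarray(a, dtype=float) for a in series)
    if t.size < 5:
        raise ValueError("need at least 5 points")
    if np.ptp(y) == 0:
        raise ValueError("values are all equal; nothing to fit")
    ym0 = float(y.max())
    y00 = float(max(y[0], 1e-3))
    if y00 >= ym0:
        y00 = 0.5 * ym0
    half = 0.5 * ym0
    above = np.flatnonzero(y >= half)
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else (t[1] if t.size > 1 else 1.0)
    k0 = 1.0 / max(t_half, 1e-6)
    p0 = (ym0, y00, k0)
    try:
        popt, pcov = curve_fit(
            gompertz, t, y, p0=p0,
            bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
            max_nfev=max_nfev,
        )
    except RuntimeError as err:
        raise FitError(f"Gompertz fit did not converge: {err}", last_params=p0) from err
    resid = y - gompertz(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return GompertzFit(YM=float(popt[0]), Y0=float(popt[1]), K=float(popt[2]),
                       R2=r2, covariance=pcov)


def baseline_correct(values, baseline: float) -> np.ndarray:
    """Subtract a scalar baseline (e.g. buffer-only fluorescence or turbidity)."""
    return np.asarray(values, dtype=float) - baseline
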