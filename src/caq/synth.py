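"""Ground-truthed synthetic microscopy scenes.

Every generator returns a :class:`SynthScene` whose ``truth`` records exactly
what was planted, so each downstream analysis (segmentation, partitioning,
network tracing, Sholl, kinetics, bouton statistics) can be validated without
any external data. Scenes emulate the morphologies the analyses assume:

* bright quasi-circular condensates in a dim dilute phase with a known
  dense/dilute intensity ratio,
* radial filament "asters" attached to condensates,
* two-channel bouton images (vesicle-marker puncta plus an actin channel with
  controllable enrichment),
* axial actin-ring line profiles with a known spatial period,
* enrichment movies following a Gompertz law with optional rigid x-y drift.

Identical ``(params, seed)`` reproduce the identical scene bit-for-bit.
Coordinates are 0-based ``(row, col)`` with row = y increasing downward;
physical units enter only through ``pixel_size_um``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .io import ImageStack, write_image

__all__ = [
    "GroundTruth",
    "SynthScene",
    "CapacityError",
    "make_condensate_field",
    "make_aster_scene",
    "make_ring_profile",
    "make_enrichment_movie",
    "make_bouton_scene",
    "make_density_scene",
    "gompertz",
    "write_scene",
]


class CapacityError(RuntimeError):
    """Raised when requested objects cannot be placed without overlap."""


@dataclass
class GroundTruth:
    """What a generator planted, in the units the analyses measure."""

    condensate_centers: list[tuple[float, float]] = field(default_factory=list)
    condensate_radii: list[float] = field(default_factory=list)
    filament_segments: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )
    dense_intensity: float = 0.0
    dilute_intensity: float = 0.0
    ring_period_um: float | None = None
    gompertz_params: tuple[float, float, float] | None = None
    drift_per_frame: tuple[float, float] | None = None
    enriched_puncta: list[int] = field(default_factory=list)
    cluster_labels: list[bool] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class SynthScene:
    image: ImageStack
    truth: GroundTruth
    seed: int
    params: dict


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius: float,
    margin: float,
    min_gap: float = 2.0,
    max_tries: int = 5000,
    capacity_radius: float | None = None,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping disk centers; capacity-check first.

    ``radius`` sets the exclusion distance between centers; the 30%% frame
    capacity check uses ``capacity_radius`` (the physical object radius)
    when that is smaller, e.g. for asters whose reach exceeds their body.
    """
    h, w = shape
    r_cap = radius if capacity_radius is None else capacity_radius
    if n * np.pi * r_cap**2 > 0.3 * h * w:
        raise CapacityError(
            f"{n} disks of radius {r_cap} exceed 30% of the {h}x{w} frame"
        )
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise CapacityError(
                f"failed to place {n} disks after {max_tries} attempts"
            )
        tries += 1
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= (2 * radius + min_gap) ** 2 for cy, cx in centers):
            centers.append((y, x))
    return centers


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_condensate_field(
    n: int = 10,
    radius_px: float = 10.0,
    kp_true: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    dilute_intensity: float = 100.0,
    psf_sigma_px: float = 1.0,
    pixel_size_um: float = 0.1,
) -> SynthScene:
    """Field of bright non-overlapping condensate disks in a dim dilute phase.

    The dense/dilute intensity ratio before PSF blur and noise is exactly
    ``kp_true``; ``noise_sd`` is additive Gaussian noise expressed as a
    fraction of ``dilute_intensity``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if kp_true <= 0:
        raise ValueError("kp_true must be positive")
    rng = _rng(seed)
    dense = kp_true * dilute_intensity
    img = np.full(shape, dilute_intensity, dtype=np.float64)
    centers = _place_disks(rng, shape, n, radius_px, margin=radius_px + 3 * psf_sigma_px + 2)
    for c in centers:
        img[_disk_mask(shape, c, radius_px)] = dense
    if psf_sigma_px > 0:
        img = ndi.gaussian_filter(img, psf_sigma_px)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd * dilute_intensity, shape)
    truth = GroundTruth(
        condensate_centers=centers,
        condensate_radii=[radius_px] * n,
        dense_intensity=dense,
        dilute_intensity=dilute_intensity,
    )
    params = dict(
        n=n, radius_px=radius_px, kp_true=kp_true, noise_sd=noise_sd,
        shape=shape, dilute_intensity=dilute_intensity,
        psf_sigma_px=psf_sigma_px, pixel_size_um=pixel_size_um,
    )
    return SynthScene(ImageStack(img, pixel_size_um), truth, seed, params)


def _render_segment(
    img: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    amplitude: float,
    width_px: float = 1.0,
) -> None:
    """Add a filament with Gaussian cross-section of sd ``width_px`` in place."""
    y0, x0 = p0
    y1, x1 = p1
    pad = int(np.ceil(3 * width_px)) + 1
    ylo = max(0, int(min(y0, y1)) - pad)
    yhi = min(img.shape[0], int(max(y0, y1)) + pad + 1)
    xlo = max(0, int(min(x0, x1)) - pad)
    xhi = min(img.shape[1], int(max(x0, x1)) + pad + 1)
    if ylo >= yhi or xlo >= xhi:
        return
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    dy, dx = y1 - y0, x1 - x0
    seg_len2 = dy * dy + dx * dx
    if seg_len2 == 0:
        d2 = (yy - y0) ** 2 + (xx - x0) ** 2
    else:
        t = ((yy - y0) * dy + (xx - x0) * dx) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        d2 = (yy - (y0 + t * dy)) ** 2 + (xx - (x0 + t * dx)) ** 2
    img[ylo:yhi, xlo:xhi] += amplitude * np.exp(-d2 / (2 * width_px**2))


def make_aster_scene(
    n_condensates: int = 3,
    filaments_per: int = 6,
    filament_len_px: float = 40.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    condensate_radius_px: float = 8.0,
    bridging: bool = False,
    noise_sd: float = 0.0,
    dilute_intensity: float = 20.0,
    filament_amplitude: float = 200.0,
    pixel_size_um: float = 0.1,
) -> SynthScene:
    """Condensates carrying straight bright filaments radiating from their centers.

    Ray angles are jittered around an even angular spacing so that, for
    ``filaments_per`` rays, every circle between the condensate rim and the
    filament reach is crossed exactly ``filaments_per`` times. With
    ``bridging`` an extra filament connects the first two condensate centers.
    """
    if filaments_per < 0:
        raise ValueError("filaments_per must be >= 0")
    rng = _rng(seed)
    reach = condensate_radius_px + filament_len_px
    img = np.full(shape, dilute_intensity, dtype=np.float64)
    centers = _place_disks(
        rng, shape, n_condensates, reach, margin=reach + 2, min_gap=4.0,
        capacity_radius=condensate_radius_px,
    )
    segments: list[tuple[tuple[float, float], tuple[float, float]]] = []
    dense = 8.0 * dilute_intensity
    for cy, cx in centers:
        img[_disk_mask(shape, (cy, cx), condensate_radius_px)] = dense
        if filaments_per == 0:
            continue
        spacing = 2 * np.pi / filaments_per
        base = rng.uniform(0, 2 * np.pi)
        angles = base + np.arange(filaments_per) * spacing
        angles = angles + rng.uniform(-0.2 * spacing, 0.2 * spacing, filaments_per)
        for a in angles:
            p0 = (cy, cx)
            p1 = (cy + reach * np.sin(a), cx + reach * np.cos(a))
            segments.append((p0, (float(p1[0]), float(p1[1]))))
            _render_segment(img, p0, p1, filament_amplitude)
    if bridging:
        if n_condensates < 2:
            raise ValueError("bridging requires at least two condensates")
        p0, p1 = centers[0], centers[1]
        segments.append((p0, p1))
        _render_segment(img, p0, p1, filament_amplitude)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd * dilute_intensity, shape)
    truth = GroundTruth(
        condensate_centers=centers,
        condensate_radii=[condensate_radius_px] * n_condensates,
        filament_segments=segments,
        dense_intensity=dense,
        dilute_intensity=dilute_intensity,
    )
    params = dict(
        n_condensates=n_condensates, filaments_per=filaments_per,
        filament_len_px=filament_len_px, shape=shape,
        condensate_radius_px=condensate_radius_px, bridging=bridging,
        noise_sd=noise_sd, pixel_size_um=pixel_size_um,
    )
    return SynthScene(ImageStack(img, pixel_size_um), truth, seed, params)


def make_ring_profile(
    period_um: float = 0.19,
    pixel_um: float = 0.02,
    length_um: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 1.0,
    amplitude: float = 0.5,
) -> tuple[np.ndarray, GroundTruth]:
    """Sinusoid-plus-baseline line profile emulating periodic axonal actin rings.

    Returns the 1D intensity profile (one sample per ``pixel_um``) and the
    truth holding the planted period. Periods at or below twice the pixel
    size violate the Nyquist limit and are rejected.
    """
    if period_um <= 2 * pixel_um:
        raise ValueError(
            f"period {period_um} um is not resolvable at pixel size {pixel_um} um"
        )
    n = int(round(length_um / pixel_um))
    x = np.arange(n) * pixel_um
    profile = baseline + amplitude * np.cos(2 * np.pi * x / period_um)
    if noise_sd > 0:
        profile = profile + _rng(seed).normal(0.0, noise_sd, n)
    truth = GroundTruth(ring_period_um=period_um, dilute_intensity=baseline,
                        dense_intensity=baseline + amplitude)
    return profile, truth


def gompertz(t: np.ndarray | float, YM: float, Y0: float, K: float):
    """Gompertz growth law ``Y(t) = YM * (Y0/YM) ** exp(-K t)``.

    ``Y(0) = Y0`` and ``Y(inf) = YM``; ``K`` is the rate constant in 1/min.
    """
    return YM * (Y0 / YM) ** np.exp(-K * np.asarray(t, dtype=float))


def make_enrichment_movie(
    gompertz_params: tuple[float, float, float] = (0.9611, 0.01032, 0.2958),
    n_frames: int = 36,
    dt_min: float = 1.0,
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    radius_px: float = 10.0,
    background: float = 0.005,
    pixel_size_um: float = 0.1,
) -> SynthScene:
    """Movie of one condensate whose mean intensity follows a Gompertz law.

    The whole frame translates rigidly by ``drift_px_per_frame`` each step;
    drift that would carry the condensate out of frame raises an error.
    """
    YM, Y0, K = gompertz_params
    if not (0 < Y0 < YM):
        raise ValueError("require 0 < Y0 < YM")
    if n_frames < 3:
        raise ValueError("n_frames must be >= 3")
    rng = _rng(seed)
    dy, dx = drift_px_per_frame
    cy0, cx0 = shape[0] / 2.0, shape[1] / 2.0
    t = np.arange(n_frames) * dt_min
    values = gompertz(t, YM, Y0, K)
    frames = np.empty((n_frames,) + shape, dtype=np.float64)
    for i in range(n_frames):
        cy = cy0 + i * dy
        cx = cx0 + i * dx
        if not (radius_px <= cy <= shape[0] - radius_px and radius_px <= cx <= shape[1] - radius_px):
            raise ValueError(f"drift carries the condensate out of frame at frame {i}")
        frame = np.full(shape, background)
        frame[_disk_mask(shape, (cy, cx), radius_px)] = values[i]
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, shape)
        frames[i] = frame
    truth = GroundTruth(
        condensate_centers=[(cy0, cx0)],
        condensate_radii=[radius_px],
        dense_intensity=float(YM),
        dilute_intensity=background,
        gompertz_params=(YM, Y0, K),
        drift_per_frame=(dy, dx),
    )
    params = dict(
        gompertz_params=gompertz_params, n_frames=n_frames, dt_min=dt_min,
        drift_px_per_frame=drift_px_per_frame, noise_sd=noise_sd, shape=shape,
        radius_px=radius_px, background=background, pixel_size_um=pixel_size_um,
    )
    stack = ImageStack(frames[:, None, None, :, :], pixel_size_um, axes="TCZYX")
    return SynthScene(stack, truth, seed, params)


def make_bouton_scene(
    n_puncta: int = 20,
    enriched_fraction: float = 0.5,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    punctum_radius_px: float = 5.0,
    marker_intensity: float = 200.0,
    actin_background: float = 20.0,
    actin_enriched: float = 180.0,
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.02,
) -> SynthScene:
    """Two-channel scene: vesicle-marker puncta plus an actin channel.

    Channel 0 carries the marker puncta; channel 1 carries actin, elevated
    inside a known subset of the puncta (``truth.enriched_puncta``).
    """
    if not 0 <= enriched_fraction <= 1:
        raise ValueError("enriched_fraction must be in [0, 1]")
    rng = _rng(seed)
    dilute = 10.0
    marker = np.full(shape, dilute)
    actin = np.full(shape, actin_background, dtype=np.float64)
    centers = _place_disks(rng, shape, n_puncta, punctum_radius_px,
                           margin=punctum_radius_px + 4, min_gap=6.0)
    n_enriched = int(round(enriched_fraction * n_puncta))
    enriched = sorted(rng.choice(n_puncta, size=n_enriched, replace=False).tolist()) if n_puncta else []
    for i, c in enumerate(centers):
        m = _disk_mask(shape, c, punctum_radius_px)
        marker[m] = marker_intensity
        if i in enriched:
            actin[m] = actin_enriched
    marker = ndi.gaussian_filter(marker, 1.0)
    actin = ndi.gaussian_filter(actin, 1.0)
    if noise_sd > 0:
        marker = marker + rng.normal(0.0, noise_sd * dilute, shape)
        actin = actin + rng.normal(0.0, noise_sd * actin_background, shape)
    truth = GroundTruth(
        condensate_centers=centers,
        condensate_radii=[punctum_radius_px] * n_puncta,
        dense_intensity=marker_intensity,
        dilute_intensity=dilute,
        enriched_puncta=enriched,
    )
    params = dict(
        n_puncta=n_puncta, enriched_fraction=enriched_fraction, shape=shape,
        punctum_radius_px=punctum_radius_px, noise_sd=noise_sd,
        pixel_size_um=pixel_size_um,
    )
    stack = ImageStack(np.stack([marker, actin]), pixel_size_um, axes="CYX")
    return SynthScene(stack, truth, seed, params)


def make_density_scene(
    n_pass: int = 3,
    n_fail_intensity: int = 1,
    n_fail_area: int = 1,
    theta_intensity: float = 4000.0,
    theta_area_px: int = 10,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    background: float = 500.0,
    pixel_size_um: float = 0.05,
) -> SynthScene:
    """Clusters planted above/below intensity and area thresholds.

    ``truth.cluster_labels[i]`` is True when cluster ``i`` passes both the
    intensity and the area criterion, so the expected object count for a
    density analysis at (``theta_intensity``, ``theta_area_px``) equals
    ``sum(truth.cluster_labels)``.
    """
    rng = _rng(seed)
    img = np.full(shape, background, dtype=np.float64)
    n_total = n_pass + n_fail_intensity + n_fail_area
    pass_radius = max(3.0, np.sqrt((theta_area_px + 6) / np.pi))
    fail_radius = max(1.0, np.sqrt(max(theta_area_px - 7, 1) / np.pi))
    centers = _place_disks(rng, shape, n_total, pass_radius + 2,
                           margin=pass_radius + 4, min_gap=8.0)
    labels: list[bool] = []
    for i, c in enumerate(centers):
        if i < n_pass:
            intensity, radius, ok = 1.5 * theta_intensity, pass_radius, True
        elif i < n_pass + n_fail_intensity:
            intensity, radius, ok = 0.7 * theta_intensity, pass_radius, False
        else:
            intensity, radius, ok = 1.5 * theta_intensity, fail_radius, False
        img[_disk_mask(shape, c, radius)] = intensity
        labels.append(ok)
    truth = GroundTruth(
        condensate_centers=centers,
        dense_intensity=1.5 * theta_intensity,
        dilute_intensity=background,
        cluster_labels=labels,
    )
    params = dict(
        n_pass=n_pass, n_fail_intensity=n_fail_intensity, n_fail_area=n_fail_area,
        theta_intensity=theta_intensity, theta_area_px=theta_area_px, shape=shape,
        pixel_size_um=pixel_size_um,
    )
    return SynthScene(ImageStack(img, pixel_size_um), truth, seed, params)


def write_scene(stem: str | Path, scene: SynthScene) -> tuple[Path, Path]:
    """Write a scene as ``<stem>.tif`` plus a side-car ``<stem>.truth.json``."""
    stem = Path(stem)
    tiff = stem.with_suffix(".tif")
    meta = stem.with_suffix(".truth.json")
    write_image(tiff, scene.image)
    payload = {
        "seed": scene.seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in scene.params.items()},
        "truth": dataclasses.asdict(scene.truth),
    }
    meta.write_text(json.dumps(payload, indent=2, default=float))
    return tiff, meta
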