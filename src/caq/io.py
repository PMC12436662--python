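"""Shared image container, TIFF I/O, run configuration and pipeline driver.

All analysis modules operate on :class:`ImageStack`, an n-dimensional
grayscale array normalized to ``(T, C, Z, Y, X)`` axis order with a physical
pixel size in micrometers. TIFF reading/writing goes through :mod:`tifffile`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "RunConfig",
    "read_image",
    "write_image",
    "run_pipeline",
    "PIPELINE_STAGES",
]


@dataclass
class ImageStack:
    """Grayscale image stack with axes ``(T, C, Z, Y, X)`` and pixel size.

    Parameters
    ----------
    data:
        Array of up to five dimensions. Missing leading axes are inserted as
        singletons according to ``axes`` (default interprets a 2D array as
        ``YX``, 3D as ``ZYX``, 4D as ``CZYX``, 5D as ``TCZYX``).
    pixel_size_um:
        Lateral pixel size in micrometers.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    axes: str = ""

    _DEFAULT_AXES = {2: "YX", 3: "ZYX", 4: "CZYX", 5: "TCZYX"}

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim < 2 or arr.ndim > 5:
            raise ValueError(f"expected 2-5 dimensional data, got {arr.ndim}D")
        axes = self.axes or self._DEFAULT_AXES[arr.ndim]
        if len(axes) != arr.ndim or any(a not in "TCZYX" for a in axes):
            raise ValueError(f"invalid axes {axes!r} for {arr.ndim}D data")
        out = arr
        order = "TCZYX"
        for i, a in enumerate(order):
            if a not in axes:
                out = np.expand_dims(out, i)
                axes = axes[:i] + a + axes[i:]
        # reorder in case axes were permuted
        perm = [axes.index(a) for a in order]
        self.data = np.transpose(out, perm)
        self.axes = order
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def plane(self, t: int = 0, c: int = 0, z: int = 0) -> np.ndarray:
        """Return a single 2D (Y, X) plane."""
        return self.data[t, c, z]

    def frames(self, c: int = 0, z: int = 0) -> np.ndarray:
        """Return the (T, Y, X) time series for one channel/slice."""
        return self.data[:, c, z]


def read_image(path: str | Path, pixel_size_um: float | None = None) -> ImageStack:
    """Read a (multi-page) grayscale TIFF into an :class:`ImageStack`.

    Pixel size is taken from ``pixel_size_um`` when given; otherwise from the
    TIFF resolution tags when present (a conflict between the two is logged
    and the explicit argument wins); otherwise it defaults to 1 µm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        axes = tif.series[0].axes if tif.series else ""
        tag_px = _pixel_size_from_tags(tif)
    if arr.ndim >= 2 and arr.shape[-1] in (3, 4) and axes.endswith("S"):
        raise ValueError("RGB(A) TIFF not supported: grayscale channels expected")
    axes = "".join(a for a in axes if a in "TCZYX")
    if len(axes) != arr.ndim:
        axes = ""  # fall back to positional default
    px = pixel_size_um
    if px is None:
        px = tag_px if tag_px else 1.0
    elif tag_px and not np.isclose(px, tag_px, rtol=1e-3):
        warnings.warn(
            f"pixel size {px} um overrides TIFF resolution tag {tag_px:.4g} um",
            stacklevel=2,
        )
    return ImageStack(arr, pixel_size_um=px, axes=axes)


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if num == 0:
        return None
    px_per_unit = num / den
    unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", None) and unit.value or 0)
    if unit_um is None:
        return None
    return unit_um / px_per_unit


def write_image(path: str | Path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF.

    Singleton axes are squeezed so movies come out as TCYX pages and
    multichannel stills as CYX, with the pixel size stored in the
    resolution tags (pixels per centimeter).
    """
    path = Path(path)
    arr = stack.data
    axes = stack.axes
    for a in "TCZ":
        i = axes.index(a)
        if arr.shape[i] == 1:
            arr = np.squeeze(arr, axis=i)
            axes = axes.replace(a, "")
    res = 1.0 / (stack.pixel_size_um * 1e-4)  # px per cm
    tifffile.imwrite(
        path,
        arr,
        metadata={"axes": axes},
        resolution=(res, res),
        resolutionunit="CENTIMETER",
    )


# ---------------------------------------------------------------------------
# Run configuration and pipeline driver
# ---------------------------------------------------------------------------

PIPELINE_STAGES = ("synth", "segment", "partition", "network", "sholl")


@dataclass
class RunConfig:
    """Configuration of a reproducible analysis run.

    Unset fields resolve to the documented defaults below, never to silent
    zeros. ``config_hash`` is embedded in every output written by
    :func:`run_pipeline` so results can be traced back to their settings.
    """

    pixel_size_um: float = 0.1
    temperature_K: float = 298.15
    gaussian_sigma_px: float = 2.0
    min_area_px: int = 20
    min_segment_px: int = 3
    theta_intensity: float = 4000.0
    theta_area_px: int = 10
    sholl_step_um: float = 0.5
    seed: int = 0
    out_dir: str = "caq_out"
    synth_scene: str = "aster"
    synth_params: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, stages: list[str], force: bool = False) -> dict:
    """Execute pipeline stages in order, writing per-stage CSV/JSON outputs.

    Stage dependencies are validated before anything runs: ``partition``
    requires ``segment``, and ``sholl`` requires ``network`` and ``segment``.
    Identical config and inputs produce identical outputs. Existing outputs
    are not overwritten unless ``force`` is set.
    """
    import pandas as pd

    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise ValueError(
            f"unknown stage(s) {unknown}; valid stages: {list(PIPELINE_STAGES)}"
        )
    deps = {"partition": {"segment"}, "sholl": {"network", "segment"}, "segment": {"synth"}, "network": {"synth"}}
    seen: set[str] = set()
    for s in stages:
        missing = deps.get(s, set()) - seen
        if missing:
            raise ValueError(f"stage {s!r} requires {sorted(missing)} to run first")
        seen.add(s)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "stages": {}}
    ctx: dict = {}

    from . import network as net
    from . import segment as seg
    from . import sholl as sh
    from . import synth

    for s in stages:
        if s == "synth":
            maker = {
                "condensates": synth.make_condensate_field,
                "aster": synth.make_aster_scene,
            }[config.synth_scene]
            scene = maker(seed=config.seed, pixel_size_um=config.pixel_size_um, **config.synth_params)
            ctx["scene"] = scene
            tiff_path = out / "scene.tif"
            if tiff_path.exists() and not force:
                raise FileExistsError(f"{tiff_path} exists; pass force=True to overwrite")
            synth.write_scene(out / "scene", scene)
            report["stages"][s] = {"image": str(tiff_path)}
        elif s == "segment":
            img = ctx["scene"].image.plane()
            ctx["seg"] = seg.segment_condensates(
                img, gaussian_sigma_px=config.gaussian_sigma_px, min_area_px=config.min_area_px
            )
            _write_df(out / "regions.csv", ctx["seg"].regions, config, force)
            report["stages"][s] = {"n_regions": int(len(ctx["seg"].regions))}
        elif s == "partition":
            img = ctx["scene"].image.plane()
            records = seg.partition_coefficient(img, ctx["seg"], T_kelvin=config.temperature_K)
            df = pd.DataFrame([dataclasses.asdict(r) for r in records])
            _write_df(out / "partition.csv", df, config, force)
            report["stages"][s] = {"n_records": int(len(records))}
        elif s == "network":
            img = ctx["scene"].image.plane()
            graph = net.trace_network(
                img, pixel_size_um=config.pixel_size_um, min_segment_px=config.min_segment_px
            )
            ctx["graph"] = graph
            _write_df(out / "edges.csv", graph.edge_table(), config, force)
            report["stages"][s] = {"n_edges": int(len(graph.edges))}
        elif s == "sholl":
            graph = ctx["graph"]
            rows = []
            for i, (cy, cx) in enumerate(ctx["scene"].truth.condensate_centers):
                prof = sh.sholl_profile(
                    graph, (cy, cx), step_um=config.sholl_step_um, condensate_id=i
                )
                rows.append(prof.to_frame())
            df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
            _write_df(out / "sholl.csv", df, config, force)
            report["stages"][s] = {"n_profiles": len(rows)}

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _write_df(path: Path, df, config: RunConfig, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    df = df.copy()
    df["config_hash"] = config.config_hash()
    df.to_csv(path, index=False)
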