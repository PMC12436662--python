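"""Sholl intersection profiling of traced actin networks.

Intersections of filament traces with concentric circles (0.5 µm radius
increments by default) around condensate centers are counted, and profiles
from different experimental conditions are compared with a linear mixed
effects model (random intercept per condensate) or, for small samples or
singular fits, a label-permutation test on the area under the profile.

Shells are half-open: a trace point exactly at radius r lies on the outer
side, so a crossing is a consecutive point pair with one point strictly
inside r and the next at or beyond it (or vice versa). A tortuous filament
crossing the same circle several times contributes each crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import SkeletonGraph

__all__ = ["ShollProfile", "sholl_profile", "sholl_crossings", "compare_sholl_lmm"]


@dataclass
class ShollProfile:
    center: tuple[float, float]
    radii_um: np.ndarray
    counts: np.ndarray
    condensate_id: int | str = 0
    condition: str = ""

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.radii_um) != len(self.counts):
            raise ValueError("radii and counts must align")

    def auc(self) -> float:
        """Area under the intersection profile (counts integrated over radius)."""
        if len(self.radii_um) < 2:
            return float(self.counts.sum())
        return float(np.trapezoid(self.counts, self.radii_um))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condensate_id": self.condensate_id,
                "condition": self.condition,
                "radius_um": self.radii_um,
                "intersections": self.counts,
            }
        )


def sholl_crossings(path_px: np.ndarray, center: tuple[float, float],
                    radius_px: float) -> int:
    """Number of times one pixel path crosses the circle of ``radius_px``.

    Crossing rule: consecutive path points straddle the circle, with points
    exactly on it counted as outside (half-open shells).
    """
    d = np.hypot(path_px[:, 0] - center[0], path_px[:, 1] - center[1])
    inside = d < radius_px
    return int(np.count_nonzero(inside[:-1] != inside[1:]))


def sholl_profile(
    graph: SkeletonGraph,
    center: tuple[float, float],
    step_um: float = 0.5,
    r_max_um: float | None = None,
    condensate_id: int | str = 0,
    condition: str = "",
    image_shape: tuple[int, int] | None = None,
) -> ShollProfile:
    """Count circle crossings of every traced edge at each shell radius.

    ``r_max_um`` defaults to the distance from the center to the farthest
    traced pixel (so the profile always ends in a zero shell); an empty
    graph yields an all-zero profile of one shell.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    if image_shape is not None:
        if not (0 <= center[0] < image_shape[0] and 0 <= center[1] < image_shape[1]):
            raise ValueError("center lies outside image bounds")
    px = graph.pixel_size_um
    if r_max_um is None:
        far = 0.0
        for path in graph.paths.values():
            d = np.hypot(path[:, 0] - center[0], path[:, 1] - center[1])
            far = max(far, float(d.max()) if d.size else 0.0)
        r_max_um = far * px + step_um
    radii = np.arange(step_um, r_max_um + 1e-9, step_um)
    if radii.size == 0:
        radii = np.array([step_um])
    counts = np.zeros(radii.size, dtype=int)
    for path in graph.paths.values():
        d = np.hypot(path[:, 0] - center[0], path[:, 1] - center[1]) * px
        inside = d[:, None] < radii[None, :]
        counts += np.count_nonzero(inside[:-1] != inside[1:], axis=0)
    return ShollProfile(center, radii, counts, condensate_id, condition)


def _long_frame(profiles: list[ShollProfile]) -> pd.DataFrame:
    frames = []
    for i, p in enumerate(profiles):
        df = p.to_frame()
        df["profile_id"] = f"{p.condition}:{p.condensate_id}:{i}"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def compare_sholl_lmm(
    profiles: list[ShollProfile],
    n_permutations: int = 1999,
    seed: int = 0,
    force_permutation: bool = False,
) -> dict:
    """Between-condition comparison of Sholl profiles.

    Fits ``intersections ~ condition * radius`` with a random intercept per
    condensate profile and reports the condition main effect. When the mixed
    model cannot be fit (singular covariance, tiny samples) the function
    falls back to a permutation test that shuffles condition labels across
    whole profiles and uses the difference in mean area-under-profile as the
    statistic (two conditions) or the between-condition variance of mean
    AUC (more).
    """
    conditions = sorted({p.condition for p in profiles})
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    for c in conditions:
        if sum(p.condition == c for p in profiles) < 3:
            raise ValueError(f"need >=3 profiles per condition (condition {c!r})")

    result: dict = {"conditions": conditions, "n_profiles": len(profiles)}
    if not force_permutation:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                import statsmodels.formula.api as smf

                df = _long_frame(profiles)
                model = smf.mixedlm(
                    "intersections ~ C(condition) * radius_um",
                    df,
                    groups=df["profile_id"],
                )
                fit = model.fit(reml=True, method="lbfgs")
            if not np.all(np.isfinite(fit.bse[:1])):
                raise np.linalg.LinAlgError("singular fixed-effect covariance")
            cond_terms = [t for t in fit.params.index if t.startswith("C(condition)")
                          and "radius" not in t]
            result.update(
                method="lmm",
                params=fit.params.to_dict(),
                pvalues=fit.pvalues.to_dict(),
                condition_effect={t: float(fit.params[t]) for t in cond_terms},
                condition_p=float(min(fit.pvalues[t] for t in cond_terms)),
                converged=bool(fit.converged),
            )
            return result
        except Exception as err:  # noqa: BLE001 - any fit failure routes to permutation
            warnings.warn(f"mixed model failed ({err}); using permutation test",
                          stacklevel=2)

    rng = np.random.default_rng(seed)
    aucs = np.array([p.auc() for p in profiles])
    labels = np.array([p.condition for p in profiles])

    def stat(lab: np.ndarray) -> float:
        means = [aucs[lab == c].mean() for c in conditions]
        if len(conditions) == 2:
            return abs(means[0] - means[1])
        return float(np.var(means))

    observed = stat(labels)
    perm = labels.copy()
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if stat(perm) >= observed:
            hits += 1
    result.update(
        method="permutation",
        statistic=float(observed),
        condition_effect={c: float(aucs[labels == c].mean()) for c in conditions},
        condition_p=float((hits + 1) / (n_permutations + 1)),
        n_permutations=n_permutations,
    )
    return result
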