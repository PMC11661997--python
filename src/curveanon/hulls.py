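"""Released hulls and the privacy/utility report.

The representative released for an equivalence class is its hull: the
pointwise lower/upper envelope of all non-dropped members, sampled on a
fixed-resolution time grid. The hull is additive — merging two classes
is a pointwise min/max — which is what makes the bottom-up merging of
classes along the ECS parenthood relation cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .curve_io import Curve
from .errors import CurveValidationError
from .metrics import emd

_EPS = 1e-9


@dataclass
class Hull:
    """Per-time-grid lower/upper envelope of an equivalence class."""

    resolution: float
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower > self.upper + _EPS):
            raise CurveValidationError("hull lower bound exceeds upper bound")


def hull_grid(interval: tuple[float, float], resolution: float) -> np.ndarray:
    """Time grid ``start + i * resolution``, last point clamped to the end."""
    t0, t1 = interval
    if resolution <= 0:
        raise ValueError("hull resolution must be positive")
    n = int(np.floor((t1 - t0 + _EPS) / resolution))
    grid = t0 + resolution * np.arange(n + 1)
    if grid[-1] < t1 - _EPS:
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1
    return grid


def build_hull(
    members: Sequence[Curve],
    resolution: float,
    interval: Optional[tuple[float, float]] = None,
    interpolation: str = "linear",
) -> Hull:
    """Pointwise envelope of the members on the resolution grid.

    The grid resolution need not match the member sampling; member
    values at grid times are interpolated (linearly for interpolable
    datasets, else by the previous/nearest sample).
    """
    members = list(members)
    if not members:
        raise CurveValidationError("cannot build a hull over an empty member list")
    if interval is None:
        interval = members[0].span
    grid = hull_grid(interval, resolution)
    values = np.stack([m.interp(grid, mode=interpolation) for m in members])
    return Hull(resolution, grid, values.min(axis=0), values.max(axis=0))


def merge_hulls(a: Hull, b: Hull) -> Hull:
    """Merge two class hulls: pointwise (min lower, max upper)."""
    if a.grid.size != b.grid.size or not np.allclose(a.grid, b.grid, atol=_EPS):
        raise CurveValidationError("cannot merge hulls on different grids")
    return Hull(
        a.resolution,
        a.grid.copy(),
        np.minimum(a.lower, b.lower),
        np.maximum(a.upper, b.upper),
    )


def exact_t(
    class_histograms: Sequence[np.ndarray],
    population_histogram: np.ndarray,
    ground: np.ndarray,
) -> tuple[list[float], float]:
    """Exact achieved t: per class, the EMD between the class's cluster
    histogram and the population's, under the (already normalized)
    reference ground distance. The overall t is the maximum. With a
    single-cluster population every class is trivially 0-close."""
    pop = np.asarray(population_histogram, dtype=float)
    if pop.size == 1:
        per = [0.0 for _ in class_histograms]
        return per, 0.0
    per = [emd(h, pop, ground) for h in class_histograms]
    return per, max(per, default=0.0)


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------

@dataclass
class ClassReport:
    """Per-equivalence-class privacy/utility figures."""

    class_id: str
    member_ids: list[str]
    dropped_ids: list[str]
    glm: float
    mre: float
    t_exact: float
    t_bound: float
    hull: Hull

    @property
    def live_ids(self) -> list[str]:
        return [m for m in self.member_ids if m not in set(self.dropped_ids)]

    def to_dict(self) -> dict:
        return {
            "class_id": self.class_id,
            "member_ids": list(self.member_ids),
            "dropped_ids": list(self.dropped_ids),
            "glm": self.glm,
            "mre": self.mre,
            "t_exact": self.t_exact,
            "t_bound": self.t_bound,
        }


@dataclass
class SegmentReport:
    """Result of anonymizing one time segment independently."""

    index: int
    interval: tuple[float, float]
    classes: list[ClassReport]
    unanonymized_ids: list[str]

    @property
    def duration(self) -> float:
        return self.interval[1] - self.interval[0]

    @property
    def mean_glm(self) -> float:
        return float(np.mean([c.glm for c in self.classes])) if self.classes else 0.0

    @property
    def dropped_ids(self) -> list[str]:
        out: list[str] = []
        for c in self.classes:
            out.extend(c.dropped_ids)
        return sorted(set(out))

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "interval": list(self.interval),
            "classes": [c.to_dict() for c in self.classes],
            "dropped_ids": self.dropped_ids,
            "unanonymized_ids": list(self.unanonymized_ids),
            "mean_glm": self.mean_glm,
        }


@dataclass
class AnonymizationResult:
    """Aggregated privacy/utility report over all segments."""

    segments: list[SegmentReport]
    aggregate_glm: float
    aggregate_glm_cleaned: Optional[float]
    cleaned_omitted_fraction: float
    median_mre: float
    t_exact: float
    t_bound: float
    params: dict = field(default_factory=dict)

    @property
    def classes(self) -> list[ClassReport]:
        return [c for s in self.segments for c in s.classes]

    def to_dict(self) -> dict:
        return {
            "segments": [s.to_dict() for s in self.segments],
            "aggregate_glm": self.aggregate_glm,
            "aggregate_glm_cleaned": self.aggregate_glm_cleaned,
            "cleaned_omitted_fraction": self.cleaned_omitted_fraction,
            "median_mre": self.median_mre,
            "t_exact": self.t_exact,
            "t_bound": self.t_bound,
            "params": self.params,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def evaluation_report(
    segments: Sequence[SegmentReport],
    hull_resolution: float,
    params: Optional[dict] = None,
) -> AnonymizationResult:
    """Aggregate per-segment results into one report.

    The aggregate information loss weights each segment's mean GLM by its
    temporal share of the whole dataset, so short segments do not drown
    out long ones. A "cleaned" variant omits segments shorter than the
    hull resolution (their GLM is an artefact of under-resolution); the
    cleaned figure is suppressed when the omitted segments would make up
    more than 25 % of the curves' duration. The dataset MRE is the median
    over the per-class MREs.
    """
    segments = list(segments)
    if not segments:
        raise CurveValidationError("evaluation_report needs at least one segment")
    durations = np.array([s.duration for s in segments])
    total = durations.sum()
    glms = np.array([s.mean_glm for s in segments])
    aggregate = float(np.dot(durations, glms) / total)

    keep = durations >= hull_resolution - _EPS
    omitted_fraction = float(durations[~keep].sum() / total)
    cleaned: Optional[float] = None
    if omitted_fraction == 0.0:
        cleaned = aggregate
    elif omitted_fraction <= 0.25 and keep.any():
        cleaned = float(np.dot(durations[keep], glms[keep]) / durations[keep].sum())

    all_classes = [c for s in segments for c in s.classes]
    median_mre = float(np.median([c.mre for c in all_classes])) if all_classes else 0.0
    t_ex = max((c.t_exact for c in all_classes), default=0.0)
    t_bd = max((c.t_bound for c in all_classes), default=0.0)
    return AnonymizationResult(
        segments=segments,
        aggregate_glm=aggregate,
        aggregate_glm_cleaned=cleaned,
        cleaned_omitted_fraction=omitted_fraction,
        median_mre=median_mre,
        t_exact=t_ex,
        t_bound=t_bd,
        params=dict(params or {}),
    )
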