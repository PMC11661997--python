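"""Splitting a dataset along the time axis into segments.

Segmentation turns the global assignment decision into a semi-local one:
within each segment the whole-curve (global) decision is made, but a
curve may land in different equivalence classes in different segments.
Three modes are supported: fixed-length, manual boundary lists, and
Windowed-Fréchet, which places boundaries at sliding windows where the
curves are most similar so segments reach from one region of similarity
to the next.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curve_io import Curve, CurveSet
from .errors import SplitError
from .metrics import frechet_distance

_EPS = 1e-9


@dataclass
class SplitConfig:
    """Parameters of one of the splitting modes.

    mode:
        ``"none"`` (single segment), ``"fixed"``, ``"manual"`` or
        ``"windowed"`` (Windowed-Fréchet).
    """

    mode: str = "none"
    segment_length: float = 0.0
    remainder_threshold: float = 0.0
    boundaries: list[tuple[float, float]] = field(default_factory=list)
    window: float = 0.0
    step: float = 0.0
    n_segments: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("none", "fixed", "manual", "windowed"):
            raise SplitError(f"unknown split mode {self.mode!r}")
        if self.mode == "windowed":
            if self.window <= 0 or self.step <= 0:
                raise SplitError("windowed split needs window > 0 and step > 0")
            if self.step > self.window + _EPS:
                raise SplitError("windowed split requires step <= window")
            if self.n_segments < 1:
                raise SplitError("n_segments must be >= 1")
        if self.mode == "fixed" and self.segment_length <= 0:
            raise SplitError("fixed split needs segment_length > 0")


@dataclass
class Segment:
    """One time interval of a split, with the curves restricted to it."""

    index: int
    interval: tuple[float, float]
    curves: CurveSet

    @property
    def duration(self) -> float:
        return self.interval[1] - self.interval[0]


def restrict_curve(curve: Curve, t0: float, t1: float) -> Curve:
    """Restrict a curve to ``[t0, t1]`` with interpolated boundary samples.

    Interior samples are kept; the exact endpoints are added by linear
    interpolation when no sample falls on them, so every restriction has
    at least 2 points.
    """
    inside = (curve.t > t0 + _EPS) & (curve.t < t1 - _EPS)
    t = curve.t[inside]
    v = curve.v[inside]
    t = np.concatenate(([t0], t, [t1]))
    v = np.concatenate(([curve.interp([t0])[0]], v, [curve.interp([t1])[0]]))
    return Curve(
        curve.curve_id, curve.subject_uuid, curve.start,
        curve.quantity_name, curve.unit, t, v,
    )


def restrict_curveset(cs: CurveSet, t0: float, t1: float) -> CurveSet:
    restricted = [restrict_curve(c, t0, t1) for c in cs]
    v_min = min(c.v.min() for c in restricted)
    v_max = max(c.v.max() for c in restricted)
    return CurveSet(restricted, (t0, t1), (float(v_min), float(v_max)))


def _segments_from_boundaries(
    cs: CurveSet, edges: list[tuple[float, float]]
) -> list[Segment]:
    return [
        Segment(i, (a, b), restrict_curveset(cs, a, b))
        for i, (a, b) in enumerate(edges)
    ]


def split_fixed(
    cs: CurveSet, segment_length: float, remainder_threshold: float = 0.0
) -> list[Segment]:
    """Equally long consecutive segments from the frame start.

    A final remainder shorter than ``remainder_threshold`` is absorbed by
    the last segment; otherwise it becomes its own segment. A segment
    length at or beyond the frame length degenerates to a single segment
    (with a warning).
    """
    if segment_length <= 0:
        raise SplitError("segment_length must be positive")
    t0, t1 = cs.common_frame
    frame = t1 - t0
    if segment_length >= frame - _EPS:
        warnings.warn(
            "segment_length covers the whole frame; returning a single segment",
            stacklevel=2,
        )
        return _segments_from_boundaries(cs, [(t0, t1)])
    n_full = int(np.floor((frame + _EPS) / segment_length))
    remainder = frame - n_full * segment_length
    if remainder < _EPS:
        remainder = 0.0
    edges = [
        (t0 + i * segment_length, t0 + (i + 1) * segment_length)
        for i in range(n_full)
    ]
    if remainder > 0:
        if remainder < remainder_threshold:
            edges[-1] = (edges[-1][0], t1)
        else:
            edges.append((edges[-1][1], t1))
    else:
        edges[-1] = (edges[-1][0], t1)  # close exactly at the frame end
    return _segments_from_boundaries(cs, edges)


def split_manual(
    cs: CurveSet, boundaries: list[tuple[float, float]]
) -> list[Segment]:
    """One segment per user-chosen interval; gaps between intervals are
    excluded from the anonymization."""
    if not boundaries:
        raise SplitError("manual split requires at least one interval")
    t0, t1 = cs.common_frame
    prev_end = None
    for a, b in boundaries:
        if b <= a:
            raise SplitError(f"empty or inverted interval [{a}, {b})")
        if a < t0 - _EPS or b > t1 + _EPS:
            raise SplitError(f"interval [{a}, {b}) outside the common frame {cs.common_frame}")
        if prev_end is not None and a < prev_end - _EPS:
            raise SplitError("manual intervals must be ordered and non-overlapping")
        prev_end = b
    return _segments_from_boundaries(cs, [(float(a), float(b)) for a, b in boundaries])


def split_windowed_frechet(
    cs: CurveSet,
    window: float,
    step: float,
    n_segments: int,
    time_scale: float = 0.0,
    value_scale: float = 1.0,
) -> list[Segment]:
    """Windowed-Fréchet splitting: boundaries where the curves agree most.

    Candidate windows start at ``frame_start + i * step``. For each window
    the mean of all pairwise Fréchet distances between the curve
    restrictions is computed. The ``n_segments - 1`` lowest-mean windows
    whose starts are pairwise at least one window length apart (and
    strictly inside the frame) become segment start boundaries; ties are
    broken toward the earlier offset. Segments partition the frame
    without gaps.
    """
    cfg = SplitConfig(mode="windowed", window=window, step=step, n_segments=n_segments)
    t0, t1 = cs.common_frame
    if n_segments == 1:
        return _segments_from_boundaries(cs, [(t0, t1)])
    offsets = []
    i = 0
    while t0 + i * step + window <= t1 + _EPS:
        offsets.append(t0 + i * step)
        i += 1
    means = []
    for off in offsets:
        win = restrict_curveset(cs, off, min(off + window, t1))
        curves = list(win)
        dists = [
            frechet_distance(curves[a], curves[b], time_scale, value_scale)
            for a in range(len(curves))
            for b in range(a + 1, len(curves))
        ]
        means.append(float(np.mean(dists)) if dists else 0.0)
    # Lowest mean first; ties resolved toward the earliest offset.
    order = sorted(range(len(offsets)), key=lambda idx: (means[idx], offsets[idx]))
    chosen: list[float] = []
    for idx in order:
        off = offsets[idx]
        if off <= t0 + _EPS or off >= t1 - _EPS:
            continue  # boundary must be strictly inside the frame
        if any(abs(off - c) < window - _EPS for c in chosen):
            continue  # conflicting: closer than one window to a chosen boundary
        chosen.append(off)
        if len(chosen) == n_segments - 1:
            break
    if len(chosen) < n_segments - 1:
        raise SplitError(
            f"only {len(chosen) + 1} segments achievable with window={window}, "
            f"step={step} on this frame; requested {n_segments}"
        )
    cuts = [t0] + sorted(chosen) + [t1]
    return _segments_from_boundaries(cs, list(zip(cuts[:-1], cuts[1:])))


def split_dataset(cs: CurveSet, config: SplitConfig) -> list[Segment]:
    """Dispatch to the configured splitting mode."""
    if config.mode == "none":
        return _segments_from_boundaries(cs, [cs.common_frame])
    if config.mode == "fixed":
        return split_fixed(cs, config.segment_length, config.remainder_threshold)
    if config.mode == "manual":
        return split_manual(cs, config.boundaries)
    return split_windowed_frechet(cs, config.window, config.step, config.n_segments)
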