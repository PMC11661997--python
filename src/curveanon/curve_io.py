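"""Reading, writing and aligning single-channel waveform curves.

The on-disk dialect is a semicolon-delimited CSV with a three-line header:

    <subject UUID>
    <ISO-8601 start datetime>
    Time [s];<quantity> [<unit>]

followed by ``time;value`` rows, time in seconds since the start datetime.
Curves are single-valued signals; multi-column files are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AlignmentError, CurveFormatError, CurveValidationError

_HEADER_RE = re.compile(r"^(?P<name>.*?)\s*\[(?P<unit>.*)\]$")


@dataclass(eq=False)
class Curve:
    """Ordered, timed samples of one physiological signal for one subject.

    Parameters
    ----------
    curve_id:
        Opaque identifier, typically the file stem.
    subject_uuid:
        Identifier of the subject in the source database.
    start:
        ISO-8601 start datetime string of the recording.
    quantity_name:
        Name of the measured quantity (e.g. ``"AWF"``).
    unit:
        Physical unit as printed inside the square brackets (e.g. ``"L/min"``).
    t, v:
        Sample times (seconds, strictly increasing) and values.
    """

    curve_id: str
    subject_uuid: str
    start: str
    quantity_name: str
    unit: str
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.v.ndim != 1 or self.t.size != self.v.size:
            raise CurveValidationError(
                f"curve {self.curve_id!r}: time and value arrays must be 1-D "
                f"and equally long"
            )
        if self.t.size < 2:
            raise CurveValidationError(
                f"curve {self.curve_id!r}: at least 2 points required, got {self.t.size}"
            )
        if not np.all(np.diff(self.t) > 0):
            raise CurveValidationError(
                f"curve {self.curve_id!r}: sample times must be strictly increasing"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    @property
    def n_points(self) -> int:
        return int(self.t.size)

    def value_range(self) -> tuple[float, float]:
        return float(self.v.min()), float(self.v.max())

    def interp(self, times: np.ndarray, mode: str = "linear") -> np.ndarray:
        """Sample the curve at arbitrary times inside its span.

        ``mode`` is ``"linear"`` for interpolable signals, ``"previous"``
        (sample-and-hold) or ``"nearest"`` for signals that must not be
        interpolated.
        """
        times = np.asarray(times, dtype=float)
        if mode == "linear":
            return np.interp(times, self.t, self.v)
        idx_prev = np.clip(np.searchsorted(self.t, times, side="right") - 1, 0, None)
        if mode == "previous":
            return self.v[idx_prev]
        if mode == "nearest":
            idx_next = np.clip(idx_prev + 1, None, self.t.size - 1)
            use_next = (self.t[idx_next] - times) < (times - self.t[idx_prev])
            return np.where(use_next, self.v[idx_next], self.v[idx_prev])
        raise ValueError(f"unknown interpolation mode {mode!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Curve):
            return NotImplemented
        return (
            self.curve_id == other.curve_id
            and self.subject_uuid == other.subject_uuid
            and self.start == other.start
            and self.quantity_name == other.quantity_name
            and self.unit == other.unit
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.v, other.v)
        )


@dataclass
class CurveSet:
    """A collection of curves aligned onto a common time frame."""

    curves: list[Curve]
    common_frame: tuple[float, float]
    value_domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.value_domain[0] > self.value_domain[1]:
            raise CurveValidationError("value_domain min exceeds max")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    @property
    def ids(self) -> list[str]:
        return [c.curve_id for c in self.curves]

    def get(self, curve_id: str) -> Curve:
        for c in self.curves:
            if c.curve_id == curve_id:
                return c
        raise KeyError(curve_id)

    @property
    def duration(self) -> float:
        return self.common_frame[1] - self.common_frame[0]


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_curve_csv(path: str | Path) -> Curve:
    """Read one curve from the semicolon-CSV dialect described above."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise CurveFormatError(
            f"{path}: expected 3 header lines and at least 2 data rows, "
            f"got {len(lines)} lines"
        )
    subject_uuid = lines[0].strip()
    start = lines[1].strip()
    columns = lines[2].split(";")
    if len(columns) != 2:
        raise CurveFormatError(
            f"{path}: header line 3 must name exactly two columns "
            f"(got {lines[2]!r}); multi-column files are not supported"
        )
    time_match = _HEADER_RE.match(columns[0].strip())
    if time_match is None or time_match.group("name") != "Time":
        raise CurveFormatError(
            f"{path}: header line 3 must start with 'Time [s]' (got {columns[0]!r})"
        )
    value_match = _HEADER_RE.match(columns[1].strip())
    if value_match is None:
        raise CurveFormatError(
            f"{path}: value column label must carry its unit in square "
            f"brackets (got {columns[1]!r})"
        )
    t, v = [], []
    for lineno, row in enumerate(lines[3:], start=4):
        if not row.strip():
            continue
        cells = row.split(";")
        if len(cells) != 2:
            raise CurveFormatError(f"{path}: line {lineno}: expected 'time;value', got {row!r}")
        try:
            t.append(float(cells[0]))
            v.append(float(cells[1]))
        except ValueError as exc:
            raise CurveFormatError(f"{path}: line {lineno}: {exc}") from None
    return Curve(
        curve_id=path.stem,
        subject_uuid=subject_uuid,
        start=start,
        quantity_name=value_match.group("name"),
        unit=value_match.group("unit"),
        t=np.asarray(t),
        v=np.asarray(v),
    )


def write_curve_csv(curve: Curve, path: str | Path) -> None:
    """Write ``curve`` in the dialect read by :func:`read_curve_csv`.

    The header field order is fixed; two writes of the same curve produce
    byte-identical files. The unit brackets are always present, even when
    the unit is empty.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{curve.subject_uuid}\n")
        fh.write(f"{curve.start}\n")
        fh.write(f"Time [s];{curve.quantity_name} [{curve.unit}]\n")
        for ti, vi in zip(curve.t, curve.v):
            fh.write(f"{float(ti)!r};{float(vi)!r}\n")


def write_hull_csv(
    grid: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    unit: str,
    subject: str,
    start: str,
    path: str | Path,
) -> None:
    """Write a released lower/upper envelope in the curve CSV dialect."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{subject}\n")
        fh.write(f"{start}\n")
        fh.write(f"Time [s];lower [{unit}];upper [{unit}]\n")
        for ti, lo, up in zip(grid, lower, upper):
            fh.write(f"{float(ti)!r};{float(lo)!r};{float(up)!r}\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_dataset(curves: Sequence[Curve] | Iterable[Curve]) -> CurveSet:
    """Shift a dataset onto a common time frame by boundary padding.

    The common frame spans from the earliest first sample to the latest
    last sample over all curves. A curve that starts late is padded by
    holding its first value back to the frame start; one that ends early
    holds its last value forward to the frame end. Padding inserts at
    most two extra samples per curve and never leaves the curve's own
    value range, which structurally removes the hazard of a class being
    only (k-1)-anonymous near the boundaries. The value domain is
    computed over the original, unpadded samples.
    """
    curves = list(curves)
    if not curves:
        raise CurveValidationError("cannot align an empty dataset")
    names = {c.quantity_name for c in curves}
    if len(names) > 1:
        raise CurveValidationError(f"mixed quantity names in dataset: {sorted(names)}")
    t_start = min(c.t[0] for c in curves)
    t_end = max(c.t[-1] for c in curves)
    v_min = min(c.v.min() for c in curves)
    v_max = max(c.v.max() for c in curves)

    aligned: list[Curve] = []
    for c in curves:
        t, v = c.t, c.v
        if t[0] > t_start:
            t = np.concatenate(([t_start], t))
            v = np.concatenate(([v[0]], v))
        if t[-1] < t_end:
            t = np.concatenate((t, [t_end]))
            v = np.concatenate((v, [v[-1]]))
        if t is c.t:
            aligned.append(c)
        else:
            aligned.append(
                Curve(c.curve_id, c.subject_uuid, c.start, c.quantity_name, c.unit, t, v)
            )
    return CurveSet(aligned, (float(t_start), float(t_end)), (float(v_min), float(v_max)))


def check_aligned(a: Curve, b: Curve) -> None:
    """Raise :class:`AlignmentError` unless two curves share a time frame."""
    if a.t[0] != b.t[0] or a.t[-1] != b.t[-1]:
        raise AlignmentError(
            f"curves {a.curve_id!r} and {b.curve_id!r} do not share a common "
            f"time frame; run align_dataset first"
        )
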