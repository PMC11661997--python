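"""Seeded synthetic waveform datasets with controllable cluster structure.

The generator produces periodic breath-like surrogate signals

    v(t) = A * sin(2*pi * RR/60 * t + phi) + noise

with per-cluster respiratory rate RR (breaths/min) and amplitude, and
per-curve jitter on amplitude, phase and rate. Waveform physiology is
irrelevant to the pipeline — only the similarity structure matters — so
a sinusoid is a sufficient surrogate for flow, pressure and saturation
traces. The three emulated dataset shapes match the evaluation data:
airway flow (AWF: 12 curves, 8 s at 50 Hz), airway pressure (AWP: 28
curves, 4 s at 50 Hz) and pulse-oximetry saturation (SPO2: 12 curves,
400 s at an irregular 0.25-1 Hz, 0.5 Hz on average).
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field

import numpy as np

from .curve_io import Curve, CurveSet, align_dataset
from .metrics import pairwise_distances


@dataclass
class FixtureSpec:
    """Full description of one synthetic dataset; the seed determines
    the output completely."""

    n_curves: int = 12
    duration: float = 8.0
    sample_rate: float = 50.0
    n_clusters: int = 2
    respiratory_rates: tuple[float, ...] = (15.0, 70.0)
    amplitudes: tuple[float, ...] = (10.0, 10.0)
    offsets: tuple[float, ...] = (0.0, 0.0)
    jitter_amplitude: float = 0.02
    jitter_phase: float = 0.05
    jitter_rate: float = 0.01
    noise_sd: float = 0.05
    irregular_sampling: bool = False
    interval_range: tuple[float, float] = (1.0, 3.0)
    quantity_name: str = "AWF"
    unit: str = "L/min"
    start: str = "2021-01-01T00:00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.respiratory_rates) < self.n_clusters:
            raise ValueError("need one respiratory rate per cluster")

    def _per_cluster(self, values: tuple[float, ...], c: int) -> float:
        return values[c % len(values)]


def cluster_of(curve_id: str) -> int:
    """Cluster index encoded in a generated curve id (``<name>-c<k>-<i>``)."""
    return int(curve_id.split("-c")[1].split("-")[0])


def generate_breath_curves(spec: FixtureSpec) -> CurveSet:
    """Generate an aligned CurveSet of jittered periodic curves.

    Curves are assigned to clusters round-robin; with zero jitter and
    noise all curves of a cluster are identical.
    """
    rng = np.random.default_rng(spec.seed)
    curves = []
    for i in range(spec.n_curves):
        c = i % spec.n_clusters
        rr = spec._per_cluster(spec.respiratory_rates, c)
        amp = spec._per_cluster(spec.amplitudes, c)
        off = spec._per_cluster(spec.offsets, c)
        amp = amp * (1.0 + spec.jitter_amplitude * rng.standard_normal())
        rr = rr * (1.0 + spec.jitter_rate * rng.standard_normal())
        phi = spec.jitter_phase * rng.standard_normal()
        if spec.irregular_sampling:
            intervals = rng.uniform(*spec.interval_range, size=int(
                np.ceil(spec.duration / spec.interval_range[0])
            ))
            t = np.concatenate(([0.0], np.cumsum(intervals)))
            t = t[t < spec.duration]
            t = np.append(t, spec.duration)
        else:
            n = int(round(spec.duration * spec.sample_rate))
            t = np.arange(n + 1) / spec.sample_rate
        v = off + amp * np.sin(2 * np.pi * rr / 60.0 * t + phi)
        if spec.noise_sd > 0:
            v = v + spec.noise_sd * rng.standard_normal(t.size)
        curves.append(
            Curve(
                curve_id=f"{spec.quantity_name.lower()}-c{c}-{i:03d}",
                subject_uuid=str(uuid.UUID(int=rng.integers(0, 2**63))),
                start=spec.start,
                quantity_name=spec.quantity_name,
                unit=spec.unit,
                t=t,
                v=v,
            )
        )
    return align_dataset(curves)


def separation_ratio(cs: CurveSet) -> float:
    """Inter-cluster / intra-cluster distance ratio of a generated set.

    Uses the cluster labels encoded in the curve ids: the minimum
    between-cluster Fréchet distance divided by the maximum
    within-cluster distance. Values well above 1 mean the clusters are
    recoverable by thresholding.
    """
    dm = pairwise_distances(cs)
    labels = np.array([cluster_of(cid) for cid in dm.ids])
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    intra = dm.d[same & off_diag]
    inter = dm.d[~same]
    if intra.size == 0 or inter.size == 0:
        return np.inf
    intra_max = float(intra.max())
    return float(inter.min()) / intra_max if intra_max > 0 else np.inf


def single_breath_curves(spec: FixtureSpec) -> CurveSet:
    """One-period variant: each curve is a single breath cropped at the
    zero crossings (duration = 60/RR of its cluster)."""
    rng = np.random.default_rng(spec.seed)
    curves = []
    for i in range(spec.n_curves):
        c = i % spec.n_clusters
        rr = spec._per_cluster(spec.respiratory_rates, c)
        amp = spec._per_cluster(spec.amplitudes, c)
        amp = amp * (1.0 + spec.jitter_amplitude * rng.standard_normal())
        period = 60.0 / rr
        n = max(int(round(period * spec.sample_rate)), 2)
        t = np.linspace(0.0, period, n + 1)
        v = amp * np.sin(2 * np.pi * t / period)
        if spec.noise_sd > 0:
            v = v + spec.noise_sd * rng.standard_normal(t.size)
        curves.append(
            Curve(
                curve_id=f"{spec.quantity_name.lower()}-c{c}-{i:03d}",
                subject_uuid=str(uuid.UUID(int=rng.integers(0, 2**63))),
                start=spec.start,
                quantity_name=spec.quantity_name,
                unit=spec.unit,
                t=t,
                v=v,
            )
        )
    return align_dataset(curves)


_SHAPES = {
    "AWF": dict(
        n_curves=12, duration=8.0, sample_rate=50.0, n_clusters=2,
        respiratory_rates=(30.0, 50.0), amplitudes=(10.0, 14.0),
        jitter_amplitude=0.05, jitter_phase=0.1, jitter_rate=0.02,
        noise_sd=0.2, quantity_name="AWF", unit="L/min",
    ),
    "AWP": dict(
        n_curves=28, duration=4.0, sample_rate=50.0, n_clusters=2,
        respiratory_rates=(30.0, 50.0), amplitudes=(8.0, 11.0),
        offsets=(12.0, 14.0), jitter_amplitude=0.05, jitter_phase=0.1,
        jitter_rate=0.02, noise_sd=0.15, quantity_name="AWP", unit="mbar",
    ),
    "SPO2": dict(
        n_curves=12, duration=400.0, n_clusters=2,
        respiratory_rates=(0.3, 0.6), amplitudes=(1.5, 2.5),
        offsets=(96.0, 93.0), jitter_amplitude=0.05, jitter_phase=0.1,
        jitter_rate=0.02, noise_sd=0.1, irregular_sampling=True,
        interval_range=(1.0, 3.0), quantity_name="SPO2", unit="%",
    ),
}


def emulate_dataset_shapes(name: str, seed: int = 0) -> CurveSet:
    """A synthetic dataset with the shape of one of the evaluation sets.

    ``"AWF"``: 12 curves of ~400 points over 8 s (50 Hz). ``"AWP"``: 28
    curves of ~200 points over 4 s (50 Hz). ``"SPO2"``: 12 curves over
    400 s, irregularly sampled with a ~2 s mean interval.
    """
    if name not in _SHAPES:
        raise ValueError(f"unknown dataset shape {name!r}; choose from {sorted(_SHAPES)}")
    return generate_breath_curves(FixtureSpec(seed=seed, **_SHAPES[name]))
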