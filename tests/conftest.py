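import numpy as np
import pytest

from curveanon import Curve, CurveSet, align_dataset


def make_curve(cid, t, v, quantity="AWF", unit="L/min"):
    return Curve(
        curve_id=cid,
        subject_uuid=f"uuid-{cid}",
        start="2021-01-01T00:00:00",
        quantity_name=quantity,
        unit=unit,
        t=np.asarray(t, dtype=float),
        v=np.asarray(v, dtype=float),
    )


def constant_curve(cid, value, t0=0.0, t1=10.0, n=21, quantity="AWF"):
    t = np.linspace(t0, t1, n)
    return make_curve(cid, t, np.full(n, float(value)), quantity=quantity)


def random_curve(cid, rng, n=None, t1=10.0):
    n = n or int(rng.integers(5, 30))
    t = np.sort(rng.uniform(0.0, t1, n - 2))
    t = np.concatenate(([0.0], t, [t1]))
    t = np.unique(t)
    while t.size < 3:
        t = np.unique(np.concatenate((t, rng.uniform(0.0, t1, 3))))
    v = rng.normal(0.0, 3.0, t.size)
    return make_curve(cid, t, v)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_set():
    """Three constant curves at 0, 1, 3 on a shared grid."""
    return align_dataset(
        [constant_curve("c0", 0.0), constant_curve("c1", 1.0), constant_curve("c2", 3.0)]
    )


@pytest.fixture
def two_groups():
    """Two tight groups of three curves each, far apart in value."""
    curves = [constant_curve(f"a{i}", 0.0 + 0.1 * i) for i in range(3)]
    curves += [constant_curve(f"b{i}", 10.0 + 0.1 * i) for i in range(3)]
    return align_dataset(curves)
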