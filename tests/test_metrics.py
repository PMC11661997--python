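import numpy as np
import pytest

from curveanon import (
    align_dataset,
    emd,
    frechet_distance,
    glm_info_loss,
    median_relative_error,
    pairwise_distances,
)
from curveanon.errors import AlignmentError
from curveanon.hulls import Hull

from conftest import constant_curve, make_curve, random_curve


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def frechet_oracle(pa, pb):
    """Plain full-lattice dynamic program over the coupling lattice,
    written independently of the implementation's anti-diagonal scheme."""
    p, q = len(pa), len(pb)
    d = np.array([[np.linalg.norm(pa[i] - pb[j]) for j in range(q)] for i in range(p)])
    ca = np.zeros((p, q))
    ca[0, 0] = d[0, 0]
    for i in range(1, p):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
    for j in range(1, q):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, p):
        for j in range(1, q):
            ca[i, j] = max(d[i, j], min(ca[i - 1, j], ca[i, j - 1], ca[i - 1, j - 1]))
    return ca[-1, -1]


def emd_flow_oracle(p, q, ground):
    """Min-cost-flow transportation solve on integer masses and costs."""
    import networkx as nx

    G = nx.DiGraph()
    for i, pi in enumerate(p):
        G.add_node(("s", i), demand=-int(pi))
    for j, qj in enumerate(q):
        G.add_node(("t", j), demand=int(qj))
    for i in range(len(p)):
        for j in range(len(q)):
            G.add_edge(("s", i), ("t", j), weight=int(ground[i, j]))
    return nx.min_cost_flow_cost(G) / p.sum()


# ---------------------------------------------------------------------------
# Fréchet distance
# ---------------------------------------------------------------------------

class TestFrechet:
    def test_identity(self, rng):
        c = random_curve("same", rng)
        assert frechet_distance(c, c) == 0.0

    def test_parallel_constant_curves(self):
        a = constant_curve("a", 1.0)
        b = constant_curve("b", 1.0 + 2.5)
        assert frechet_distance(a, b) == pytest.approx(2.5)
        assert frechet_distance(a, b, value_scale=2.0) == pytest.approx(5.0)

    def test_unaligned_curves_rejected(self):
        a = make_curve("a", [0, 10], [0, 0])
        b = make_curve("b", [0, 8], [0, 0])
        with pytest.raises(AlignmentError):
            frechet_distance(a, b)

    def test_matches_lattice_oracle_on_random_pairs(self, rng):
        # Shared grid: oracle couples the same (t=0-scaled) point sequences.
        for _ in range(20):
            n = int(rng.integers(4, 25))
            t = np.linspace(0, 10, n)
            a = make_curve("a", t, rng.normal(size=n))
            b = make_curve("b", t, rng.normal(size=n))
            got = frechet_distance(a, b)
            expect = frechet_oracle(a.v[:, None], b.v[:, None])
            assert got == pytest.approx(expect, abs=1e-12)

    def test_matches_oracle_with_time_axis(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 15))
            t = np.linspace(0, 5, n)
            a = make_curve("a", t, rng.normal(size=n))
            b = make_curve("b", t, rng.normal(size=n))
            got = frechet_distance(a, b, time_scale=1.0, value_scale=0.5)
            pa = np.column_stack((t, 0.5 * a.v))
            pb = np.column_stack((t, 0.5 * b.v))
            assert got == pytest.approx(frechet_oracle(pa, pb), abs=1e-12)

    def test_union_grid_resampling(self):
        # Different grids, same underlying constant signals.
        a = make_curve("a", [0, 3, 10], [1, 1, 1])
        b = make_curve("b", [0, 7, 10], [4, 4, 4])
        assert frechet_distance(a, b) == pytest.approx(3.0)

    def test_metric_axioms_on_seeded_triples(self, rng):
        t = np.linspace(0, 10, 12)
        for _ in range(100):
            a, b, c = (make_curve(x, t, rng.normal(size=12)) for x in "abc")
            dab = frechet_distance(a, b)
            dba = frechet_distance(b, a)
            dac = frechet_distance(a, c)
            dcb = frechet_distance(c, b)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= dac + dcb + 1e-12


class TestPairwise:
    def test_identical_curves_zero_matrix(self):
        cs = align_dataset([constant_curve(f"i{k}", 2.0) for k in range(4)])
        dm = pairwise_distances(cs)
        assert np.all(dm.d == 0.0)

    def test_three_constants_closed_form(self, constant_set):
        dm = pairwise_distances(constant_set)
        assert np.allclose(dm.d, [[0, 1, 3], [1, 0, 2], [3, 2, 0]])

    def test_symmetry_and_zero_diagonal(self, rng):
        t = np.linspace(0, 10, 15)
        cs = align_dataset([make_curve(f"p{k}", t, rng.normal(size=15)) for k in range(6)])
        dm = pairwise_distances(cs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)
        assert np.all(dm.d >= 0)


# ---------------------------------------------------------------------------
# EMD
# ---------------------------------------------------------------------------

class TestEMD:
    def test_equal_histograms(self):
        g = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert emd(np.array([2.0, 1.0]), np.array([4.0, 2.0]), g) == 0.0

    def test_point_masses_cost_is_ground(self):
        g = np.array([[0.0, 2.5, 1.0], [2.5, 0.0, 3.0], [1.0, 3.0, 0.0]])
        p = np.array([1.0, 0.0, 0.0])
        q = np.array([0.0, 1.0, 0.0])
        assert emd(p, q, g) == pytest.approx(2.5)

    def test_symmetry(self, rng):
        for _ in range(20):
            g = rng.integers(0, 10, (4, 4)).astype(float)
            g = (g + g.T) / 2
            np.fill_diagonal(g, 0)
            p = rng.integers(1, 8, 4).astype(float)
            q = rng.integers(1, 8, 4).astype(float)
            assert emd(p, q, g) == pytest.approx(emd(q, p, g), abs=1e-10)

    def test_matches_flow_oracle(self, rng):
        for _ in range(100):
            n = 5
            g = rng.integers(0, 20, (n, n))
            g = g + g.T
            np.fill_diagonal(g, 0)
            p = rng.integers(0, 9, n)
            if p.sum() == 0:
                p[0] = 1
            q = rng.multinomial(p.sum(), np.full(n, 1 / n))
            got = emd(p.astype(float), q.astype(float), g.astype(float))
            assert got == pytest.approx(emd_flow_oracle(p, q, g), abs=1e-9)

    def test_empty_histogram_rejected(self):
        g = np.zeros((2, 2))
        with pytest.raises(ValueError, match="empty"):
            emd(np.zeros(2), np.ones(2), g)


# ---------------------------------------------------------------------------
# GLM and MRE
# ---------------------------------------------------------------------------

def _hull(lower, upper, t0=0.0, t1=10.0):
    grid = np.linspace(t0, t1, len(lower))
    return Hull(resolution=(t1 - t0) / (len(lower) - 1), grid=grid,
                lower=np.asarray(lower, float), upper=np.asarray(upper, float))


class TestGLM:
    def test_single_member_class_is_lossless(self):
        h = _hull([0, 0, 0], [5, 5, 5])
        assert glm_info_loss(h, (0.0, 5.0), member_count=1) == 0.0

    def test_full_domain_hull(self):
        h = _hull([0, 0, 0], [5, 5, 5])
        assert glm_info_loss(h, (0.0, 5.0), member_count=3) == 1.0

    def test_constant_width_fraction(self):
        h = _hull([1, 1, 1, 1], [3, 3, 3, 3])
        assert glm_info_loss(h, (0.0, 8.0), member_count=2) == pytest.approx(0.25)

    def test_degenerate_domain_warns_and_returns_zero(self):
        h = _hull([1, 1], [1, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            assert glm_info_loss(h, (1.0, 1.0), member_count=2) == 0.0

    def test_monotone_under_pointwise_enlargement(self, rng):
        for _ in range(20):
            lo = rng.normal(size=8)
            width = rng.uniform(0, 2, 8)
            h1 = _hull(lo, lo + width)
            h2 = _hull(lo - rng.uniform(0, 1, 8), lo + width + rng.uniform(0, 1, 8))
            dom = (-10.0, 10.0)
            assert glm_info_loss(h2, dom, 3) >= glm_info_loss(h1, dom, 3)


class TestMRE:
    def test_members_on_bounds_give_zero(self):
        members = [constant_curve("lo", 0.0), constant_curve("hi", 2.0)]
        h = _hull([0] * 5, [2] * 5)
        assert median_relative_error(members, h) == 0.0

    def test_middle_member_pooled_median(self):
        members = [constant_curve("lo", 0.0), constant_curve("hi", 2.0),
                   constant_curve("mid", 1.0)]
        h = _hull([0] * 5, [2] * 5)
        # Per grid point the errors are {0, 0, 1}; pooled median is 0.
        assert median_relative_error(members, h) == 0.0

    def test_lone_interior_member_distance_to_nearer_bound(self):
        h = _hull([0] * 5, [3] * 5)
        assert median_relative_error([constant_curve("m", 1.0)], h) == pytest.approx(1.0)

    def test_invariant_under_duplicate_bound_member(self, rng):
        members = [constant_curve("lo", 0.0), constant_curve("mid", 0.7),
                   constant_curve("hi", 2.0)]
        h = _hull([0] * 7, [2] * 7)
        base = median_relative_error(members, h)
        more = members + [constant_curve("lo2", 0.0)]
        assert median_relative_error(more, h) == base

    def test_empty_class_rejected(self):
        with pytest.raises(Exception):
            median_relative_error([], _hull([0, 0], [1, 1]))
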