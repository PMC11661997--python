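from collections import deque

import numpy as np
import pytest

from curveanon import (
    CONSTRAINED,
    RELAXED,
    InfeasibleAnonymizationError,
    Params,
    SplitConfig,
    align_dataset,
    anonymize,
    marked_redistribution,
    prepare,
    unmarked_redistribution,
)
from curveanon.builder import (
    EquivalenceClass,
    _insert,
    data_distribution_phase,
    run_phases,
)
from curveanon.trees import ECSNode

from conftest import constant_curve, make_curve


def _params(**kw):
    kw.setdefault("s_d", 1.0)
    kw.setdefault("hull_resolution", 1.0)
    return Params(**kw)


def _near_identical_set(n, base=0.0, step=0.01, prefix="c"):
    return align_dataset(
        [constant_curve(f"{prefix}{i}", base + step * i) for i in range(n)]
    )


class TestPrepare:
    def test_identical_curves_quotas_sum_to_n(self):
        cs = _near_identical_set(6, step=0.0)
        state = prepare(cs, _params(k=3))
        total = sum(e.target_size for e in state.unmarked)
        assert total == 6

    def test_too_small_database(self):
        cs = _near_identical_set(2)
        with pytest.raises(InfeasibleAnonymizationError, match="too small"):
            prepare(cs, _params(k=3))

    def test_determinism(self):
        cs = _near_identical_set(8, step=0.5)
        s1 = prepare(cs, _params(k=3))
        s2 = prepare(cs, _params(k=3))
        assert [list(e.quota) for e in s1.unmarked] == [list(e.quota) for e in s2.unmarked]
        assert s1.tree.root.to_dict() == s2.tree.root.to_dict()

    def test_external_distribution_sets_proportional_quotas(self):
        # Population: 4 curves near 0, 8 near 10 (1:2). The set to be
        # anonymized holds 6 of each; quotas must follow the population.
        pop = align_dataset(
            [constant_curve(f"pa{i}", 0.0 + 0.01 * i) for i in range(4)]
            + [constant_curve(f"pb{i}", 10.0 + 0.01 * i) for i in range(8)]
        )
        cs = align_dataset(
            [constant_curve(f"a{i}", 0.0 + 0.01 * i) for i in range(6)]
            + [constant_curve(f"b{i}", 10.0 + 0.01 * i) for i in range(6)]
        )
        state = prepare(cs, _params(k=3, s_d=1.0), population=pop)
        assert state.distribution.source == "external"
        root = state.ecs.root.virtual_buckets
        # Bucket of the near-0 group gets 1/3 of the target, near-10 two
        # thirds, capped by what the buckets can serve: totals 3 and 6.
        assert sorted(root.tolist()) == [3, 6]


class TestDataDistribution:
    def test_identical_curves_one_marked_class_zero_loss(self):
        cs = _near_identical_set(3, step=0.0)
        state = prepare(cs, _params(k=3))
        data_distribution_phase(state)
        assert len(state.marked) == 1
        assert not state.unmarked
        e = state.marked[0]
        assert e.n_live == 3
        assert np.all(e.upper - e.lower == 0)

    def test_no_drop_no_split_at_default_thresholds(self, rng):
        t = np.linspace(0, 10, 30)
        cs = align_dataset(
            [make_curve(f"r{i}", t, rng.normal(0, 5, 30)) for i in range(9)]
        )
        state = prepare(cs, _params(k=3, s_d=100.0))
        data_distribution_phase(state)
        for e in state.marked:
            assert not e.dropped
            assert "." not in e.eqc_id  # no ECS splits happened

    def test_two_separated_groups_give_pure_classes(self, two_groups):
        state = prepare(two_groups, _params(k=3))
        data_distribution_phase(state)
        assert len(state.marked) == 2
        groups = sorted(sorted(cid[0] for cid in e.live_ids) for e in state.marked)
        assert groups == [["a", "a", "a"], ["b", "b", "b"]]

    def test_drop_threshold_drops_outlier(self):
        curves = [constant_curve(f"n{i}", 0.01 * i) for i in range(3)]
        curves.append(constant_curve("zfar", 100.0))
        cs = align_dataset(curves)
        state = prepare(cs, _params(k=3, s_d=1000.0, depth_b=0, d=0.5, s_eqc=0.5))
        data_distribution_phase(state)
        assert len(state.marked) == 1
        e = state.marked[0]
        assert e.dropped == {"zfar"}
        assert e.n_live == 3
        assert float(e.upper.max()) < 1.0  # dropped member not in the hull

    def test_class_splitting_on_s_eqc(self, two_groups):
        # A class holding a non-leaf ECS node splits along the node's
        # children once its loss crosses s_eqc; members and quotas are
        # conserved across the split and everything still gets released.
        params = _params(k=3, depth_b=0, s_eqc=0.3, d=1.0)
        state = prepare(two_groups, params)
        root = state.ecs.root
        assert root.children is not None
        state.unmarked = deque(
            [EquivalenceClass(eqc_id="e0", ecs_node=root, quota=root.virtual_buckets)]
        )
        run_phases(state)
        assert all("." in e.eqc_id for e in state.marked)
        assert sum(e.target_size for e in state.marked) == 6
        released = sorted(cid for e in state.marked for cid, _ in e.members)
        assert released == sorted(two_groups.ids)
        assert all(e.n_live >= 3 for e in state.marked)


def _manual_two_halves(k=4):
    """State with two half-filled, compatible unmarked classes."""
    cs = _near_identical_set(2 * k, step=0.01)
    params = _params(k=k, depth_b=0)
    state = prepare(cs, params)
    state.unmarked = deque()
    state.marked = []
    n_b = len(state.buckets)
    ids = sorted(cs.ids)
    halves = [ids[:k // 2], ids[k // 2 : k]]
    for tag, half in zip("xy", halves):
        quota = np.zeros(n_b, dtype=int)
        quota[0] = k
        e = EquivalenceClass(eqc_id=f"u{tag}", ecs_node=ECSNode(quota), quota=quota)
        for cid in half:
            _insert(e, cid, 0, state, dropped=False)
        state.unmarked.append(e)
    state.remaining = [[] for _ in range(n_b)]
    return state, params


class TestUnmarkedRedistribution:
    def test_empty_queue_is_identity(self, two_groups):
        state = prepare(two_groups, _params(k=3))
        data_distribution_phase(state)
        marked_before = len(state.marked)
        unmarked_redistribution(state)
        assert len(state.marked) == marked_before

    def test_two_half_filled_classes_merge_into_one_marked(self):
        state, _ = _manual_two_halves(k=4)
        unmarked_redistribution(state)
        assert len(state.marked) == 1
        assert state.marked[0].n_live == 4
        assert not state.unmarked

    def test_incompatible_leftovers_leave_state_unchanged(self):
        # max_cost (= s_eqc) so tight that no move is allowed.
        cs = align_dataset(
            [constant_curve(f"a{i}", 0.0 + 0.01 * i) for i in range(2)]
            + [constant_curve(f"b{i}", 10.0 + 0.01 * i) for i in range(2)]
        )
        params = _params(k=4, depth_b=0, s_eqc=0.001, d=1.0)
        state = prepare(cs, params)
        state.unmarked = deque()
        n_b = len(state.buckets)
        for tag, members in (("xa", ["a0", "a1"]), ("xb", ["b0", "b1"])):
            quota = np.zeros(n_b, dtype=int)
            quota[0] = 4
            e = EquivalenceClass(eqc_id=tag, ecs_node=ECSNode(quota), quota=quota)
            for cid in members:
                _insert(e, cid, 0, state, dropped=False)
            state.unmarked.append(e)
        state.remaining = [[] for _ in range(n_b)]
        unmarked_redistribution(state)
        assert len(state.unmarked) == 2
        assert not state.marked
        assert {cid for e in state.unmarked for cid, _ in e.members} == {
            "a0", "a1", "b0", "b1"
        }


class TestMarkedRedistribution:
    def _state_with_marked(self, leftover_value, **param_kw):
        curves = [constant_curve(f"m{i}", 0.01 * i) for i in range(3)]
        curves.append(constant_curve("left", leftover_value))
        cs = align_dataset(curves)
        params = _params(k=3, depth_b=0, **param_kw)
        state = prepare(cs, params)
        state.unmarked = deque()
        state.marked = []
        n_b = len(state.buckets)
        quota = np.zeros(n_b, dtype=int)
        quota[0] = 3
        host = EquivalenceClass(eqc_id="host", ecs_node=ECSNode(quota), quota=quota)
        for cid in ("m0", "m1", "m2"):
            _insert(host, cid, 0, state, dropped=False)
        host.marked = True
        state.marked.append(host)
        donor = EquivalenceClass(eqc_id="don", ecs_node=ECSNode(quota), quota=quota)
        _insert(donor, "left", 0, state, dropped=False)
        state.unmarked.append(donor)
        state.remaining = [[] for _ in range(n_b)]
        return state

    def test_nearby_leftover_inserted_under_constrained(self):
        state = self._state_with_marked(0.05)
        marked_redistribution(state, CONSTRAINED)
        assert not state.unmarked
        assert "left" in state.marked[0].live_ids

    def test_far_leftover_stays_for_relaxed(self):
        state = self._state_with_marked(100.0, s_eqc=0.01, d=1.0)
        marked_redistribution(state, CONSTRAINED)
        assert len(state.unmarked) == 1
        marked_redistribution(state, RELAXED)
        assert not state.unmarked
        host = state.marked[0]
        assert "left" in [cid for cid, _ in host.members]

    def test_relaxed_with_no_marked_reports_unanonymizable(self):
        state = self._state_with_marked(100.0)
        state.marked = []
        marked_redistribution(state, RELAXED)
        assert not state.unmarked
        assert state.unanonymizable == ["left"]

    def test_invalid_flag_rejected(self):
        state = self._state_with_marked(0.05)
        with pytest.raises(ValueError):
            marked_redistribution(state, "LOOSE")


class TestAnonymize:
    def test_identical_curves_full_pipeline(self):
        cs = _near_identical_set(3, step=0.0)
        res = anonymize(cs, _params(k=3))
        assert len(res.classes) == 1
        cls = res.classes[0]
        assert cls.glm == 0.0 and cls.mre == 0.0 and cls.t_exact == 0.0
        assert res.t_exact == 0.0

    def test_input_smaller_than_k_is_infeasible(self):
        cs = _near_identical_set(2)
        with pytest.raises(InfeasibleAnonymizationError):
            anonymize(cs, _params(k=3))

    def test_rerun_byte_identical_report(self, two_groups):
        p = _params(k=3)
        r1 = anonymize(two_groups, p).to_json()
        r2 = anonymize(two_groups, _params(k=3)).to_json()
        assert r1.encode() == r2.encode()

    def test_every_released_class_has_k_live_members(self, rng):
        t = np.linspace(0, 10, 40)
        cs = align_dataset(
            [make_curve(f"r{i}", t, rng.normal(0, 2, 40) + rng.normal()) for i in range(14)]
        )
        res = anonymize(cs, _params(k=4, s_d=50.0))
        assert res.classes
        for cls in res.classes:
            assert len(cls.live_ids) >= 4

    def test_conservation_across_classes(self, rng):
        t = np.linspace(0, 10, 30)
        cs = align_dataset(
            [make_curve(f"r{i}", t, rng.normal(0, 2, 30)) for i in range(10)]
        )
        res = anonymize(cs, _params(k=3, s_d=50.0))
        for seg in res.segments:
            seen = [m for c in seg.classes for m in c.member_ids]
            seen += list(seg.unanonymized_ids)
            assert sorted(seen) == sorted(cs.ids)

    def test_curve_changes_class_between_segments(self):
        # A switcher curve follows group A in the first half of the time
        # frame and group B in the second; split anonymization moves it.
        t = np.linspace(0, 10, 41)
        curves = [make_curve(f"a{i}", t, np.full(41, 0.0 + 0.05 * i)) for i in range(3)]
        curves += [make_curve(f"b{i}", t, np.full(41, 10.0 + 0.05 * i)) for i in range(3)]
        v_switch = np.where(t < 5.0, 0.1, 10.1)
        curves.append(make_curve("switch", t, v_switch))
        cs = align_dataset(curves)
        params = _params(
            k=3, s_d=3.0,
            split=SplitConfig(mode="fixed", segment_length=5.0),
        )
        res = anonymize(cs, params)
        assert len(res.segments) == 2
        mates = []
        for seg in res.segments:
            for cls in seg.classes:
                if "switch" in cls.member_ids:
                    mates.append({m[0] for m in cls.member_ids if m != "switch"})
        assert mates[0] == {"a"} and mates[1] == {"b"}

    def test_marked_count_monotone_across_phases(self, rng):
        t = np.linspace(0, 10, 30)
        cs = align_dataset(
            [make_curve(f"r{i}", t, rng.normal(0, 3, 30)) for i in range(12)]
        )
        state = prepare(cs, _params(k=3, s_d=100.0))
        counts = [len(state.marked)]
        data_distribution_phase(state)
        counts.append(len(state.marked))
        unmarked_redistribution(state)
        counts.append(len(state.marked))
        marked_redistribution(state, CONSTRAINED)
        counts.append(len(state.marked))
        marked_redistribution(state, RELAXED)
        counts.append(len(state.marked))
        assert counts == sorted(counts)

    def test_proportional_mode_follows_quotas(self, two_groups):
        res = anonymize(two_groups, _params(k=3, greedy=False))
        # Quota-proportional filling mixes the groups per class.
        for cls in res.classes:
            prefixes = {m[0] for m in cls.member_ids}
            assert prefixes == {"a", "b"}
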