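"""Multiphase distribution of curves into equivalence classes.

The pipeline per segment:

1. *Preparation* — pairwise Fréchet distances, the population
   distribution (built here or supplied externally), the Bucket Tree,
   the ECS tree, and the empty equivalence classes with their quotas.
2. *Data distribution* — classes are dequeued and filled greedily from
   the buckets, proportionally to their per-bucket quotas; curves whose
   insertion would push the information loss above the drop threshold
   ``d`` are dropped, losses between ``s_eqc`` and ``d`` split the class
   along its ECS children.
3. *Unmarked redistribution* — unfinished classes donate their members
   to other unfinished classes (smallest donor first) until all are
   marked or an iteration adds nothing.
4. *Marked redistribution*, constrained then relaxed — leftovers are
   pushed into already-marked classes; the relaxed pass waives the
   maximum-cost constraint but keeps the drop threshold, so it always
   terminates with the unmarked queue empty.

Everything is deterministic: identical inputs and parameters give
identical results, down to the released report bytes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .clustering import (
    Distribution,
    attribute_members,
    cluster_distribution,
    eqc_histogram,
    reference_ground,
)
from .curve_io import CurveSet
from .errors import InfeasibleAnonymizationError
from .hulls import (
    ClassReport,
    SegmentReport,
    AnonymizationResult,
    build_hull,
    evaluation_report,
    exact_t,
    hull_grid,
)
from .metrics import (
    DistanceMatrix,
    frechet_distance,
    glm_from_envelope,
    glm_info_loss,
    median_relative_error,
    pairwise_distances,
)
from .segmentation import Segment, SplitConfig, restrict_curveset, split_dataset
from .trees import (
    BucketNode,
    BucketTree,
    ECSNode,
    ECSTree,
    TBound,
    build_bucket_tree,
    build_ecs_tree,
    estimate_t,
    select_buckets,
    _largest_remainder,
)

CONSTRAINED = "CONSTRAINED"
RELAXED = "RELAXED"


@dataclass
class Params:
    """All tunable knobs of the anonymization.

    k:
        Minimal equivalence-class size. 3 is the default: below that the
        released bounds coincide with the data.
    s_d:
        Distribution sensitivity — the Fréchet threshold of the
        population clustering, in the same unit as the curve values
        (times the value scale).
    f:
        Bucket Tree balancing factor, the minimum child fraction of a
        split; above 0.5 the constraint is unfulfillable.
    depth_b:
        Bucket Tree depth to select buckets from (1 = two buckets).
    s_eqc, d:
        Information-loss thresholds: a class whose loss passes ``s_eqc``
        is split, a curve pushing it past ``d`` is dropped. The defaults
        of 1.0 disable both, since the GLM never exceeds 1.
    max_cost:
        Maximum post-insertion GLM accepted during the constrained
        redistribution phases; defaults to ``s_eqc``.
    hull_resolution:
        Grid step (seconds) of the released hulls and of every GLM/MRE
        evaluation during the fill.
    split:
        Time-axis segmentation configuration.
    interpolation:
        ``"linear"`` for interpolable signals, else ``"previous"`` or
        ``"nearest"``.
    normalize_ground:
        Normalize the EMD ground distance by the maximum pairwise
        reference distance so that t lands in [0, 1].
    time_scale, value_scale:
        Axis scaling of the Fréchet ground distance; the default
        ``time_scale = 0`` compares values at coupled sample indices.
    """

    k: int = 3
    s_d: float = 1.0
    f: float = 0.4
    depth_b: int = 1
    s_eqc: float = 1.0
    d: float = 1.0
    max_cost: Optional[float] = None
    hull_resolution: float = 0.05
    split: SplitConfig = field(default_factory=SplitConfig)
    interpolation: str = "linear"
    normalize_ground: bool = True
    time_scale: float = 0.0
    value_scale: float = 1.0
    greedy: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 <= self.s_eqc <= self.d <= 1):
            raise ValueError("thresholds must satisfy 0 <= s_eqc <= d <= 1")
        if self.hull_resolution <= 0:
            raise ValueError("hull_resolution must be positive")
        if self.max_cost is not None and not (0 <= self.max_cost <= self.d):
            raise ValueError("max_cost must lie in [0, d]")
        if isinstance(self.split, dict):
            self.split = SplitConfig(**self.split)

    @property
    def max_cost_effective(self) -> float:
        return self.s_eqc if self.max_cost is None else self.max_cost

    def to_dict(self) -> dict:
        out = asdict(self)
        out["max_cost"] = self.max_cost_effective
        return out


@dataclass
class EquivalenceClass:
    """A (possibly unfinished) equivalence class during the build."""

    eqc_id: str
    ecs_node: ECSNode
    quota: np.ndarray
    members: list[tuple[str, int]] = field(default_factory=list)
    dropped: set[str] = field(default_factory=set)
    taken: np.ndarray = field(default=None)  # type: ignore[assignment]
    marked: bool = False
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.quota = np.asarray(self.quota, dtype=int)
        if self.taken is None:
            self.taken = np.zeros_like(self.quota)

    @property
    def target_size(self) -> int:
        return int(self.quota.sum())

    @property
    def total(self) -> int:
        return len(self.members)

    @property
    def live_ids(self) -> list[str]:
        return [cid for cid, _ in self.members if cid not in self.dropped]

    @property
    def n_live(self) -> int:
        return self.total - len(self.dropped)


@dataclass
class BuilderState:
    """Everything the phases share for one segment."""

    cs: CurveSet
    params: Params
    interval: tuple[float, float]
    value_domain: tuple[float, float]
    dm: DistanceMatrix
    distribution: Distribution
    ref_dist: np.ndarray
    ground: np.ndarray
    normalizer: float
    tree: BucketTree
    buckets: list[BucketNode]
    ecs: ECSTree
    t_bound: TBound
    grid: np.ndarray
    member_vals: dict[str, np.ndarray]
    unmarked: deque[EquivalenceClass]
    marked: list[EquivalenceClass] = field(default_factory=list)
    remaining: list[list[str]] = field(default_factory=list)
    unanonymizable: list[str] = field(default_factory=list)

    def assigned_ids(self) -> list[str]:
        out = []
        for e in list(self.unmarked) + self.marked:
            out.extend(cid for cid, _ in e.members)
        return out


# ---------------------------------------------------------------------------
# Preparation
# ---------------------------------------------------------------------------

def _external_root_vector(
    buckets: list[BucketNode],
    distribution: Distribution,
    ref_dist: np.ndarray,
    all_ids: tuple[str, ...],
    k: int,
) -> np.ndarray:
    """Per-bucket targets following an external population's proportions.

    Each curve of the anonymization set is attributed to its nearest
    population cluster. A bucket's weight is the population mass of the
    clusters its members stand in, shared evenly among the set's members
    of that cluster. The total target is the largest count that the
    buckets can serve at those proportions; over-represented curves are
    left in their buckets for the redistribution phases.
    """
    labels = attribute_members(list(all_ids), distribution, ref_dist, all_ids)
    by_id = dict(zip(all_ids, labels))
    pop = distribution.counts
    pop_share = pop / pop.sum()
    counts_in_set = np.bincount(labels, minlength=len(distribution.clusters))
    weights = np.zeros(len(buckets))
    for j, b in enumerate(buckets):
        for m in b.member_ids:
            c = by_id[m]
            weights[j] += pop_share[c] / counts_in_set[c]
    weights = weights / weights.sum()
    sizes = np.array([b.n for b in buckets], dtype=int)
    n = int(sizes.sum())
    feasible = [
        int(np.floor(sizes[j] / weights[j] + 1e-9))
        for j in range(len(buckets))
        if weights[j] > 0
    ]
    total = min([n] + feasible)
    if total < k:
        raise InfeasibleAnonymizationError(
            f"external distribution leaves only {total} proportionally "
            f"assignable curves; cannot satisfy k={k}"
        )
    vec = np.minimum(_largest_remainder(weights, total), sizes)
    return vec


def prepare(
    cs: CurveSet,
    params: Params,
    population: Optional[CurveSet] = None,
    value_domain: Optional[tuple[float, float]] = None,
    interval: Optional[tuple[float, float]] = None,
) -> BuilderState:
    """Compute distances, distribution, trees and the empty classes."""
    if len(cs) < params.k:
        raise InfeasibleAnonymizationError(
            f"database too small: {len(cs)} curves cannot satisfy k={params.k}"
        )
    interval = interval or cs.common_frame
    value_domain = value_domain or cs.value_domain
    dm = pairwise_distances(cs, params.time_scale, params.value_scale)

    if population is None:
        distribution = cluster_distribution(dm, params.s_d)
        ref_ids = distribution.reference_ids
        ref_idx = [dm.index(r) for r in ref_ids]
        ref_pair = dm.d[np.ix_(ref_idx, ref_idx)]
        ref_dist = dm.d[:, ref_idx]
    else:
        # The distribution comes from the (larger) population; distances
        # are then recomputed on the curves actually being anonymized.
        dm_pop = pairwise_distances(population, params.time_scale, params.value_scale)
        distribution = cluster_distribution(dm_pop, params.s_d)
        distribution.source = "external"
        ref_ids = distribution.reference_ids
        ref_idx = [dm_pop.index(r) for r in ref_ids]
        ref_pair = dm_pop.d[np.ix_(ref_idx, ref_idx)]
        refs = [population.get(r) for r in ref_ids]
        ref_dist = np.array(
            [
                [
                    frechet_distance(c, r, params.time_scale, params.value_scale)
                    for r in refs
                ]
                for c in cs
            ]
        )

    ground, normalizer = reference_ground(
        distribution, ref_pair, normalize=params.normalize_ground
    )

    tree = build_bucket_tree(dm, params.f)
    buckets = select_buckets(tree, params.depth_b)
    if population is None:
        root_vec = [b.n for b in buckets]
    else:
        root_vec = _external_root_vector(
            buckets, distribution, ref_dist, dm.ids, params.k
        )
    ecs = build_ecs_tree(root_vec, params.k)
    leaves = ecs.leaves()
    t_bound = estimate_t(leaves, buckets, normalizer)

    grid = hull_grid(interval, params.hull_resolution)
    member_vals = {
        c.curve_id: c.interp(grid, mode=params.interpolation) for c in cs
    }
    unmarked = deque(
        EquivalenceClass(eqc_id=f"e{i}", ecs_node=leaf, quota=leaf.virtual_buckets)
        for i, leaf in enumerate(leaves)
    )
    remaining = [sorted(b.member_ids) for b in buckets]
    return BuilderState(
        cs=cs,
        params=params,
        interval=interval,
        value_domain=value_domain,
        dm=dm,
        distribution=distribution,
        ref_dist=ref_dist,
        ground=ground,
        normalizer=normalizer,
        tree=tree,
        buckets=buckets,
        ecs=ecs,
        t_bound=t_bound,
        grid=grid,
        member_vals=member_vals,
        unmarked=unmarked,
        remaining=remaining,
    )


# ---------------------------------------------------------------------------
# Shared fill machinery
# ---------------------------------------------------------------------------

def _post_glm(e: EquivalenceClass, cid: str, state: BuilderState) -> float:
    """GLM of the class after (hypothetically) adding ``cid`` live."""
    vals = state.member_vals[cid]
    if e.lower is None:
        lower, upper = vals, vals
    else:
        lower = np.minimum(e.lower, vals)
        upper = np.maximum(e.upper, vals)
    return glm_from_envelope(lower, upper, state.value_domain, e.n_live + 1)


def _insert(
    e: EquivalenceClass,
    cid: str,
    bucket_idx: int,
    state: BuilderState,
    dropped: bool,
) -> None:
    e.members.append((cid, bucket_idx))
    if 0 <= bucket_idx < e.taken.size:
        e.taken[bucket_idx] += 1
    if dropped:
        e.dropped.add(cid)
        return
    vals = state.member_vals[cid]
    if e.lower is None:
        e.lower, e.upper = vals.copy(), vals.copy()
    else:
        e.lower = np.minimum(e.lower, vals)
        e.upper = np.maximum(e.upper, vals)


def _meets_target(e: EquivalenceClass, k: int) -> bool:
    return e.total >= e.target_size and e.n_live >= k


def _proportional_ok(e: EquivalenceClass, k: int) -> bool:
    """Exhaustion marking: >= k live members, per-bucket takes within
    one of the quota proportions scaled to the achieved size."""
    if e.n_live < k or e.target_size == 0:
        return False
    expected = e.quota * (e.total / e.target_size)
    return bool(np.all(np.abs(e.taken - expected) <= 1 + 1e-9))


def _next_bucket(e: EquivalenceClass, state: BuilderState) -> Optional[int]:
    """Round-robin proportional choice: the bucket lagging furthest
    behind its quota share, among buckets with data and quota left."""
    best = None
    best_ratio = None
    for j, ids in enumerate(state.remaining):
        if not ids or e.quota[j] == 0 or e.taken[j] >= e.quota[j]:
            continue
        ratio = e.taken[j] / e.quota[j]
        if best_ratio is None or ratio < best_ratio:
            best, best_ratio = j, ratio
    return best


def _best_candidate(
    e: EquivalenceClass, bucket_indices: list[int], state: BuilderState
) -> tuple[str, int, float]:
    """Greedy pick: the remaining curve (over the given buckets) that
    minimizes the class's post-insertion information loss. Ties go to
    the ascending curve id."""
    best: Optional[tuple[str, int, float]] = None
    for j in bucket_indices:
        for cid in state.remaining[j]:
            g = _post_glm(e, cid, state)
            if best is None or (g, cid) < (best[2], best[0]):
                best = (cid, j, g)
    assert best is not None
    return best


def _take(e: EquivalenceClass, cid: str, bucket_idx: int, state: BuilderState, dropped: bool) -> None:
    state.remaining[bucket_idx].remove(cid)
    _insert(e, cid, bucket_idx, state, dropped)


# ---------------------------------------------------------------------------
# Phase 1: data distribution
# ---------------------------------------------------------------------------

def _fill_class(e: EquivalenceClass, state: BuilderState) -> str:
    """Fill one class from the buckets until its target size is reached.

    In greedy mode (the default) the minimum-loss curve over all buckets
    with data is taken, which keeps similar curves together; in
    proportional mode the buckets are drawn round-robin according to the
    class's quota, which is what the t over-approximation presumes.
    """
    p = state.params
    while e.total < e.target_size:
        if p.greedy:
            buckets = [j for j, ids in enumerate(state.remaining) if ids]
            if not buckets:
                return "exhausted"
        else:
            j = _next_bucket(e, state)
            if j is None:
                return "exhausted"
            buckets = [j]
        cid, j, g = _best_candidate(e, buckets, state)
        if g > p.d:
            _take(e, cid, j, state, dropped=True)
        elif g > p.s_eqc and e.ecs_node.children is not None:
            return "split"
        else:
            _take(e, cid, j, state, dropped=False)
    return "filled"


def _split_class(e: EquivalenceClass, state: BuilderState) -> list[EquivalenceClass]:
    """Split an over-wide class along its ECS children.

    The current members are reassigned greedily: each goes to the child
    minimizing the post-insertion loss among children with quota left
    for its source bucket (or either child when both quotas are spent).
    """
    assert e.ecs_node.children is not None
    children = [
        EquivalenceClass(
            eqc_id=f"{e.eqc_id}.{tag}", ecs_node=node, quota=node.virtual_buckets
        )
        for tag, node in zip("ab", e.ecs_node.children)
    ]
    for cid, b in e.members:
        open_children = [
            c for c in children if b < c.quota.size and c.taken[b] < c.quota[b]
        ] or children
        was_dropped = cid in e.dropped
        best = min(
            open_children,
            key=lambda c: (np.inf if was_dropped else _post_glm(c, cid, state), c.eqc_id),
        )
        _insert(best, cid, b, state, dropped=was_dropped)
    return children


def data_distribution_phase(state: BuilderState) -> BuilderState:
    """Fill the prepared classes from the buckets (Phase 1)."""
    queue = state.unmarked
    state.unmarked = deque()
    while queue:
        if not any(state.remaining):
            state.unmarked.extend(queue)
            break
        e = queue.popleft()
        outcome = _fill_class(e, state)
        if outcome == "split":
            children = _split_class(e, state)
            queue.extendleft(reversed(children))
            continue
        if _meets_target(e, state.params.k):
            e.marked = True
            state.marked.append(e)
        else:
            state.unmarked.append(e)
    # Buckets ran dry: mark what reached >= k live members anyway (in
    # proportional mode only if its takes stayed within +-1 of quota).
    still = deque()
    for e in state.unmarked:
        ok = (
            e.n_live >= state.params.k
            if state.params.greedy
            else _proportional_ok(e, state.params.k)
        )
        if not any(state.remaining) and ok:
            e.marked = True
            state.marked.append(e)
        else:
            still.append(e)
    state.unmarked = still
    return state


# ---------------------------------------------------------------------------
# Phase 2: unmarked redistribution
# ---------------------------------------------------------------------------

def _promote(state: BuilderState) -> None:
    """Move unmarked classes that now satisfy k-anonymity to marked."""
    still = deque()
    for e in state.unmarked:
        if e.n_live >= state.params.k:
            e.marked = True
            state.marked.append(e)
        else:
            still.append(e)
    state.unmarked = still


def unmarked_redistribution(state: BuilderState) -> BuilderState:
    """Dissolve the smallest unmarked class into the other unmarked
    classes (greedy min-loss, max-cost constraint active) until all are
    marked or an iteration adds no data."""
    p = state.params
    while True:
        # Empty classes hold no data; discard them outright.
        state.unmarked = deque(e for e in state.unmarked if e.total > 0)
        if len(state.unmarked) < 2:
            break
        donor = min(state.unmarked, key=lambda e: (e.total, e.eqc_id))
        state.unmarked.remove(donor)
        placed = 0
        for cid, b in sorted(donor.members):
            best, best_g = None, None
            for r in state.unmarked:
                g = _post_glm(r, cid, state)
                if g > p.max_cost_effective:
                    continue
                if best_g is None or (g, r.eqc_id) < (best_g, best.eqc_id):
                    best, best_g = r, g
            if best is not None:
                _insert(best, cid, b, state, dropped=False)
                placed += 1
            else:
                state.remaining[b].append(cid)
                state.remaining[b].sort()
        if placed == 0:
            # Nothing was added in a whole iteration: restore and stop.
            for cid, b in donor.members:
                state.remaining[b].remove(cid)
            state.unmarked.append(donor)
            break
        _promote(state)
        if not state.unmarked:
            break
    return state


# ---------------------------------------------------------------------------
# Phases 3 & 4: marked redistribution
# ---------------------------------------------------------------------------

def marked_redistribution(state: BuilderState, constrain: str) -> BuilderState:
    """Dissolve the remaining unmarked classes into the marked ones.

    CONSTRAINED keeps the maximum-cost constraint; members that fit
    nowhere stay in their class for the relaxed pass. RELAXED waives the
    cost constraint (classes are no longer split) but keeps the drop
    threshold ``d``: over-costly members are inserted as dropped, so the
    unmarked queue always empties.
    """
    if constrain not in (CONSTRAINED, RELAXED):
        raise ValueError(f"unknown constrain flag {constrain!r}")
    p = state.params
    donors = sorted(state.unmarked, key=lambda e: (e.total, e.eqc_id))
    state.unmarked = deque()
    for donor in donors:
        kept: list[tuple[str, int]] = []
        for cid, b in sorted(donor.members):
            best, best_g = None, None
            for r in state.marked:
                g = _post_glm(r, cid, state)
                if constrain == CONSTRAINED and g > p.max_cost_effective:
                    continue
                if best_g is None or (g, r.eqc_id) < (best_g, best.eqc_id):
                    best, best_g = r, g
            if best is not None:
                _insert(best, cid, b, state, dropped=best_g > p.d)
            else:
                kept.append((cid, b))
        if kept:
            if constrain == CONSTRAINED:
                donor.members = kept
                donor.dropped = {cid for cid in donor.dropped if cid in {c for c, _ in kept}}
                state.unmarked.append(donor)
            else:
                # No marked class exists at all: nothing is releasable.
                state.unanonymizable.extend(sorted(cid for cid, _ in kept))
    if constrain == RELAXED:
        for b, ids in enumerate(state.remaining):
            for cid in list(ids):
                best, best_g = None, None
                for r in state.marked:
                    g = _post_glm(r, cid, state)
                    if best_g is None or (g, r.eqc_id) < (best_g, best.eqc_id):
                        best, best_g = r, g
                if best is not None:
                    _insert(best, cid, b, state, dropped=best_g > p.d)
                else:
                    state.unanonymizable.append(cid)
                ids.remove(cid)
    return state


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def run_phases(state: BuilderState) -> BuilderState:
    data_distribution_phase(state)
    if state.unmarked:
        unmarked_redistribution(state)
    if state.unmarked:
        marked_redistribution(state, CONSTRAINED)
    if state.unmarked or any(state.remaining):
        marked_redistribution(state, RELAXED)
    return state


def _segment_report(state: BuilderState, segment: Segment) -> SegmentReport:
    p = state.params
    histograms = []
    classes = sorted(state.marked, key=lambda e: e.eqc_id)
    for e in classes:
        histograms.append(
            eqc_histogram(e.live_ids, state.distribution, state.ref_dist, state.dm.ids)
        )
    per_t, _ = exact_t(histograms, state.distribution.counts, state.ground)
    reports = []
    for e, t_ex in zip(classes, per_t):
        live_curves = [state.cs.get(cid) for cid in e.live_ids]
        hull = build_hull(
            live_curves, p.hull_resolution, segment.interval, p.interpolation
        )
        glm = glm_info_loss(hull, state.value_domain, len(live_curves))
        mre = median_relative_error(live_curves, hull, p.interpolation)
        reports.append(
            ClassReport(
                class_id=f"s{segment.index}:{e.eqc_id}",
                member_ids=sorted(cid for cid, _ in e.members),
                dropped_ids=sorted(e.dropped),
                glm=glm,
                mre=mre,
                t_exact=t_ex,
                t_bound=state.t_bound.t,
                hull=hull,
            )
        )
    return SegmentReport(
        index=segment.index,
        interval=segment.interval,
        classes=reports,
        unanonymized_ids=sorted(state.unanonymizable),
    )


def anonymize(
    cs: CurveSet,
    params: Params,
    population: Optional[CurveSet] = None,
) -> AnonymizationResult:
    """Run the full pipeline: split, then anonymize each segment
    independently (the semi-local decision), then aggregate the report.

    Raises :class:`InfeasibleAnonymizationError` when the dataset is
    smaller than ``k`` or a segment yields no releasable class.
    """
    if len(cs) < params.k:
        raise InfeasibleAnonymizationError(
            f"database too small: {len(cs)} curves cannot satisfy k={params.k}"
        )
    segments = split_dataset(cs, params.split)
    value_domain = cs.value_domain
    seg_reports = []
    for seg in segments:
        pop_seg = None
        if population is not None:
            pop_seg = restrict_curveset(population, *seg.interval)
        state = prepare(
            seg.curves,
            params,
            population=pop_seg,
            value_domain=value_domain,
            interval=seg.interval,
        )
        run_phases(state)
        if not state.marked:
            raise InfeasibleAnonymizationError(
                f"no releasable equivalence class in segment {seg.index}; "
                f"the dataset cannot be anonymized under these constraints"
            )
        seg_reports.append(_segment_report(state, seg))
    return evaluation_report(seg_reports, params.hull_resolution, params.to_dict())
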