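"""Anonymization trees: Bucket Trees and Equivalence Class Size Trees.

A Bucket Tree recursively partitions the dataset into similarity
buckets; selecting all nodes at one depth yields a bucketization with an
implicit maximum cost (the largest bucket error at that depth), instead
of asking the user for an explicit cost bound. The Equivalence Class
Size (ECS) Tree splits the vector of bucket sizes into per-class,
per-bucket quotas that preserve the population proportions, so that
classes filled to quota stay t-close by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import CurveValidationError, InfeasibleAnonymizationError
from .metrics import DistanceMatrix


# ---------------------------------------------------------------------------
# Bucket Tree
# ---------------------------------------------------------------------------

@dataclass
class BucketNode:
    """A similarity bucket: members, a reference curve and a max error."""

    member_ids: tuple[str, ...]
    reference_id: str
    err: float
    depth: int
    children: Optional[tuple["BucketNode", "BucketNode"]] = None

    @property
    def n(self) -> int:
        return len(self.member_ids)

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "reference_id": self.reference_id,
            "err": self.err,
            "member_ids": list(self.member_ids),
        }
        if self.children:
            out["children"] = [c.to_dict() for c in self.children]
        return out


@dataclass
class BucketTree:
    """Fully balanced (up to ``usable_depth``) binary tree of buckets."""

    root: BucketNode
    f: float
    usable_depth: int

    def level(self, depth: int) -> list[BucketNode]:
        """All nodes at ``depth``; they partition the dataset for any
        depth up to ``usable_depth``."""
        nodes = [self.root]
        for _ in range(depth):
            nxt: list[BucketNode] = []
            for node in nodes:
                if node.children is None:
                    raise CurveValidationError(
                        f"branch ends above depth {depth}; tree usable depth is "
                        f"{self.usable_depth}"
                    )
                nxt.extend(node.children)
            nodes = nxt
        return nodes


def bucket_error(member_ids: Sequence[str], reference_id: str, dm: DistanceMatrix) -> float:
    """Maximum distance from the bucket reference to any member (0 for
    singletons). Every value drawn from a bucket is treated as its
    reference; this error is the worst-case misrepresentation."""
    return max((dm.dist(m, reference_id) for m in member_ids), default=0.0)


def _farthest_pair(members: list[str], dm: DistanceMatrix) -> tuple[str, str]:
    """Mutually farthest member pair; ties toward the ascending-id pair."""
    best = None
    best_d = -1.0
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            d = dm.dist(a, b)
            if d > best_d:
                best_d = d
                best = (a, b)
    assert best is not None
    return best


def _split_members(
    members: list[str], dm: DistanceMatrix, f: float
) -> tuple[list[str], list[str], str, str]:
    """Split a bucket by farthest-pair seeding with margin rebalancing.

    The two mutually farthest members seed the children; every other
    member joins the nearer seed (ties toward the smaller-id seed). Each
    child must then hold at least ``ceil(f * n)`` members; the members
    with the smallest assignment margin (least committed to their seed)
    are moved from the larger child until the constraint holds.
    """
    n = len(members)
    seed_a, seed_b = _farthest_pair(members, dm)
    if seed_b < seed_a:
        seed_a, seed_b = seed_b, seed_a
    group_a, group_b = [seed_a], [seed_b]
    margins: dict[str, float] = {}
    for m in sorted(members):
        if m in (seed_a, seed_b):
            continue
        da, db = dm.dist(m, seed_a), dm.dist(m, seed_b)
        if da <= db:
            group_a.append(m)
        else:
            group_b.append(m)
        margins[m] = abs(db - da)
    # Minimum child fraction f, capped at the most balanced integral split.
    min_size = min(int(np.ceil(f * n)), n // 2)

    def rebalance(src: list[str], dst: list[str], seed_src: str) -> None:
        movable = sorted(
            (m for m in src if m != seed_src), key=lambda m: (margins[m], m)
        )
        while len(dst) < min_size and movable:
            m = movable.pop(0)
            src.remove(m)
            dst.append(m)

    if len(group_a) < min_size:
        rebalance(group_b, group_a, seed_b)
    elif len(group_b) < min_size:
        rebalance(group_a, group_b, seed_a)
    return sorted(group_a), sorted(group_b), seed_a, seed_b


def build_bucket_tree(dm: DistanceMatrix, f: float) -> BucketTree:
    """Build a Bucket Tree over all curves of a distance matrix.

    Every node of size >= 2 is split recursively; recursion stops at
    singletons. The balancing factor ``f`` (0 < f <= 0.5) is the minimum
    child fraction: a perfectly balanced tree (f = 0.5) rarely fits the
    data, while a small f can leave the tree too shallow to represent a
    complex distribution. ``usable_depth`` is the minimum leaf depth —
    the deepest level on which the node set still partitions the data.
    """
    if not (0 < f <= 0.5):
        raise ValueError("balancing factor f must satisfy 0 < f <= 0.5")
    if not dm.ids:
        raise CurveValidationError("cannot build a bucket tree over an empty set")

    def build(members: list[str], reference: str, depth: int) -> BucketNode:
        node = BucketNode(
            member_ids=tuple(members),
            reference_id=reference,
            err=bucket_error(members, reference, dm),
            depth=depth,
        )
        if len(members) >= 2:
            left, right, seed_a, seed_b = _split_members(members, dm, f)
            node.children = (
                build(left, seed_a, depth + 1),
                build(right, seed_b, depth + 1),
            )
        return node

    ids = sorted(dm.ids)
    root = build(ids, ids[0], 0)

    def min_leaf_depth(node: BucketNode) -> int:
        if node.children is None:
            return node.depth
        return min(min_leaf_depth(c) for c in node.children)

    return BucketTree(root, f, min_leaf_depth(root))


def select_buckets(tree: BucketTree, depth_b: int) -> list[BucketNode]:
    """The ``2**depth_b`` buckets at the chosen depth."""
    if depth_b < 0 or depth_b > tree.usable_depth:
        raise CurveValidationError(
            f"depth {depth_b} not usable; the tree is fully balanced up to "
            f"depth {tree.usable_depth}"
        )
    return tree.level(depth_b)


# ---------------------------------------------------------------------------
# Equivalence Class Size Tree
# ---------------------------------------------------------------------------

@dataclass
class ECSNode:
    """Virtual-bucket target counts for one (potential) equivalence class."""

    virtual_buckets: np.ndarray
    children: Optional[tuple["ECSNode", "ECSNode"]] = None

    def __post_init__(self) -> None:
        self.virtual_buckets = np.asarray(self.virtual_buckets, dtype=int)

    @property
    def target_size(self) -> int:
        return int(self.virtual_buckets.sum())

    def to_dict(self) -> dict:
        out = {"virtual_buckets": self.virtual_buckets.tolist()}
        if self.children:
            out["children"] = [c.to_dict() for c in self.children]
        return out


@dataclass
class ECSTree:
    root: ECSNode

    def leaves(self) -> list[ECSNode]:
        out: list[ECSNode] = []

        def walk(node: ECSNode) -> None:
            if node.children is None:
                out.append(node)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out


def _largest_remainder(vec: np.ndarray, target: int) -> np.ndarray:
    """Integer apportionment of ``target`` over ``vec`` proportions."""
    total = vec.sum()
    ideal = vec * (target / total)
    base = np.floor(ideal).astype(int)
    short = target - int(base.sum())
    # Largest remainders first; ties toward the lower bucket index.
    order = sorted(range(vec.size), key=lambda i: (-(ideal[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def build_ecs_tree(bucket_sizes: Sequence[int], k: int) -> ECSTree:
    """Recursively halve the bucket-size vector into class quotas.

    Each node's target size is split into two near-equal halves; the
    per-bucket counts are apportioned by largest remainder to preserve
    the population proportions. Splitting stops once a virtual bucket is
    down to one element or a child's target size would drop below ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sizes = np.asarray(list(bucket_sizes), dtype=int)
    if sizes.sum() < k:
        raise InfeasibleAnonymizationError(
            f"database too small: {int(sizes.sum())} curves cannot fill an "
            f"equivalence class of size k={k}"
        )

    def build(vec: np.ndarray) -> ECSNode:
        node = ECSNode(vec)
        s = node.target_size
        if np.any(vec == 1) or s // 2 < k:
            return node
        size_hi = s - s // 2
        child_a = _largest_remainder(vec, size_hi)
        child_b = vec - child_a
        if np.any(child_b < 0):  # pragma: no cover - apportionment guard
            raise RuntimeError("apportionment produced a negative quota")
        node.children = (build(child_a), build(child_b))
        return node

    return ECSTree(build(sizes))


# ---------------------------------------------------------------------------
# Implied t bound
# ---------------------------------------------------------------------------

@dataclass
class TBound:
    """Over-approximation of the achievable t, from bucket errors.

    ``err(eqc) = sum_j err_j * p_j`` where ``p_j`` is a bucket's share of
    the dataset; classes filled proportionally from the buckets cannot be
    farther than this from the population, so the released t can safely
    be set to the maximum over classes.
    """

    per_eqc: list[float]
    t: float
    p: np.ndarray


def estimate_t(
    leaves: Sequence[ECSNode],
    buckets: Sequence[BucketNode],
    normalizer: float = 1.0,
) -> TBound:
    sizes = np.array([b.n for b in buckets], dtype=float)
    p = sizes / sizes.sum()
    errs = np.array([b.err for b in buckets], dtype=float)
    bound = float(np.dot(errs, p) / normalizer)
    per_eqc = [bound for _ in leaves]
    return TBound(per_eqc=per_eqc, t=max(per_eqc, default=bound), p=p)
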