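"""Distribution clustering: a surrogate population distribution.

Without clustering, every curve in a population would be its own
distribution bin and the population distribution would be uniform.
Curves are therefore grouped into clusters of similar curves, each
identified by a reference curve (the first member added). A cluster of
``n`` members contributes ``n`` occurrences of its reference to the
distribution. t-closeness is then measured between the cluster histogram
of an equivalence class and that of the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CurveValidationError
from .metrics import DistanceMatrix


@dataclass
class Cluster:
    """A set of similar curves identified by a reference curve."""

    reference_id: str
    member_ids: list[str]

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass
class Distribution:
    """A clustering of a curve population into similarity clusters.

    ``s_d`` is the distribution sensitivity: the Fréchet-distance
    threshold within which curves join an existing cluster. ``source``
    records whether the distribution was built on the anonymization set
    itself or on separate (larger) population data.
    """

    clusters: list[Cluster]
    s_d: float
    source: str = "self"

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clusters], dtype=float)

    @property
    def reference_ids(self) -> list[str]:
        return [c.reference_id for c in self.clusters]

    @property
    def total(self) -> int:
        return sum(c.count for c in self.clusters)

    def to_dict(self) -> dict:
        return {
            "s_d": self.s_d,
            "source": self.source,
            "clusters": [
                {"reference_id": c.reference_id, "member_ids": list(c.member_ids)}
                for c in self.clusters
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Distribution":
        return cls(
            clusters=[
                Cluster(c["reference_id"], list(c["member_ids"]))
                for c in data["clusters"]
            ],
            s_d=float(data["s_d"]),
            source=str(data.get("source", "external")),
        )


def cluster_distribution(dm: DistanceMatrix, s_d: float) -> Distribution:
    """Greedy single-pass clustering with threshold ``s_d``.

    Curves are scanned in ascending id order. Each curve joins the first
    existing cluster whose reference is within ``s_d``, else founds a new
    cluster with itself as reference. Singleton clusters are then merged
    away (:func:`merge_singletons`), because a single-member cluster
    forces either merged equivalence classes or a large t.
    """
    if s_d < 0:
        raise ValueError("distribution sensitivity s_d must be non-negative")
    if not dm.ids:
        raise CurveValidationError("cannot cluster an empty curve set")
    clusters: list[Cluster] = []
    for cid in sorted(dm.ids):
        for cl in clusters:
            if dm.dist(cid, cl.reference_id) <= s_d:
                cl.member_ids.append(cid)
                break
        else:
            clusters.append(Cluster(cid, [cid]))
    return merge_singletons(Distribution(clusters, s_d, "self"), dm)


def merge_singletons(dist: Distribution, dm: DistanceMatrix) -> Distribution:
    """Merge size-1 clusters into the cluster with the nearest reference.

    Iterated to a fixed point; merging only grows clusters, so one pass
    over the singletons terminates. Post-merge members may exceed the
    ``s_d`` bound: the merge rule overrides the threshold. A population
    of only singletons collapses into the cluster with the smallest
    reference id. A single-curve population stays a singleton (there is
    nothing to merge with).
    """
    clusters = [replace(c, member_ids=list(c.member_ids)) for c in dist.clusters]
    while True:
        singleton_idx = next(
            (i for i, c in enumerate(clusters) if c.count == 1 and len(clusters) > 1),
            None,
        )
        if singleton_idx is None:
            break
        lone = clusters.pop(singleton_idx)
        best = min(
            range(len(clusters)),
            key=lambda i: (dm.dist(lone.reference_id, clusters[i].reference_id), i),
        )
        clusters[best].member_ids.extend(lone.member_ids)
    return Distribution(clusters, dist.s_d, dist.source)


def attribute_members(
    member_ids: list[str],
    dist: Distribution,
    ref_dist: np.ndarray,
    all_ids: tuple[str, ...],
) -> np.ndarray:
    """Cluster index per member, by nearest reference (ties: lower index).

    ``ref_dist`` is the (n_curves, n_clusters) matrix of distances from
    every curve to every cluster reference, indexed by ``all_ids``.
    """
    if not member_ids:
        raise CurveValidationError("cannot attribute an empty member set")
    order = {cid: i for i, cid in enumerate(all_ids)}
    rows = np.array([order[m] for m in member_ids])
    return np.argmin(ref_dist[rows], axis=1)


def eqc_histogram(
    member_ids: list[str],
    dist: Distribution,
    ref_dist: np.ndarray,
    all_ids: tuple[str, ...],
) -> np.ndarray:
    """Histogram of an equivalence class over the distribution's clusters."""
    labels = attribute_members(member_ids, dist, ref_dist, all_ids)
    return np.bincount(labels, minlength=len(dist.clusters)).astype(float)


def reference_ground(
    dist: Distribution,
    ref_pair_dist: np.ndarray,
    normalize: bool = True,
) -> tuple[np.ndarray, float]:
    """Ground-distance matrix between cluster references and its normalizer.

    When ``normalize`` is on, distances are scaled by the maximum pairwise
    reference distance so t lands in [0, 1]; the normalizer is returned
    for use on the estimated bound as well. A single-cluster population
    has no pairs; its normalizer is 1 (t is 0 regardless).
    """
    ground = np.asarray(ref_pair_dist, dtype=float)
    if ground.shape != (len(dist.clusters), len(dist.clusters)):
        raise ValueError("reference distance matrix shape mismatch")
    normalizer = float(ground.max()) if ground.size > 1 else 0.0
    if normalizer <= 0:
        normalizer = 1.0
    if normalize:
        return ground / normalizer, normalizer
    return ground, 1.0
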