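"""Block-based k-medoids partitioning (BlockD-KM).

Initial medoids are chosen deterministically from the data itself rather
than at random: objects are ordered by the sample standard deviation of
their own p values (ties broken by the row sum, then by original index),
the ordering is cut into blocks of exactly equal deviations, and the first
object of each of the first k blocks seeds the k clusters.  The partition
is then refined by alternating two steps until the medoid set is stable:

1. assign every object to its nearest medoid;
2. in each cluster, move the medoid to the member with the smallest
   average distance to its co-members.

The algorithm is seed-free: every tie (sorting, assignment, medoid update)
is broken by the lowest index, so a given table and distance always yield
the same partition.  The quantity tracked per iteration is SDW(k), the sum
of distances from all objects to their own cluster's medoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import FeatureTable
from .proximity import DistanceSpec, pairwise_distances

__all__ = ["BlockOrdering", "ClusteringResult", "row_stats",
           "initial_medoids", "assign", "update_medoids", "fit"]


@dataclass(frozen=True)
class BlockOrdering:
    """Per-object row statistics and the block structure built from them.

    ``order`` lists 0-based object indices sorted ascending by (u, w,
    index); ``blocks`` partitions that ordering into maximal runs of
    exactly equal u.
    """

    u: np.ndarray  # per-object sample std dev across the p variables
    w: np.ndarray  # per-object row sum
    order: tuple[int, ...]
    blocks: tuple[tuple[int, ...], ...]


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of one BlockD-KM run at a fixed k.

    ``labels`` assigns each object to a cluster 1..k; cluster g is the one
    whose medoid is ``medoids[g-1]`` (0-based object index).  ``sdw_history``
    records SDW(k) after the initial assignment and after each reassignment.
    """

    labels: np.ndarray
    medoids: tuple[int, ...]
    sdw_history: tuple[float, ...]
    iterations: int
    converged: bool
    medoid_ids: tuple[str, ...] = field(default=())

    @property
    def k(self) -> int:
        return len(self.medoids)

    @property
    def sdw(self) -> float:
        return self.sdw_history[-1]

    def cluster_members(self, g: int) -> np.ndarray:
        """0-based object indices of cluster g (1-based)."""
        return np.flatnonzero(self.labels == g)


def row_stats(table: FeatureTable) -> BlockOrdering:
    """Row sums, row standard deviations, and the induced block ordering."""
    if table.p < 2:
        raise ValueError("row standard deviation needs p >= 2 variables")
    x = table.values
    w = x.sum(axis=1)
    u = x.std(axis=1, ddof=1)
    n = table.n
    order = np.lexsort((np.arange(n), w, u))
    blocks: list[tuple[int, ...]] = []
    current: list[int] = []
    for pos, idx in enumerate(order):
        if current and u[idx] != u[order[pos - 1]]:
            blocks.append(tuple(current))
            current = []
        current.append(int(idx))
    blocks.append(tuple(current))
    return BlockOrdering(u=u, w=w, order=tuple(int(i) for i in order),
                         blocks=tuple(blocks))


def initial_medoids(ordering: BlockOrdering, k: int) -> tuple[int, ...]:
    """First object of each of the first k blocks.

    When fewer than k distinct-deviation blocks exist the choice falls back
    to the first k objects of the full (u, w, index) ordering.
    """
    n = len(ordering.order)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if len(ordering.blocks) >= k:
        return tuple(block[0] for block in ordering.blocks[:k])
    return tuple(ordering.order[:k])


def _assign_from_matrix(dist: np.ndarray, medoids) -> np.ndarray:
    medoids = np.asarray(medoids)
    # argmin returns the first minimiser, i.e. the lowest medoid position
    labels = dist[:, medoids].argmin(axis=1) + 1
    # a medoid always heads its own cluster, even when another medoid is an
    # identical row (possible with categorical data); without this pin a
    # zero-distance tie would empty the higher-position cluster
    labels[medoids] = np.arange(1, medoids.size + 1)
    return labels


def assign(table: FeatureTable, medoids, spec: DistanceSpec) -> np.ndarray:
    """Label each object 1..k by its nearest medoid (ties: lowest medoid
    position; each medoid belongs to its own cluster)."""
    from .proximity import distances_to_medoids

    md = distances_to_medoids(table, medoids, spec)
    labels = md.matrix.argmin(axis=1) + 1
    labels[np.asarray(md.medoids)] = np.arange(1, md.k + 1)
    return labels


def _update_from_matrix(dist: np.ndarray, labels: np.ndarray, k: int
                        ) -> tuple[int, ...]:
    new = []
    for g in range(1, k + 1):
        members = np.flatnonzero(labels == g)
        if members.size == 0:
            raise ValueError(f"cluster {g} is empty")
        sub = dist[np.ix_(members, members)]
        # mean over n_g includes the zero self-distance; the argmin is the
        # same as for the mean over co-members, and ties fall to the lowest
        # original index because `members` is sorted
        new.append(int(members[sub.mean(axis=1).argmin()]))
    return tuple(new)


def update_medoids(table: FeatureTable, labels, spec: DistanceSpec
                   ) -> tuple[int, ...]:
    """Per cluster, the member minimizing the average distance to the
    cluster's members."""
    labels = np.asarray(labels)
    dist = pairwise_distances(table, spec)
    return _update_from_matrix(dist, labels, int(labels.max()))


def fit(
    table: FeatureTable,
    k: int,
    spec: DistanceSpec | None = None,
    max_iter: int = 100,
    dist: np.ndarray | None = None,
) -> ClusteringResult:
    """Run BlockD-KM to convergence.

    Stops when the medoid set no longer changes, or when SDW(k) exactly
    repeats the previous value, or after ``max_iter`` refinement rounds
    (the last case sets ``converged=False`` and emits a warning).  A
    precomputed pairwise matrix may be passed via ``dist`` to avoid
    recomputation across k values.
    """
    spec = spec or DistanceSpec()
    n = table.n
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside 2..{n}")
    if dist is None:
        dist = pairwise_distances(table, spec)

    medoids = initial_medoids(row_stats(table), k)
    labels = _assign_from_matrix(dist, medoids)

    def sdw_of(labels: np.ndarray, medoids) -> float:
        med = np.asarray(medoids)
        return float(dist[np.arange(n), med[labels - 1]].sum())

    history = [sdw_of(labels, medoids)]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new_medoids = _update_from_matrix(dist, labels, k)
        if set(new_medoids) == set(medoids):
            converged = True
            break
        medoids = new_medoids
        labels = _assign_from_matrix(dist, medoids)
        history.append(sdw_of(labels, medoids))
        if history[-1] == history[-2]:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"BlockD-KM did not converge in {max_iter} iterations (k={k})",
            RuntimeWarning,
            stacklevel=2,
        )
    return ClusteringResult(
        labels=labels,
        medoids=tuple(medoids),
        sdw_history=tuple(history),
        iterations=iterations,
        converged=converged,
        medoid_ids=tuple(table.objects[i] for i in medoids),
    )
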