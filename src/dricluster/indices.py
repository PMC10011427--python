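"""Cluster-number selection criteria.

The centrepiece is the deviation ratio index (DRI), computed from the
n x k matrix of object-to-final-medoid distances produced by a k-medoids
run:

* SDW(k) — sum over all objects of the distance to their own cluster's
  medoid (within-group deviation);
* SDB(k) — sum over all objects of their distances to the k-1 medoids of
  the *other* clusters (between-group deviation);
* DR(k)  = (SDW(k)/(n-k)) / (SDB(k)/(k-1)), small when clusters are
  compact and well separated;
* DRI(k) = DR(k)/DR(k+1).

The number of clusters chosen is the smallest k with DRI(k) < 1: adding a
cluster beyond that point no longer improves the deviation ratio.  The
index is undefined at k=1 (no other group to deviate from).

Comparator criteria are also provided: the distance-based variance ratio
criterion (VRC, the Calinski-Harabasz index generalized to arbitrary
dissimilarities), the mean silhouette width, the medoid-based shadow value
(MSV), and external clustering accuracy under optimal one-to-one label
matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .blockdkm import ClusteringResult, fit
from .dataset import FeatureTable
from .proximity import DistanceSpec, MedoidDistances, pairwise_distances

__all__ = [
    "IndexCurve",
    "KSelection",
    "sdw",
    "sdb",
    "deviation_ratio",
    "dri_curve",
    "select_k",
    "vrc",
    "silhouette",
    "msv",
    "clustering_accuracy",
]


def _check_labels(md: MedoidDistances, labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (md.n,):
        raise ValueError("labels length inconsistent with distance matrix")
    if labels.min() < 1 or labels.max() > md.k:
        raise ValueError(f"labels outside 1..{md.k}")
    return labels


def sdw(md: MedoidDistances, labels) -> float:
    """Within-group deviation: each object's distance to its own medoid,
    summed."""
    labels = _check_labels(md, labels)
    return float(md.matrix[np.arange(md.n), labels - 1].sum())


def sdb(md: MedoidDistances, labels) -> float:
    """Between-group deviation: each object's distances to the k-1 medoids
    of the other clusters, summed over objects and medoids."""
    labels = _check_labels(md, labels)
    if md.k < 2:
        raise ValueError("SDB needs k >= 2 (no other groups at k=1)")
    return float(md.matrix.sum() - md.matrix[np.arange(md.n), labels - 1].sum())


def deviation_ratio(sdw_val: float, sdb_val: float, n: int, k: int) -> float:
    """DR(k) = (SDW/(n-k)) / (SDB/(k-1))."""
    if not 2 <= k < n:
        raise ValueError(f"k={k} outside 2..{n - 1}")
    if sdb_val <= 0:
        raise ValueError(
            "SDB is zero: all objects coincide with all medoids; "
            "DR is undefined"
        )
    return (sdw_val / (n - k)) / (sdb_val / (k - 1))


@dataclass(frozen=True)
class IndexCurve:
    """Per-k record of the selection criteria over a scanned k range.

    Arrays are aligned with ``ks``; ``dri`` is NaN at the last k (DRI needs
    DR at k+1).  Comparator columns are NaN where not requested.
    """

    ks: tuple[int, ...]
    sdw: np.ndarray
    sdb: np.ndarray
    dr: np.ndarray
    dri: np.ndarray
    vrc: np.ndarray
    silhouette: np.ndarray
    msv: np.ndarray
    results: tuple[ClusteringResult, ...] = field(repr=False)

    def as_dict(self) -> dict[int, dict[str, float]]:
        out = {}
        for i, k in enumerate(self.ks):
            out[k] = {
                "sdw": float(self.sdw[i]),
                "sdb": float(self.sdb[i]),
                "dr": float(self.dr[i]),
                "dri": float(self.dri[i]),
                "vrc": float(self.vrc[i]),
                "silhouette": float(self.silhouette[i]),
                "msv": float(self.msv[i]),
            }
        return out


@dataclass(frozen=True)
class KSelection:
    """A chosen number of clusters under one selection rule.

    ``k`` is None when no k in the scanned range qualifies (reported, not
    silently coerced).
    """

    k: int | None
    rule: str
    curve: IndexCurve = field(repr=False)

    @property
    def found(self) -> bool:
        return self.k is not None


def dri_curve(
    table: FeatureTable,
    spec: DistanceSpec | None = None,
    k_min: int = 2,
    k_max: int = 10,
    early_stop: bool = False,
    compute_comparators: bool = True,
    max_iter: int = 100,
) -> IndexCurve:
    """Fit BlockD-KM for each k in [k_min, k_max] and tabulate the criteria.

    DR(k) is computed from each converged solution's medoid-distance
    matrix; DRI(k) = DR(k)/DR(k+1) wherever k+1 was scanned.  With
    ``early_stop`` the scan halts at the first k with DR(k) < DR(k+1)
    (i.e. DRI(k) < 1), which suffices for the smallest-k selection rule.
    """
    spec = spec or DistanceSpec()
    n = table.n
    if not 2 <= k_min <= k_max < n:
        raise ValueError(f"need 2 <= k_min <= k_max < n; got [{k_min}, {k_max}], n={n}")
    dist = pairwise_distances(table, spec)

    ks: list[int] = []
    results: list[ClusteringResult] = []
    sdw_vals: list[float] = []
    sdb_vals: list[float] = []
    dr_vals: list[float] = []
    vrc_vals: list[float] = []
    sil_vals: list[float] = []
    msv_vals: list[float] = []

    for k in range(k_min, k_max + 1):
        res = fit(table, k, spec, max_iter=max_iter, dist=dist)
        md = MedoidDistances(
            matrix=dist[:, np.asarray(res.medoids)], medoids=res.medoids
        )
        s_w = sdw(md, res.labels)
        s_b = sdb(md, res.labels)
        ks.append(k)
        results.append(res)
        sdw_vals.append(s_w)
        sdb_vals.append(s_b)
        dr_vals.append(deviation_ratio(s_w, s_b, n, k))
        if compute_comparators:
            vrc_vals.append(vrc(dist, res.labels))
            sil_vals.append(silhouette(dist, res.labels)[1])
            msv_vals.append(msv(md, res.labels)[1])
        else:
            vrc_vals.append(np.nan)
            sil_vals.append(np.nan)
            msv_vals.append(np.nan)
        if early_stop and len(dr_vals) >= 2 and dr_vals[-2] < dr_vals[-1]:
            break

    dr = np.array(dr_vals)
    dri = np.full(len(ks), np.nan)
    if len(ks) > 1:
        dri[:-1] = dr[:-1] / dr[1:]
    return IndexCurve(
        ks=tuple(ks),
        sdw=np.array(sdw_vals),
        sdb=np.array(sdb_vals),
        dr=dr,
        dri=dri,
        vrc=np.array(vrc_vals),
        silhouette=np.array(sil_vals),
        msv=np.array(msv_vals),
        results=tuple(results),
    )


def select_k(curve: IndexCurve, rule: str = "dri") -> KSelection:
    """Choose k from a scanned curve.

    ``dri``: smallest k with DRI(k) < 1 (None when no k qualifies);
    ``vrc`` / ``silhouette`` / ``msv``: the k maximizing the criterion.
    """
    if len(curve.ks) == 0:
        raise ValueError("empty curve")
    if rule == "dri":
        for i, k in enumerate(curve.ks):
            if np.isfinite(curve.dri[i]) and curve.dri[i] < 1.0:
                return KSelection(k=k, rule=rule, curve=curve)
        return KSelection(k=None, rule=rule, curve=curve)
    arrays = {"vrc": curve.vrc, "silhouette": curve.silhouette, "msv": curve.msv}
    if rule not in arrays:
        raise ValueError(f"unknown selection rule {rule!r}")
    arr = arrays[rule]
    if not np.isfinite(arr).any():
        return KSelection(k=None, rule=rule, curve=curve)
    return KSelection(k=curve.ks[int(np.nanargmax(arr))], rule=rule, curve=curve)


def vrc(dist_or_table, labels, spec: DistanceSpec | None = None,
        squared: bool = True) -> float:
    """Distance-based variance ratio criterion (Calinski-Harabasz).

    VRC = (BGSS/(k-1)) / (WGSS/(n-k)) with

        WGSS = 1/2 * sum_g (n_g - 1) * db_g,
        BGSS = 1/2 * ((k-1) * db + (n-k) * A_k),
        A_k  = 1/(n-k) * sum_g (n_g - 1) * (db - db_g),

    where db and db_g are the overall and within-group mean (squared, by
    default) pairwise dissimilarities.  ``squared=False`` uses raw
    distances instead, for dissimilarities whose square is not meaningful.
    """
    labels = np.asarray(labels, dtype=int)
    if isinstance(dist_or_table, FeatureTable):
        dist = pairwise_distances(dist_or_table, spec or DistanceSpec())
    else:
        dist = np.asarray(dist_or_table, dtype=float)
    n = dist.shape[0]
    ks = np.unique(labels)
    k = ks.size
    if k < 2:
        raise ValueError("VRC needs k >= 2")
    if n == k:
        raise ValueError("VRC undefined for n == k (zero denominator)")
    d = dist**2 if squared else dist

    def mean_pair(sub: np.ndarray) -> float:
        m = sub.shape[0]
        if m < 2:
            return 0.0
        iu = np.triu_indices(m, 1)
        return float(sub[iu].mean())

    db = mean_pair(d)
    wgss = 0.0
    a_sum = 0.0
    for g in ks:
        members = np.flatnonzero(labels == g)
        db_g = mean_pair(d[np.ix_(members, members)])
        wgss += (members.size - 1) * db_g
        a_sum += (members.size - 1) * (db - db_g)
    wgss *= 0.5
    a_k = a_sum / (n - k)
    bgss = 0.5 * ((k - 1) * db + (n - k) * a_k)
    if wgss == 0.0:
        return float("inf")  # perfect separation within groups
    return (bgss / (k - 1)) / (wgss / (n - k))


def silhouette(dist, labels) -> tuple[np.ndarray, float]:
    """Per-object silhouette widths s(i) and their mean.

    a(i) is the mean distance to co-members, b(i) the smallest mean
    distance to another cluster; s(i) = (b-a)/max(a,b).  Objects in
    singleton clusters get s(i) = 0.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = dist.shape[0]
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("silhouette needs k >= 2")
    members = {g: np.flatnonzero(labels == g) for g in groups}
    s = np.zeros(n)
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (own.size - 1)
        b = min(
            dist[i, members[g]].mean() for g in groups if g != labels[i]
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def msv(md: MedoidDistances, labels=None) -> tuple[np.ndarray, float]:
    """Medoid-based shadow values and their mean.

    msv(x) = (d(x, m') - d(x, m)) / d(x, m') with m the closest and m' the
    second-closest medoid; in [0, 1], 1 when x sits on its medoid, 0 when
    torn between two medoids (or coincident with both).
    """
    if md.k < 2:
        raise ValueError("MSV needs k >= 2")
    part = np.sort(md.matrix, axis=1)
    d1, d2 = part[:, 0], part[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(d2 > 0, (d2 - d1) / np.where(d2 > 0, d2, 1.0), 0.0)
    return vals, float(vals.mean())


def clustering_accuracy(labels, truth) -> float:
    """Fraction of objects correctly assigned under the best one-to-one
    mapping of predicted clusters onto true classes (Hungarian matching)."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape or labels.size == 0:
        raise ValueError("labels/truth must be equal-length and non-empty")
    pred_ids = np.unique(labels)
    true_ids = np.unique(truth)
    m = max(pred_ids.size, true_ids.size)
    contingency = np.zeros((m, m))
    for pi, p in enumerate(pred_ids):
        for ti, t in enumerate(true_ids):
            contingency[pi, ti] = np.sum((labels == p) & (truth == t))
    row, col = linear_sum_assignment(-contingency)
    return float(contingency[row, col].sum() / labels.size)
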