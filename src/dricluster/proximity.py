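"""Dissimilarity measures between object rows.

Four measures cover the data types the clustering front end accepts:

* Euclidean distance for numeric rows;
* Canberra distance for non-negative numeric rows (terms with both
  coordinates zero contribute 0);
* simple matching distance for categorical rows — one minus the fraction
  of variables on which two objects agree;
* a generalized distance function (GDF, a Gower-type measure) for mixed
  rows — a weighted sum of binary mismatches, categorical mismatches and
  absolute numeric differences on [0, 1]-standardized values, raised to a
  global exponent.  With the default weights (1, 1, 1, 1) it is a plain
  additive dissimilarity.

All functions are symmetric, non-negative, and zero on identical rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import CATEGORICAL_KINDS, FeatureTable

__all__ = [
    "DistanceSpec",
    "MedoidDistances",
    "euclidean",
    "canberra",
    "matching_distance",
    "gower",
    "pairwise_distances",
    "distances_to_medoids",
    "resolve_method",
]

METHODS = ("euclidean", "canberra", "matching", "gower")


@dataclass(frozen=True)
class DistanceSpec:
    """Which dissimilarity to use, and the GDF weights.

    ``weights`` = (alpha, beta, gamma, omega): alpha scales the binary
    term, beta the categorical term, gamma the numeric term, and omega is
    the exponent applied to the whole sum.  Defaults (1, 1, 1, 1).
    """

    method: str = "euclidean"
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.method not in METHODS + ("auto",):
            raise ValueError(f"unknown distance method {self.method!r}")
        if any(w < 0 for w in self.weights):
            raise ValueError("GDF weights must be non-negative")


@dataclass(frozen=True)
class MedoidDistances:
    """The n x k matrix of object-to-medoid distances.

    Column g holds the distance of every object to medoid g.  This is the
    only proximity structure the deviation-ratio index needs.
    """

    matrix: np.ndarray
    medoids: tuple[int, ...]  # 0-based object indices

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "medoids", tuple(int(i) for i in self.medoids))
        if m.ndim != 2 or m.shape[1] != len(self.medoids):
            raise ValueError("matrix shape inconsistent with medoid count")
        if (m < 0).any():
            raise ValueError("negative distance")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


def _check_lengths(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return x, y


def euclidean(x, y) -> float:
    """Root of the summed squared coordinate differences."""
    x, y = _check_lengths(x, y)
    return float(np.sqrt(((x - y) ** 2).sum()))


def canberra(x, y) -> float:
    """Sum of |x_l - y_l| / (|x_l| + |y_l|); 0/0 terms count as 0."""
    x, y = _check_lengths(x, y)
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(terms.sum())


def matching_distance(x, y) -> float:
    """One minus the fraction of variables on which the rows agree."""
    x, y = _check_lengths(x, y)
    return float(np.mean(x != y))


def gower(x, y, schema, spec: DistanceSpec | None = None) -> float:
    """Generalized distance for one pair of mixed rows.

    Numeric (and rank-scaled ordinal) parts must already lie in [0, 1]
    for the per-variable terms to be commensurate.
    """
    x, y = _check_lengths(x, y)
    if len(schema) != x.size:
        raise ValueError("schema/row length mismatch")
    spec = spec or DistanceSpec(method="gower")
    alpha, beta, gamma, omega = spec.weights
    d_bin = d_cat = d_num = 0.0
    for xl, yl, var in zip(x, y, schema):
        if var.kind == "binary":
            d_bin += var.weight * (xl != yl)
        elif var.kind == "nominal":
            d_cat += var.weight * (xl != yl)
        else:  # numeric or rank-scaled ordinal
            d_num += var.weight * abs(xl - yl)
    return float((alpha * d_bin + beta * d_cat + gamma * d_num) ** omega)


def resolve_method(table: FeatureTable, method: str = "auto") -> str:
    """Pick the distance for a table: Euclidean for all-numeric data,
    matching for all-categorical, GDF/Gower for mixed."""
    if method != "auto":
        return method
    if table.is_all_numeric():
        return "euclidean"
    if table.is_all_categorical():
        return "matching"
    return "gower"


def _gower_cross(
    a: np.ndarray, b: np.ndarray, table: FeatureTable, spec: DistanceSpec
) -> np.ndarray:
    alpha, beta, gamma, omega = spec.weights
    out = np.zeros((a.shape[0], b.shape[0]))
    for j, var in enumerate(table.schema):
        diff = a[:, j][:, None] - b[None, :, j]
        if var.kind == "binary":
            out += alpha * var.weight * (diff != 0)
        elif var.kind == "nominal":
            out += beta * var.weight * (diff != 0)
        else:
            out += gamma * var.weight * np.abs(diff)
    if omega != 1.0:
        out = out**omega
    return out


def _cross_distances(
    table: FeatureTable, rows_b: np.ndarray | None, spec: DistanceSpec
) -> np.ndarray:
    """Distances from every object to the rows indexed by ``rows_b``
    (all objects when None)."""
    a = table.values
    b = a if rows_b is None else a[rows_b]
    method = resolve_method(table, spec.method)
    if method == "euclidean":
        return cdist(a, b, metric="euclidean")
    if method == "canberra":
        # scipy's canberra already treats 0/0 terms as 0
        return cdist(a, b, metric="canberra")
    if method == "matching":
        return cdist(a, b, metric="hamming")
    return _gower_cross(a, b, table, spec)


def pairwise_distances(table: FeatureTable, spec: DistanceSpec) -> np.ndarray:
    """Full symmetric n x n dissimilarity matrix for a table."""
    d = _cross_distances(table, None, spec)
    np.fill_diagonal(d, 0.0)
    return d


def distances_to_medoids(
    table: FeatureTable, medoids, spec: DistanceSpec
) -> MedoidDistances:
    """The n x k matrix of distances from every object to each medoid.

    ``medoids`` are distinct 0-based object indices.
    """
    medoids = tuple(int(i) for i in medoids)
    n = table.n
    if len(set(medoids)) != len(medoids):
        raise ValueError("duplicate medoid indices")
    if any(i < 0 or i >= n for i in medoids):
        raise ValueError(f"medoid index outside 0..{n - 1}")
    matrix = _cross_distances(table, np.array(medoids), spec)
    return MedoidDistances(matrix=matrix, medoids=medoids)
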