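"""Standardization of numeric and ordinal columns before clustering.

Numeric columns are rescaled linearly to [0, 1] by subtracting the column
minimum and dividing by the range (min-max standardization).  Ordinal
columns carrying ranks 1..M are rescaled to [0, 1] via (r - 1)/(M - 1),
which spaces the M categories evenly.  Binary and nominal columns pass
through untouched — the distance layer compares them by match/mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import FeatureTable, ValidationError

__all__ = [
    "StandardizedTable",
    "minmax_column",
    "ordinal_standardize",
    "minmax_standardize",
    "standardize",
]


@dataclass(frozen=True)
class StandardizedTable(FeatureTable):
    """A FeatureTable whose transformed columns lie in [0, 1].

    ``provenance`` records per column how the values were obtained:
    "raw", "minmax" or "ordinal-rank".
    """

    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "provenance", tuple(self.provenance))
        super().__post_init__()
        if len(self.provenance) != self.p:
            raise ValidationError("provenance/column count mismatch")

    def _validate_columns(self, values: np.ndarray) -> None:
        # transformed columns live in [0, 1]; raw columns keep the
        # FeatureTable contract for their declared kind
        for j, var in enumerate(self.schema):
            col = values[:, j]
            if self.provenance[j] == "raw":
                self._validate_column(col, var)
            elif col.min() < 0 or col.max() > 1:
                raise ValidationError(
                    f"standardized column {var.name!r} outside [0, 1]"
                )


def minmax_column(col: np.ndarray, name: str = "") -> np.ndarray:
    """Rescale one numeric column to [0, 1]; constant columns are an error."""
    col = np.asarray(col, dtype=float)
    lo, hi = col.min(), col.max()
    if hi == lo:
        raise ValidationError(
            f"column {name!r} is constant (zero range); cannot min-max standardize"
        )
    return (col - lo) / (hi - lo)


def ordinal_standardize(ranks, M: int) -> np.ndarray:
    """Map integer ranks 1..M onto [0, 1] as (r - 1)/(M - 1)."""
    ranks = np.asarray(ranks, dtype=float)
    if M < 2:
        raise ValidationError("ordinal standardization needs M >= 2")
    if ranks.size and (ranks.min() < 1 or ranks.max() > M):
        raise ValidationError(f"rank outside 1..{M}")
    return (ranks - 1.0) / (M - 1.0)


def minmax_standardize(table: FeatureTable) -> StandardizedTable:
    """Min-max standardize numeric columns and rank-scale ordinal columns.

    Binary and nominal columns are carried through unchanged.
    """
    values = table.values.copy()
    provenance = []
    for j, var in enumerate(table.schema):
        if var.kind == "numeric":
            values[:, j] = minmax_column(values[:, j], var.name)
            provenance.append("minmax")
        elif var.kind == "ordinal":
            values[:, j] = ordinal_standardize(values[:, j], var.levels)
            provenance.append("ordinal-rank")
        else:
            provenance.append("raw")
    return StandardizedTable(
        objects=table.objects,
        values=values,
        schema=table.schema,
        provenance=tuple(provenance),
    )


def standardize(table: FeatureTable, policy: str = "minmax") -> FeatureTable:
    """Apply the requested standardization policy.

    ``minmax`` rescales numeric columns to [0, 1] and rank-scales ordinals;
    ``none`` leaves numeric columns alone but still rank-scales ordinal
    columns when the table is mixed, so that the generalized distance
    compares variables on commensurate [0, 1] scales.
    """
    if policy == "minmax":
        return minmax_standardize(table)
    if policy == "none":
        ordinal_cols = table.columns_of_kind("ordinal")
        if ordinal_cols and not table.is_all_categorical():
            values = table.values.copy()
            provenance = ["raw"] * table.p
            for j in ordinal_cols:
                values[:, j] = ordinal_standardize(
                    values[:, j], table.schema[j].levels
                )
                provenance[j] = "ordinal-rank"
            return StandardizedTable(
                objects=table.objects,
                values=values,
                schema=table.schema,
                provenance=tuple(provenance),
            )
        return table
    raise ValueError(f"unknown standardization policy {policy!r}")
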