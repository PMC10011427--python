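"""Data model for rectangular mixed-type tables.

A :class:`FeatureTable` holds n objects observed on p variables, each
variable declared as binary, nominal, ordinal (with its number of levels)
or numeric through a :class:`VariableSpec` schema.  Categorical values are
stored as numeric codes; binary columns must encode to {0, 1} and ordinal
columns carry integer ranks in 1..M.  Missing values are rejected at load
time: the dissimilarity layer is defined for complete data only.

The module also ships an embedded worked-example table: environmental
health scores (air quality, water & sanitation, heavy metals, waste
management) for 25 Asia-Pacific countries, min-max standardized to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "FeatureTable",
    "SchemaError",
    "ValidationError",
    "load_table",
    "load_schema",
    "save_table",
    "environment_fixture",
]

KINDS = ("binary", "nominal", "ordinal", "numeric")
CATEGORICAL_KINDS = ("binary", "nominal")


class SchemaError(ValueError):
    """Raised when a variable schema is malformed or inconsistent."""


class ValidationError(ValueError):
    """Raised when table values violate the schema contract."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one column: its name, measurement kind and weight.

    ``levels`` is the number of ordinal categories M (highest rank) and is
    required for ordinal variables only.  ``weight`` is the per-variable
    weight used by the generalized distance function; the default 1 gives
    every variable equal say.
    """

    name: str
    kind: str
    levels: int | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(
                f"unknown variable kind {self.kind!r} for {self.name!r}; "
                f"expected one of {KINDS}"
            )
        if self.kind == "ordinal":
            if self.levels is None or self.levels < 2:
                raise SchemaError(
                    f"ordinal variable {self.name!r} needs levels >= 2"
                )
        if self.weight < 0:
            raise SchemaError(f"negative weight for variable {self.name!r}")


@dataclass(frozen=True)
class FeatureTable:
    """An n x p table of values plus the per-column schema.

    ``objects`` are row identifiers (strings, e.g. country codes); all
    algorithmic indices are positional and are surfaced 1-based in
    user-facing reports.
    """

    objects: tuple[str, ...]
    values: np.ndarray
    schema: tuple[VariableSpec, ...] = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "objects", tuple(str(o) for o in self.objects))
        object.__setattr__(self, "schema", tuple(self.schema))
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, p = values.shape
        if n == 0:
            raise ValidationError("no objects")
        if len(self.objects) != n:
            raise ValidationError("objects/values row count mismatch")
        if len(self.schema) != p:
            raise ValidationError("schema/values column count mismatch")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at row {i + 1} ({self.objects[i]!r}), "
                f"column {self.schema[j].name!r}"
            )
        self._validate_columns(values)

    def _validate_columns(self, values: np.ndarray) -> None:
        for j, var in enumerate(self.schema):
            self._validate_column(values[:, j], var)

    @staticmethod
    def _validate_column(col: np.ndarray, var: VariableSpec) -> None:
        if var.kind == "binary":
            if not np.isin(col, (0.0, 1.0)).all():
                raise ValidationError(
                    f"binary column {var.name!r} contains values other than 0/1"
                )
        elif var.kind == "ordinal":
            if not np.array_equal(col, np.round(col)):
                raise ValidationError(
                    f"ordinal column {var.name!r} contains non-integer ranks"
                )
            if col.min() < 1 or col.max() > var.levels:
                raise ValidationError(
                    f"ordinal column {var.name!r} has ranks outside 1..{var.levels}"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.schema)

    def kinds(self) -> tuple[str, ...]:
        return tuple(v.kind for v in self.schema)

    def columns_of_kind(self, *kinds: str) -> list[int]:
        return [j for j, v in enumerate(self.schema) if v.kind in kinds]

    def is_all_numeric(self) -> bool:
        return all(v.kind == "numeric" for v in self.schema)

    def is_all_categorical(self) -> bool:
        return all(v.kind in CATEGORICAL_KINDS for v in self.schema)

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.objects), columns=list(self.column_names)
        )


def load_schema(schema_path: str | Path) -> tuple[VariableSpec, ...]:
    """Read a JSON schema file: a list of {name, kind, levels?, weight?}."""
    with open(schema_path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list) or not raw:
        raise SchemaError(f"{schema_path}: schema must be a non-empty list")
    specs = []
    for entry in raw:
        try:
            specs.append(
                VariableSpec(
                    name=entry["name"],
                    kind=entry["kind"],
                    levels=entry.get("levels"),
                    weight=entry.get("weight", 1.0),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{schema_path}: schema entry missing {exc}") from None
    return tuple(specs)


def load_table(csv_path: str | Path, schema_path: str | Path) -> FeatureTable:
    """Load a CSV (header row required) against a JSON schema.

    If the CSV's first column is not named in the schema it is taken as the
    row-identifier column; otherwise identifiers default to "1".."n".
    Any blank cell is a load error naming its row and column.
    """
    schema = load_schema(schema_path)
    df = pd.read_csv(csv_path, dtype=str, skipinitialspace=True)
    if df.shape[0] == 0:
        raise ValidationError(f"{csv_path}: no objects")
    names = {v.name for v in schema}
    if df.columns[0] not in names:
        objects = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    else:
        objects = [str(i + 1) for i in range(df.shape[0])]
    missing_cols = [v.name for v in schema if v.name not in df.columns]
    if missing_cols:
        raise SchemaError(f"{csv_path}: columns absent from CSV: {missing_cols}")
    df = df[[v.name for v in schema]]
    mask = df.isna() | (df == "")
    if mask.to_numpy().any():
        i, j = np.argwhere(mask.to_numpy())[0]
        raise ValidationError(
            f"{csv_path}: missing value at row {i + 1} ({objects[i]!r}), "
            f"column {df.columns[j]!r}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{csv_path}: non-numeric cell ({exc})") from None
    return FeatureTable(objects=tuple(objects), values=values, schema=schema)


def save_table(
    table: FeatureTable, csv_path: str | Path, schema_path: str | Path
) -> None:
    """Write a table back to CSV + JSON schema (round-trip exact)."""
    df = table.to_frame()
    df.insert(0, "id", list(table.objects))
    df.to_csv(csv_path, index=False)
    entries = []
    for v in table.schema:
        entry: dict = {"name": v.name, "kind": v.kind}
        if v.levels is not None:
            entry["levels"] = v.levels
        if v.weight != 1.0:
            entry["weight"] = v.weight
        entries.append(entry)
    with open(schema_path, "w") as fh:
        json.dump(entries, fh, indent=1)
        fh.write("\n")


def environment_fixture() -> FeatureTable:
    """The 25-country Asia-Pacific environmental-health table.

    Four min-max standardized scores per country — air quality (AQ), water
    and sanitation (WS), heavy metals (HM), waste management (WM) — carried
    at the 2-decimal precision of the published table.
    """
    pkg = resources.files("dricluster.data")
    with resources.as_file(pkg / "asia_pacific_env.csv") as csv_path, resources.as_file(
        pkg / "asia_pacific_env.schema.json"
    ) as schema_path:
        return load_table(csv_path, schema_path)
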