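"""Mixed-type table model: column declarations, schemas and conforming tables.

A clinical table mixes continuous measurements (blood pressure, cholesterol,
BMI, ...) with categorical diagnoses and demographics. The rest of the
pipeline — mode-specific normalization, the dual-pathway generator, the
fidelity metrics — is driven entirely by the :class:`TableSchema`, so the
schema is the single place where column kinds and category vocabularies are
declared.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ColumnKind",
    "ColumnSpec",
    "TableSchema",
    "DataTable",
    "load_column_config",
    "save_column_config",
]


class ColumnKind(str, enum.Enum):
    CONTINUOUS = "continuous"
    CATEGORICAL = "categorical"


@dataclass(frozen=True)
class ColumnSpec:
    """Declaration of a single column.

    Parameters
    ----------
    name
        Non-empty column identifier, unique within a schema.
    kind
        ``continuous`` or ``categorical``.
    categories
        Ordered category labels; required (non-empty) for categorical
        columns, forbidden for continuous ones.
    """

    name: str
    kind: ColumnKind
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("column name must be non-empty")
        kind = ColumnKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is ColumnKind.CATEGORICAL:
            if not self.categories:
                raise ValueError(
                    f"categorical column {self.name!r} needs >= 1 category"
                )
            cats = tuple(str(c) for c in self.categories)
            if len(set(cats)) != len(cats):
                raise ValueError(f"duplicate categories in column {self.name!r}")
            object.__setattr__(self, "categories", cats)
        else:
            if self.categories is not None:
                raise ValueError(
                    f"continuous column {self.name!r} must not declare categories"
                )

    @property
    def is_continuous(self) -> bool:
        return self.kind is ColumnKind.CONTINUOUS


@dataclass(frozen=True)
class TableSchema:
    """Ordered mixed-type column layout.

    ``k`` continuous plus ``l`` categorical columns, ``m = k + l`` total.
    """

    columns: tuple[ColumnSpec, ...]

    def __post_init__(self) -> None:
        cols = tuple(self.columns)
        if len(cols) < 1:
            raise ValueError("schema needs at least one column")
        names = [c.name for c in cols]
        if len(set(names)) != len(names):
            raise ValueError("column names must be unique")
        object.__setattr__(self, "columns", cols)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def continuous(self) -> list[ColumnSpec]:
        return [c for c in self.columns if c.is_continuous]

    @property
    def categorical(self) -> list[ColumnSpec]:
        return [c for c in self.columns if not c.is_continuous]

    @property
    def k(self) -> int:
        """Number of continuous columns."""
        return len(self.continuous)

    @property
    def l(self) -> int:
        """Number of categorical columns."""
        return len(self.categorical)

    @property
    def m(self) -> int:
        return len(self.columns)

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass
class DataTable:
    """A schema plus ``n`` conforming records, backed by a DataFrame.

    Validation enforces that categorical cells come from the declared
    vocabulary and continuous cells are finite numbers.
    """

    schema: TableSchema
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.frame.empty and len(self.frame.columns) == 0:
            self.frame = pd.DataFrame({c.name: [] for c in self.schema.columns})
        self.frame = self.frame.loc[:, self.schema.names].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for spec in self.schema.columns:
            col = self.frame[spec.name]
            if spec.is_continuous:
                vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
                if len(vals) and not np.all(np.isfinite(vals)):
                    raise ValueError(
                        f"non-finite or missing value in continuous column {spec.name!r}"
                    )
                self.frame[spec.name] = vals
            else:
                vals = col.astype(str)
                bad = set(vals) - set(spec.categories)
                if len(col) and bad:
                    raise ValueError(
                        f"unknown category {sorted(bad)!r} in column {spec.name!r}"
                    )
                self.frame[spec.name] = vals

    @property
    def n(self) -> int:
        return len(self.frame)

    def continuous_matrix(self) -> np.ndarray:
        """(n, k) float matrix of the continuous columns in schema order."""
        names = [c.name for c in self.schema.continuous]
        return self.frame[names].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, schema: TableSchema) -> "DataTable":
        frame = pd.read_csv(path)
        missing = set(schema.names) - set(frame.columns)
        if missing:
            raise ValueError(f"CSV is missing declared columns: {sorted(missing)}")
        return cls(schema=schema, frame=frame)

    @classmethod
    def from_records(
        cls, schema: TableSchema, records: Iterable[Mapping[str, object]]
    ) -> "DataTable":
        return cls(schema=schema, frame=pd.DataFrame(list(records)))


def schema_from_kinds(
    kinds: Mapping[str, str], frame: pd.DataFrame | None = None,
    categories: Mapping[str, Sequence[str]] | None = None,
) -> TableSchema:
    """Build a schema from a ``{name: kind}`` mapping.

    Category vocabularies are taken from ``categories`` when given, otherwise
    inferred as the sorted distinct labels observed in ``frame``.
    """
    cols = []
    for name, kind in kinds.items():
        if ColumnKind(kind) is ColumnKind.CATEGORICAL:
            if categories and name in categories:
                cats = tuple(categories[name])
            elif frame is not None:
                cats = tuple(sorted(frame[name].astype(str).unique()))
            else:
                raise ValueError(
                    f"no category vocabulary available for column {name!r}"
                )
            cols.append(ColumnSpec(name, ColumnKind.CATEGORICAL, cats))
        else:
            cols.append(ColumnSpec(name, ColumnKind.CONTINUOUS))
    return TableSchema(tuple(cols))


def load_column_config(path: str | Path) -> dict:
    """Read a YAML column config: ``columns: {Age: continuous, ...}``.

    Optional ``categories: {Gender: [female, male], ...}`` pins vocabularies;
    otherwise they are inferred from the data at load time.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "columns" not in cfg:
        raise ValueError("column config must contain a top-level 'columns' mapping")
    known = {"columns", "categories", "units"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def save_column_config(
    path: str | Path, schema: TableSchema, units: Mapping[str, str] | None = None
) -> None:
    cfg: dict = {"columns": {c.name: c.kind.value for c in schema.columns}}
    cats = {c.name: list(c.categories) for c in schema.categorical}
    if cats:
        cfg["categories"] = cats
    if units:
        cfg["units"] = dict(units)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def schema_from_config(cfg: dict, frame: pd.DataFrame | None = None) -> TableSchema:
    return schema_from_kinds(cfg["columns"], frame=frame, categories=cfg.get("categories"))
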