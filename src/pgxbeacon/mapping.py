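"""Declarative flattening of nested Beacon v2 entity documents into tables.

Beacon responses are deeply nested JSON documents whose useful content sits at
predictable key paths (``histologicalDiagnosis.id``, ``externalReferences[].id``
...).  This module turns lists of such documents into rectangular
:class:`pandas.DataFrame` tables, driven by small YAML mapping configurations
so the column inventory is data, not code.

Path dialect
------------
A path is a dot-separated sequence of keys.  A key suffixed with ``[]`` marks a
list: resolution continues inside every element and the results are collected
into a list.  This is a deliberately tiny subset of JSONPath — enough for the
Beacon default models, small enough to audit.

Cardinalities
-------------
``scalar``  take the resolved value as-is (default).
``first``   take the first element when the value is a list.
``join``    join list elements into one delimited string.
``explode`` emit one output row per list element (at most one such column per
            config, so row multiplication stays unambiguous).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "ColumnSpec",
    "MappingConfig",
    "MappingConfigError",
    "load_mapping",
    "default_mapping",
    "resolve_path",
    "flatten_records",
    "harmonize_tables",
    "write_table",
]

CARDINALITIES = ("scalar", "first", "join", "explode")

_PATH_KEY_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*(\[\])?$")


class MappingConfigError(ValueError):
    """Raised when a mapping configuration violates its invariants."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    path: str
    cardinality: str = "scalar"
    delimiter: str = ";"

    def __post_init__(self) -> None:
        if self.cardinality not in CARDINALITIES:
            raise MappingConfigError(
                f"column {self.name!r}: unknown cardinality {self.cardinality!r}; "
                f"valid: {', '.join(CARDINALITIES)}"
            )
        for part in self.path.split("."):
            if not _PATH_KEY_RE.match(part):
                raise MappingConfigError(
                    f"column {self.name!r}: malformed path segment {part!r} "
                    f"in {self.path!r}"
                )


@dataclass(frozen=True)
class MappingConfig:
    """Ordered column mapping for one Beacon entity."""

    entity: str
    columns: tuple[ColumnSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise MappingConfigError(f"duplicate column names: {sorted(dupes)}")
        exploded = [c.name for c in self.columns if c.cardinality == "explode"]
        if len(exploded) > 1:
            raise MappingConfigError(
                f"at most one explode column allowed, got {exploded}"
            )

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


def load_mapping(text_or_path: str) -> MappingConfig:
    """Parse a YAML mapping document (a string or a file path) and validate it."""
    text = text_or_path
    if "\n" not in text_or_path and text_or_path.endswith((".yaml", ".yml")):
        with open(text_or_path, encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "entity" not in doc:
        raise MappingConfigError("mapping document must be a map with an 'entity' key")
    cols = []
    for entry in doc.get("columns", []):
        if not isinstance(entry, dict) or "name" not in entry or "path" not in entry:
            raise MappingConfigError(f"column entry needs 'name' and 'path': {entry!r}")
        cols.append(
            ColumnSpec(
                name=str(entry["name"]),
                path=str(entry["path"]),
                cardinality=str(entry.get("cardinality", "scalar")),
                delimiter=str(entry.get("delimiter", ";")),
            )
        )
    return MappingConfig(entity=str(doc["entity"]), columns=tuple(cols))


def default_mapping(entity: str) -> MappingConfig:
    """Load the packaged default mapping config for a Beacon entity."""
    ref = resources.files("pgxbeacon.config").joinpath(f"{entity}.yaml")
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise MappingConfigError(f"no packaged mapping config for entity {entity!r}")
    return load_mapping(text)


def resolve_path(record: Any, path: str) -> Any:
    """Resolve a dot path against a nested document.

    Total: any missing key, wrong type or empty traversal yields ``None``,
    never an exception.  ``[]`` markers collect values across list elements
    (nested markers nest the collection, then the list is flattened one level
    per marker so the result is a flat list of scalars).
    """
    return _resolve(record, path.split("."))


def _resolve(node: Any, parts: Sequence[str]) -> Any:
    if not parts:
        return node
    key = parts[0]
    rest = parts[1:]
    if key.endswith("[]"):
        key = key[:-2]
        if not isinstance(node, dict):
            return None
        value = node.get(key)
        if not isinstance(value, list):
            return None
        out: list[Any] = []
        for elem in value:
            got = _resolve(elem, rest)
            if isinstance(got, list):
                out.extend(got)
            elif got is not None:
                out.append(got)
        return out
    if not isinstance(node, dict):
        return None
    return _resolve(node.get(key), rest)


def _finalize(value: Any, spec: ColumnSpec) -> Any:
    if value is None:
        return None
    if spec.cardinality == "first":
        if isinstance(value, list):
            return value[0] if value else None
        return value
    if spec.cardinality == "join":
        if isinstance(value, list):
            return spec.delimiter.join(str(v) for v in value) if value else None
        return value
    return value


def flatten_records(
    records: Iterable[dict],
    config: MappingConfig,
    domain: str | None = None,
) -> pd.DataFrame:
    """Flatten nested documents into a table, one row per record.

    A column with ``explode`` cardinality multiplies each record into one row
    per list element; a record with an empty (or missing) list still yields a
    single row with a null in that column.  When *domain* is given it is
    recorded in a ``domain`` provenance column.
    """
    explode_col = next(
        (c.name for c in config.columns if c.cardinality == "explode"), None
    )
    rows: list[dict[str, Any]] = []
    for record in records:
        base: dict[str, Any] = {}
        explode_values: list[Any] | None = None
        for spec in config.columns:
            raw = resolve_path(record, spec.path)
            if spec.cardinality == "explode":
                if isinstance(raw, list):
                    explode_values = raw
                elif raw is not None:
                    explode_values = [raw]
                else:
                    explode_values = []
            else:
                base[spec.name] = _finalize(raw, spec)
        if explode_col is None:
            rows.append(base)
        else:
            if explode_values:
                for v in explode_values:
                    rows.append({**base, explode_col: v})
            else:
                rows.append({**base, explode_col: None})
    columns = list(config.column_names)
    table = pd.DataFrame(rows, columns=columns, dtype=object)
    table = table.where(pd.notna(table), None)
    if domain is not None:
        table.insert(0, "domain", domain)
    return table


def harmonize_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Stack tables row-wise over the ordered union of their columns.

    Column order is first-seen order across inputs; cells absent from a source
    table are null.  Idempotent, and the identity on a single table.
    """
    if not tables:
        return pd.DataFrame()
    columns: list[str] = []
    for t in tables:
        for c in t.columns:
            if c not in columns:
                columns.append(c)
    aligned = []
    for t in tables:
        block = t.reindex(columns=columns)
        aligned.append(block)
    out = pd.concat(aligned, ignore_index=True) if aligned else pd.DataFrame()
    out = out.astype(object).where(pd.notna(out), None)
    return out[columns]


def write_table(table: pd.DataFrame, path: str, sep: str | None = None) -> None:
    """Export a flat table as TSV (default) or CSV; nulls become empty strings."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    table.to_csv(path, sep=sep, index=False, na_rep="")
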