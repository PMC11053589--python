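"""Metrics store: one endpoint per measurement type, JSON-array
ingestion, and per-column query-string filters over an embedded SQLite
database.

Filter dialect: ``col=v`` is equality, ``col.gt=v`` / ``col.lt=v`` are
strict greater/less-than; text columns support only equality; a column
may carry at most one ``gt`` and one ``lt`` (a range) or one ``eq``.
"""

from __future__ import annotations

import json
import re
import sqlite3
from dataclasses import dataclass
from typing import Any, Iterable, Sequence
from urllib.parse import parse_qsl

from gaitfuse.errors import (
    FilterError,
    RecordValidationError,
    SchemaError,
    UnsupportedOperatorError,
)

__all__ = ["COLUMN_TYPES", "MeasurementSchema", "ColumnFilter", "MetricsStore", "parse_filters"]

COLUMN_TYPES = ("text", "integer", "real", "timestamp")

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

_SQL_TYPE = {"text": "TEXT", "integer": "INTEGER", "real": "REAL", "timestamp": "REAL"}
_SQL_OP = {"eq": "=", "gt": ">", "lt": "<"}

_META_TABLE = "_endpoint_schemas"


def _check_name(name: str, what: str) -> None:
    if not _NAME_RE.match(name):
        raise SchemaError(f"invalid {what} name {name!r}")


@dataclass(frozen=True)
class MeasurementSchema:
    """An endpoint name plus its ordered (column, type) pairs."""

    endpoint_name: str
    columns: tuple

    def __init__(self, endpoint_name: str, columns: Iterable[Sequence[str]]):
        object.__setattr__(self, "endpoint_name", endpoint_name)
        object.__setattr__(self, "columns", tuple((str(c), str(t)) for c, t in columns))
        _check_name(self.endpoint_name, "endpoint")
        names = [c for c, _ in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names")
        for c, t in self.columns:
            _check_name(c, "column")
            if t not in COLUMN_TYPES:
                raise SchemaError(f"unknown column type {t!r} (allowed: {COLUMN_TYPES})")
        if not any(t == "timestamp" for _, t in self.columns):
            raise SchemaError("schema must include at least one timestamp column")

    def column_type(self, name: str) -> str:
        for c, t in self.columns:
            if c == name:
                return t
        raise FilterError(f"unknown column {name!r} on endpoint {self.endpoint_name!r}")

    def coerce(self, column: str, value: Any) -> Any:
        """Coerce a value to the column's type; raises on mismatch."""
        ctype = self.column_type(column)
        try:
            if ctype == "text":
                if not isinstance(value, str):
                    raise TypeError(f"expected text, got {type(value).__name__}")
                return value
            if ctype == "integer":
                if isinstance(value, bool):
                    raise TypeError("booleans are not integers")
                if isinstance(value, int):
                    return value
                if isinstance(value, str):
                    return int(value)
                if isinstance(value, float) and value.is_integer():
                    return int(value)
                raise TypeError(f"expected integer, got {value!r}")
            # real / timestamp
            if isinstance(value, bool):
                raise TypeError("booleans are not numbers")
            if isinstance(value, (int, float)):
                return float(value)
            if isinstance(value, str):
                return float(value)
            raise TypeError(f"expected number, got {type(value).__name__}")
        except (TypeError, ValueError) as exc:
            raise TypeError(f"column {column!r}: {exc}") from None


@dataclass(frozen=True)
class ColumnFilter:
    column: str
    op: str  # eq | gt | lt
    value: Any


def _validate_filters(filters: Iterable[ColumnFilter], schema: MeasurementSchema) -> list:
    filters = list(filters)
    seen: dict[tuple[str, str], int] = {}
    for f in filters:
        ctype = schema.column_type(f.column)
        if f.op not in _SQL_OP:
            raise FilterError(f"unknown operator {f.op!r}")
        if ctype == "text" and f.op != "eq":
            raise UnsupportedOperatorError(
                f"text column {f.column!r} can only be compared for equality"
            )
        key = (f.column, f.op)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] > 1:
            raise FilterError(f"duplicate {f.op} filter on column {f.column!r}")
    return filters


def parse_filters(query_string: str, schema: MeasurementSchema) -> list:
    """Parse a query string into validated, type-coerced column filters.

    ``col=v`` maps to equality, ``col.gt=v`` and ``col.lt=v`` to strict
    inequalities. Values are coerced to the column's type.
    """
    filters = []
    for key, raw in parse_qsl(query_string, keep_blank_values=True, strict_parsing=False):
        if key.endswith(".gt"):
            column, op = key[:-3], "gt"
        elif key.endswith(".lt"):
            column, op = key[:-3], "lt"
        else:
            column, op = key, "eq"
        try:
            value = schema.coerce(column, raw)
        except TypeError as exc:
            raise FilterError(str(exc)) from None
        filters.append(ColumnFilter(column, op, value))
    return _validate_filters(filters, schema)


class MetricsStore:
    """SQLite-backed store with one table per measurement endpoint.

    Schemas are persisted in a meta table so a store file reopens with
    its endpoints intact. Use ``path=":memory:"`` for an ephemeral store.
    """

    def __init__(self, path: str = ":memory:"):
        # check_same_thread off so the HTTP binding can serve from worker
        # threads; it serializes access with its own lock
        self._conn = sqlite3.connect(path, check_same_thread=False)
        self._conn.execute(
            f"CREATE TABLE IF NOT EXISTS {_META_TABLE} (name TEXT PRIMARY KEY, schema_json TEXT)"
        )
        self._schemas: dict[str, MeasurementSchema] = {}
        for name, blob in self._conn.execute(f"SELECT name, schema_json FROM {_META_TABLE}"):
            self._schemas[name] = MeasurementSchema(name, json.loads(blob))

    def close(self) -> None:
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    @property
    def endpoints(self) -> list:
        return sorted(self._schemas)

    def schema(self, endpoint: str) -> MeasurementSchema:
        try:
            return self._schemas[endpoint]
        except KeyError:
            raise SchemaError(f"unknown endpoint {endpoint!r}") from None

    def define_endpoint(self, schema: MeasurementSchema) -> str:
        """Create the endpoint's backing table; idempotent for identical
        schemas, error on a conflicting redefinition."""
        existing = self._schemas.get(schema.endpoint_name)
        if existing is not None:
            if existing.columns != schema.columns:
                raise SchemaError(
                    f"endpoint {schema.endpoint_name!r} already defined with a different schema"
                )
            return schema.endpoint_name
        cols = ", ".join(f'"{c}" {_SQL_TYPE[t]}' for c, t in schema.columns)
        with self._conn:
            self._conn.execute(f'CREATE TABLE "{schema.endpoint_name}" ({cols})')
            self._conn.execute(
                f"INSERT INTO {_META_TABLE} (name, schema_json) VALUES (?, ?)",
                (schema.endpoint_name, json.dumps(schema.columns)),
            )
        self._schemas[schema.endpoint_name] = schema
        return schema.endpoint_name

    def insert(self, endpoint: str, records: Sequence[dict]) -> int:
        """All-or-nothing batch insertion; returns the inserted count.

        Any record that does not conform to the schema rejects the whole
        batch, reporting the index of the first offender.
        """
        schema = self.schema(endpoint)
        col_names = [c for c, _ in schema.columns]
        rows = []
        for i, rec in enumerate(records):
            if not isinstance(rec, dict):
                raise RecordValidationError(i, f"not an object: {type(rec).__name__}")
            extra = set(rec) - set(col_names)
            if extra:
                raise RecordValidationError(i, f"unknown columns {sorted(extra)}")
            missing = set(col_names) - set(rec)
            if missing:
                raise RecordValidationError(i, f"missing columns {sorted(missing)}")
            try:
                rows.append(tuple(schema.coerce(c, rec[c]) for c in col_names))
            except TypeError as exc:
                raise RecordValidationError(i, str(exc)) from None
        placeholders = ", ".join("?" for _ in col_names)
        quoted = ", ".join(f'"{c}"' for c in col_names)
        with self._conn:
            self._conn.executemany(
                f'INSERT INTO "{endpoint}" ({quoted}) VALUES ({placeholders})', rows
            )
        return len(rows)

    def query(self, endpoint: str, filters=None) -> list:
        """Records satisfying the conjunction of filters, insertion order.

        ``filters`` may be a list of :class:`ColumnFilter` or a raw query
        string. Returns JSON-serializable dicts.
        """
        schema = self.schema(endpoint)
        if filters is None:
            filters = []
        if isinstance(filters, str):
            filters = parse_filters(filters, schema)
        else:
            filters = _validate_filters(filters, schema)

        col_names = [c for c, _ in schema.columns]
        quoted = ", ".join(f'"{c}"' for c in col_names)
        sql = f'SELECT {quoted} FROM "{endpoint}"'
        params = []
        if filters:
            clauses = []
            for f in filters:
                clauses.append(f'"{f.column}" {_SQL_OP[f.op]} ?')
                params.append(schema.coerce(f.column, f.value))
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY rowid"
        rows = self._conn.execute(sql, params).fetchall()
        return [dict(zip(col_names, row)) for row in rows]
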