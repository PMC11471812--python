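"""Typed private tables: CSV ingestion into secret shares, concatenation,
column access and oblivious selection masks.

A :class:`PrivateTable` is the server-side image of one site's cohort CSV:
every cell is secret-shared across the three compute parties at ingestion
time and the plaintext buffers are overwritten immediately afterwards.  The
only public facts about a table are its schema and its row count (the study
design publishes per-site n, so n is deliberately not protected).

Selection predicates — conjunctions of ``column <relation> constant``
clauses — are evaluated entirely on shares and yield a
:class:`SelectionMask` of shared bits; no party learns which rows matched.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ring as R
from .ring import (BIT, FIXED, INT, DEFAULT_RING, Ring, SharedValue,
                   TripleStore, bit_not, equals_public, less_than, mul)

CATEGORICAL = "categorical"
METRIC = "metric"

_RELATIONS = ("==", "!=", "<", "<=", ">", ">=")


class IngestionError(ValueError):
    """Raised when a CSV payload cannot be coded against the dictionary."""


class SchemaMismatchError(TypeError):
    """Raised when two tables with different schemas are combined."""


@dataclass(frozen=True)
class ColumnSpec:
    """One agreed column: name, kind, category codes and unit.

    Categorical values are transported as text labels and coded to their
    index in ``categories``; metric values are fixed-point encoded.
    ``min_value`` lets the dictionary enforce domain constraints (e.g.
    follow-up months must be non-negative) at ingestion time.
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    unit: str = ""
    min_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, METRIC):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == CATEGORICAL and not self.categories:
            raise ValueError(f"categorical column {self.name!r} needs categories")

    def code(self, label: str) -> int:
        try:
            return self.categories.index(str(label))
        except ValueError:
            raise IngestionError(
                f"value {label!r} is not a known category of column {self.name!r}"
            ) from None


@dataclass
class DataDictionary:
    """The pre-agreed spreadsheet format shared by all sites."""

    columns: tuple[ColumnSpec, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("column names must be unique")
        self._by_name = {c.name: c for c in self.columns}

    def __getitem__(self, name: str) -> ColumnSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "columns": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    "categories": list(c.categories),
                    "unit": c.unit,
                    **({"min_value": c.min_value} if c.min_value is not None else {}),
                }
                for c in self.columns
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "DataDictionary":
        cols = tuple(
            ColumnSpec(
                name=c["name"],
                kind=c["kind"],
                categories=tuple(c.get("categories", ())),
                unit=c.get("unit", ""),
                min_value=c.get("min_value"),
            )
            for c in d["columns"]
        )
        return cls(columns=cols, version=d.get("version", "unversioned"))

    @classmethod
    def from_yaml(cls, text: str) -> "DataDictionary":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_json(cls, text: str) -> "DataDictionary":
        return cls.from_dict(json.loads(text))


@dataclass
class PrivateColumn:
    spec: ColumnSpec
    values: SharedValue

    def __len__(self) -> int:
        return len(self.values)

    @property
    def kind(self) -> str:
        return self.spec.kind


@dataclass
class PrivateTable:
    columns: dict[str, PrivateColumn]
    site_label: str
    n_rows: int
    dictionary: DataDictionary

    def column(self, name: str) -> PrivateColumn:
        if name not in self.columns:
            raise KeyError(f"table {self.site_label!r} has no column {name!r}")
        return self.columns[name]

    def __contains__(self, name: str) -> bool:
        return name in self.columns


@dataclass
class SelectionMask:
    """Shared-bit row filter; bit i reconstructs to 1 iff row i matches."""

    bits: SharedValue
    source: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.bits)


def nrows(t: PrivateTable) -> int:
    return t.n_rows


def column(t: PrivateTable, name: str) -> PrivateColumn:
    return t.column(name)


def ingest_csv(
    text: str,
    dictionary: DataDictionary,
    *,
    site_label: str = "site",
    rng: np.random.Generator | None = None,
    ring: Ring = DEFAULT_RING,
) -> PrivateTable:
    """Parse one site's CSV against the agreed dictionary and secret-share it.

    Comma separator, '.' decimal point, UTF-8, header row required; dates
    must have been resolved to numeric months client-side.  After sharing,
    the intermediate plaintext buffers are overwritten in place (best effort
    at the Python level) so no single-node state retains raw cell values.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not text or not text.strip():
        raise IngestionError("empty CSV payload")
    try:
        df = pd.read_csv(io.StringIO(text), dtype=str, skipinitialspace=True)
    except Exception as exc:  # malformed CSV
        raise IngestionError(f"unparseable CSV: {exc}") from exc
    header = list(df.columns)
    unknown = [c for c in header if c not in dictionary]
    if unknown:
        raise IngestionError(f"unknown column(s) {unknown} not in data dictionary")
    missing = [c for c in dictionary.names if c not in header]
    if missing:
        raise IngestionError(f"column(s) {missing} required by dictionary but absent")
    if len(df) == 0:
        raise IngestionError("CSV has a header but no data rows")

    cols: dict[str, PrivateColumn] = {}
    scratch: list[np.ndarray] = []
    for spec in dictionary.columns:
        raw = df[spec.name]
        if spec.kind == CATEGORICAL:
            codes = np.empty(len(raw), dtype=np.int64)
            for i, v in enumerate(raw):
                if pd.isna(v):
                    raise IngestionError(
                        f"missing value in categorical column {spec.name!r}, row {i + 1}"
                    )
                codes[i] = spec.code(v)
            sv = R.share(codes, rng, ring=ring, kind=INT)
            scratch.append(codes)
        else:
            vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=np.float64)
            bad = np.nonzero(~np.isfinite(vals))[0]
            if bad.size:
                raise IngestionError(
                    f"non-numeric metric cell in column {spec.name!r}, row {bad[0] + 1}"
                )
            if spec.min_value is not None and np.any(vals < spec.min_value):
                row = int(np.nonzero(vals < spec.min_value)[0][0])
                raise IngestionError(
                    f"column {spec.name!r}, row {row + 1}: value below "
                    f"minimum {spec.min_value}"
                )
            sv = R.share(vals, rng, ring=ring, kind=FIXED)
            scratch.append(vals)
        cols[spec.name] = PrivateColumn(spec=spec, values=sv)

    n = len(df)
    # wipe plaintext working buffers after sharing
    for buf in scratch:
        buf.fill(0)
    df.loc[:, :] = ""
    del df
    return PrivateTable(columns=cols, site_label=site_label, n_rows=n,
                        dictionary=dictionary)


def concat(a: PrivateTable, b: PrivateTable) -> PrivateTable:
    """Pool two site tables share-wise — the federation step.

    Shares are copied without any reconstruction, so pooling reveals nothing
    beyond the (public) combined row count.
    """
    if a.dictionary.names != b.dictionary.names or any(
        a.dictionary[n] != b.dictionary[n] for n in a.dictionary.names
    ):
        raise SchemaMismatchError("tables have different column specifications")
    cols: dict[str, PrivateColumn] = {}
    for name in a.dictionary.names:
        ca, cb = a.columns[name], b.columns[name]
        shares = tuple(
            np.concatenate([sa, sb]) for sa, sb in zip(ca.values.shares, cb.values.shares)
        )
        cols[name] = PrivateColumn(
            spec=ca.spec,
            values=SharedValue(ca.values.ring, ca.values.kind, shares),
        )
    return PrivateTable(
        columns=cols,
        site_label=f"{a.site_label}+{b.site_label}",
        n_rows=a.n_rows + b.n_rows,
        dictionary=a.dictionary,
    )


def concat_columns(a: PrivateColumn, b: PrivateColumn) -> PrivateColumn:
    if a.spec != b.spec:
        raise SchemaMismatchError(
            f"cannot concatenate columns {a.spec.name!r} and {b.spec.name!r} "
            "with different specifications"
        )
    shares = tuple(
        np.concatenate([sa, sb]) for sa, sb in zip(a.values.shares, b.values.shares)
    )
    return PrivateColumn(spec=a.spec,
                         values=SharedValue(a.values.ring, a.values.kind, shares))


@dataclass(frozen=True)
class Clause:
    """One predicate atom ``column <relation> constant``."""

    column: str
    relation: str
    constant: object

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise ValueError(f"unsupported relation {self.relation!r}")


def _clause_bits(t: PrivateTable, clause: Clause, store: TripleStore) -> SharedValue:
    col = t.column(clause.column)
    sv = col.values
    if col.kind == CATEGORICAL:
        if clause.relation not in ("==", "!="):
            raise SchemaMismatchError(
                f"ordering relation {clause.relation!r} is not defined on "
                f"categorical column {clause.column!r}"
            )
        code = (clause.constant if isinstance(clause.constant, (int, np.integer))
                else col.spec.code(str(clause.constant)))
        eq = equals_public(sv, int(code), store)
        return bit_not(eq) if clause.relation == "!=" else eq
    # metric column: share the public constant and compare obliviously
    const = R.public_share(float(clause.constant), ring=sv.ring, kind=FIXED,
                           shape=sv.shape)
    rel = clause.relation
    if rel == "==":
        return equals_public(sv, float(clause.constant), store)
    if rel == "!=":
        return bit_not(equals_public(sv, float(clause.constant), store))
    if rel == "<":
        return less_than(sv, const, store)
    if rel == ">":
        return less_than(const, sv, store)
    if rel == "<=":
        return bit_not(less_than(const, sv, store))
    return bit_not(less_than(sv, const, store))  # ">="


def build_mask(t: PrivateTable, predicate: Sequence[Clause] | Clause,
               store: TripleStore) -> SelectionMask:
    """Evaluate a conjunction of clauses into a shared-bit mask.

    Each clause costs one oblivious comparison per row; clauses are combined
    with secure bit multiplication, so neither the per-row outcomes nor the
    matching rows are revealed (only aggregate statistics over the mask may
    later be opened, subject to disclosure control).
    """
    clauses = [predicate] if isinstance(predicate, Clause) else list(predicate)
    if not clauses:
        raise ValueError("predicate needs at least one clause")
    acc: SharedValue | None = None
    for cl in clauses:
        bits = _clause_bits(t, cl, store)
        acc = bits if acc is None else mul(acc, bits, store)
    desc = " & ".join(f"{c.column} {c.relation} {c.constant}" for c in clauses)
    return SelectionMask(bits=acc, source=t.site_label, description=desc)


def mask_and(a: SelectionMask, b: SelectionMask, store: TripleStore) -> SelectionMask:
    if len(a) != len(b):
        raise SchemaMismatchError("masks cover different row counts")
    return SelectionMask(
        bits=mul(a.bits, b.bits, store),
        source=a.source,
        description=f"({a.description}) & ({b.description})",
    )


def concat_masks(a: SelectionMask, b: SelectionMask) -> SelectionMask:
    shares = tuple(np.concatenate([sa, sb]) for sa, sb in zip(a.bits.shares, b.bits.shares))
    return SelectionMask(
        bits=SharedValue(a.bits.ring, BIT, shares),
        source=f"{a.source}+{b.source}",
        description=a.description or b.description,
    )
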