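"""Declarative factor schemas for mixed-type student survey records.

A :class:`FactorSchema` is an ordered list of factors, each numeric, ordinal,
binary or categorical.  The schema fully determines the encoded design-matrix
layout (see :mod:`glnet.encoding`): numeric/ordinal/binary factors occupy one
column each, categorical factors are expanded into one indicator column per
level with no reference level dropped, so that every level can receive its own
attribution score downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("numeric", "ordinal", "categorical", "binary")

#: Survey factors that are expanded into per-level indicator columns whenever
#: they appear in a schema (categorical factors are always expanded; this set
#: documents the canonical student-survey ones).
SPLIT_FACTORS = frozenset(
    {"profession", "degree", "city", "sleep_duration", "dietary_habits"}
)


class SchemaError(ValueError):
    """Raised when a file or record does not match the declared schema."""


class EncodingError(ValueError):
    """Raised when a record value cannot be encoded under the schema."""


@dataclass(frozen=True)
class Factor:
    """One raw survey factor.

    Parameters
    ----------
    name:
        Column name in the raw CSV.
    kind:
        ``numeric`` | ``ordinal`` | ``categorical`` | ``binary``.
    levels:
        Ordered level vocabulary; required (>=2 entries) for categorical and
        exactly 2 entries for binary, empty otherwise.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown factor kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise SchemaError(f"categorical factor {self.name!r} needs >=2 levels")
        if self.kind == "binary" and len(self.levels) != 2:
            raise SchemaError(f"binary factor {self.name!r} needs exactly 2 levels")
        if self.kind in ("numeric", "ordinal") and self.levels:
            raise SchemaError(f"{self.kind} factor {self.name!r} must not have levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"duplicate levels in factor {self.name!r}")

    def encoded_columns(self) -> list[str]:
        if self.kind == "categorical":
            return [f"{self.name}={lvl}" for lvl in self.levels]
        if self.kind == "binary":
            return [f"{self.name}={self.levels[1]}"]
        return [self.name]


@dataclass(frozen=True)
class FactorSchema:
    """Ordered collection of :class:`Factor` definitions."""

    factors: tuple[Factor, ...]
    label_column: str = "depression"

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise SchemaError("factor names must be unique")
        if self.label_column in names:
            raise SchemaError("label column must not be listed as a factor")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.factors)

    def encoded_columns(self) -> list[str]:
        cols: list[str] = []
        for f in self.factors:
            cols.extend(f.encoded_columns())
        return cols

    @property
    def n_encoded(self) -> int:
        return len(self.encoded_columns())

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label_column": self.label_column,
            "factors": [
                {"name": f.name, "kind": f.kind, "levels": list(f.levels)}
                for f in self.factors
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FactorSchema":
        factors = tuple(
            Factor(f["name"], f["kind"], tuple(f.get("levels", ())))
            for f in d["factors"]
        )
        return cls(factors=factors, label_column=d.get("label_column", "depression"))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def identifier(self) -> str:
        """Stable content hash used to tie downstream artifacts to a schema."""
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def infer_schema(
    path: str | Path,
    overrides: Mapping[str, str | Factor] | None = None,
    label_column: str = "depression",
    max_levels: int = 100,
) -> FactorSchema:
    """Infer a :class:`FactorSchema` from a CSV header and its values.

    Numeric columns become ``numeric`` factors (``ordinal`` via *overrides*);
    text columns become ``categorical`` with their observed levels sorted
    lexicographically.  An override may be a kind string or a full
    :class:`Factor` and always wins.  A text column with more than
    *max_levels* distinct values and no override is rejected — this guards
    against accidentally one-hot-encoding an identifier column.
    """
    overrides = dict(overrides or {})
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty file")
    factors: list[Factor] = []
    for col in df.columns:
        if col == label_column:
            continue
        ov = overrides.get(col)
        if isinstance(ov, Factor):
            factors.append(ov)
            continue
        series = df[col].dropna()
        if pd.api.types.is_numeric_dtype(series):
            kind = ov if isinstance(ov, str) else "numeric"
            factors.append(Factor(col, kind))
        else:
            levels = sorted(str(v) for v in series.unique())
            kind = ov if isinstance(ov, str) else (
                "binary" if len(levels) == 2 else "categorical"
            )
            if kind in ("categorical", "binary"):
                if len(levels) > max_levels:
                    raise SchemaError(
                        f"column {col!r} has {len(levels)} distinct values "
                        f"(max_levels={max_levels}); override its kind if intended"
                    )
                factors.append(Factor(col, kind, tuple(levels)))
            else:
                factors.append(Factor(col, kind))
    return FactorSchema(tuple(factors), label_column=label_column)


def load_records(
    path: str | Path, schema: FactorSchema
) -> tuple[pd.DataFrame, int]:
    """Read raw records, dropping incomplete rows (listwise deletion).

    Returns the clean records (factor columns in schema order, plus the label
    column when present) and the number of dropped rows.  Rows are dropped
    when any factor value is missing, a numeric/ordinal value fails to parse,
    or the label is missing/non-binary.  Unknown categorical *levels* are not
    dropped here — they surface later as :class:`EncodingError`.
    """
    df = pd.read_csv(Path(path))
    if df.empty:
        raise SchemaError(f"{path}: empty file")
    have = set(df.columns)
    missing = [n for n in schema.names if n not in have]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    unknown = have - set(schema.names) - {schema.label_column}
    if unknown:
        raise SchemaError(f"{path}: unknown columns {sorted(unknown)}")

    cols = list(schema.names)
    has_label = schema.label_column in have
    if has_label:
        cols.append(schema.label_column)
    df = df[cols].copy()

    keep = pd.Series(True, index=df.index)
    for f in schema.factors:
        col = df[f.name]
        if f.kind in ("numeric", "ordinal"):
            parsed = pd.to_numeric(col, errors="coerce")
            df[f.name] = parsed
            keep &= parsed.notna()
        else:
            keep &= col.notna() & (col.astype(str).str.len() > 0)
            df[f.name] = col.astype(str)
    if has_label:
        lab = pd.to_numeric(df[schema.label_column], errors="coerce")
        keep &= lab.isin([0, 1])
        df[schema.label_column] = lab
    dropped = int((~keep).sum())
    out = df.loc[keep].reset_index(drop=True)
    if has_label:
        out[schema.label_column] = out[schema.label_column].astype(int)
    if dropped:
        logger.info("load_records: dropped %d incomplete rows", dropped)
    return out, dropped
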