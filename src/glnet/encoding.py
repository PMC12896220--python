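"""Design-matrix encoding, stratified splitting and train-only standardization.

The single interchange object between pipeline stages is
:class:`EncodedDataset`: a dense float64 matrix whose column layout is a pure
function of the :class:`~glnet.schema.FactorSchema`, plus 0/1 labels
(depressed -> 1).  Standardization parameters are always fitted on the
training partition only and carried as a JSON-serializable sidecar so a run
can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import EncodingError, FactorSchema, SchemaError

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-8


@dataclass
class EncodedDataset:
    matrix: np.ndarray  # (n_samples, n_columns) float64
    columns: list[str]
    labels: np.ndarray | None  # (n_samples,) in {0,1}, or None for unlabeled
    schema_id: str = ""
    standardized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("matrix shape inconsistent with column names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.matrix.shape[0],):
                raise ValueError("labels length mismatch")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def subset(self, idx: Sequence[int]) -> "EncodedDataset":
        idx = np.asarray(idx, dtype=np.int64)
        return EncodedDataset(
            self.matrix[idx],
            list(self.columns),
            None if self.labels is None else self.labels[idx],
            schema_id=self.schema_id,
            standardized=self.standardized,
        )


def encode_dataset(records: pd.DataFrame, schema: FactorSchema) -> EncodedDataset:
    """Encode cleaned records into the numeric design matrix.

    Numeric/ordinal factors are copied as single columns, binary factors map
    to {0,1} (second level -> 1), and every categorical factor expands into
    one indicator column per level ("factor=level"), with exactly one
    indicator set per row.
    """
    n = len(records)
    blocks: list[np.ndarray] = []
    for f in schema.factors:
        col = records[f.name]
        if f.kind in ("numeric", "ordinal"):
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=np.float64)
            if np.isnan(vals).any():
                row = int(np.flatnonzero(np.isnan(vals))[0])
                raise EncodingError(f"row {row}: non-numeric value for factor {f.name!r}")
            blocks.append(vals[:, None])
        else:
            values = col.astype(str).to_numpy()
            level_index = {lvl: i for i, lvl in enumerate(f.levels)}
            codes = np.empty(n, dtype=np.int64)
            for i, v in enumerate(values):
                try:
                    codes[i] = level_index[v]
                except KeyError:
                    raise EncodingError(
                        f"row {i}: value {v!r} not in levels of factor {f.name!r}"
                    ) from None
            if f.kind == "binary":
                blocks.append((codes == 1).astype(np.float64)[:, None])
            else:
                onehot = np.zeros((n, len(f.levels)))
                onehot[np.arange(n), codes] = 1.0
                blocks.append(onehot)
    matrix = np.hstack(blocks) if blocks else np.zeros((n, 0))
    labels = None
    if schema.label_column in records.columns:
        labels = records[schema.label_column].to_numpy(dtype=np.int64)
    return EncodedDataset(matrix, schema.encoded_columns(), labels,
                          schema_id=schema.identifier())


def decode_categorical(ds: EncodedDataset, schema: FactorSchema, name: str) -> np.ndarray:
    """Recover the raw level of categorical factor *name* for every row
    (argmax over its indicator block); inverse of the one-hot expansion."""
    f = schema[name]
    if f.kind != "categorical":
        raise ValueError(f"{name!r} is not categorical")
    cols = [ds.columns.index(c) for c in f.encoded_columns()]
    codes = np.argmax(ds.matrix[:, cols], axis=1)
    return np.asarray(f.levels, dtype=object)[codes]


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitResult:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed,
             "train": self.train.tolist(),
             "validation": self.validation.tolist(),
             "test": self.test.tolist()}, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["train"], dtype=np.int64),
                   np.asarray(d["validation"], dtype=np.int64),
                   np.asarray(d["test"], dtype=np.int64), int(d["seed"]))

    @property
    def train_pool(self) -> np.ndarray:
        return np.sort(np.concatenate([self.train, self.validation]))


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    """Allocate *total* slots proportionally to *counts* with exact sum."""
    quota = counts * total / counts.sum()
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        # break remainder ties toward the larger stratum, then lower index
        order = np.lexsort((np.arange(len(counts)), -counts, -(quota - base)))
        base[order[:short]] += 1
    return base


def split_dataset(
    dataset: EncodedDataset,
    test_fraction: float = 0.2,
    val_fraction_of_train: float = 0.15,
    seed: int = 0,
) -> SplitResult:
    """Label-stratified train/validation/test partition.

    The training pool is ``floor(n * (1 - test_fraction))`` and the test set
    is the remainder (27,898 rows at an 80:20 ratio give a 22,318-row pool and
    5,580 test rows); the validation set is ``floor(pool *
    val_fraction_of_train)`` carved from the pool.  Per-label allocations use
    largest-remainder rounding so partition prevalences track the parent.
    Deterministic for a given seed.
    """
    if not (0 < test_fraction < 1 and 0 < val_fraction_of_train < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if dataset.labels is None:
        raise ValueError("split_dataset requires labels")
    n = dataset.n
    labels = dataset.labels
    pool_target = int(np.floor(n * (1.0 - test_fraction)))
    test_target = n - pool_target
    val_target = int(np.floor(pool_target * val_fraction_of_train))

    classes, counts = np.unique(labels, return_counts=True)
    usable = counts >= 2
    if not usable.all():
        warnings.warn(
            "stratum with <2 members assigned wholly to train", stacklevel=2
        )
    eff_counts = counts[usable]
    test_alloc = np.zeros(len(classes), dtype=np.int64)
    val_alloc = np.zeros(len(classes), dtype=np.int64)
    if eff_counts.size:
        test_alloc[usable] = _largest_remainder(eff_counts, min(test_target, int(eff_counts.sum())))
        pool_counts = eff_counts - test_alloc[usable]
        val_alloc[usable] = _largest_remainder(pool_counts, min(val_target, int(pool_counts.sum())))

    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = [], [], []
    for ci, c in enumerate(classes):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        t, v = test_alloc[ci], val_alloc[ci]
        test_idx.append(idx[:t])
        val_idx.append(idx[t:t + v])
        train_idx.append(idx[t + v:])
    return SplitResult(
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(val_idx)),
        np.sort(np.concatenate(test_idx)),
        seed,
    )


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray
    columns: list[str]
    fitted_on: str = "train"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"mean": self.mean.tolist(), "sd": self.sd.tolist(),
             "columns": self.columns, "fitted_on": self.fitted_on},
            sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationParams":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]),
                   list(d["columns"]), d["fitted_on"])


def fit_standardizer(
    dataset: EncodedDataset, train_idx: Sequence[int]
) -> StandardizationParams:
    """Per-column mean/sd over the *training rows only*; sd floored so that
    constant columns map to zero rather than dividing by zero."""
    train_idx = np.asarray(train_idx, dtype=np.int64)
    if train_idx.size == 0:
        raise ValueError("train_idx must be non-empty")
    sub = dataset.matrix[train_idx]
    mean = sub.mean(axis=0)
    sd = np.maximum(sub.std(axis=0), SD_FLOOR)
    return StandardizationParams(mean, sd, list(dataset.columns))


def apply_standardizer(
    dataset: EncodedDataset, params: StandardizationParams
) -> EncodedDataset:
    if list(dataset.columns) != list(params.columns):
        raise ValueError("column sets differ between dataset and standardizer")
    out = replace(dataset)
    out.matrix = (dataset.matrix - params.mean) / params.sd
    out.standardized = True
    return out


def invert_standardizer(
    dataset: EncodedDataset, params: StandardizationParams
) -> EncodedDataset:
    if list(dataset.columns) != list(params.columns):
        raise ValueError("column sets differ between dataset and standardizer")
    out = replace(dataset)
    out.matrix = dataset.matrix * params.sd + params.mean
    out.standardized = False
    return out
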