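"""Encoding, normalization, splitting and class re-balancing.

Categorical columns are one-hot encoded (every level, including binary 0/1
columns, gets its own indicator so the encoded block is a partition of
unity); continuous columns are min-max normalized to [0, 1].  The labeled
portion of a cohort is split 8:2 into train and test sets stratified by
outcome and survival-time quintile, and the majority (survival) class of
the training set can be under-sampled to a 1:1 ratio before model fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EncodingMap",
    "SplitIndices",
    "one_hot_encode",
    "apply_encoding",
    "invert_encoding",
    "min_max_normalize",
    "MinMaxScalerMap",
    "split_cohort",
    "undersample_majority",
]


@dataclass
class EncodingMap:
    """Invertible record of a one-hot encoding.

    Maps each original categorical column to its ordered level list; the
    encoded frame has one indicator column ``{col}={level}`` per level.
    Continuous (non-categorical) columns pass through unchanged, in their
    original relative order after the encoded block of each categorical.
    """

    levels: dict[str, list] = field(default_factory=dict)
    column_order: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"levels": self.levels, "column_order": self.column_order}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EncodingMap":
        d = json.loads(Path(path).read_text())
        return cls(levels=d["levels"], column_order=d["column_order"])


def one_hot_encode(
    raw: pd.DataFrame, categorical: list[str] | None = None
) -> tuple[pd.DataFrame, EncodingMap]:
    """One-hot encode the categorical columns of ``raw``.

    Every k-level categorical column becomes k indicator columns whose
    row-wise sum is 1.  ``categorical`` defaults to all object/category
    columns plus integer columns with at most 10 distinct values.
    Returns the encoded frame and an invertible :class:`EncodingMap`.
    """
    if categorical is None:
        categorical = [
            c
            for c in raw.columns
            if raw[c].dtype == object
            or isinstance(raw[c].dtype, pd.CategoricalDtype)
            or (pd.api.types.is_integer_dtype(raw[c]) and raw[c].nunique() <= 10)
        ]
    emap = EncodingMap(column_order=list(raw.columns))
    for c in categorical:
        emap.levels[c] = sorted(raw[c].unique().tolist())
    return apply_encoding(raw, emap), emap


def apply_encoding(raw: pd.DataFrame, emap: EncodingMap) -> pd.DataFrame:
    """Encode ``raw`` with a previously fitted map.

    Raises ``ValueError`` naming the column if a value outside the fitted
    level set is encountered.
    """
    pieces = []
    for c in emap.column_order:
        if c in emap.levels:
            levels = emap.levels[c]
            unseen = set(raw[c].unique()) - set(levels)
            if unseen:
                raise ValueError(f"column {c!r}: unseen level(s) {sorted(unseen)!r}")
            block = pd.DataFrame(
                {f"{c}={lv}": (raw[c] == lv).astype(float) for lv in levels},
                index=raw.index,
            )
            pieces.append(block)
        else:
            pieces.append(raw[[c]].astype(float))
    return pd.concat(pieces, axis=1)


def invert_encoding(encoded: pd.DataFrame, emap: EncodingMap) -> pd.DataFrame:
    """Recover the original table from an encoded frame."""
    out = {}
    for c in emap.column_order:
        if c in emap.levels:
            levels = emap.levels[c]
            block = encoded[[f"{c}={lv}" for lv in levels]].to_numpy()
            out[c] = [levels[i] for i in block.argmax(axis=1)]
        else:
            out[c] = encoded[c].to_numpy()
    return pd.DataFrame(out, index=encoded.index)


@dataclass
class MinMaxScalerMap:
    """Stored (min, max) per column for reproducible normalization."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)


def min_max_normalize(
    column: np.ndarray | pd.Series,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Map a column linearly onto [0, 1]: ``(x - min) / (max - min)``.

    A constant column has no scale; it maps to all-zeros with a warning
    instead of dividing by zero.
    """
    x = np.asarray(column, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        warnings.warn("constant column: min-max normalization maps it to zeros")
        return np.zeros_like(x), (lo, hi)
    return (x - lo) / (hi - lo), (lo, hi)


def normalize_frame(
    frame: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, MinMaxScalerMap]:
    """Min-max normalize the given (default: all) columns of a frame."""
    out = frame.copy()
    smap = MinMaxScalerMap()
    for c in columns if columns is not None else frame.columns:
        out[c], smap.bounds[c] = min_max_normalize(frame[c])
    return out, smap


@dataclass
class SplitIndices:
    """Disjoint train/test index sets over the labeled records."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_ids": np.asarray(self.train_ids).tolist(),
                    "test_ids": np.asarray(self.test_ids).tolist(),
                    "seed": self.seed,
                },
                indent=2,
            )
        )


def split_cohort(
    outcome: np.ndarray | pd.Series,
    time: np.ndarray | pd.Series,
    train_ratio: float = 0.8,
    seed: int = 0,
    ids: np.ndarray | None = None,
) -> SplitIndices:
    """Stratified train/test split of the labeled records.

    Strata are outcome x survival-time quintile, so both splits see
    comparable outcome rates and follow-up time distributions.  The total
    train size is ``round(n * train_ratio)`` (1370 labeled records at 0.8
    give exactly 1096/274); per-stratum sizes are allocated proportionally
    with a largest-remainder correction so the total is exact.
    """
    y = np.asarray(outcome, dtype=float)
    t = np.asarray(time, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 labeled records to split")
    if not (0.0 < train_ratio < 1.0):
        raise ValueError("train_ratio must be in (0, 1)")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)

    # survival-time quintile within the labeled set
    qs = np.quantile(t, [0.2, 0.4, 0.6, 0.8])
    quint = np.searchsorted(qs, t, side="right")
    strata = (y.astype(int) * 5 + quint).astype(int)

    n_train_total = int(round(n * train_ratio))
    rng = np.random.default_rng(seed)

    uniq = np.unique(strata)
    targets = {}
    remainders = []
    allotted = 0
    for s in uniq:
        size = int(np.sum(strata == s))
        exact = size * train_ratio
        base = int(np.floor(exact))
        targets[s] = base
        allotted += base
        remainders.append((exact - base, s))
    # largest-remainder: hand out the leftover train slots
    remainders.sort(key=lambda r: (-r[0], r[1]))
    for _, s in remainders[: n_train_total - allotted]:
        targets[s] += 1

    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for s in uniq:
        members = np.where(strata == s)[0]
        perm = rng.permutation(members)
        k = min(targets[s], len(members))
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return SplitIndices(train_ids=ids[tr], test_ids=ids[te], seed=seed)


def undersample_majority(labels: np.ndarray | pd.Series, seed: int = 0) -> np.ndarray:
    """Balance a 0/1 label vector to exactly 1:1 by down-sampling the majority.

    Keeps every minority-class index and a seeded uniform sample of the
    majority class of equal size.  Returns sorted positional indices.
    """
    y = np.asarray(labels, dtype=int)
    ones = np.where(y == 1)[0]
    zeros = np.where(y == 0)[0]
    if len(ones) == 0 or len(zeros) == 0:
        raise ValueError("both classes must be present to balance")
    minority, majority = (ones, zeros) if len(ones) <= len(zeros) else (zeros, ones)
    rng = np.random.default_rng(seed)
    kept = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, kept]))
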