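"""Per-cell feature tables and their delimited-text I/O.

Imaging flow cytometers export one row per cell and one numeric column per
extracted feature (morphology, texture, fluorescence intensities, ...),
optionally together with a categorical class label obtained from a gating
strategy (e.g. ``viable`` / ``apoptotic``).  :class:`FeatureTable` is the
in-memory form of such an export and the container every other module of
this package operates on.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("ifcstate")

__all__ = [
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "split_holdout",
    "drop_features_matching",
]


@dataclass
class FeatureTable:
    """An m x n numeric per-cell feature matrix with optional class labels.

    Parameters
    ----------
    values
        ``(m, n)`` float array; rows are cells, columns are features.
    feature_names
        ``n`` unique, non-empty column names.
    sample_ids
        Optional per-cell identifiers (length ``m``).
    labels
        Optional per-cell class labels (length ``m``); every value must
        occur in ``class_names``.
    class_names
        Ordered distinct class identifiers.  When omitted it is derived
        from ``labels`` in order of first appearance; that order fixes the
        row/column order of confusion matrices downstream.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str] | None = None
    labels: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.feature_names) != n:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {n} columns"
            )
        if len(set(self.feature_names)) != n:
            dup = sorted(
                {f for f in self.feature_names if self.feature_names.count(f) > 1}
            )
            raise ValueError(f"duplicate feature names: {dup}")
        if any(not f for f in self.feature_names):
            raise ValueError("feature names must be non-empty")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != m:
                raise ValueError("sample_ids length does not match row count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (m,):
                raise ValueError("labels length does not match row count")
            if not self.class_names:
                seen: list[str] = []
                for lab in self.labels:
                    if lab not in seen:
                        seen.append(lab)
                self.class_names = seen
            unknown = set(self.labels) - set(self.class_names)
            if unknown:
                raise ValueError(f"labels not in class_names: {sorted(unknown)}")
            if len(self.class_names) < 2:
                raise ValueError("at least 2 classes required when labels present")
        bad = ~np.isfinite(self.values)
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                f"(row {r}, column '{self.feature_names[c]}')"
                for r, c in list(zip(rows, cols))[:5]
            ]
            raise ValueError(
                f"{bad.sum()} non-finite values, e.g. {', '.join(cells)}"
            )

    # -- basic introspection -------------------------------------------------

    @property
    def m(self) -> int:
        """Number of cells (rows)."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of features (columns)."""
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> dict[str, int]:
        """Per-class cell counts in ``class_names`` order."""
        if self.labels is None:
            raise ValueError("table has no labels")
        return {c: int(np.sum(self.labels == c)) for c in self.class_names}

    def take_rows(self, idx: np.ndarray) -> "FeatureTable":
        """Row subset/permutation by integer indices."""
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx] if self.sample_ids else None,
            labels=self.labels[idx] if self.labels is not None else None,
            class_names=list(self.class_names),
        )

    def take_features(self, idx: list[int] | np.ndarray) -> "FeatureTable":
        """Column subset/permutation by integer indices."""
        idx = list(idx)
        return FeatureTable(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            sample_ids=list(self.sample_ids) if self.sample_ids else None,
            labels=self.labels.copy() if self.labels is not None else None,
            class_names=list(self.class_names),
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        """DataFrame view including sample ids and labels when present."""
        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            df[label_column] = self.labels
        if self.sample_ids is not None:
            df.insert(0, "sample_id", self.sample_ids)
        return df


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_table(
    path: str,
    label_column: str | None = "label",
    delimiter: str | None = None,
    drop_bad_rows: bool = False,
) -> FeatureTable:
    """Read a delimited feature table with a mandatory header row.

    A column named ``sample_id`` (if present) supplies per-cell identifiers.
    ``label_column`` names the class column; it is removed from the numeric
    matrix and stored as labels.  If that column is absent the table is
    returned unlabeled.  Non-numeric feature cells are an error naming the
    offending row and column; NaN/inf cells are rejected unless
    ``drop_bad_rows`` is set, in which case the affected rows are dropped
    and the count is logged.
    """
    sep = _delimiter_for(path, delimiter)
    try:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
    except FileNotFoundError:
        raise FileNotFoundError(f"feature table not found: {path}")
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise ValueError(f"duplicate header names in {path}: {dup}")
    # round_trip parsing: written doubles must reproduce bit-exactly
    df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")

    sample_ids = None
    if "sample_id" in df.columns:
        sample_ids = [str(s) for s in df.pop("sample_id")]
    labels = None
    if label_column is not None and label_column in df.columns:
        labels = df.pop(label_column).astype(str).to_numpy(dtype=object)

    feature_names = [str(c) for c in df.columns]
    for col in feature_names:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            row = int(np.nonzero(newly_bad.to_numpy())[0][0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in feature column "
                f"'{col}', data row {row}"
            )
        df[col] = coerced
    values = df.to_numpy(dtype=float)

    bad_rows = ~np.isfinite(values).all(axis=1)
    if bad_rows.any():
        if not drop_bad_rows:
            rows, cols = np.nonzero(~np.isfinite(values))
            cells = ", ".join(
                f"(row {r}, column '{feature_names[c]}')"
                for r, c in list(zip(rows, cols))[:5]
            )
            raise ValueError(
                f"{bad_rows.sum()} rows with missing/non-finite values in "
                f"{path}: {cells}; pass drop_bad_rows=True to drop them"
            )
        logger.warning("dropping %d rows with non-finite values", bad_rows.sum())
        keep = ~bad_rows
        values = values[keep]
        if labels is not None:
            labels = labels[keep]
        if sample_ids is not None:
            sample_ids = [s for s, k in zip(sample_ids, keep) if k]

    return FeatureTable(
        values=values,
        feature_names=feature_names,
        sample_ids=sample_ids,
        labels=labels,
    )


def write_feature_table(
    table: FeatureTable,
    path: str,
    label_column: str = "label",
    delimiter: str | None = None,
    float_format: str = "%.17g",
) -> None:
    """Write a table as delimited text; %.17g round-trips doubles exactly."""
    sep = _delimiter_for(path, delimiter)
    table.to_frame(label_column).to_csv(
        path, sep=sep, index=False, float_format=float_format
    )


def split_holdout(
    table: FeatureTable,
    test_fraction: float,
    seed: int,
    stratified: bool = True,
) -> tuple[FeatureTable, FeatureTable]:
    """Partition a labeled table into model-selection and held-out test parts.

    The held-out part has ``round(test_fraction * m)`` rows overall; under
    stratification each class contributes its proportional share (largest-
    remainder rounding), so per-class proportions in both parts stay within
    one sample of the full-table proportions.  Deterministic per seed.
    """
    if table.labels is None:
        raise ValueError("split_holdout requires labels")
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    m = table.m
    n_test = int(round(test_fraction * m))
    rng = np.random.default_rng(seed)

    if n_test == 0:
        return table.take_rows(np.arange(m)), table.take_rows(np.arange(0))

    if not stratified:
        perm = rng.permutation(m)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
    else:
        counts = table.class_counts()
        for c, mk in counts.items():
            if mk < 2:
                raise ValueError(
                    f"stratified split impossible: class '{c}' has {mk} member(s)"
                )
        # largest-remainder allocation of n_test across classes
        quotas = {c: test_fraction * mk for c, mk in counts.items()}
        alloc = {c: int(np.floor(q)) for c, q in quotas.items()}
        short = n_test - sum(alloc.values())
        remainders = sorted(
            table.class_names, key=lambda c: quotas[c] - alloc[c], reverse=True
        )
        for c in remainders[:short]:
            alloc[c] += 1
        test_parts, train_parts = [], []
        for c in table.class_names:
            cls_idx = np.nonzero(table.labels == c)[0]
            perm = rng.permutation(len(cls_idx))
            test_parts.append(cls_idx[perm[: alloc[c]]])
            train_parts.append(cls_idx[perm[alloc[c] :]])
        test_idx = np.sort(np.concatenate(test_parts))
        train_idx = np.sort(np.concatenate(train_parts))

    return table.take_rows(train_idx), table.take_rows(test_idx)


def drop_features_matching(
    table: FeatureTable, patterns: list[str]
) -> FeatureTable:
    """Remove feature columns whose names match any shell-style pattern.

    Used to exclude channels known to mislead classification (e.g. a
    transient viability dye) before training.  Column order of the
    remaining features is preserved; zero matches only logs a warning.
    """
    drop = set()
    for pat in patterns:
        hits = fnmatch.filter(table.feature_names, pat)
        if not hits:
            logger.warning("pattern %r matched no features", pat)
        drop.update(hits)
    keep = [i for i, f in enumerate(table.feature_names) if f not in drop]
    if not keep:
        raise ValueError("no features remain after dropping matched columns")
    if len(keep) == table.n:
        return table
    return table.take_features(keep)
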