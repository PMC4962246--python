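"""Descriptor-table I/O and degenerate-descriptor preprocessing.

The pipeline currency is :class:`LabeledDataset`: a numeric descriptor
matrix (rows = compounds, columns = descriptors) with an optional aligned
binary label vector (binder = 1, non-binder = 0).  Tables are plain
delimited text with a header row; the first column holds the compound id.

Preprocessing removes the two kinds of degenerate descriptor that make
tree induction ill-posed: columns constant across all compounds, and
columns whose full value vector exactly duplicates an earlier column (the
earlier column is kept).  Nothing else is altered — no scaling, no
imputation (missing values are rejected), and the surviving column order
is the original order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "LabeledDataset",
    "PreprocessReport",
    "read_descriptor_table",
    "write_descriptor_table",
    "read_labels",
    "read_compound_list",
    "read_free_energies",
    "preprocess_descriptors",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One screened compound: unique id plus optional name and SMILES.

    SMILES strings are carried verbatim for reporting; descriptors are
    always supplied externally, so the structure is never parsed here.
    """

    compound_id: str
    name: str | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")


@dataclass
class LabeledDataset:
    """Descriptor matrix with optional binary ER-binding labels.

    Parameters
    ----------
    matrix
        DataFrame indexed by compound id; columns are descriptor names and
        every cell is finite numeric.
    labels
        Optional Series aligned to ``matrix.index`` with values in {0, 1}
        (1 = ER binder).
    """

    matrix: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.matrix.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate compound_id: {dup!r}")
        if pd.Index(self.matrix.columns).has_duplicates:
            cols = pd.Index(self.matrix.columns)
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate descriptor name: {dup!r}")
        values = self.matrix.to_numpy()
        if values.size and not np.isfinite(values.astype(float)).all():
            raise ValueError("descriptor matrix contains non-finite values")
        if self.labels is not None:
            self.labels = pd.Series(self.labels)
            if not self.labels.index.equals(idx):
                self.labels = self.labels.reindex(idx)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()][0]
                raise ValueError(f"missing label for compound {missing!r}")
            bad = ~self.labels.isin([0, 1])
            if bad.any():
                raise ValueError(
                    f"labels must be 0/1; got {self.labels[bad].iloc[0]!r}"
                )
            self.labels = self.labels.astype(np.int64)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_compounds(self) -> int:
        return len(self.matrix)

    @property
    def n_descriptors(self) -> int:
        return self.matrix.shape[1]

    def is_labeled(self) -> bool:
        return self.labels is not None

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=np.float64)

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return self.labels.to_numpy(dtype=np.int64)

    def subset_rows(self, indices: np.ndarray) -> "LabeledDataset":
        labels = None if self.labels is None else self.labels.iloc[indices]
        return LabeledDataset(self.matrix.iloc[indices], labels)


@dataclass
class PreprocessReport:
    """Accounting of the columns removed by :func:`preprocess_descriptors`."""

    removed_constant: list[str] = field(default_factory=list)
    removed_duplicate: list[tuple[str, str]] = field(default_factory=list)
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return len(self.removed_constant) + len(self.removed_duplicate)


def _read_table(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, header=0, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no columns found")
    return df


def read_descriptor_table(
    path,
    label_column: str | None = None,
    sep: str = ",",
) -> LabeledDataset:
    """Read a delimited descriptor table into a :class:`LabeledDataset`.

    The first column is the compound id; all remaining columns must be
    numeric.  When *label_column* is given, that column is split off as the
    binary label vector and must contain no missing values.
    """
    df = _read_table(path, sep)
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate compound_id: {dup!r}")
    df = df.set_index(id_col)
    df.index.name = "compound_id"

    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        labels = df[label_column]
        if labels.isna().any():
            missing = labels.index[labels.isna()][0]
            raise ValueError(f"missing label for compound {missing!r}")
        df = df.drop(columns=[label_column])

    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric value in column {col!r}, compound {row!r}: "
                f"{df.loc[row, col]!r}"
            )
        if numeric.isna().any():
            row = df.index[numeric.isna()][0]
            raise ValueError(f"missing value in column {col!r}, compound {row!r}")
        df[col] = numeric.astype(np.float64)

    return LabeledDataset(df, labels)


def write_descriptor_table(
    ds: LabeledDataset,
    path,
    label_column: str | None = None,
    sep: str = ",",
) -> None:
    """Write *ds* back to delimited text; inverse of :func:`read_descriptor_table`.

    Values are rendered with ``repr`` precision so a read-back reproduces
    them bit-exactly.
    """
    df = ds.matrix.copy()
    if label_column is not None:
        if ds.labels is None:
            raise ValueError("dataset has no labels to write")
        df[label_column] = ds.labels
    df.to_csv(path, sep=sep, index=True, index_label="compound_id", float_format="%.17g")


def read_labels(path, sep: str = ",") -> pd.Series:
    """Read a two-column (id, label) file into a 0/1 Series."""
    df = _read_table(path, sep)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (id, label)")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate compound_id: {ids[ids.duplicated()].iloc[0]!r}")
    labels = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if labels.isna().any():
        raise ValueError("non-numeric or missing label value")
    out = pd.Series(labels.to_numpy(), index=pd.Index(ids, name="compound_id"))
    if not out.isin([0, 1]).all():
        raise ValueError("labels must be 0/1")
    return out.astype(np.int64)


def read_compound_list(path, sep: str = ",") -> list[CompoundRecord]:
    """Read an id,name,smiles compound list; SMILES is passed through verbatim."""
    df = _read_table(path, sep)
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate compound_id: {ids[ids.duplicated()].iloc[0]!r}")
    names = df.iloc[:, 1] if df.shape[1] > 1 else pd.Series([None] * len(df))
    smiles = df.iloc[:, 2] if df.shape[1] > 2 else pd.Series([None] * len(df))
    return [
        CompoundRecord(
            compound_id=i,
            name=None if pd.isna(n) else str(n),
            smiles=None if pd.isna(s) else str(s),
        )
        for i, n, s in zip(ids, names, smiles)
    ]


def read_free_energies(path, sep: str = ",") -> dict[str, float]:
    """Read a two-column (id, binding free energy in kcal/mol) file.

    The map need not cover every screened compound: docking can fail for
    individual structures, in which case the compound is simply absent.
    """
    df = _read_table(path, sep)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (id, energy)")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate compound_id: {ids[ids.duplicated()].iloc[0]!r}")
    energies = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = energies.isna() & df.iloc[:, 1].notna()
    if bad.any():
        raise ValueError(
            f"non-numeric energy for compound {ids[bad].iloc[0]!r}: "
            f"{df.iloc[:, 1][bad].iloc[0]!r}"
        )
    if energies.isna().any():
        raise ValueError(f"missing energy for compound {ids[energies.isna()].iloc[0]!r}")
    return dict(zip(ids, energies.astype(float)))


def preprocess_descriptors(
    ds: LabeledDataset,
) -> tuple[LabeledDataset, PreprocessReport]:
    """Drop constant and exact-duplicate descriptor columns.

    A column is *constant* when every compound shares one value; a column
    is a *duplicate* when its full value vector equals that of an
    earlier-listed column bit-for-bit (the earlier column is kept).
    Retained columns keep their original order and values; labels are
    untouched.  Applying the function twice removes nothing the second
    time.
    """
    if ds.n_compounds == 0 or ds.n_descriptors == 0:
        raise ValueError("cannot preprocess an empty descriptor matrix")

    values = ds.values()
    names = ds.descriptor_names
    removed_constant: list[str] = []
    removed_duplicate: list[tuple[str, str]] = []
    keep: list[int] = []
    seen: dict[bytes, int] = {}
    for j, name in enumerate(names):
        col = values[:, j]
        if np.all(col == col[0]):
            removed_constant.append(name)
            continue
        key = col.tobytes()
        if key in seen:
            removed_duplicate.append((names[seen[key]], name))
            continue
        seen[key] = j
        keep.append(j)

    report = PreprocessReport(
        removed_constant=removed_constant,
        removed_duplicate=removed_duplicate,
        n_retained=len(keep),
    )
    out = LabeledDataset(ds.matrix.iloc[:, keep], ds.labels)
    return out, report
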