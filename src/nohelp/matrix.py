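"""Core in-memory containers: count matrices, normalized expression, metadata.

Both matrix types wrap a pandas DataFrame (genes as rows, samples as
columns) and validate the invariants the downstream stages rely on:
unique non-empty identifiers, correct dtypes, non-negative values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "ExpressionMatrix", "SampleMetadata"]


def _check_ids(ids: pd.Index, kind: str) -> None:
    if len(ids) == 0:
        raise ValueError(f"empty {kind} list")
    as_str = ids.astype(str)
    if (as_str.str.strip() == "").any():
        raise ValueError(f"empty {kind} identifier")
    if as_str.duplicated().any():
        dup = as_str[as_str.duplicated()].tolist()
        raise ValueError(f"duplicate {kind} id: {dup[:5]}")


@dataclass
class CountMatrix:
    """Integer gene x sample read counts.

    ``data`` is a DataFrame indexed by gene id with sample ids as columns.
    All cells must be non-negative integers; gene and sample ids must be
    unique and non-empty.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_ids(df.index, "gene")
        _check_ids(df.columns, "sample")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values.astype(float))):
                raise ValueError("non-finite count")
            if not np.all(values == np.floor(values)):
                raise ValueError("non-integer count")
            df = df.astype(np.int64)
            object.__setattr__(self, "data", df)
            values = df.to_numpy()
        if (values < 0).any():
            raise ValueError("negative count")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.data[list(samples)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.data.equals(other.data)


@dataclass
class ExpressionMatrix:
    """Normalized gene x sample expression (CPM units unless ``log2`` set)."""

    data: pd.DataFrame
    units: str = "cpm"
    log2: bool = False

    def __post_init__(self) -> None:
        _check_ids(self.data.index, "gene")
        _check_ids(self.data.columns, "sample")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite expression value")
        if not self.log2 and (values < 0).any():
            raise ValueError("negative expression value")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def profile(self, sample_id: str) -> pd.Series:
        """One sample's per-gene expression vector."""
        return self.data[sample_id]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.units, self.log2)


@dataclass
class SampleMetadata:
    """Per-sample condition labels, with optional subject ids for matched designs."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "condition")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"metadata missing column '{col}'")
        if "subject_id" not in df.columns:
            df = df.assign(subject_id=pd.NA)
        df = df[["sample_id", "condition", "subject_id"]].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["condition"] = df["condition"].astype(str)
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        return list(dict.fromkeys(self.table["condition"]))

    def samples_in(self, condition: str) -> list[str]:
        mask = self.table["condition"] == condition
        return list(self.table.loc[mask, "sample_id"])

    def check_against(self, matrix: CountMatrix | ExpressionMatrix) -> None:
        """Require sample sets of metadata and matrix to coincide."""
        meta = set(self.sample_ids)
        mat = set(matrix.sample_ids)
        if meta != mat:
            missing = sorted(mat - meta)
            extra = sorted(meta - mat)
            raise ValueError(
                f"metadata/matrix sample mismatch (missing from metadata: "
                f"{missing[:5]}; absent from matrix: {extra[:5]})"
            )

    def require_two_conditions(self) -> tuple[str, str]:
        conds = self.conditions
        if len(conds) != 2:
            raise ValueError(
                f"exactly two conditions required, found {len(conds)}: {conds}"
            )
        return conds[0], conds[1]
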