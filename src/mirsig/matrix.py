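"""Core in-memory containers shared by every pipeline stage.

The universal numeric carrier is :class:`ExpressionMatrix`, a labelled
non-negative miRNA x column matrix where a column is a single cell, an
aggregated cell type, or a bulk sample.  Genomic intervals for miRNA genes
are carried by :class:`MirnaAnnotation` (1-based inclusive coordinates, the
GFF3 convention), and two-column pair tables (disease-miRNA, TF-miRNA,
miRNA-target) by :class:`AssociationTable`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COL_KINDS = ("cell", "cell_type", "sample")


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


def normalize_mirna_names(names) -> list[str]:
    """Lowercase miRNA identifiers; exact-string de-duplication only."""
    return [str(n).strip().lower() for n in names]


@dataclass
class ExpressionMatrix:
    """Labelled non-negative matrix: rows = miRNAs, columns = cells /
    cell types / samples.

    Parameters
    ----------
    data : pandas.DataFrame
        Numeric values; index = miRNA names, columns = column labels.
    col_kind : str
        One of ``cell``, ``cell_type``, ``sample``.
    """

    data: pd.DataFrame
    col_kind: str = "cell_type"

    def __post_init__(self) -> None:
        if self.col_kind not in COL_KINDS:
            raise ValidationError(
                f"col_kind must be one of {COL_KINDS}, got {self.col_kind!r}"
            )
        self.data = self.data.astype(float)

    def validate(self) -> "ExpressionMatrix":
        df = self.data
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"matrix must be at least 2x2, got {df.shape[0]}x{df.shape[1]}"
            )
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated row names after loading: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated column labels: {dups[:5]}")
        vals = df.to_numpy()
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at row {df.index[bad[0]]!r}, "
                f"column {df.columns[bad[1]]!r}"
            )
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value at row {df.index[bad[0]]!r}, "
                f"column {df.columns[bad[1]]!r}"
            )
        return self

    @property
    def row_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def merge_duplicate_rows(df: pd.DataFrame, how: str = "sum") -> pd.DataFrame:
    """Combine rows sharing one (normalized) miRNA name.

    Counts/CPM are additive across redundant annotations, so the default
    combine rule is summation; ``how="mean"`` is available for intensity-like
    units.  First-appearance row order is preserved.
    """
    if how not in ("sum", "mean"):
        raise ValueError(f"unknown combine rule {how!r}")
    if not df.index.duplicated().any():
        return df
    order = df.index[~df.index.duplicated()].tolist()
    grouped = df.groupby(level=0, sort=False)
    out = grouped.sum() if how == "sum" else grouped.mean()
    return out.loc[order]


@dataclass
class MirnaAnnotation:
    """miRNA gene intervals, 1-based inclusive, chromosome names verbatim.

    ``df`` columns: chrom (str), start (int), end (int), strand ("+"/"-"),
    name (str, unique).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "strand", "name"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        self.df = self.df[required].reset_index(drop=True)
        self.df["start"] = self.df["start"].astype(int)
        self.df["end"] = self.df["end"].astype(int)

    def validate(self) -> "MirnaAnnotation":
        if len(self.df) == 0:
            raise ValidationError("annotation contains zero records")
        if (self.df["start"] > self.df["end"]).any():
            bad = self.df.loc[self.df["start"] > self.df["end"], "name"].iloc[0]
            raise ValidationError(f"start > end for record {bad!r}")
        if self.df["name"].duplicated().any():
            dups = self.df.loc[self.df["name"].duplicated(), "name"].unique()
            raise ValidationError(f"duplicated miRNA names: {list(dups[:5])}")
        return self

    @property
    def names(self) -> list[str]:
        return list(self.df["name"])

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class AssociationTable:
    """Pairs (key, mirna) with an optional per-pair causal flag.

    ``key`` is a disease, transcription factor, or target-gene identifier
    depending on the source table; miRNA names are case-normalized and
    duplicate (key, mirna) pairs are collapsed (a pair is causal if any of
    its occurrences was flagged causal).
    """

    df: pd.DataFrame
    kind: str = "association"

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "causal" not in df.columns:
            df["causal"] = False
        df["mirna"] = normalize_mirna_names(df["mirna"])
        df["key"] = df["key"].astype(str)
        df["causal"] = df["causal"].astype(bool)
        dup = df.duplicated(subset=["key", "mirna"], keep=False)
        if dup.any():
            df = (
                df.groupby(["key", "mirna"], sort=False, as_index=False)
                .agg(causal=("causal", "any"))
            )
        self.df = df.reset_index(drop=True)

    def sets_by_key(self, causal_only: bool = False) -> dict[str, set[str]]:
        sub = self.df[self.df["causal"]] if causal_only else self.df
        return {
            k: set(g["mirna"]) for k, g in sub.groupby("key", sort=False)
        }

    @property
    def mirnas(self) -> set[str]:
        return set(self.df["mirna"])

    def __len__(self) -> int:
        return len(self.df)


def warn_data(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=3)
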