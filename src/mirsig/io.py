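"""Readers and writers for every external format the pipeline touches.

Formats: tab-separated labelled matrices, MatrixMarket coordinate triplets
with ``rows.txt``/``cols.txt`` sidecars, miRBase-dialect GFF3, BED4+ peak
intervals, GMT signature sets, and two-column association tables.  All
readers validate on load and return the shared in-memory containers from
:mod:`mirsig.matrix`.

Coordinate conventions: GFF3 is kept 1-based inclusive internally; BED is
converted from 0-based half-open at the parser boundary, so all downstream
overlap arithmetic is done on 1-based inclusive intervals.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import (
    AssociationTable,
    ExpressionMatrix,
    MirnaAnnotation,
    ValidationError,
    merge_duplicate_rows,
    normalize_mirna_names,
    warn_data,
)

# ---------------------------------------------------------------------------
# expression matrices


def read_matrix(
    path: str | Path,
    fmt: str = "tsv",
    col_kind: str = "cell_type",
    combine: str = "sum",
) -> ExpressionMatrix:
    """Read a miRNA x column matrix from TSV or a MatrixMarket triplet.

    Duplicated miRNA rows (after case normalization) are merged; the default
    combine rule is summation.  For ``fmt="mtx-triplet"`` the path names the
    ``.mtx`` file and sidecar ``rows.txt``/``cols.txt`` files must sit next
    to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if fmt == "tsv":
        df = _read_tsv_matrix(path)
    elif fmt == "mtx-triplet":
        df = _read_mtx_triplet(path)
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    df.index = normalize_mirna_names(df.index)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate column label(s) in {path}: {dups[:5]}")
    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        warn_data(f"{path}: merged {n_dup} duplicated miRNA row(s) by {combine}")
        df = merge_duplicate_rows(df, how=combine)
    return ExpressionMatrix(df, col_kind=col_kind).validate()


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = pd.Index(header)
    if seen.duplicated().any():  # pandas would silently mangle these
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate column label(s): {dups[:5]}")
    # round_trip parsing keeps write -> read bitwise-exact
    df = pd.read_csv(path, sep="\t", index_col=0, header=0,
                     float_precision="round_trip")
    try:
        df = df.astype(float)
    except ValueError as exc:
        # locate the offending cell for the error message
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValidationError(
                    f"{path}: malformed numeric cell at row {row!r}, "
                    f"column {col!r}: {df.loc[row, col]!r}"
                ) from exc
        raise
    return df


def _read_mtx_triplet(path: Path) -> pd.DataFrame:
    rows_file = path.parent / "rows.txt"
    cols_file = path.parent / "cols.txt"
    for side in (rows_file, cols_file):
        if not side.exists():
            raise FileNotFoundError(f"missing sidecar name file: {side}")
    mat = scipy.io.mmread(os.fspath(path))
    dense = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
    )
    row_names = rows_file.read_text().splitlines()
    col_names = cols_file.read_text().splitlines()
    if len(row_names) != dense.shape[0] or len(col_names) != dense.shape[1]:
        raise ValidationError(
            f"{path}: matrix is {dense.shape} but sidecars name "
            f"{len(row_names)} rows / {len(col_names)} columns"
        )
    return pd.DataFrame(dense, index=row_names, columns=col_names)


def write_matrix(mat: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix as TSV (header row, first column = miRNA)."""
    df = mat.data if isinstance(mat, ExpressionMatrix) else mat
    df.to_csv(path, sep="\t", index_label="mirna")


def write_mtx_triplet(mat: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write MatrixMarket coordinate format plus rows.txt/cols.txt sidecars."""
    df = mat.data if isinstance(mat, ExpressionMatrix) else mat
    path = Path(path)
    scipy.io.mmwrite(os.fspath(path), scipy.sparse.coo_matrix(df.to_numpy()))
    (path.parent / "rows.txt").write_text("\n".join(map(str, df.index)) + "\n")
    (path.parent / "cols.txt").write_text("\n".join(map(str, df.columns)) + "\n")


# ---------------------------------------------------------------------------
# miRBase GFF3


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, _, v = part.partition("=")
            out[k.strip()] = v.strip()
    return out


def read_mirna_gff3(
    path: str | Path, feature_type: str = "miRNA_primary_transcript"
) -> MirnaAnnotation:
    """Parse a miRBase-dialect GFF3 into gene-level miRNA intervals.

    By default only ``miRNA_primary_transcript`` features are retained
    (gene-level coordinates); pass ``feature_type="miRNA"`` for mature
    products instead.  Features missing a ``Name=`` attribute are skipped
    with a warning; zero retained records is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    records: list[dict] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            if fields[2] != feature_type:
                continue
            attrs = _gff3_attributes(fields[8])
            name = attrs.get("Name")
            if name is None:
                skipped += 1
                continue
            records.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[3]),
                    "end": int(fields[4]),
                    "strand": fields[6] if fields[6] in "+-" else "+",
                    "name": name.lower(),
                }
            )
    if skipped:
        warn_data(f"{path}: skipped {skipped} feature(s) without a Name attribute")
    if not records:
        raise ValidationError(
            f"{path}: no {feature_type!r} records with Name attributes found"
        )
    df = pd.DataFrame(records)
    if df["name"].duplicated().any():
        n = int(df["name"].duplicated().sum())
        warn_data(f"{path}: dropped {n} duplicate-name record(s), kept first")
        df = df[~df["name"].duplicated()]
    return MirnaAnnotation(df).validate()


def write_mirna_gff3(ann: MirnaAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, rec in enumerate(ann.df.itertuples(index=False)):
            fh.write(
                f"{rec.chrom}\t.\tmiRNA_primary_transcript\t{rec.start}\t"
                f"{rec.end}\t.\t{rec.strand}\t.\t"
                f"ID=MI{i:07d};Name={rec.name}\n"
            )


# ---------------------------------------------------------------------------
# BED peaks


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """Read BED4+ peak intervals; convert to 1-based inclusive coordinates.

    Returns a DataFrame with columns chrom, start, end, name and, when a
    fifth column is present, score.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: BED needs at least 3 columns")
    cols = ["chrom", "start", "end", "name", "score"][: df.shape[1]]
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if "name" not in df.columns:
        df["name"] = [f"peak_{i}" for i in range(len(df))]
    # BED is 0-based half-open; internal convention is 1-based inclusive
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise ValidationError(f"{path}: malformed interval (start > end)")
    return df.reset_index(drop=True)


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    out = peaks.copy()
    out["start"] = out["start"].astype(int) - 1  # back to 0-based half-open
    cols = [c for c in ["chrom", "start", "end", "name", "score"] if c in out.columns]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# cell annotation (barcode -> cell type)


def read_cell_annotation(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping cell barcode to cell-type label."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need barcode and cell-type columns")
    if df.iloc[0, 0] in ("barcode", "cell"):  # tolerate a header line
        df = df.iloc[1:]
    if df[0].duplicated().any():
        dup = df.loc[df[0].duplicated(), 0].iloc[0]
        raise ValidationError(f"{path}: barcode {dup!r} labelled more than once")
    return dict(zip(df[0], df[1]))


# ---------------------------------------------------------------------------
# GMT signature sets


def write_signature_gmt(catalog, path: str | Path) -> None:
    """One line per cell type: name, description, tab-separated member list.

    The description records the member count and the Gini threshold used.
    Cell types whose signatures were entirely filtered away still get a
    header-only line so the catalog round-trips completely.
    """
    entries = catalog.entries
    if not entries:
        raise ValidationError("cannot write an empty catalog")
    thr = catalog.params.get("gini_threshold", "")
    with open(path, "w") as fh:
        for cell_type, members in entries.items():
            names = [m.mirna for m in members]
            desc = f"n={len(names)};gini>{thr}"
            fh.write("\t".join([cell_type, desc, *names]) + "\n")


def read_signature_gmt(path: str | Path):
    """Read a GMT written by :func:`write_signature_gmt` (names only)."""
    from .specificity import SignatureCatalog, SignatureEntry

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    entries: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}: GMT line needs name and description")
            name, _desc, *members = fields
            entries[name] = [
                SignatureEntry(mirna=m, distance=float("nan"), gini=float("nan"))
                for m in members
            ]
    return SignatureCatalog(entries=entries, params={})


# ---------------------------------------------------------------------------
# association tables


def read_associations(
    path: str | Path, kind: str = "association"
) -> AssociationTable:
    """Two-column TSV of (key, mirna) pairs with an optional causal column.

    A header line is detected by the literal column names (``key``/
    ``disease``/``tf``/``target`` and ``mirna``).  The causal column accepts
    yes/no, true/false, or 1/0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need at least key and mirna columns")
    first = [str(x).lower() for x in df.iloc[0]]
    if first[0] in ("key", "disease", "tf", "target") or first[1] == "mirna":
        df = df.iloc[1:].reset_index(drop=True)
    out = pd.DataFrame({"key": df[0], "mirna": df[1]})
    if df.shape[1] >= 3:
        out["causal"] = (
            df[2].fillna("").str.strip().str.lower().isin(("yes", "true", "1", "causal"))
        )
    return AssociationTable(out, kind=kind)


def write_associations(table: AssociationTable, path: str | Path) -> None:
    df = table.df.copy()
    df["causal"] = np.where(df["causal"], "yes", "no")
    df.to_csv(path, sep="\t", header=["key", "mirna", "causal"], index=False)
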