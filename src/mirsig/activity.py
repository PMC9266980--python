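"""Chromatin activity of miRNA genes from single-cell ATAC peak matrices.

The activity of a miRNA in a cell is the sum of the scores of all peaks in
that cell whose interval overlaps (by at least 1 bp) a window extending the
miRNA gene by ``window_bp`` on each side.  Per-cell activities are then
averaged within each annotated cell type to give the miRNA x cell-type
chromatin activity matrix — a proxy for the transcriptional potential of
the locus in that cell type.  ATAC accessibility is unstranded, so strand
is ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from intervaltree import IntervalTree

from .matrix import ExpressionMatrix, MirnaAnnotation, ValidationError

DEFAULT_WINDOW_BP = 2000


@dataclass
class PeakSet:
    """Peak intervals aligned to the rows of a peak x cell score matrix.

    ``peaks``: DataFrame with chrom/start/end (1-based inclusive), row i
    describing row i of ``matrix``.  ``barcodes`` align to the columns and
    ``cell_type_of`` maps every barcode to exactly one cell-type label.
    """

    peaks: pd.DataFrame
    matrix: scipy.sparse.spmatrix
    barcodes: list[str]
    cell_type_of: dict[str, str]

    def __post_init__(self) -> None:
        self.matrix = scipy.sparse.csc_matrix(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.peaks), len(self.barcodes)):
            raise ValidationError(
                f"peak matrix is {self.matrix.shape} but there are "
                f"{len(self.peaks)} peaks and {len(self.barcodes)} barcodes"
            )
        if (self.peaks["start"] > self.peaks["end"]).any():
            raise ValidationError("malformed peak interval (start > end)")
        missing = [b for b in self.barcodes if b not in self.cell_type_of]
        if missing:
            raise ValidationError(
                f"{len(missing)} barcode(s) lack a cell-type label, "
                f"e.g. {missing[:3]}"
            )


def mirna_window(ann: MirnaAnnotation, window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Extend each miRNA gene interval by ``window_bp`` on both sides.

    Coordinates are clamped at position 1; strand is ignored.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    win = ann.df.copy()
    win["start"] = np.maximum(1, win["start"] - window_bp)
    win["end"] = win["end"] + window_bp
    return win[["chrom", "start", "end", "name"]]


def score_mirna_by_cell(peaks: PeakSet, windows: pd.DataFrame) -> ExpressionMatrix:
    """Sum peak scores per cell over each miRNA's window (miRNA x cell).

    Any >= 1 bp intersection counts, with no length weighting; a peak that
    overlaps two windows contributes its full score to both.  miRNAs whose
    window overlaps no peak keep an all-zero row.
    """
    peak_chroms = set(peaks.peaks["chrom"])
    win_chroms = set(windows["chrom"])
    if not peak_chroms & win_chroms:
        raise ValidationError(
            "peak and miRNA chromosome names share no entries "
            f"(peaks use e.g. {sorted(peak_chroms)[:3]}, miRNAs "
            f"{sorted(win_chroms)[:3]}) — check naming (chr1 vs 1)"
        )
    # interval tree per chromosome over windows; trees use half-open ends
    trees: dict[str, IntervalTree] = {}
    for idx, rec in enumerate(windows.itertuples(index=False)):
        trees.setdefault(rec.chrom, IntervalTree()).addi(
            rec.start, rec.end + 1, idx
        )
    n_mirna = len(windows)
    rows: list[int] = []  # miRNA index
    cols: list[int] = []  # peak index
    for p_idx, rec in enumerate(peaks.peaks.itertuples(index=False)):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(rec.start, rec.end + 1):
            rows.append(hit.data)
            cols.append(p_idx)
    indicator = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(n_mirna, len(peaks.peaks)),
    )
    scores = np.asarray((indicator @ peaks.matrix).todense(), dtype=float)
    df = pd.DataFrame(scores, index=list(windows["name"]), columns=peaks.barcodes)
    return ExpressionMatrix(df, col_kind="cell")


def aggregate_by_cell_type(
    per_cell: ExpressionMatrix, cell_type_of: dict[str, str]
) -> ExpressionMatrix:
    """Average per-cell columns within each cell-type label.

    Cell types are ordered by first appearance among the matrix columns.
    """
    missing = [c for c in per_cell.col_names if c not in cell_type_of]
    if missing:
        raise ValidationError(
            f"{len(missing)} column(s) missing from the cell annotation, "
            f"e.g. {missing[:3]}"
        )
    labels = [cell_type_of[c] for c in per_cell.col_names]
    order = list(dict.fromkeys(labels))
    grouped = per_cell.data.T.groupby(pd.Series(labels, index=per_cell.data.columns), sort=False).mean().T
    grouped = grouped[order]
    return ExpressionMatrix(grouped, col_kind="cell_type")


@dataclass
class ActivityResult:
    """miRNA x cell-type activity matrix plus the window size that made it."""

    matrix: ExpressionMatrix
    window_bp: int


def chromatin_activity(
    peaks: PeakSet, ann: MirnaAnnotation, window_bp: int = DEFAULT_WINDOW_BP
) -> ActivityResult:
    """Full stage: windows -> per-cell peak-score sums -> cell-type means."""
    windows = mirna_window(ann, window_bp)
    per_cell = score_mirna_by_cell(peaks, windows)
    mat = aggregate_by_cell_type(per_cell, peaks.cell_type_of)
    return ActivityResult(matrix=mat, window_bp=window_bp)
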