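"""Cell-type composition scoring of bulk miRNA profiles (mirCellType core).

Each bulk sample is scored against every cell type's signature set by one
of two methods:

* ``ssgsea`` — a single-sample rank-based running-sum enrichment score.
  miRNAs are ordered by descending expression; walking down that order, an
  in-set hit advances a weighted empirical CDF (weights ``|rank|^alpha``
  normalized to sum 1, alpha = 0.25 by default) while an out-of-set miss
  advances a uniform CDF.  The score is the integrated difference of the
  two CDFs summed over all positions.  High scores mean the signature
  concentrates at the top of the sample's expression profile.
* ``abundance`` — log2 geometric mean of the signature members'
  (expression + pseudocount); identical to the mean of
  log2(x + pseudocount) over the members.

Both scores are relative measures of a cell type's contribution, not
proportions summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix, ValidationError, merge_duplicate_rows, warn_data
from .specificity import SignatureCatalog

DEFAULT_ALPHA = 0.25
DEFAULT_PSEUDOCOUNT = 1.0


def _present_members(signature: set[str], rows: pd.Index, label: str = "") -> list[str]:
    members = [m for m in rows if m in signature]
    absent = len(signature) - len(members)
    if absent:
        warn_data(
            f"{absent} signature member(s){' for ' + label if label else ''} "
            "absent from the expression matrix; dropped"
        )
    return members


def ssgsea_score(
    expr: pd.DataFrame | ExpressionMatrix,
    signature: set[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Integrated running-sum enrichment score per sample.

    Tie handling is deterministic: average ranks supply the weights while
    the walking order breaks ties by input row order (stable sort).  A
    sample with all-zero expression has no ranking and scores NaN; when
    every measured miRNA is in the set there is no out-of-set CDF and the
    score is defined as 0.
    """
    df = expr.data if isinstance(expr, ExpressionMatrix) else expr
    members = _present_members(set(signature), df.index)
    if not members:
        return pd.Series(np.nan, index=df.columns, name="ssgsea")
    in_set = df.index.isin(members)
    n_out = int((~in_set).sum())
    vals = df.to_numpy(dtype=float)
    scores = np.empty(df.shape[1])
    for j in range(df.shape[1]):
        x = vals[:, j]
        if x.sum() == 0:
            warn_data(f"sample {df.columns[j]!r} is all-zero; ssGSEA undefined")
            scores[j] = np.nan
            continue
        if n_out == 0:
            scores[j] = 0.0
            continue
        order = np.argsort(-x, kind="stable")
        ranks = rankdata(x, method="average")  # largest value -> rank N
        w = np.abs(ranks) ** alpha
        w_in = np.where(in_set, w, 0.0)
        w_in /= w_in.sum()
        cdf_in = np.cumsum(w_in[order])
        cdf_out = np.cumsum(np.where(in_set, 0.0, 1.0 / n_out)[order])
        scores[j] = float(np.sum(cdf_in - cdf_out))
    return pd.Series(scores, index=df.columns, name="ssgsea")


def abundance_score(
    expr: pd.DataFrame | ExpressionMatrix,
    signature: set[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """log2 geometric mean of (member expression + pseudocount) per sample."""
    df = expr.data if isinstance(expr, ExpressionMatrix) else expr
    members = _present_members(set(signature), df.index)
    if not members:
        return pd.Series(np.nan, index=df.columns, name="abundance")
    sub = df.loc[members].to_numpy(dtype=float)
    scores = np.log2(sub + pseudocount).mean(axis=0)
    return pd.Series(scores, index=df.columns, name="abundance")


@dataclass
class ScoreMatrix:
    """Cell type x sample composition scores with clustering orders."""

    data: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)
    dropped_members: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="cell_type")


def _cluster_order(df: pd.DataFrame, axis: int) -> list[str]:
    labels = list(df.index if axis == 0 else df.columns)
    if len(labels) < 3:
        return labels
    mat = df.to_numpy() if axis == 0 else df.to_numpy().T
    finite = np.isfinite(mat).all(axis=1)
    if not finite.all():  # rows with NaN scores cannot be clustered; append them
        usable = [l for l, f in zip(labels, finite) if f]
        rest = [l for l, f in zip(labels, finite) if not f]
        if len(usable) < 3:
            return labels
        sub = mat[finite]
        link = sch.linkage(ssd.pdist(sub), method="average")
        return [usable[i] for i in sch.leaves_list(link)] + rest
    link = sch.linkage(ssd.pdist(mat), method="average")
    return [labels[i] for i in sch.leaves_list(link)]


def score_all(
    expr: ExpressionMatrix,
    catalog: SignatureCatalog,
    method: str = "ssgsea",
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalize: bool = False,
) -> ScoreMatrix:
    """Score every sample against every cell type's signature.

    Duplicated expression rows are combined (summed) before scoring.  With
    ``normalize=True`` ssGSEA scores are divided by the global score range
    across the whole matrix.  Average-linkage clustering orders for rows
    and columns are attached for heatmap rendering.
    """
    if method not in ("ssgsea", "abundance"):
        raise ValueError(f"unknown scoring method {method!r}")
    if not catalog.entries:
        raise ValidationError("catalog is empty")
    df = merge_duplicate_rows(expr.data, how="sum")
    rows = {}
    dropped = {}
    for cell_type, sig in catalog.sets().items():
        present = [m for m in sig if m in df.index]
        dropped[cell_type] = len(sig) - len(present)
        if not present:
            warn_data(f"no signature members of {cell_type!r} in the matrix")
            rows[cell_type] = pd.Series(np.nan, index=df.columns)
            continue
        if method == "ssgsea":
            rows[cell_type] = ssgsea_score(df, set(present), alpha=alpha)
        else:
            rows[cell_type] = abundance_score(df, set(present), pseudocount=pseudocount)
    data = pd.DataFrame(rows).T
    data = data.loc[list(catalog.entries), list(df.columns)]
    if normalize:
        rng = np.nanmax(data.to_numpy()) - np.nanmin(data.to_numpy())
        if rng > 0:
            data = data / rng
    params = {
        "alpha": alpha,
        "pseudocount": pseudocount,
        "normalize": normalize,
    }
    return ScoreMatrix(
        data=data,
        method=method,
        params=params,
        row_order=_cluster_order(data, axis=0),
        col_order=_cluster_order(data, axis=1),
        dropped_members=dropped,
    )
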