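"""Gini specificity index and assembly of the cell-type-specific catalog.

The Gini coefficient of a miRNA's profile across n cell types measures how
concentrated its signal is: 0 for a perfectly even distribution, 1 - 1/n
when all signal sits in a single cell type.  With values x ordered
ascending it is

    G = (n+1)/n - 2 * sum_i (n+1-i) x_(i) / (n * sum(x)),

equivalently half the mean absolute pairwise difference divided by the
mean.  Candidate signatures from the correspondence-analysis ranking are
hard-filtered at G > 0.5 by default; survivors form the cell-type-specific
miRNA catalog.

Note on ordering: applying the weight (n+1-i) to *descending*-ordered
values yields negative numbers for concentrated profiles (e.g. (1, 0) gives
-0.5), the opposite of the stated meaning of the index; the ascending form
used here is the standard Gini and gives (1, 0) -> 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError, warn_data
from .mca import SignatureRanking, top_k

DEFAULT_GINI_THRESHOLD = 0.5


def gini(x) -> float:
    """Gini coefficient of a non-negative vector (length >= 2).

    Returns NaN when all entries are zero (specificity of an unobserved
    miRNA is undefined); raises on negative entries.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("gini needs a 1-D vector of length >= 2")
    if (x < 0).any():
        raise ValidationError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        return float("nan")
    n = x.size
    xs = np.sort(x)  # ascending
    i = np.arange(1, n + 1)
    return float((n + 1) / n - 2.0 * np.sum((n + 1 - i) * xs) / (n * total))


def specificity_index(mat: ExpressionMatrix) -> pd.Series:
    """Row-wise Gini over cell-type columns; NaN for all-zero rows."""
    vals = mat.data.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("specificity index requires non-negative values")
    n = vals.shape[1]
    if n < 2:
        raise ValidationError("need at least 2 cell types")
    totals = vals.sum(axis=1)
    xs = np.sort(vals, axis=1)
    i = np.arange(1, n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (n + 1) / n - 2.0 * (xs * (n + 1 - i)).sum(axis=1) / (n * totals)
    g = np.where(totals > 0, g, np.nan)
    n_zero = int((totals == 0).sum())
    if n_zero:
        warn_data(f"{n_zero} all-zero miRNA row(s): Gini undefined, reported NaN")
    return pd.Series(g, index=mat.data.index, name="gini")


@dataclass
class SignatureEntry:
    mirna: str
    distance: float
    gini: float


@dataclass
class SignatureCatalog:
    """Per-cell-type ordered signature lists with embedding distance and
    Gini value, plus the parameters that produced them."""

    entries: dict[str, list[SignatureEntry]]
    params: dict = field(default_factory=dict)

    def sets(self) -> dict[str, set[str]]:
        return {t: {e.mirna for e in members} for t, members in self.entries.items()}

    def sizes(self) -> pd.Series:
        return pd.Series({t: len(m) for t, m in self.entries.items()}, name="n")

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for members in self.entries.values():
            out.update(e.mirna for e in members)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell_type, members in self.entries.items():
            for rank, e in enumerate(members, start=1):
                rows.append(
                    {
                        "cell_type": cell_type,
                        "rank": rank,
                        "mirna": e.mirna,
                        "distance": e.distance,
                        "gini": e.gini,
                    }
                )
        return pd.DataFrame(
            rows, columns=["cell_type", "rank", "mirna", "distance", "gini"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_catalog(
    ranking: SignatureRanking,
    mat: ExpressionMatrix,
    k: int = 20,
    threshold: float = DEFAULT_GINI_THRESHOLD,
    **extra_params,
) -> SignatureCatalog:
    """Top-k signature candidates filtered at Gini > threshold.

    The Gini is computed on the same (raw) matrix that fed the embedding.
    Rank order is preserved; a cell type may end up with an empty signature
    and is still recorded.  miRNAs with undefined Gini (all-zero rows) are
    ineligible.
    """
    g = specificity_index(mat)
    heads = top_k(ranking, k)
    entries: dict[str, list[SignatureEntry]] = {}
    for cell_type, df in heads.items():
        members = []
        for rec in df.itertuples(index=False):
            gv = g.get(rec.mirna, np.nan)
            if np.isnan(gv) or gv <= threshold:
                continue
            members.append(
                SignatureEntry(mirna=rec.mirna, distance=float(rec.distance), gini=float(gv))
            )
        entries[cell_type] = members
    params = {"k": k, "gini_threshold": threshold, **extra_params}
    return SignatureCatalog(entries=entries, params=params)
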