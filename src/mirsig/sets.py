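"""Signature-set comparison and specificity-vs-covariate correlation.

Jaccard similarity between cell types' signature sets (with an
average-linkage clustering order for heatmaps), distinct-partner counts
from TF-miRNA / miRNA-target pair tables, and Spearman correlation of the
Gini specificity index against any per-miRNA covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from .matrix import AssociationTable, ValidationError
from .specificity import SignatureCatalog


def jaccard(A: set, B: set) -> float:
    """|A n B| / |A u B|; two empty sets give 0 (no similarity evidence)."""
    union = len(A | B)
    if union == 0:
        return 0.0
    return len(A & B) / union


def jaccard_matrix(catalog: SignatureCatalog) -> tuple[pd.DataFrame, list[str]]:
    """All pairwise Jaccard similarities plus a dendrogram leaf order.

    Clustering uses average linkage on the distance 1 - J; the returned
    order is the heatmap row/column order.
    """
    sets = catalog.sets()
    names = list(sets)
    if len(names) < 2:
        raise ValidationError("need at least 2 cell types")
    n = len(names)
    J = np.eye(n)
    for i in range(n):
        if not sets[names[i]]:
            J[i, i] = 0.0  # empty set: J(S, S) = 0 under the empty-set rule
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jaccard(sets[names[i]], sets[names[j]])
    dist = 1.0 - J
    np.fill_diagonal(dist, 0.0)
    linkage = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    order = [names[i] for i in sch.leaves_list(linkage)]
    return pd.DataFrame(J, index=names, columns=names), order


def count_partners(assoc: AssociationTable, mirnas=None) -> pd.Series:
    """Distinct partner keys per miRNA (not pair multiplicities).

    When ``mirnas`` is given the result is reindexed to it, absent miRNAs
    getting 0.
    """
    counts = assoc.df.groupby("mirna", sort=False)["key"].nunique()
    if mirnas is not None:
        counts = counts.reindex(list(mirnas), fill_value=0)
    return counts.astype(int).rename("n_partners")


def correlate_specificity(
    gini: pd.Series, cov: pd.Series, exact: bool = False
) -> tuple[float, float]:
    """Spearman correlation between the specificity index and a covariate.

    Pairs by miRNA name (inner join), drops missing values, and requires at
    least 3 paired observations.  The p-value uses the large-sample t
    approximation; with ``exact=True`` and n <= 10 an exact permutation
    p-value is computed instead.
    """
    joined = pd.concat([gini.rename("g"), cov.rename("c")], axis=1, join="inner")
    joined = joined.dropna()
    n = len(joined)
    if n < 3:
        raise ValidationError(f"need >= 3 paired observations, got {n}")
    rho, p = scipy.stats.spearmanr(joined["g"], joined["c"])
    if exact and n <= 10:
        p = _exact_spearman_p(joined["g"].to_numpy(), joined["c"].to_numpy(), rho)
    return float(rho), float(p)


def _exact_spearman_p(x, y, rho_obs) -> float:
    """Two-sided exact p by enumerating all pairings of one variable."""
    from itertools import permutations

    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    hits = total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in permutations(range(n)):
        r = float(rx[list(perm)] @ ry) / n
        hits += abs(r) >= thresh
        total += 1
    return hits / total
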