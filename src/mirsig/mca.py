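"""Joint embedding of cell types and miRNAs by correspondence analysis.

Continuous expression (or chromatin activity) values are fuzzy-coded: each
miRNA is min-max scaled across cell types to u in [0, 1] and doubled into a
complementary pair (u, 1-u), turning the data into a non-negative
cell-type x 2m table whose feature pairs each sum to one.  Correspondence
analysis of that table places cell types and miRNA features in one
Euclidean space in which a short cell-to-feature distance means the miRNA's
signal concentrates in that cell type.  Ranking features by distance to a
cell type and cutting at the top k yields that cell type's candidate
signature.

Because min-max scaling absorbs any per-miRNA affine transform a*x + b
(a > 0), the embedding and all rankings are invariant to such rescalings of
the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError, warn_data

DEFAULT_TOP_K = 20
_RANK_TOL = 1e-12


@dataclass
class FuzzyCoded:
    """Doubled indicator-like table: rows = cell types, columns = feature
    pairs (positive, negative)."""

    table: np.ndarray  # n_cell_types x 2m, pairs interleaved
    cell_names: list[str]
    feature_names: list[str]  # m retained features (positive members)
    dropped: list[str]  # constant rows removed before coding


@dataclass
class McaEmbedding:
    cell_coords: pd.DataFrame  # cell type x d
    feature_coords: pd.DataFrame  # miRNA x d (positive pair members only)
    inertia: np.ndarray  # per-dimension explained inertia, non-increasing
    d: int
    dropped: list[str] = field(default_factory=list)


@dataclass
class SignatureRanking:
    """Per cell type: every retained miRNA with its embedding distance,
    ascending; ties ordered lexicographically by name."""

    per_type: dict[str, pd.DataFrame]  # columns: mirna, distance

    def cell_types(self) -> list[str]:
        return list(self.per_type)


def fuzzy_code(mat: ExpressionMatrix) -> FuzzyCoded:
    """Min-max scale each miRNA across cell types and double into (u, 1-u).

    Rows constant across all cell types have no defined scaling and are
    dropped with a warning.
    """
    df = mat.data
    if df.shape[1] < 2:
        raise ValidationError("fuzzy coding needs at least 2 columns")
    vals = df.to_numpy(dtype=float)
    rng = vals.max(axis=1) - vals.min(axis=1)
    keep = rng > 0
    dropped = [n for n, k in zip(df.index, keep) if not k]
    if dropped:
        warn_data(
            f"dropped {len(dropped)} miRNA(s) constant across cell types, "
            f"e.g. {dropped[:3]}"
        )
    vals = vals[keep]
    u = (vals - vals.min(axis=1, keepdims=True)) / rng[keep, None]
    m, n = u.shape
    table = np.empty((n, 2 * m))
    table[:, 0::2] = u.T
    table[:, 1::2] = 1.0 - u.T
    return FuzzyCoded(
        table=table,
        cell_names=list(df.columns),
        feature_names=[n_ for n_, k in zip(df.index, keep) if k],
        dropped=dropped,
    )


def default_dims(n_cell_types: int, cap: int = 50) -> int:
    return max(1, min(cap, n_cell_types - 1))


def correspondence_analysis(
    coded: FuzzyCoded, d: int | None = None, scaling: str = "asymmetric"
) -> McaEmbedding:
    """Correspondence analysis of the fuzzy-coded table.

    With P the table divided by its grand total, row masses r = P 1 and
    column masses c = P' 1, the standardized residuals
    S = Dr^{-1/2} (P - r c') Dc^{-1/2} are decomposed by SVD; the first d
    axes are kept.  Only the positive member of each doubled feature pair
    is reported.  Per-axis inertia is the squared singular value.

    ``scaling`` picks the joint-map convention:

    * ``asymmetric`` (default) — cell types in standard coordinates
      (Dr^{-1/2} U), features in principal coordinates (Dc^{-1/2} V S).  A
      feature then sits exactly at the profile-weighted barycenter of the
      cell-type points, so an indicator-like feature lands on its cell
      type and cell-to-feature Euclidean distance directly measures
      association — the geometry the signature ranking relies on.
    * ``principal`` — both sides scaled by the singular values (axes
      weighted by explained inertia).
    * ``standard`` — neither side scaled.
    """
    if scaling not in ("asymmetric", "principal", "standard"):
        raise ValueError(f"unknown scaling {scaling!r}")
    F = np.asarray(coded.table, dtype=float)
    if (F < 0).any():
        raise ValidationError("correspondence analysis requires a non-negative table")
    total = F.sum()
    if total <= 0:
        raise ValidationError("correspondence analysis requires a positive grand total")
    if d is None:
        d = default_dims(F.shape[0])
    P = F / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    # columns with zero mass (feature pinned at 0 or 1 everywhere after a
    # non-constant row) cannot occur: pairs sum to 1 and rows are non-constant,
    # but guard against exact zeros from degenerate inputs anyway
    c_safe = np.where(c > 0, c, 1.0)
    r_safe = np.where(r > 0, r, 1.0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r_safe, c_safe))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int((sig > max(S.shape) * np.finfo(float).eps * (sig[0] if sig.size else 1.0)).sum())
    if d > rank:
        warn_data(f"requested {d} dimensions but rank is {rank}; truncated")
        d = max(1, rank)
    cell_scale = sig[:d] if scaling == "principal" else np.ones(d)
    feat_scale = np.ones(d) if scaling == "standard" else sig[:d]
    cell = (U[:, :d] / np.sqrt(r_safe)[:, None]) * cell_scale
    feat = (Vt[:d].T / np.sqrt(c_safe)[:, None]) * feat_scale
    feat_pos = feat[0::2]  # positive member of each doubled pair
    return McaEmbedding(
        cell_coords=pd.DataFrame(cell, index=coded.cell_names),
        feature_coords=pd.DataFrame(feat_pos, index=coded.feature_names),
        inertia=sig[:d] ** 2,
        d=d,
        dropped=list(coded.dropped),
    )


def mca(
    mat: ExpressionMatrix, d: int | None = None, scaling: str = "asymmetric"
) -> McaEmbedding:
    """Convenience wrapper: fuzzy-code then run correspondence analysis."""
    return correspondence_analysis(fuzzy_code(mat), d=d, scaling=scaling)


def rank_features(emb: McaEmbedding) -> SignatureRanking:
    """Per cell type, every feature sorted by ascending Euclidean distance."""
    cells = emb.cell_coords.to_numpy()
    feats = emb.feature_coords.to_numpy()
    if cells.shape[1] != feats.shape[1]:
        raise ValidationError("cell and feature coordinates disagree in dimension")
    names = np.asarray(emb.feature_coords.index)
    name_order = np.argsort(names, kind="stable")
    per_type: dict[str, pd.DataFrame] = {}
    # lexicographic-by-name tie-break: pre-sort by name, then stable-sort by distance
    for i, cell_type in enumerate(emb.cell_coords.index):
        dist = np.linalg.norm(feats - cells[i], axis=1)
        sub = dist[name_order]
        order = name_order[np.argsort(sub, kind="stable")]
        per_type[cell_type] = pd.DataFrame(
            {"mirna": names[order], "distance": dist[order]}
        ).reset_index(drop=True)
    return SignatureRanking(per_type=per_type)


def top_k(ranking: SignatureRanking, k: int = DEFAULT_TOP_K) -> dict[str, pd.DataFrame]:
    """First k entries of each cell type's ranking.

    Ties straddling the cut were already broken lexicographically by name in
    :func:`rank_features`, so the head is deterministic.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    out = {}
    for cell_type, df in ranking.per_type.items():
        if k > len(df):
            warn_data(
                f"k={k} exceeds {len(df)} ranked features for {cell_type!r}; "
                "returning full list"
            )
        out[cell_type] = df.head(k).reset_index(drop=True)
    return out
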