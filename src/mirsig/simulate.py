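"""Synthetic data with known ground truth for every pipeline stage.

Three generators cover the three external inputs:

* cell-type expression/activity profiles with planted specific miRNAs —
  log-normal background with each planted miRNA boosted ``fold``-fold in
  exactly one cell type's column (optionally shared with a neighbour type);
* a toy peak x cell chromatin fixture whose expected activity matrix is
  known by construction, because each peak is placed deliberately inside or
  outside a miRNA window;
* bulk mixtures of the profiles with Dirichlet-sampled known proportions
  and multiplicative log-normal noise.

A single integer seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import scipy.sparse

from .activity import PeakSet, aggregate_by_cell_type
from .matrix import ExpressionMatrix, MirnaAnnotation


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults: 30 cell types x 300 miRNAs with 10 planted specific miRNAs
    per type at 20-fold enrichment over a log-normal background
    (mu = 1, sigma = 1 on the log scale, mimicking CPM skew); 50 bulk
    mixtures with flat Dirichlet proportions and 20% multiplicative noise.
    """

    n_cell_types: int = 30
    n_mirnas: int = 300
    planted_per_type: int = 10
    fold: float = 20.0
    background_mu: float = 1.0
    background_sigma: float = 1.0
    noise_cv: float = 0.2
    n_samples: int = 50
    dirichlet_alpha: float = 1.0
    overlap_fraction: float = 0.0
    broad_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_per_type * self.n_cell_types > self.n_mirnas:
            raise ValueError(
                "planted_per_type * n_cell_types must not exceed n_mirnas"
            )
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0 <= self.broad_fraction <= 1:
            raise ValueError("broad_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def _mirna_names(n: int) -> list[str]:
    return [f"hsa-mir-{i + 1:04d}" for i in range(n)]


def _cell_type_names(n: int) -> list[str]:
    return [f"celltype_{i + 1:02d}" for i in range(n)]


def make_profiles(spec: FixtureSpec) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """miRNA x cell-type profiles with planted specific miRNAs.

    Background entries are i.i.d. log-normal.  A planted miRNA for cell
    type t takes the value ``fold * E[background]`` (fold times the
    log-normal mean) in column t only, a controlled fold-enrichment over
    the background level.  Planted sets are disjoint blocks by default;
    with ``overlap_fraction`` f > 0 each type additionally plants the
    first ``floor(f * planted_per_type)`` miRNAs of the next type's block,
    simulating signatures shared between related cell types.

    With ``broad_fraction`` > 0, that fraction of the non-planted rows is
    generated as broadly expressed decoys: one log-normal base level per
    row times mild multiplicative jitter (CV = ``noise_cv``), i.e. near
    uniform across cell types and therefore low-Gini.
    """
    rng = np.random.default_rng(spec.seed)
    mirnas = _mirna_names(spec.n_mirnas)
    types = _cell_type_names(spec.n_cell_types)
    vals = rng.lognormal(
        mean=spec.background_mu,
        sigma=spec.background_sigma,
        size=(spec.n_mirnas, spec.n_cell_types),
    )
    level = spec.fold * np.exp(spec.background_mu + spec.background_sigma**2 / 2)
    truth: dict[str, set[str]] = {}
    n_shared = int(spec.overlap_fraction * spec.planted_per_type)
    for t_idx, t in enumerate(types):
        lo = t_idx * spec.planted_per_type
        own = list(range(lo, lo + spec.planted_per_type))
        shared = []
        if n_shared and spec.n_cell_types > 1:
            nxt = ((t_idx + 1) % spec.n_cell_types) * spec.planted_per_type
            shared = list(range(nxt, nxt + n_shared))
        planted = own + shared
        vals[planted, t_idx] = level
        truth[t] = {mirnas[i] for i in planted}
    n_planted_rows = spec.planted_per_type * spec.n_cell_types
    n_broad = int(spec.broad_fraction * (spec.n_mirnas - n_planted_rows))
    if n_broad:
        base = rng.lognormal(
            mean=spec.background_mu, sigma=spec.background_sigma, size=n_broad
        )
        cv = max(spec.noise_cv, 1e-6)
        sigma2 = np.log1p(cv**2)
        jitter = rng.lognormal(
            mean=-sigma2 / 2, sigma=np.sqrt(sigma2),
            size=(n_broad, spec.n_cell_types),
        )
        vals[n_planted_rows:n_planted_rows + n_broad] = base[:, None] * jitter
    mat = ExpressionMatrix(
        pd.DataFrame(vals, index=mirnas, columns=types), col_kind="cell_type"
    ).validate()
    return mat, truth


def make_peak_fixture(
    spec: FixtureSpec,
    window_bp: int = 2000,
    cells_per_type: int = 3,
    gene_length: int = 80,
    max_peaks_in: int = 2,
    max_peaks_out: int = 2,
) -> tuple[PeakSet, MirnaAnnotation, ExpressionMatrix]:
    """Toy chromatin fixture with a construction-time expected activity.

    miRNA genes are laid out on one toy chromosome with gaps wide enough
    that windows never touch.  For every miRNA and cell, up to
    ``max_peaks_in`` peaks land strictly inside the window (their scores
    are tallied into the expected per-cell activity) and up to
    ``max_peaks_out`` land strictly in the inter-window gap (contributing
    nothing).  The expected miRNA x cell-type matrix is the per-type mean
    of the tallies — computed from placement bookkeeping, not from any
    overlap code.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_mir = spec.n_mirnas
    n_types = spec.n_cell_types
    mirnas = _mirna_names(n_mir)
    types = _cell_type_names(n_types)
    barcodes = [f"cell_{i + 1:04d}" for i in range(n_types * cells_per_type)]
    cell_type_of = {b: types[i % n_types] for i, b in enumerate(barcodes)}

    # windows [g_start - w, g_end + w]; pitch leaves a gap > 2w between them
    pitch = gene_length + 4 * window_bp + 2000
    g_start = np.arange(n_mir) * pitch + 2 * window_bp + 1000
    ann = MirnaAnnotation(
        pd.DataFrame(
            {
                "chrom": "chrS",
                "start": g_start,
                "end": g_start + gene_length - 1,
                "strand": "+",
                "name": mirnas,
            }
        )
    ).validate()

    expected = np.zeros((n_mir, len(barcodes)))
    rows, cols, data = [], [], []
    peak_rows = []

    def add_peak(start: int, end: int, cell_j: int, score: float) -> None:
        rows.append(len(peak_rows))
        cols.append(cell_j)
        data.append(score)
        peak_rows.append({"chrom": "chrS", "start": start, "end": end})

    for m in range(n_mir):
        w_lo = max(1, g_start[m] - window_bp)
        w_hi = g_start[m] + gene_length - 1 + window_bp
        gap_lo = w_hi + 200  # strictly between this window and the next
        gap_hi = gap_lo + window_bp
        for j in range(len(barcodes)):
            for _ in range(rng.integers(0, max_peaks_in + 1)):
                s = int(rng.integers(w_lo, w_hi - 50))
                score = float(np.round(rng.uniform(0.5, 3.0), 3))
                add_peak(s, s + 50, j, score)
                expected[m, j] += score
            for _ in range(rng.integers(0, max_peaks_out + 1)):
                s = int(rng.integers(gap_lo, gap_hi))
                add_peak(s, s + 50, j, float(np.round(rng.uniform(0.5, 3.0), 3)))

    matrix = scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(peak_rows), len(barcodes))
    )
    peaks = PeakSet(
        peaks=pd.DataFrame(peak_rows),
        matrix=matrix,
        barcodes=barcodes,
        cell_type_of=cell_type_of,
    )
    per_cell = ExpressionMatrix(
        pd.DataFrame(expected, index=mirnas, columns=barcodes), col_kind="cell"
    )
    expected_activity = aggregate_by_cell_type(per_cell, cell_type_of)
    return peaks, ann, expected_activity


def make_mixtures(
    profiles: ExpressionMatrix, spec: FixtureSpec
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Bulk mixtures of the cell-type profiles with known proportions.

    Per sample, proportions ~ Dirichlet(alpha * 1); expression is the
    proportion-weighted sum of profiles times multiplicative log-normal
    noise with unit mean and coefficient of variation ``noise_cv``.
    """
    rng = np.random.default_rng(spec.seed + 2)
    K = profiles.shape[1]
    props = rng.dirichlet([spec.dirichlet_alpha] * K, size=spec.n_samples)
    clean = profiles.data.to_numpy() @ props.T  # miRNA x sample
    if spec.noise_cv > 0:
        sigma2 = np.log1p(spec.noise_cv**2)
        noise = rng.lognormal(
            mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=clean.shape
        )
    else:
        noise = 1.0
    samples = [f"sample_{i + 1:03d}" for i in range(spec.n_samples)]
    expr = ExpressionMatrix(
        pd.DataFrame(clean * noise, index=profiles.row_names, columns=samples),
        col_kind="sample",
    ).validate()
    truth = pd.DataFrame(props, index=samples, columns=profiles.col_names)
    return expr, truth
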