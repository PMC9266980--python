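"""Chromatin activity: windowing, peak-overlap summation, cell-type means."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse

from mirsig import (
    ExpressionMatrix,
    MirnaAnnotation,
    PeakSet,
    ValidationError,
    aggregate_by_cell_type,
    mirna_window,
    score_mirna_by_cell,
)


def _ann(rows):
    return MirnaAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])
    ).validate()


@pytest.mark.parametrize(
    "start,end,window,expected",
    [
        (5000, 5080, 2000, (3000, 7080)),
        (1000, 1080, 2000, (1, 3080)),  # clamped at chromosome start
        (5000, 5080, 0, (5000, 5080)),
    ],
)
def test_mirna_window_arithmetic(start, end, window, expected):
    ann = _ann([("chr1", start, end, "+", "mir-a"), ("chr1", 10**6, 10**6 + 10, "+", "mir-b")])
    win = mirna_window(ann, window)
    assert (win.loc[0, "start"], win.loc[0, "end"]) == expected


def _peakset(peak_rows, scores, barcodes, cell_type_of):
    mat = scipy.sparse.csr_matrix(np.asarray(scores, dtype=float))
    return PeakSet(
        peaks=pd.DataFrame(peak_rows, columns=["chrom", "start", "end"]),
        matrix=mat,
        barcodes=barcodes,
        cell_type_of=cell_type_of,
    )


def test_single_overlap_and_outside_peak():
    ann = _ann([("chr1", 5000, 5080, "+", "mir-a"), ("chr1", 50000, 50080, "+", "mir-b")])
    win = mirna_window(ann, 2000)
    peaks = _peakset(
        [("chr1", 3500, 3600), ("chr1", 20000, 20100)],
        [[2.0, 0.0], [5.0, 1.0]],
        ["c1", "c2"],
        {"c1": "T", "c2": "B"},
    )
    mat = score_mirna_by_cell(peaks, win)
    assert mat.data.loc["mir-a", "c1"] == 2.0
    assert mat.data.loc["mir-a", "c2"] == 0.0
    # the second peak sits outside both windows and contributes nowhere
    assert (mat.data.loc["mir-b"] == 0).all()


def test_chromosome_namespace_mismatch_is_fatal():
    ann = _ann([("chr1", 5000, 5080, "+", "a"), ("chr1", 9000, 9080, "+", "b")])
    win = mirna_window(ann, 100)
    peaks = _peakset([("1", 5000, 5100)], [[1.0]], ["c1"], {"c1": "T"})
    with pytest.raises(ValidationError, match="chr1 vs 1"):
        score_mirna_by_cell(peaks, win)


def _brute_force_activity(peaks, windows):
    """O(peaks x miRNAs) reference: 1-based inclusive interval overlap."""
    dense = np.asarray(peaks.matrix.todense())
    out = np.zeros((len(windows), dense.shape[1]))
    for m, w in enumerate(windows.itertuples(index=False)):
        for p, pk in enumerate(peaks.peaks.itertuples(index=False)):
            if pk.chrom == w.chrom and pk.start <= w.end and w.start <= pk.end:
                out[m] += dense[p]
    return out


def test_random_peaks_match_brute_force_oracle(rng):
    n_peaks, n_mir, n_cells = 200, 20, 30
    ann = _ann(
        [
            ("chrT", int(s), int(s) + 100, "+", f"mir-{i}")
            for i, s in enumerate(rng.integers(1, 2 * 10**5, size=n_mir))
        ]
    )
    win = mirna_window(ann, 2000)
    starts = rng.integers(1, 2 * 10**5, size=n_peaks)
    scores = rng.uniform(0, 3, size=(n_peaks, n_cells))
    scores[rng.uniform(size=scores.shape) < 0.6] = 0.0
    peaks = _peakset(
        [("chrT", int(s), int(s) + 50) for s in starts],
        scores,
        [f"c{j}" for j in range(n_cells)],
        {f"c{j}": f"type{j % 4}" for j in range(n_cells)},
    )
    got = score_mirna_by_cell(peaks, win)
    assert np.array_equal(got.data.to_numpy(), _brute_force_activity(peaks, win))


def test_split_peak_additivity(rng):
    ann = _ann([("chrT", 5000, 5100, "+", "a"), ("chrT", 30000, 30100, "+", "b")])
    win = mirna_window(ann, 2000)
    whole = _peakset(
        [("chrT", 4000, 4100)], [[3.0, 1.0]], ["c1", "c2"], {"c1": "T", "c2": "T"}
    )
    halves = _peakset(
        [("chrT", 4000, 4100), ("chrT", 4000, 4100)],
        [[1.5, 0.5], [1.5, 0.5]],
        ["c1", "c2"],
        {"c1": "T", "c2": "T"},
    )
    a = score_mirna_by_cell(whole, win).data.to_numpy()
    b = score_mirna_by_cell(halves, win).data.to_numpy()
    assert np.allclose(a, b, atol=1e-12)


def test_increasing_a_peak_score_is_monotone(rng):
    ann = _ann(
        [("chrT", int(s), int(s) + 80, "+", f"m{i}") for i, s in
         enumerate(rng.integers(1, 10**5, size=10))]
    )
    win = mirna_window(ann, 1500)
    scores = rng.uniform(0, 2, size=(30, 8))
    mk = lambda sc: _peakset(
        [("chrT", int(s), int(s) + 60) for s in rng2_starts],
        sc, [f"c{j}" for j in range(8)], {f"c{j}": "T" for j in range(8)},
    )
    rng2_starts = rng.integers(1, 10**5, size=30)
    base = score_mirna_by_cell(mk(scores), win).data.to_numpy()
    bumped = scores.copy()
    bumped[7, 3] += 5.0
    after = score_mirna_by_cell(mk(bumped), win).data.to_numpy()
    assert (after >= base - 1e-12).all()


class TestAggregate:
    def test_mean_of_two(self):
        per_cell = ExpressionMatrix(
            pd.DataFrame([[2.0, 4.0], [0.0, 8.0]], index=["a", "b"],
                         columns=["c1", "c2"]),
            col_kind="cell",
        )
        out = aggregate_by_cell_type(per_cell, {"c1": "T cell", "c2": "T cell"})
        assert list(out.data["T cell"]) == [3.0, 4.0]

    def test_one_cell_per_type_is_identity(self, rng):
        vals = rng.uniform(size=(5, 3))
        per_cell = ExpressionMatrix(
            pd.DataFrame(vals, index=list("abcde"), columns=["c1", "c2", "c3"]),
            col_kind="cell",
        )
        out = aggregate_by_cell_type(per_cell, {"c1": "X", "c2": "Y", "c3": "Z"})
        assert np.array_equal(out.data.to_numpy(), vals)
        assert out.col_names == ["X", "Y", "Z"]

    def test_random_labels_match_loop_oracle(self, rng):
        vals = rng.uniform(size=(50, 40))
        cells = [f"c{j}" for j in range(40)]
        labels = {c: f"t{rng.integers(5)}" for c in cells}
        per_cell = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"m{i}" for i in range(50)], columns=cells),
            col_kind="cell",
        )
        out = aggregate_by_cell_type(per_cell, labels)
        for t in out.col_names:
            cols = [j for j, c in enumerate(cells) if labels[c] == t]
            expected = vals[:, cols].mean(axis=1)
            assert np.allclose(out.data[t].to_numpy(), expected, atol=1e-12)

    def test_column_permutation_invariance(self, rng):
        vals = rng.uniform(size=(6, 8))
        cells = [f"c{j}" for j in range(8)]
        labels = {c: f"t{j % 2}" for j, c in enumerate(cells)}
        mk = lambda order: aggregate_by_cell_type(
            ExpressionMatrix(
                pd.DataFrame(vals[:, order], index=list("abcdef"),
                             columns=[cells[j] for j in order]),
                col_kind="cell",
            ),
            labels,
        )
        a = mk(list(range(8)))
        b = mk(list(reversed(range(8))))
        pd.testing.assert_frame_equal(
            a.data.sort_index(axis=1), b.data.sort_index(axis=1)
        )

    def test_unlabelled_cell_is_fatal(self):
        per_cell = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"],
                         columns=["c1", "c2"]),
            col_kind="cell",
        )
        with pytest.raises(ValidationError, match="c2"):
            aggregate_by_cell_type(per_cell, {"c1": "T"})
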