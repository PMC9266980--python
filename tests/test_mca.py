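"""Fuzzy coding, correspondence analysis, and signature ranking."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from mirsig import (
    ExpressionMatrix,
    correspondence_analysis,
    fuzzy_code,
    mca,
    rank_features,
    top_k,
)
from mirsig.mca import McaEmbedding


def _mat(vals, rows=None, cols=None):
    vals = np.asarray(vals, dtype=float)
    rows = rows or [f"m{i}" for i in range(vals.shape[0])]
    cols = cols or [f"t{j}" for j in range(vals.shape[1])]
    return ExpressionMatrix(pd.DataFrame(vals, index=rows, columns=cols))


class TestFuzzyCode:
    def test_min_max_arithmetic(self):
        coded = fuzzy_code(_mat([[0, 5, 10], [1, 2, 3]]))
        # feature m0 occupies columns 0 (u) and 1 (1-u)
        assert np.allclose(coded.table[:, 0], [0.0, 0.5, 1.0])
        assert np.allclose(coded.table[:, 1], [1.0, 0.5, 0.0])

    def test_already_unit_scale_unchanged(self):
        coded = fuzzy_code(_mat([[0, 1], [1, 0]]))
        assert np.allclose(coded.table[:, 0], [0.0, 1.0])

    def test_pairs_sum_to_one(self, rng):
        coded = fuzzy_code(_mat(rng.uniform(size=(10, 5))))
        sums = coded.table[:, 0::2] + coded.table[:, 1::2]
        assert np.allclose(sums, 1.0)

    def test_constant_row_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            coded = fuzzy_code(_mat([[3, 3, 3], [0, 1, 2], [5, 1, 0]]))
        assert coded.feature_names == ["m1", "m2"]
        assert coded.dropped == ["m0"]


def _oracle_ca(table, cell_names, feature_names, d):
    """Independent correspondence-analysis reference.

    Works through the eigendecomposition of S S' (not an SVD) and obtains
    feature principal coordinates by the transition formula
    G = Dc^{-1} P' F_std, the barycentric relation the asymmetric map
    guarantees.
    """
    F = np.asarray(table, float)
    P = F / F.sum()
    r, c = P.sum(1), P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, evecs = scipy.linalg.eigh(S @ S.T)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    sig = np.sqrt(np.clip(evals, 0, None))[:d]
    U = evecs[:, :d]
    cell_std = U / np.sqrt(r)[:, None]
    # barycentre of cell standard coordinates, feature-profile weighted
    feat_prin = (P.T @ cell_std) / c[:, None]
    return cell_std, feat_prin[0::2], sig**2


def _match_up_to_sign(a, b, tol):
    assert a.shape == b.shape
    for k in range(a.shape[1]):
        assert (
            np.max(np.abs(a[:, k] - b[:, k])) < tol
            or np.max(np.abs(a[:, k] + b[:, k])) < tol
        ), f"axis {k} differs beyond sign"


class TestCorrespondenceAnalysis:
    def test_inertia_equals_frobenius_norm_of_residuals(self, rng):
        mat = _mat(rng.gamma(2, 2, size=(12, 6)))
        coded = fuzzy_code(mat)
        emb = correspondence_analysis(coded, d=5)
        F = coded.table
        P = F / F.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        assert abs(emb.inertia.sum() - np.linalg.norm(S) ** 2) < 1e-8

    def test_agrees_with_eigendecomposition_oracle(self, rng):
        mat = _mat(rng.gamma(2, 2, size=(12, 6)))
        coded = fuzzy_code(mat)
        emb = correspondence_analysis(coded, d=5)
        cell_o, feat_o, inertia_o = _oracle_ca(
            coded.table, coded.cell_names, coded.feature_names, 5
        )
        assert np.allclose(emb.inertia, inertia_o, atol=1e-8)
        _match_up_to_sign(emb.cell_coords.to_numpy(), cell_o, 1e-8)
        _match_up_to_sign(emb.feature_coords.to_numpy(), feat_o, 1e-8)

    def test_indicator_feature_is_nearest_to_its_cell_type(self):
        # 6 indicator features, one per cell type, plus mild noise features
        rng = np.random.default_rng(5)
        n_t = 6
        ind = np.eye(n_t) * 10.0 + 0.1
        noise = rng.uniform(0.5, 1.5, size=(6, n_t))
        mat = _mat(np.vstack([ind, noise]),
                   rows=[f"ind{j}" for j in range(n_t)] + [f"n{i}" for i in range(6)])
        emb = mca(mat)
        rk = rank_features(emb)
        for j, t in enumerate(emb.cell_coords.index):
            best_ind = (
                rk.per_type[t].query("mirna.str.startswith('ind')").iloc[0]["mirna"]
            )
            assert best_ind == f"ind{j}"

    def test_rank_truncation_warns(self, rng):
        mat = _mat(rng.gamma(2, 2, size=(8, 4)))
        with pytest.warns(UserWarning, match="rank"):
            emb = mca(mat, d=10)
        assert emb.d <= 4

    def test_scaling_variants_exposed(self, rng):
        mat = _mat(rng.gamma(2, 2, size=(8, 4)))
        coded = fuzzy_code(mat)
        e1 = correspondence_analysis(coded, d=3, scaling="principal")
        e2 = correspondence_analysis(coded, d=3, scaling="asymmetric")
        sig = np.sqrt(e1.inertia)
        # principal cells = standard cells scaled per-axis by sigma_k
        assert np.allclose(
            e1.cell_coords.to_numpy(),
            e2.cell_coords.to_numpy() * sig,
            atol=1e-10,
        )


class TestRanking:
    def _toy_embedding(self):
        cells = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["T", "B"])
        feats = pd.DataFrame(
            [[0.0, 0.0], [3.0, 4.0], [1.0, 1.0]], index=["f0", "f5", "f1"]
        )
        return McaEmbedding(cell_coords=cells, feature_coords=feats,
                            inertia=np.array([1.0, 0.5]), d=2)

    def test_zero_distance_is_rank_one(self):
        rk = rank_features(self._toy_embedding())
        assert rk.per_type["T"].iloc[0]["mirna"] == "f0"
        assert rk.per_type["T"].iloc[0]["distance"] == 0.0
        assert rk.per_type["B"].iloc[0]["mirna"] == "f1"

    def test_matches_double_loop_oracle(self, rng):
        cells = pd.DataFrame(rng.normal(size=(10, 4)),
                             index=[f"t{j}" for j in range(10)])
        feats = pd.DataFrame(rng.normal(size=(30, 4)),
                             index=[f"m{i:02d}" for i in range(30)])
        emb = McaEmbedding(cell_coords=cells, feature_coords=feats,
                           inertia=np.ones(4), d=4)
        rk = rank_features(emb)
        for t in cells.index:
            dists = {
                m: float(np.sqrt(((feats.loc[m] - cells.loc[t]) ** 2).sum()))
                for m in feats.index
            }
            expected = sorted(dists, key=lambda m: (dists[m], m))
            assert list(rk.per_type[t]["mirna"]) == expected

    def test_duplicate_feature_gives_adjacent_equal_ranks(self):
        emb = self._toy_embedding()
        emb.feature_coords.loc["f5dup"] = [3.0, 4.0]
        rk = rank_features(emb)
        df = rk.per_type["T"]
        pos = df.index[df["mirna"].isin(["f5", "f5dup"])].tolist()
        assert pos == [2, 3]  # adjacent
        assert df.loc[pos[0], "distance"] == df.loc[pos[1], "distance"]

    def test_top_k_identity_and_cardinality(self):
        rk = rank_features(self._toy_embedding())
        full = top_k(rk, 3)
        pd.testing.assert_frame_equal(full["T"], rk.per_type["T"])
        one = top_k(rk, 1)
        assert len(one["T"]) == 1
        with pytest.warns(UserWarning, match="full list"):
            top_k(rk, 99)


class TestInvariances:
    def test_affine_rescaling_leaves_rankings_unchanged(self, rng):
        vals = rng.gamma(2, 2, size=(15, 5))
        mat = _mat(vals)
        scaled = vals * rng.uniform(0.5, 4.0, size=(15, 1)) + rng.uniform(
            0.0, 3.0, size=(15, 1)
        )
        mat2 = _mat(scaled)
        rk1 = rank_features(mca(mat, d=4))
        rk2 = rank_features(mca(mat2, d=4))
        for t in rk1.per_type:
            assert list(rk1.per_type[t]["mirna"]) == list(rk2.per_type[t]["mirna"])

    def test_axis_sign_flip_leaves_distances_unchanged(self, rng):
        mat = _mat(rng.gamma(2, 2, size=(12, 5)))
        emb = mca(mat, d=4)
        flipped = McaEmbedding(
            cell_coords=emb.cell_coords * [1, -1, 1, -1],
            feature_coords=emb.feature_coords * [1, -1, 1, -1],
            inertia=emb.inertia,
            d=emb.d,
        )
        r1, r2 = rank_features(emb), rank_features(flipped)
        for t in r1.per_type:
            assert np.allclose(
                r1.per_type[t]["distance"], r2.per_type[t]["distance"], atol=1e-12
            )

    def test_planted_recovery_small_fixture(self, small_profiles):
        prof, truth = small_profiles
        tops = top_k(rank_features(mca(prof)), 5)
        hits = [
            len(truth[t] & set(tops[t]["mirna"])) / len(truth[t]) for t in truth
        ]
        assert np.mean(hits) >= 0.9
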