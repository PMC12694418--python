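"""Normalization, collinearity screening, ordination, PERMANOVA, PLS/VIP."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from cytomorph.mstats import (
    bray_curtis,
    minmax_normalize,
    pca,
    pcoa,
    permanova,
    pls_regression,
    spearman_filter,
    vip,
)


class TestMinmaxNormalize:
    def test_basic_mapping(self):
        out, flags = minmax_normalize(pd.DataFrame({"a": [2.0, 4.0, 6.0]}))
        assert out["a"].tolist() == [0.0, 0.5, 1.0]
        assert flags == []

    def test_constant_column_flagged_and_zeroed(self):
        out, flags = minmax_normalize(pd.DataFrame({"c": [3.0, 3.0]}))
        assert out["c"].tolist() == [0.0, 0.0]
        assert flags == ["c"]

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.uniform(size=(30, 4)), columns=list("abcd"))
        once, _ = minmax_normalize(df)
        twice, _ = minmax_normalize(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSpearmanFilter:
    def test_monotone_pair_drops_one(self, rng):
        x = rng.uniform(size=100)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        retained, dropped, corr = spearman_filter(df)
        assert len(retained) == 1 and len(dropped) == 1
        assert corr.loc["x", "y"] == pytest.approx(1.0)

    def test_independent_columns_all_survive(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.uniform(size=(200, 3)), columns=list("abc"))
        retained, dropped, _ = spearman_filter(df)
        assert dropped == []
        assert retained == list("abc")

    def test_constructed_v_l_pair(self):
        rng = np.random.default_rng(11)
        v = rng.uniform(size=150)
        df = pd.DataFrame(
            {
                "V": v,
                "L": v + 0.15 * rng.uniform(size=150),  # rank corr ~0.9
                "H": rng.uniform(size=150),
                "W": rng.uniform(size=150),
            }
        )
        retained, dropped, _ = spearman_filter(df)
        assert len(dropped) == 1 and dropped[0] in {"V", "L"}
        assert {"H", "W"} <= set(retained)

    def test_sample_order_invariant(self, rng):
        df = pd.DataFrame(rng.uniform(size=(80, 5)), columns=list("abcde"))
        df["f"] = df["a"] * 2 + 0.01 * rng.uniform(size=80)
        r1, d1, _ = spearman_filter(df)
        shuffled = df.sample(frac=1.0, random_state=3)
        r2, d2, _ = spearman_filter(shuffled)
        assert r1 == r2 and d1 == d2

    def test_retained_set_below_threshold(self, rng):
        base = rng.uniform(size=(60, 3))
        df = pd.DataFrame(
            np.column_stack([base, base + 0.05 * rng.uniform(size=(60, 3))]),
            columns=list("abcdef"),
        )
        retained, _, corr = spearman_filter(df, threshold=0.6)
        sub = corr.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() < 0.6


class TestPCA:
    def test_data_on_a_line(self):
        t = np.linspace(0, 1, 40)
        df = pd.DataFrame({"x": t, "y": 2 * t})
        res = pca(df)
        assert res.explained[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_splits_evenly(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((100_000, 3)), columns=list("abc"))
        res = pca(df)
        np.testing.assert_allclose(res.explained, 1 / 3, rtol=0.02)

    def test_duplicated_column_loads_symmetrically(self, rng):
        x = rng.standard_normal(500)
        df = pd.DataFrame({"x1": x, "x2": x, "z": 0.1 * rng.standard_normal(500)})
        res = pca(df)
        assert abs(res.loadings[0, 0]) == pytest.approx(abs(res.loadings[1, 0]), rel=1e-6)

    def test_sign_convention(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
        res = pca(df)
        for k in range(res.loadings.shape[1]):
            assert res.loadings[np.argmax(np.abs(res.loadings[:, k])), k] > 0


class TestBrayCurtis:
    def test_identical_rows(self):
        D = bray_curtis([[1.0, 2.0], [1.0, 2.0]])
        assert D[0, 1] == 0.0

    def test_disjoint_rows(self):
        assert bray_curtis([[1.0, 0.0], [0.0, 1.0]])[0, 1] == 1.0

    def test_hand_computed_value(self):
        D = bray_curtis([[1.0, 1.0], [0.0, 1.0]])
        assert D[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_pair_defined_as_zero(self):
        with pytest.warns(UserWarning):
            D = bray_curtis([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        assert D[0, 1] == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([[-1.0, 0.0], [0.0, 1.0]])


class TestPCoA:
    def test_recovers_euclidean_configuration(self):
        gx, gy = np.meshgrid(np.arange(5.0), np.arange(4.0))
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        D = squareform(pdist(pts))
        res = pcoa(D)
        _, _, disparity = procrustes(pts, res.coordinates[:, :2])
        assert disparity < 1e-8

    def test_identical_samples_coincide(self, rng):
        pts = rng.uniform(size=(6, 3))
        pts[3] = pts[0]
        D = squareform(pdist(pts))
        res = pcoa(D)
        np.testing.assert_allclose(
            res.coordinates[0], res.coordinates[3], atol=1e-8
        )

    def test_one_dimensional_data_one_positive_eigenvalue(self):
        x = np.array([[0.0], [1.0], [3.0], [6.0]])
        res = pcoa(squareform(pdist(x)))
        assert res.coordinates.shape[1] == 1
        assert res.relative_eigenvalues[0] == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            pcoa(D)

    def test_matches_skbio_eigenvalues(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        X = rng.uniform(size=(12, 5))
        D = bray_curtis(X)
        mine = pcoa(D)
        theirs = skbio_pcoa(D, method="eigh")
        k = len(mine.relative_eigenvalues)
        np.testing.assert_allclose(
            mine.eigenvalues[:k], theirs.eigvals.to_numpy()[:k], atol=1e-8
        )


class TestPermanova:
    def test_relabelling_invariance(self, rng):
        X = rng.uniform(size=(20, 4))
        D = bray_curtis(X)
        groups = np.array([0] * 10 + [1] * 10)
        perm = rng.permutation(20)
        r1 = permanova(D, groups, n_permutations=99, seed=1)
        r2 = permanova(D[np.ix_(perm, perm)], groups[perm], n_permutations=99, seed=1)
        assert r1.r_squared == pytest.approx(r2.r_squared)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)

    def test_strong_separation(self, rng):
        a = rng.uniform(size=(12, 3))
        b = rng.uniform(size=(12, 3)) + 10.0
        D = squareform(pdist(np.vstack([a, b])))
        res = permanova(D, [0] * 12 + [1] * 12, n_permutations=999, seed=2)
        assert res.r_squared > 0.5
        assert res.p_value == pytest.approx(0.001)

    def test_single_group_rejected(self, rng):
        D = bray_curtis(rng.uniform(size=(5, 3)))
        with pytest.raises(ValueError):
            permanova(D, [0] * 5)

    def test_matches_skbio_statistic(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        X = rng.uniform(size=(18, 4))
        D = bray_curtis(X)
        groups = np.array([0] * 6 + [1] * 6 + [2] * 6)
        mine = permanova(D, groups, n_permutations=99, seed=0)
        theirs = skbio_permanova(DistanceMatrix(D), groups, permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)


class TestPLS:
    def test_noiseless_rank_one_relation(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 5)), columns=list("abcde"))
        w = np.array([1.0, -2.0, 0.5, 0.0, 1.5])
        Y = pd.DataFrame({"y1": X.to_numpy() @ w, "y2": 2.0 * (X.to_numpy() @ w)})
        res = pls_regression(X, Y, n_components=5)
        # noiseless linear relation: the full fit explains all of Y, and the
        # first component carries the bulk (exactly 100% only when X'X is
        # spherical)
        assert res.explained_y[0] > 0.9
        assert res.explained_y.sum() == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_design_closed_form(self, rng):
        # zero-mean orthogonal predictors: QR of a column-centered matrix
        A = rng.standard_normal((60, 6))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        Q /= Q.std(axis=0, ddof=1)
        X = pd.DataFrame(Q, columns=[f"x{i}" for i in range(6)])
        Y = pd.DataFrame({"y": Q[:, 0]})
        res = pls_regression(X, Y, n_components=1)
        coef = res.coefficients[:, 0]
        assert coef[0] == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(coef[1:], 0.0, atol=1e-8)

    def test_constant_column_rejected(self, rng):
        X = pd.DataFrame({"a": np.ones(20), "b": rng.standard_normal(20)})
        Y = pd.DataFrame({"y": rng.standard_normal(20)})
        with pytest.raises(ValueError):
            pls_regression(X, Y, n_components=1)

    def test_components_beyond_rank_rejected(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": 2 * x + 1e-14 * rng.standard_normal(30)})
        Y = pd.DataFrame({"y": rng.standard_normal(30)})
        with pytest.raises(ValueError):
            pls_regression(X, Y, n_components=2)


class TestVIP:
    def test_single_predictor_is_one(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(40)})
        Y = pd.DataFrame({"y": X["a"] + 0.1 * rng.standard_normal(40)})
        res = pls_regression(X, Y, n_components=1)
        assert vip(res)[0] == pytest.approx(1.0, abs=1e-9)

    def test_informative_predictor_dominates_noise(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame(
            rng.standard_normal((150, 10)), columns=[f"x{i}" for i in range(10)]
        )
        Y = pd.DataFrame({"y": X["x0"] + 0.2 * rng.standard_normal(150)})
        res = pls_regression(X, Y, n_components=2)
        scores = vip(res)
        assert np.argmax(scores) == 0
        assert scores[0] > 0.8

    def test_exchangeable_predictors_all_near_one(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame(
            rng.standard_normal((500, 4)), columns=list("abcd")
        )
        Y = pd.DataFrame({"y": X.sum(axis=1) + 0.1 * rng.standard_normal(500)})
        res = pls_regression(X, Y, n_components=2)
        np.testing.assert_allclose(vip(res), 1.0, atol=0.1)

    def test_sum_of_squares_equals_predictor_count(self, rng):
        X = pd.DataFrame(
            rng.standard_normal((80, 7)), columns=[f"x{i}" for i in range(7)]
        )
        Y = pd.DataFrame(
            rng.standard_normal((80, 3)), columns=["y1", "y2", "y3"]
        )
        res = pls_regression(X, Y, n_components=3)
        assert float(np.sum(vip(res) ** 2)) == pytest.approx(7.0, abs=1e-6)
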