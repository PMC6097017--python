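import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from limnodiv.core import CommunityMatrix
from limnodiv.distance_tests import (
    build_design,
    dispersion_homogeneity,
    gower_center,
    mdmr,
    permanova,
)
from limnodiv.nullmodels import DistanceMatrix, sorensen_matrix

# 10 x 12 incidence fixture whose Sørensen results were cross-computed with
# the reference R implementation (vegan 2.7: vegdist binary bray,
# betadisper type="centroid", adonis2); values frozen to 10 decimals.
VEGAN_INC = np.array([
    [0,0,1,0,0,0,1,0,1,0,0,0],
    [1,1,1,1,0,0,0,1,1,0,0,0],
    [0,0,0,1,0,0,1,0,0,1,1,1],
    [0,0,0,0,0,1,1,0,0,0,0,1],
    [1,1,1,0,0,1,1,1,0,1,0,0],
    [1,1,0,0,0,0,0,1,0,0,0,1],
    [1,1,1,1,0,0,0,0,0,0,0,0],
    [1,0,0,0,0,0,1,0,1,0,0,0],
    [1,0,0,0,0,0,1,0,1,0,0,1],
    [0,0,0,1,0,0,0,0,1,0,1,0],
])
VEGAN_GROUPS = np.repeat(["a", "b"], 5)
VEGAN_DIST_TO_CENTROID = np.array([
    0.3914358570, 0.4932577800, 0.4509744256, 0.4785327941, 0.2838651685,
    0.4683097895, 0.4287830166, 0.3381203881, 0.2930796677, 0.5569953000,
])
VEGAN_BETADISPER_F = 0.0017881138
VEGAN_ADONIS_F = 0.8594935244
VEGAN_ADONIS_R2 = 0.0970138442


def _euclid(X, ids=None):
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    n = X.shape[0]
    ids = ids or tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(ids, squareform(pdist(X)), "euclidean")


@pytest.fixture(scope="module")
def vegan_sorensen():
    cm = CommunityMatrix(tuple(f"s{i}" for i in range(10)),
                         tuple(f"p{j}" for j in range(12)), VEGAN_INC)
    return sorensen_matrix(cm)


class TestGowerCenter:
    def test_two_site_closed_form(self):
        d = 3.0
        G = gower_center(DistanceMatrix(("a", "b"), np.array([[0, d], [d, 0]]))).G
        np.testing.assert_allclose(G, [[d**2 / 4, -d**2 / 4], [-d**2 / 4, d**2 / 4]])

    def test_zero_matrix(self):
        G = gower_center(DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))).G
        np.testing.assert_allclose(G, 0.0)

    def test_pcoa_identity_for_euclidean_cloud(self, rng):
        X = rng.normal(size=(12, 4))
        G = gower_center(_euclid(X)).G
        Xc = X - X.mean(axis=0)
        expected = np.linalg.eigvalsh(Xc @ Xc.T)
        np.testing.assert_allclose(np.linalg.eigvalsh(G), expected, atol=1e-8)
        # rows and columns sum to zero
        np.testing.assert_allclose(G.sum(axis=0), 0.0, atol=1e-9)


class TestPermanova:
    def test_univariate_worked_example_f_eight(self):
        res = permanova(_euclid([0.0, 1.0, 2.0, 3.0]), ["A", "A", "B", "B"],
                        permutations=9, seed=0)
        assert res.statistic == pytest.approx(8.0)
        assert (res.df1, res.df2) == (1, 2)
        assert res.r_squared == pytest.approx(0.8)

    def test_equals_classical_anova_f(self, rng):
        x = rng.normal(size=15)
        g = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        res = permanova(_euclid(x), g, permutations=9, seed=0)
        f_ref = stats.f_oneway(x[:5], x[5:10], x[10:])[0]
        assert res.statistic == pytest.approx(f_ref, rel=1e-10)

    def test_permutation_p_matches_enumeration(self, rng):
        x = rng.normal(size=6)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(_euclid(x), g, permutations=9999, seed=1)

        def stat(perm):
            lab = g[list(perm)]
            return permanova(_euclid(x), lab, permutations=1, seed=0).statistic

        f_obs = res.statistic
        stats_all = [stat(p) for p in itertools.permutations(range(6))]
        exact_p = np.mean([s >= f_obs - 1e-12 for s in stats_all])
        assert res.pvalue == pytest.approx(exact_p, abs=0.02)

    def test_matches_vegan_adonis(self, vegan_sorensen):
        res = permanova(vegan_sorensen, VEGAN_GROUPS, permutations=9, seed=0)
        assert res.statistic == pytest.approx(VEGAN_ADONIS_F, abs=1e-9)
        assert res.r_squared == pytest.approx(VEGAN_ADONIS_R2, abs=1e-9)

    def test_site_order_invariance(self, rng):
        x = rng.normal(size=(12, 3))
        g = np.array(["a"] * 6 + ["b"] * 6)
        res = permanova(_euclid(x), g, permutations=19, seed=0)
        perm = rng.permutation(12)
        D2 = _euclid(x[perm])
        res2 = permanova(D2, g[perm], permutations=19, seed=0)
        assert res.statistic == pytest.approx(res2.statistic)

    def test_group_size_one_rejected(self):
        with pytest.raises(ValueError, match="size < 2"):
            permanova(_euclid([0.0, 1, 2]), ["a", "a", "b"], permutations=9, seed=0)

    def test_p_floor_respected(self, rng):
        x = np.array([0.0, 0.1, 5.0, 5.1])
        res = permanova(_euclid(x), ["a", "a", "b", "b"], permutations=99, seed=0)
        assert res.pvalue >= 1 / 100


class TestDispersion:
    def test_univariate_distances_are_abs_deviations(self, rng):
        x = rng.normal(size=12)
        g = np.repeat(["a", "b", "c"], 4)
        res = dispersion_homogeneity(_euclid(x), g, permutations=9, seed=0)
        expected = np.abs(x - pd.Series(x).groupby(g).transform("mean").to_numpy())
        np.testing.assert_allclose(res.distances, expected, atol=1e-10)

    def test_identical_group_members_have_zero_distance(self):
        x = np.array([2.0, 2.0, 2.0, 1.0, 5.0, 6.0])
        g = ["a"] * 3 + ["b"] * 3
        res = dispersion_homogeneity(_euclid(x), g, permutations=9, seed=0)
        np.testing.assert_allclose(res.distances[:3], 0.0, atol=1e-12)

    def test_matches_vegan_betadisper_with_negative_eigenvalues(self, vegan_sorensen):
        res = dispersion_homogeneity(vegan_sorensen, VEGAN_GROUPS, permutations=9, seed=0)
        np.testing.assert_allclose(res.distances, VEGAN_DIST_TO_CENTROID, atol=1e-9)
        assert res.statistic == pytest.approx(VEGAN_BETADISPER_F, abs=1e-9)
        assert res.n_negative_eigenvalues > 0


class TestMdmr:
    def test_pseudo_r2_equals_ols_trace_r2(self, rng):
        Y = rng.normal(size=(20, 5))
        x = rng.normal(size=20)
        res = mdmr(_euclid(Y), pd.DataFrame({"x": x}), permutations=9, seed=0)
        Xd = np.column_stack([np.ones(20), x])
        H = Xd @ np.linalg.inv(Xd.T @ Xd) @ Xd.T
        Yc = Y - Y.mean(axis=0)
        expected = np.trace(H @ Yc @ Yc.T) / np.trace(Yc @ Yc.T)
        assert res.omnibus["pseudo_r2"] == pytest.approx(expected, abs=1e-8)

    def test_categorical_pseudo_r2_equals_permanova_r2(self, vegan_sorensen):
        res = mdmr(vegan_sorensen, pd.DataFrame({"g": list(VEGAN_GROUPS)}),
                   permutations=9, seed=0)
        pr = permanova(vegan_sorensen, VEGAN_GROUPS, permutations=9, seed=0)
        assert res.per_predictor.loc["g", "pseudo_r2"] == pytest.approx(pr.r_squared, abs=1e-10)

    def test_conditional_r2_bounded_by_omnibus(self, rng):
        Y = rng.normal(size=(18, 3))
        X = pd.DataFrame({"x1": rng.normal(size=18), "x2": rng.normal(size=18)})
        res = mdmr(_euclid(Y), X, permutations=19, seed=0)
        assert (res.per_predictor["pseudo_r2"] <= res.omnibus["pseudo_r2"] + 1e-12).all()
        assert ((res.per_predictor["pvalue"] >= 1 / 20) &
                (res.per_predictor["pvalue"] <= 1)).all()

    def test_seeded_bit_reproducibility(self, rng):
        Y = rng.normal(size=(15, 3))
        X = pd.DataFrame({"x": rng.normal(size=15)})
        a = mdmr(_euclid(Y), X, permutations=49, seed=7)
        b = mdmr(_euclid(Y), X, permutations=49, seed=7)
        assert a.omnibus["pvalue"] == b.omnibus["pvalue"]
        pd.testing.assert_frame_equal(a.per_predictor, b.per_predictor)

    def test_rank_deficient_design_rejected(self, rng):
        Y = rng.normal(size=(10, 2))
        x = rng.normal(size=10)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            mdmr(_euclid(Y), X, permutations=9, seed=0)

    def test_build_design_dummy_codes_categoricals(self):
        X = pd.DataFrame({"g": ["u", "v", "w", "u"], "x": [1.0, 2.0, 3.0, 4.0]})
        mat, owners = build_design(X)
        assert mat.shape == (4, 4)  # intercept + 2 dummies + 1 continuous
        assert owners["g"] == [1, 2] and owners["x"] == [3]
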