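import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from limnodiv.core import CommunityMatrix, OccupancyWeights, occupancy
from limnodiv.nullmodels import (
    DistanceMatrix,
    NullModelConfig,
    calibrate_pool_rates,
    curveball_draw,
    null_draw,
    ses_dissimilarity,
    shift_nonnegative,
    sorensen_matrix,
    weighted_incidence,
)


def _cm(rows, prefix="s"):
    rows = np.asarray(rows)
    return CommunityMatrix(tuple(f"{prefix}{i}" for i in range(rows.shape[0])),
                           tuple(f"sp{j}" for j in range(rows.shape[1])), rows)


class TestSorensen:
    def test_identical_sites_zero(self):
        d = sorensen_matrix(_cm([[1, 1, 0], [1, 1, 0]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_sites_one(self):
        d = sorensen_matrix(_cm([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_worked_example_one_third(self):
        # {s1,s2,s3} vs {s2,s3,s4}: a=2, b=c=1 -> 2/6
        d = sorensen_matrix(_cm([[1, 1, 1, 0], [0, 1, 1, 1]]))
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_pair_of_empty_sites_rejected(self):
        with pytest.raises(ValueError, match="empty sites"):
            sorensen_matrix(_cm([[0, 0], [0, 0], [1, 0]]))
        d = sorensen_matrix(_cm([[0, 0], [0, 0], [1, 0]]), drop_empty_sites=True)
        assert d.n == 1

    @given(st.integers(0, 2**30 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_scipy_dice_and_identity(self, seed):
        rng = np.random.default_rng(seed)
        inc = (rng.random((6, 9)) < 0.4).astype(int)
        inc[inc.sum(axis=1) == 0, 0] = 1  # avoid empty sites
        d = sorensen_matrix(_cm(inc)).values
        ref = squareform(pdist(inc.astype(bool), "dice"))
        np.testing.assert_allclose(d, ref, atol=1e-12)
        # algebraic identity d = 1 - 2a/(2a+b+c), bounds and symmetry
        assert d.min() >= 0 and d.max() <= 1
        np.testing.assert_allclose(d, d.T)


class TestNullDraw:
    WEIGHTS = OccupancyWeights(("a", "b", "c", "d"), np.array([1, 2, 1, 1]))

    def test_row_sums_exact(self, rng):
        out = null_draw([2, 2, 1], self.WEIGHTS, rng)
        assert out.richness().tolist() == [2, 2, 1]

    def test_zero_weight_species_never_drawn(self, rng):
        w = OccupancyWeights(("a", "b", "c", "d"), np.array([3, 2, 1, 0]))
        out = null_draw(np.full(200, 3), w, rng)
        assert out.incidence[:, 3].sum() == 0

    def test_richness_equal_to_pool_forces_all_ones(self, rng):
        out = null_draw([4, 4], self.WEIGHTS, rng)
        assert (out.incidence == 1).all()

    def test_infeasible_richness_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds pool"):
            null_draw([5], self.WEIGHTS, rng)

    @staticmethod
    def successive_inclusion_probs(w, k):
        """Exact inclusion probabilities by enumerating ordered draws."""
        w = np.asarray(w, float)
        S = len(w)
        probs = np.zeros(S)
        for perm in itertools.permutations(range(S), k):
            p, rem = 1.0, 1.0
            for s in perm:
                p *= w[s] / rem
                rem -= w[s]
            for s in perm:
                probs[s] += p
        return probs

    def test_inclusion_matches_enumeration_oracle(self):
        # 4-species pool, weights (0.2, 0.4, 0.2, 0.2), richness 2
        w = np.array([0.2, 0.4, 0.2, 0.2])
        expected = self.successive_inclusion_probs(w, 2)
        n = 20_000
        rng = np.random.default_rng(5)
        inc = weighted_incidence(np.full(n, 2), w, rng)
        observed = inc.mean(axis=0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(observed - expected) < 3 * se).all()

    def test_column_sum_chisquare_against_oracle(self):
        from scipy import stats
        w = np.array([0.2, 0.4, 0.2, 0.2])
        expected = self.successive_inclusion_probs(w, 2)
        n = 20_000
        inc = weighted_incidence(np.full(n, 2), w, np.random.default_rng(17))
        counts = inc.sum(axis=0)
        chi2 = ((counts - n * expected) ** 2 / (n * expected * (1 - expected))).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.001


class TestCalibratedRates:
    def test_poissonized_margins_match(self, rng):
        inc = (rng.random((30, 40)) < rng.uniform(0.05, 0.6, 40)).astype(int)
        inc[inc.sum(axis=1) == 0, 0] = 1
        counts = inc.sum(axis=0)
        k = inc.sum(axis=1)
        x = calibrate_pool_rates(counts, k)
        # solve site thresholds and check both margin conditions
        t = np.ones(len(k), float)
        for _ in range(60):
            E = np.exp(-np.outer(t, x))
            t = np.maximum(t - ((1 - E).sum(1) - k) / (E * x).sum(1), 1e-12)
        pi = 1 - np.exp(-np.outer(t, x))
        np.testing.assert_allclose(pi.sum(axis=1), k, atol=1e-6)
        pos = counts > 0
        np.testing.assert_allclose(pi.sum(axis=0)[pos], counts[pos], atol=1e-4)
        assert (x[counts == 0] == 0).all()


class TestCurveball:
    def test_margins_preserved_exactly(self, rng):
        inc = (rng.random((15, 25)) < 0.3).astype(np.int8)
        out = curveball_draw(inc, rng)
        assert (out.sum(axis=1) == inc.sum(axis=1)).all()
        assert (out.sum(axis=0) == inc.sum(axis=0)).all()

    def test_actually_shuffles(self, rng):
        inc = (np.random.default_rng(0).random((20, 30)) < 0.3).astype(np.int8)
        out = curveball_draw(inc, rng)
        assert (out != inc).any()


class TestSesDissimilarity:
    def test_seed_reproducible_bit_identical(self, tiny_community):
        cm = _cm((np.random.default_rng(3).random((8, 12)) < 0.4).astype(int))
        cm = cm.drop_empty_sites()
        a = ses_dissimilarity(cm, NullModelConfig(iterations=49, seed=11))
        b = ses_dissimilarity(cm, NullModelConfig(iterations=49, seed=11))
        np.testing.assert_array_equal(a.ses, b.ses)
        np.testing.assert_array_equal(a.null_mean, b.null_mean)

    def test_saturated_matrix_all_pairs_masked(self):
        cm = _cm(np.ones((4, 6), dtype=int))
        res = ses_dissimilarity(cm, NullModelConfig(iterations=19, seed=0))
        iu = np.triu_indices(4, 1)
        assert not res.defined[iu].any()

    def test_sd_uses_sample_denominator(self):
        cm = _cm((np.random.default_rng(4).random((6, 10)) < 0.5).astype(int))
        res = ses_dissimilarity(cm, NullModelConfig(iterations=25, seed=2))
        # recompute one pair's null SD by replaying the draws
        draws = []
        from limnodiv.nullmodels import curveball_draw as cb
        cm2 = cm.drop_empty_sites()
        for i in range(25):
            r = np.random.default_rng(np.random.SeedSequence(2, spawn_key=(i,)))
            inc = cb(cm2.incidence, r)
            draws.append(sorensen_matrix(_cm(inc)).values[0, 1])
        assert res.null_sd[0, 1] == pytest.approx(np.std(draws, ddof=1), rel=1e-10)

    def test_weighted_sampler_available(self):
        cm = _cm((np.random.default_rng(5).random((8, 15)) < 0.4).astype(int))
        cm = cm.drop_empty_sites()
        res = ses_dissimilarity(cm, NullModelConfig(
            iterations=29, seed=3, sampler="weighted", pool_rates="occupancy"))
        assert res.iterations == 29

    def test_filtered_synthetic_within_group_ses_negative(self, filtered_dataset):
        ses = ses_dissimilarity(filtered_dataset.community,
                                NullModelConfig(iterations=99, seed=4))
        lab = filtered_dataset.labels.for_sites(ses.site_ids)
        iu = np.triu_indices(len(lab), 1)
        within = lab[iu[0]] == lab[iu[1]]
        assert ses.ses[iu][within].mean() < 0


class TestShiftNonnegative:
    @staticmethod
    def _ses_result(values):
        from limnodiv.nullmodels import SesResult
        n = values.shape[0]
        defined = ~np.eye(n, dtype=bool)
        return SesResult(tuple(f"s{i}" for i in range(n)), values * 0, values * 0,
                         values * 0 + 1, values, defined, 99, 0)

    def test_already_nonnegative_identity(self):
        v = np.array([[0, 0.0, 1.5], [0.0, 0, 2.0], [1.5, 2.0, 0]])
        shifted, c = shift_nonnegative(self._ses_result(v))
        assert c == 0.0
        np.testing.assert_allclose(shifted.values, v)

    def test_constant_matrix_becomes_zero(self):
        v = np.full((3, 3), -2.0)
        np.fill_diagonal(v, 0.0)
        shifted, c = shift_nonnegative(self._ses_result(v))
        assert c == pytest.approx(2.0)
        assert np.allclose(shifted.values[np.triu_indices(3, 1)], 0.0)

    def test_masked_pair_rejected(self):
        from limnodiv.nullmodels import SesResult
        v = np.zeros((3, 3))
        defined = ~np.eye(3, dtype=bool)
        defined[0, 1] = defined[1, 0] = False
        res = SesResult(("a", "b", "c"), v, v, v, v, defined, 99, 0)
        with pytest.raises(ValueError, match="undefined SES"):
            shift_nonnegative(res)

    def test_permanova_shift_sensitivity_recorded(self, rng):
        """pseudo-F changes smoothly but not identically across shift constants."""
        from limnodiv.distance_tests import permanova
        inc = (rng.random((10, 20)) < 0.4).astype(int)
        inc[inc.sum(axis=1) == 0, 0] = 1
        cm = _cm(inc)
        ses = ses_dissimilarity(cm.drop_empty_sites(), NullModelConfig(iterations=49, seed=6))
        shifted, c = shift_nonnegative(ses)
        g = np.array(["a"] * 5 + ["b"] * (shifted.n - 5))
        f1 = permanova(shifted, g, permutations=9, seed=0).statistic
        extra = DistanceMatrix(shifted.site_ids,
                               shifted.values + 1.0 - np.eye(shifted.n), shifted.kind)
        f2 = permanova(extra, g, permutations=9, seed=0).statistic
        assert np.isfinite(f1) and np.isfinite(f2)
        assert f1 != pytest.approx(f2)
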