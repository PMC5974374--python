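import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from e2fsig import MarkerThresholds, bh_adjust, permutation_p, select_markers, welch_t
from e2fsig.exceptions import ParameterError
from e2fsig.io import ExpressionMatrix

from conftest import random_matrix


class TestWelchT:
    def test_identical_groups_zero(self):
        assert welch_t([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_known_value(self):
        # A={1,2,3}, B={4,5,6}: Welch t = -3.674 (equal variances, n=3 each)
        assert welch_t([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.674, abs=5e-4)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        assert welch_t(a, b) == pytest.approx(-welch_t(b, a))

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 10))
            b = rng.normal(0.5, 2, size=rng.integers(3, 10))
            expected = stats.ttest_ind(a, b, equal_var=False).statistic
            assert welch_t(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_unequal_means_flagged_infinite(self):
        assert welch_t([2.0, 2.0], [1.0, 1.0]) == np.inf
        assert welch_t([1.0, 1.0], [2.0, 2.0]) == -np.inf


class TestPermutationP:
    def test_agrees_with_exhaustive_enumeration(self):
        # 3+3 samples: exhaustive two-sided permutation p over all splits
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        pooled = a + b
        obs = abs(welch_t(a, b))
        hits = total = 0
        for comb in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in comb]
            gb = [pooled[i] for i in range(6) if i not in comb]
            total += 1
            hits += abs(welch_t(ga, gb)) >= obs - 1e-12
        exact = hits / total  # = 0.1
        p = permutation_p(a, b, n_perm=4000, seed=2)
        assert p == pytest.approx(exact, abs=0.02)

    def test_identical_groups_p_near_one(self):
        p = permutation_p([1.0, 2, 3, 4], [1.0, 2, 3, 4], n_perm=500, seed=0)
        assert p > 0.9

    def test_reproducible_by_seed(self):
        args = ([1.0, 2, 3], [2.0, 3, 8], 300)
        assert permutation_p(*args, seed=9) == permutation_p(*args, seed=9)

    def test_p_strictly_positive_floor(self):
        # +1 smoothing: p can never be below 1/(n_perm+1)
        p = permutation_p([1.0, 1.01, 0.99], [100.0, 101, 99], n_perm=200, seed=1)
        assert p >= 1 / 201

    def test_validation(self):
        with pytest.raises(ParameterError):
            permutation_p([1.0, 2], [3.0, 4], n_perm=10)
        with pytest.raises(ParameterError):
            permutation_p([], [1.0, 2], n_perm=200)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 5), 0.04)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(1e-6, 1, size=50)
        q = bh_adjust(p)
        assert ((q > 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.0, 0.5])


@pytest.fixture(scope="module")
def selection(default_cohort, averaged_matrix):
    lab = default_cohort.truth.sample_labels
    hi = lab.index[lab == "E2F-high"].tolist()
    lo = lab.index[lab == "E2F-low"].tolist()
    records, summary = select_markers(averaged_matrix, hi, lo, n_perm=1000, seed=1)
    return default_cohort, records, summary


class TestSelectMarkers:

    def test_recovers_planted_markers(self, selection):
        cohort, records, summary = selection
        roles = cohort.truth.gene_roles
        assert (records.loc[roles == "up", "direction"] == "up").all()
        assert (records.loc[roles == "down", "direction"] == "down").all()
        null_rate = (records.loc[roles == "null", "direction"] != "none").mean()
        assert null_rate <= 0.05

    def test_called_genes_satisfy_all_four_criteria(self, selection):
        _, records, _ = selection
        thr = MarkerThresholds()
        up = records[records["direction"] == "up"]
        assert (up["raw_p"] < thr.raw_p).all()
        assert (up["fdr_q"] < thr.fdr_q).all()
        assert (up["t_score"] > thr.t).all()
        assert (up["signed_fc"] > thr.fc).all()
        down = records[records["direction"] == "down"]
        assert (down["t_score"] <= -thr.t).all()
        assert (down["signed_fc"] <= -thr.fc).all()

    def test_boundary_t_excluded(self, selection):
        # a gene passing p/q/fc but with |t| below 6 must not be called
        _, records, _ = selection
        near = records[(records["t_score"].abs() <= 6) & (records["signed_fc"].abs() > 1.2)]
        assert (near["direction"] == "none").all()

    def test_direction_sign_consistency(self, selection):
        _, records, _ = selection
        assert (records.loc[records["direction"] == "up", "t_score"] > 0).all()
        assert (records.loc[records["direction"] == "down", "t_score"] < 0).all()
        assert (records["signed_fc"].abs() >= 1).all()

    def test_scale_invariance_under_global_doubling(self, rng):
        m = random_matrix(rng, 25, 12)
        groups = (m.sample_ids[:6], m.sample_ids[6:])
        rec1, _ = select_markers(m, *groups, n_perm=300, seed=3)
        doubled = ExpressionMatrix(m.values * 2.0, "linear")
        rec2, _ = select_markers(doubled, *groups, n_perm=300, seed=3)
        np.testing.assert_allclose(rec1["t_score"], rec2["t_score"], rtol=1e-9)
        np.testing.assert_allclose(rec1["raw_p"], rec2["raw_p"])
        np.testing.assert_allclose(rec1["signed_fc"], rec2["signed_fc"], rtol=1e-9)

    def test_row_order_independence(self, rng):
        m = random_matrix(rng, 20, 10)
        groups = (m.sample_ids[:5], m.sample_ids[5:])
        rec1, _ = select_markers(m, *groups, n_perm=300, seed=4)
        shuffled = ExpressionMatrix(m.values.sample(frac=1, random_state=7), "linear")
        rec2, _ = select_markers(shuffled, *groups, n_perm=300, seed=4)
        pd.testing.assert_frame_equal(rec1.sort_index(), rec2.sort_index())

    def test_group_validation(self, rng):
        m = random_matrix(rng, 5, 6)
        with pytest.raises(ParameterError):
            select_markers(m, m.sample_ids[:1], m.sample_ids[1:], n_perm=300)
        with pytest.raises(ParameterError):
            select_markers(m, m.sample_ids[:3], m.sample_ids[2:], n_perm=300)

    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            MarkerThresholds(raw_p=1.5)
        with pytest.raises(ParameterError):
            MarkerThresholds(fc=0.5)
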