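"""Upper-sided tests, effect statistics and BH adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from npirepro import bh_adjust, effect_stats, t_test_upper, wmt_upper
from npirepro.stats import bh_adjust_matrix, t_test_upper_matrix, wmt_upper_matrix
from conftest import ATOL_3DP, ATOL_4DP, TABLE2

PAIRS = list(TABLE2)


class TestTTestUpper:
    @pytest.mark.parametrize("pair", PAIRS)
    def test_case_study_pvalues_and_decisions(self, table1, pair):
        exp = TABLE2[pair]
        res = t_test_upper(table1[pair[0]], table1[pair[1]])
        assert res.p_value == pytest.approx(exp["p"], abs=ATOL_4DP)
        assert res.reject is exp["reject"]

    def test_identical_samples(self):
        res = t_test_upper([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)
        assert not res.reject

    def test_zero_pooled_variance_is_an_error(self):
        with pytest.raises(ValueError):
            t_test_upper([1.0, 1.0], [1.0, 1.0])

    def test_p_exactly_alpha_does_not_reject(self):
        from npirepro.stats import TestResult

        assert not TestResult(1.0, 0.05, 0.05, "t").reject

    @settings(max_examples=50, deadline=None)
    @given(
        st.integers(0, 2**32 - 1),
        st.floats(0.1, 3.0, allow_nan=False),
    )
    def test_rejection_monotone_in_upward_shift(self, seed, shift):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=6), rng.normal(size=6)
        assert t_test_upper(x + shift, y).p_value <= t_test_upper(x, y).p_value


class TestWmtUpper:
    def test_case_study_outcomes_match_t_test(self, table1):
        outcomes = "".join(
            wmt_upper(table1[a], table1[b]).outcome for a, b in PAIRS
        )
        assert outcomes == "YYYYN"

    def test_identical_samples_do_not_reject(self):
        res = wmt_upper([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value >= 0.5
        assert not res.reject

    def test_exact_small_sample_p(self):
        # all 3 ranks above: one of C(6,3)=20 equally likely assignments
        res = wmt_upper([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1 / 20)
        assert not res.reject  # p == alpha exactly: strict rule


class TestMatrixRoutesAgreeWithScalar:
    """The vectorised bootstrap paths against the scipy scalar routes."""

    @pytest.mark.parametrize("nx, ny", [(6, 6), (8, 10), (12, 12)])
    def test_t_matrix(self, nx, ny):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(100, nx)), rng.normal(0.5, 1.0, size=(100, ny))
        p = t_test_upper_matrix(X, Y)
        for i in range(100):
            assert p[i] == pytest.approx(t_test_upper(X[i], Y[i]).p_value, rel=1e-9)

    @pytest.mark.parametrize("nx, ny", [(6, 6), (9, 10), (12, 12)])
    def test_wmt_matrix(self, nx, ny):
        rng = np.random.default_rng(3)
        X, Y = rng.normal(size=(100, nx)), rng.normal(0.5, 1.0, size=(100, ny))
        p = wmt_upper_matrix(X, Y)
        for i in range(100):
            assert p[i] == pytest.approx(wmt_upper(X[i], Y[i]).p_value, rel=1e-9)


class TestEffectStats:
    @pytest.mark.parametrize("pair", PAIRS)
    def test_case_study_effect_sizes(self, table1, pair):
        exp = TABLE2[pair]
        eff = effect_stats(table1[pair[0]], table1[pair[1]])
        assert eff.effect_size == pytest.approx(exp["es"], abs=ATOL_3DP)
        assert eff.cohens_d == pytest.approx(exp["d"], abs=ATOL_3DP)

    def test_identical_samples(self):
        eff = effect_stats([1.0, 2.0], [1.0, 2.0])
        assert eff.effect_size == 0.0
        assert eff.cohens_d == 0.0

    def test_both_constant_is_an_error(self):
        with pytest.raises(ValueError):
            effect_stats([1.0, 1.0], [2.0, 2.0])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=7), rng.normal(1.0, 2.0, size=9)
        fwd, rev = effect_stats(x, y), effect_stats(y, x)
        assert rev.effect_size == -fwd.effect_size
        assert rev.cohens_d == -fwd.cohens_d
        assert rev.pooled_sd == fwd.pooled_sd


class TestBhAdjust:
    def test_case_study_adjusted_pvalues(self, table1):
        raw = [t_test_upper(table1[a], table1[b]).p_value for a, b in PAIRS]
        adj = bh_adjust(raw)
        # printed values for A vs B, C vs D, D vs E, E vs F (the B-vs-C cell
        # is of order 1e-6)
        assert adj[0] == pytest.approx(0.0007, abs=ATOL_4DP)
        assert adj[1] < 1e-5
        assert adj[2] == pytest.approx(0.0012, abs=ATOL_4DP)
        assert adj[3] == pytest.approx(0.0239, abs=ATOL_4DP)
        assert adj[4] == pytest.approx(0.5977, abs=ATOL_4DP)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_step_up_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_rejects_p_outside_unit_interval(self):
        with pytest.raises(ValueError):
            bh_adjust([0.2, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10))
    def test_dominates_input_and_is_permutation_equivariant(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        perm = np.random.default_rng(0).permutation(p.size)
        assert np.allclose(bh_adjust(p[perm]), adj[perm])

    def test_matrix_route_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(size=(200, 5))
        adj = bh_adjust_matrix(P)
        for i in range(200):
            assert np.allclose(adj[i], multipletests(P[i], method="fdr_bh")[1])
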