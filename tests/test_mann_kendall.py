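"""Classical/sequential Mann-Kendall statistics against brute-force
oracles, closed forms, and the published worked tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respirocod import (detect_endogenous_onset, detect_mutation_point,
                        mk_trend_test, sequential_mk)
from respirocod.mann_kendall import round_half_up
from tests.conftest import make_series


def brute_force_s(x):
    """Pairwise sign count, the defining double loop."""
    n = len(x)
    s = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            s += int(x[j] > x[i]) - int(x[j] < x[i])
    return s


def brute_force_sk(x):
    """Cumulative count of earlier values strictly below each sample."""
    out = []
    total = 0
    for i in range(len(x)):
        total += sum(1 for j in range(i) if x[j] < x[i])
        out.append(total)
    return out


class TestClassical:
    def test_reference_table_statistics(self, table2):
        res = mk_trend_test(table2)
        assert res.s_stat == -130
        assert int(res.var_s) == 589
        assert res.var_s == pytest.approx(17 * 16 * 39 / 18)
        assert round_half_up(res.z_mk, 1) == -5.3
        assert res.significant and res.direction == "down"

    def test_strictly_increasing(self):
        res = mk_trend_test(np.arange(1.0, 11.0), alpha=0.05)
        assert res.s_stat == 45
        assert res.direction == "up"

    def test_constant_vector(self):
        res = mk_trend_test(np.full(8, 3.3))
        assert res.s_stat == 0
        assert res.z_mk == 0.0
        assert not res.significant

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            mk_trend_test([1.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False), min_size=2, max_size=12))
    def test_s_matches_brute_force(self, values):
        assert mk_trend_test(values).s_stat == brute_force_s(values)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False), min_size=2, max_size=12,
                    unique=True))
    def test_antisymmetry_on_tie_free_series(self, values):
        fwd = mk_trend_test(values)
        rev = mk_trend_test(values[::-1])
        assert rev.s_stat == -fwd.s_stat
        assert rev.z_mk == pytest.approx(-fwd.z_mk)

    def test_concordant_discordant_split(self, table2):
        """S decomposes into the rise/fall pair counts of the worked
        spreadsheet (3 rises, 133 falls)."""
        x = table2.our
        n = len(x)
        rises = sum(1 for i in range(n - 1) for j in range(i + 1, n)
                    if x[j] > x[i])
        falls = sum(1 for i in range(n - 1) for j in range(i + 1, n)
                    if x[j] < x[i])
        assert (rises, falls) == (3, 133)
        assert mk_trend_test(x).s_stat == rises - falls


class TestSequential:
    def test_reference_forward_tabulation(self, table3):
        seq = sequential_mk(table3)
        assert seq.s_k[-1] == 4
        assert seq.e_sk[-1] == 68
        assert seq.var_sk[-1] == pytest.approx(147.333, abs=5e-3)
        assert round_half_up(seq.uf[8]) == -3.54   # k = 9, t = 40 min
        assert round_half_up(seq.uf[16]) == -5.27  # k = 17, t = 80 min

    def test_closed_form_expectation_and_variance(self, table3):
        seq = sequential_mk(table3)
        k = seq.k.astype(float)
        np.testing.assert_allclose(seq.e_sk, k * (k - 1) / 4)
        np.testing.assert_allclose(seq.var_sk, k * (k - 1) * (2 * k + 5) / 72)

    def test_uf1_defined_as_zero(self, table3):
        assert sequential_mk(table3).uf[0] == 0.0

    def test_strictly_increasing_maximal_concordance(self):
        x = np.arange(1.0, 13.0)
        seq = sequential_mk(x)
        k = seq.k.astype(float)
        np.testing.assert_allclose(seq.s_k, k * (k - 1) / 2)
        assert np.all(seq.uf[1:] > 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False), min_size=3, max_size=12))
    def test_sk_matches_brute_force(self, values):
        np.testing.assert_array_equal(sequential_mk(values).s_k,
                                      brute_force_sk(values))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False), min_size=3, max_size=12,
                    unique=True))
    def test_sn_relates_to_classical_s_when_tie_free(self, values):
        n = len(values)
        seq = sequential_mk(values)
        s = mk_trend_test(values).s_stat
        assert seq.s_k[-1] == (n * (n - 1) / 2 + s) / 2

    def test_ub_is_negated_reversed_forward_recipe(self, table3, table4):
        seq = sequential_mk(table3)
        seq_rev = sequential_mk(table4)
        np.testing.assert_allclose(seq.ub, -seq_rev.uf[::-1])

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            sequential_mk([1.0, 2.0])


class TestEndogenousOnset:
    def test_reference_table_plateau_at_70min(self, table2):
        t2, window, trace = detect_endogenous_onset(table2)
        assert t2 == 70.0
        assert window == (14, 16)  # the (11, 11.2, 11.3) tail
        assert len(trace) >= 1

    def test_constant_series_is_all_plateau(self):
        s = make_series(np.arange(10) * 5.0, np.full(10, 11.5))
        t2, window, _ = detect_endogenous_onset(s)
        assert t2 == 0.0
        assert window == (0, 9)

    def test_steadily_decaying_series_has_no_plateau(self):
        s = make_series(np.arange(8) * 5.0,
                        50.0 * 0.8 ** np.arange(8))
        with pytest.raises(ValueError, match="no endogenous plateau"):
            detect_endogenous_onset(s, min_window=4)

    def test_too_short_series(self):
        s = make_series([0.0, 5.0, 10.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="too short"):
            detect_endogenous_onset(s, min_window=3)

    def test_idempotent_on_returned_plateau(self, table2):
        t2, window, _ = detect_endogenous_onset(table2)
        suffix = make_series(table2.times[window[0]:],
                             table2.our[window[0]:])
        t2_again, _, _ = detect_endogenous_onset(
            suffix, min_window=len(suffix) - 1)
        assert t2_again == t2

    def test_single_spike_does_not_end_plateau(self):
        rng = np.random.default_rng(5)
        n = 40
        our = 11.5 + rng.normal(0, 0.1, n)
        our[10] = 14.0  # isolated aberrant sample inside the plateau
        s = make_series(np.arange(n) * 2.0, our)
        t2, _, _ = detect_endogenous_onset(s)
        assert t2 <= 2.0 * 9


class TestMutationPoint:
    def test_symmetric_crossing(self):
        class Seq:
            uf = np.array([-1.0, 0.0, 1.0])
            ub = np.array([1.0, 0.0, -1.0])
            times = np.array([0.0, 5.0, 10.0])

        t_cross, within, degenerate = detect_mutation_point(Seq())
        assert t_cross == 5.0
        assert within and not degenerate

    def test_identical_curves_flagged_degenerate(self):
        class Seq:
            uf = np.array([0.3, 0.4, 0.5])
            ub = np.array([0.3, 0.4, 0.5])
            times = np.array([0.0, 5.0, 10.0])

        t_cross, within, degenerate = detect_mutation_point(Seq())
        assert t_cross == 0.0
        assert degenerate

    def test_no_crossing_returns_none(self, table3):
        seq = sequential_mk(table3)
        res_t, within, degenerate = detect_mutation_point(seq)
        # forward/backward curves of this series do cross once
        assert res_t is not None

    def test_crossing_matches_independent_interpolation(self, table3):
        seq = sequential_mk(table3)
        t_cross, _, _ = detect_mutation_point(seq)
        d = seq.uf - seq.ub
        i = int(np.flatnonzero(np.diff(np.sign(d)) != 0)[0])
        frac = d[i] / (d[i] - d[i + 1])
        expected = seq.times[i] + frac * (seq.times[i + 1] - seq.times[i])
        assert t_cross == pytest.approx(expected)
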