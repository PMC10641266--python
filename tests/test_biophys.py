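"""Melt-curve fitting, derivative Tm, exact tests and delta summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cysscan import (FitError, MeltCurve, delta_summary, dsf_tm, fisher_exact,
                     fit_boltzmann, paired_signed_rank, refolding_alpha)
from cysscan.biophys import BoltzmannMeltModel, boltzmann
from cysscan.synthetic import gen_melt


class TestBoltzmannFit:
    def test_noise_free_roundtrip(self):
        curve = gen_melt(tm=65.0, slope=2.5, noise_sd=0.0)
        res = fit_boltzmann(curve)
        assert res.tm == pytest.approx(65.0, abs=0.05)
        assert res.slope == pytest.approx(2.5, abs=0.05)
        assert res.lower_plateau == pytest.approx(0.0, abs=0.1)
        assert res.upper_plateau == pytest.approx(100.0, abs=0.1)
        assert res.rms_residual < 1e-6 * (res.upper_plateau - res.lower_plateau)

    def test_noisy_tm_within_half_degree(self):
        curve = gen_melt(tm=71.3, slope=3.0, noise_sd=2.0, seed=17)
        res = fit_boltzmann(curve)
        assert abs(res.tm - 71.3) <= 0.5

    def test_sharp_transition_tm_approaches_step_location(self):
        for slope in (1.0, 0.3, 0.1):
            curve = gen_melt(tm=60.0, slope=slope)
            assert fit_boltzmann(curve).tm == pytest.approx(60.0, abs=0.25)

    def test_constrained_plateaus_mode(self):
        curve = gen_melt(tm=55.0, slope=2.0, noise_sd=1.0, seed=3)
        res = fit_boltzmann(curve, constrain_plateaus=True)
        assert res.constrained
        assert abs(res.tm - 55.0) <= 0.5

    def test_flat_data_refused(self):
        t = np.arange(25.0, 80.0, 0.5)
        with pytest.raises(FitError):
            fit_boltzmann(MeltCurve(t, np.full_like(t, 3.0)))

    def test_summary_and_predict(self):
        curve = gen_melt(tm=65.0)
        res = fit_boltzmann(curve)
        assert "tm" in res.summary()
        assert res.predict(65.0) == pytest.approx(
            (res.lower_plateau + res.upper_plateau) / 2, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            MeltCurve(np.arange(5), np.arange(5))

    def test_nonmonotone_temperatures_rejected(self):
        t = np.array([25, 26, 26, 27, 28, 29, 30, 31, 32, 33], dtype=float)
        with pytest.raises(ValueError):
            MeltCurve(t, np.zeros_like(t))


class TestRefoldingAlpha:
    def test_plateau_ratio(self):
        first = fit_boltzmann(gen_melt(tm=65.0, upper=100.0))
        second = fit_boltzmann(gen_melt(tm=65.0, upper=80.0))
        assert refolding_alpha(first, second).alpha == pytest.approx(0.8, abs=1e-3)

    def test_identical_curves_give_exactly_one(self):
        res = fit_boltzmann(gen_melt(tm=60.0))
        assert refolding_alpha(res, res).alpha == pytest.approx(1.0, abs=1e-12)

    def test_generator_roundtrip_at_configured_alpha(self):
        first = fit_boltzmann(gen_melt(tm=63.0, upper=100.0, noise_sd=1.0, seed=8))
        second = fit_boltzmann(gen_melt(tm=58.0, upper=65.0, noise_sd=1.0, seed=9))
        assert refolding_alpha(first, second).alpha == pytest.approx(0.65, abs=0.02)

    def test_degenerate_first_plateau_rejected(self):
        res = fit_boltzmann(gen_melt(tm=60.0))
        shrunk = type(res)(model=res.model, tm=res.tm, slope=res.slope,
                           lower_plateau=5.0, upper_plateau=5.0, cov=res.cov,
                           rms_residual=res.rms_residual, constrained=False)
        with pytest.raises(ValueError):
            refolding_alpha(shrunk, res)


class TestDsfTm:
    def test_inflection_recovered_on_half_degree_grid(self):
        curve = gen_melt(tm=55.0, slope=2.0, kind="DSF")
        assert abs(dsf_tm(curve) - 55.0) <= 0.5

    def test_linear_signal_fails(self):
        t = np.arange(25.0, 45.0, 0.5)
        with pytest.raises(FitError):
            dsf_tm(MeltCurve(t, 2.0 * t, kind="DSF"))

    def test_grid_shift_moves_estimate_at_most_one_step(self):
        grid = np.arange(25.0, 90.0, 0.5)
        a = dsf_tm(gen_melt(tm=55.0, slope=2.0, grid=grid, kind="DSF"))
        b = dsf_tm(gen_melt(tm=55.0, slope=2.0, grid=grid + 0.25, kind="DSF"))
        assert abs(a - b) <= 0.5

    def test_agrees_with_boltzmann_tm_on_shared_sigmoids(self):
        for tm in (45.0, 60.0, 75.0):
            curve = gen_melt(tm=tm, slope=2.5)
            fitted = fit_boltzmann(curve).tm
            derivative = dsf_tm(MeltCurve(curve.temperature, curve.signal,
                                          kind="DSF"))
            assert abs(fitted - derivative) <= 0.5  # one grid step

    def test_smoothing_window_validation(self):
        curve = gen_melt(tm=55.0, kind="DSF")
        with pytest.raises(ValueError):
            dsf_tm(curve, smooth_window=2)


def signed_rank_bruteforce(deltas):
    """Literal enumeration of all 2^n sign assignments."""
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    hits = total = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestSignedRank:
    def test_three_positive_deltas(self):
        assert paired_signed_rank([1.0, 2.0, 3.0]).p_value == pytest.approx(0.25)

    def test_single_pair_two_sided_p_is_one(self):
        assert paired_signed_rank([1.5]).p_value == pytest.approx(1.0)

    def test_zeros_dropped_and_reported(self):
        res = paired_signed_rank([0.0, 0.0, 1.0, -2.0, 3.0])
        assert res.n_zero == 2 and res.n_used == 3

    def test_all_zero_deltas_undefined(self):
        with pytest.raises(ValueError):
            paired_signed_rank([0.0, 0.0])

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(deltas=st.lists(
        st.floats(-10, 10, allow_nan=False).filter(lambda x: x != 0),
        min_size=1, max_size=10))
    def test_matches_bruteforce_enumeration_up_to_n10(self, deltas):
        assert paired_signed_rank(deltas).p_value == pytest.approx(
            signed_rank_bruteforce(deltas), abs=1e-12)

    def test_tied_magnitudes_use_midranks(self):
        # |deltas| = 2,2,5 -> midranks 1.5,1.5,3
        assert paired_signed_rank([2.0, -2.0, 5.0]).p_value == pytest.approx(
            signed_rank_bruteforce([2.0, -2.0, 5.0]))

    def test_agrees_with_scipy_when_tie_free(self):
        deltas = [1.0, -2.0, 3.5, 4.0, -5.5, 7.0, 8.5]
        ours = paired_signed_rank(deltas).p_value
        theirs = stats.wilcoxon(deltas, mode="exact",
                                alternative="two-sided").pvalue
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(
            2 / 252, abs=1e-10)  # hypergeometric enumeration: 2 of C(10,5)

    def test_identical_rows_give_one(self):
        assert fisher_exact([[3, 7], [3, 7]]) == pytest.approx(1.0)

    def test_transpose_invariance(self):
        table = [[2, 9], [5, 1]]
        transposed = [[2, 5], [9, 1]]
        assert fisher_exact(table) == pytest.approx(fisher_exact(transposed))

    def test_empty_margin_flagged_as_no_association(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_matches_scipy_on_all_small_tables(self):
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b + c + d == 0:
                continue
            ours = fisher_exact([[a, b], [c, d]])
            theirs = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, abs=1e-9), (a, b, c, d)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestDeltaSummary:
    def test_median_of_differences(self):
        wt = {"a": 60.0, "b": 61.0, "c": 62.0}
        eng = {"a": 62.0, "b": 64.0, "c": 66.0}
        res = delta_summary(wt, eng, kind="tm")
        assert res.median_delta == pytest.approx(3.0)
        assert res.n_pairs == 3

    def test_kd_is_a_ratio_above_one_means_weaker(self):
        res = delta_summary({"x": 1.0}, {"x": 4.0}, kind="kd")
        assert res.median_delta == pytest.approx(4.0)

    def test_pair_order_invariance(self):
        wt = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        eng = {"a": 2.5, "b": 1.5, "c": 6.0, "d": 4.5}
        forward = delta_summary(wt, eng, kind="tm")
        rev_wt = dict(reversed(list(wt.items())))
        rev_eng = dict(reversed(list(eng.items())))
        backward = delta_summary(rev_wt, rev_eng, kind="tm")
        assert forward.median_delta == backward.median_delta
        assert forward.p_value == backward.p_value

    def test_unpaired_ids_are_ignored_and_disjoint_rejected(self):
        res = delta_summary({"a": 1.0, "b": 2.0}, {"b": 3.0, "c": 9.0}, "tm")
        assert res.n_pairs == 1
        with pytest.raises(ValueError):
            delta_summary({"a": 1.0}, {"b": 2.0}, "tm")

    def test_summary_text(self):
        res = delta_summary({"a": 60.0, "b": 60.0}, {"a": 72.0, "b": 75.0}, "tm")
        assert "median delta" in res.summary()
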