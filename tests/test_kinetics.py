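"""Threshold fitting, high-FRET fraction, and crossing-rate estimation,
including the exhaustive brute-force crossing oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndcfret import KineticsConfig, simulate_state_path
from ndcfret.kinetics import (
    SpuriousCrossingModel,
    compute_threshold,
    correct_switching_estimate,
    estimate_switching_rates,
    fit_no_fret_gaussian,
    high_fret_fraction,
)

from conftest import markov_occupancy_se


def brute_force_crossings(e, threshold):
    """Independent oracle: enumerate every consecutive valid frame pair."""
    ups = downs = 0
    for a, b in zip(e[:-1], e[1:]):
        if np.isnan(a) or np.isnan(b):
            continue
        if a <= threshold < b:
            ups += 1
        if a > threshold >= b:
            downs += 1
    return ups, downs


class TestGaussianFit:
    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.0, 0.15, size=10_000)
        mu, sigma = fit_no_fret_gaussian(values)
        # binned least-squares fit: tolerance of 3 SE plus half a bin of
        # discretization slack
        assert abs(mu) < 3 * 0.15 / np.sqrt(10_000) + 0.025
        assert abs(sigma - 0.15) < 3 * 0.15 / np.sqrt(2 * 10_000) + 0.025

    def test_symmetric_data_mu_near_median(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0.2, 0.1, size=5000)
        mu, _ = fit_no_fret_gaussian(values)
        assert abs(mu - np.median(values)) < 0.05  # one bin

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            fit_no_fret_gaussian(np.zeros(500))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_no_fret_gaussian(np.random.default_rng(2).normal(size=50))


class TestThreshold:
    def test_paper_working_point(self):
        assert compute_threshold(0.0, 0.15) == pytest.approx(0.30)

    def test_generic(self):
        assert compute_threshold(0.1, 0.05) == pytest.approx(0.20)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(0.0, 0.0)


class TestHighFretFraction:
    def test_hand_count(self):
        frac, _ = high_fret_fraction(np.array([0.1, 0.5, 0.2, 0.9]), 0.3)
        assert frac == pytest.approx(0.5)

    def test_all_below(self):
        frac, _ = high_fret_fraction(np.array([0.0, 0.1, 0.2]), 0.3)
        assert frac == 0.0

    def test_batch_sem(self):
        e = np.array([0.9, 0.0, 0.9, 0.0, 0.0, 0.0])
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        frac, sem = high_fret_fraction(e, 0.3, labels)
        per_batch = np.array([0.5, 0.5, 0.0])
        assert frac == pytest.approx(2 / 6)
        assert sem == pytest.approx(per_batch.std(ddof=1) / np.sqrt(3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            high_fret_fraction(np.array([np.nan]), 0.3)

    def test_stationary_noise_free_fraction(self, paper_kinetics):
        # noise-free two-state traces at the measured switching rates:
        # the high-FRET fraction is the stationary closed occupancy 0.193
        rng = np.random.default_rng(3)
        es = [
            np.where(simulate_state_path(paper_kinetics, 2.5, 10.0, rng), 0.8, 0.0)
            for _ in range(2000)
        ]
        pool = np.concatenate(es)
        frac, _ = high_fret_fraction(pool, 0.3)
        expected = 0.23 / 1.19
        se = markov_occupancy_se(expected, 25, 1.19, 0.1) / np.sqrt(2000)
        assert abs(frac - expected) < 3 * se


class TestSwitchingRates:
    def test_hand_enumerated_trace(self):
        e = np.array([0, 0, 0.8, 0.8, 0.8, 0.8, 0.8, 0, 0, 0], dtype=float)
        est = estimate_switching_rates([e], 0.3, 0.1)
        assert (est.n_up, est.n_down) == (1, 1)
        assert est.t_below == pytest.approx(0.5)
        assert est.t_above == pytest.approx(0.5)
        assert est.k_closing == pytest.approx(2.0)
        assert est.k_opening == pytest.approx(2.0)

    def test_constant_low_trace_undefined_opening(self):
        est = estimate_switching_rates([np.zeros(20)], 0.3, 0.1)
        assert est.n_up == 0 and est.t_above == 0.0
        assert not est.k_opening_defined

    def test_matches_brute_force_on_randomized_traces(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            n = rng.integers(2, 30)
            e = rng.normal(0.3, 0.4, size=n)
            e[rng.random(n) < 0.1] = np.nan
            est = estimate_switching_rates([e], 0.3, 0.1)
            # oracle must also skip pairs with an invalid member
            ups, downs = brute_force_crossings(e, 0.3)
            assert (est.n_up, est.n_down) == (ups, downs)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(-0.5, 1.5, allow_nan=False), min_size=2, max_size=50))
    def test_up_down_counts_differ_at_most_one_per_trace(self, values):
        est = estimate_switching_rates([np.array(values)], 0.3, 0.1)
        assert abs(est.n_up - est.n_down) <= 1

    def test_no_crossing_counted_across_gap(self):
        e = np.array([0.0, np.nan, 0.8, 0.8, np.nan, 0.0])
        est = estimate_switching_rates([e], 0.3, 0.1)
        assert est.n_up == 0 and est.n_down == 0

    def test_noise_free_rate_recovery(self, paper_kinetics):
        # discretization bias at 10 fps stays below 10% for these rates
        rng = np.random.default_rng(5)
        es = [
            np.where(simulate_state_path(paper_kinetics, 50.0, 10.0, rng), 0.8, 0.0)
            for _ in range(200)
        ]
        est = estimate_switching_rates(es, 0.3, 0.1)
        assert est.k_closing == pytest.approx(0.23, rel=0.10)
        assert est.k_opening == pytest.approx(0.96, rel=0.10)

    def test_occupancy_consistency(self, paper_kinetics):
        # fraction of time above threshold ~ k_closing/(k_closing+k_opening)
        rng = np.random.default_rng(6)
        es = [
            np.where(simulate_state_path(paper_kinetics, 100.0, 10.0, rng), 0.8, 0.0)
            for _ in range(50)
        ]
        est = estimate_switching_rates(es, 0.3, 0.1)
        frac_above = est.t_above / (est.t_above + est.t_below)
        implied = est.k_closing / (est.k_closing + est.k_opening)
        assert frac_above == pytest.approx(implied, abs=0.01)


class TestSpuriousCorrection:
    def test_zero_spurious_keeps_counts_and_uses_pair_time(self):
        est = estimate_switching_rates(
            [np.array([0, 0, 0.8, 0.8, 0, 0, 0, 0, 0, 0], float)], 0.3, 0.1
        )
        spurious = SpuriousCrossingModel(up_rate=0.0, above_occupancy=0.0, n_up=0)
        out = correct_switching_estimate(est, spurious)
        assert (out.n_up, out.n_down) == (est.n_up, est.n_down)
        # rates switch to the discrete-chain form -ln(1 - events/pairs)/dt
        assert out.k_closing == pytest.approx(
            -np.log1p(-est.n_up / est.n_below_pairs) / 0.1
        )
        assert out.k_opening == pytest.approx(
            -np.log1p(-est.n_down / est.n_above_pairs) / 0.1
        )

    def test_never_negative_counts(self):
        est = estimate_switching_rates(
            [np.array([0, 0.8, 0, 0.8, 0], float)], 0.3, 0.1
        )
        spurious = SpuriousCrossingModel(up_rate=100.0, above_occupancy=0.0, n_up=50, q_up=10.0)
        out = correct_switching_estimate(est, spurious)
        assert out.n_up == 0 and out.k_closing == 0.0
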