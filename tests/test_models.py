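"""Closed-form decay models: examples, continuity, reductions, derived quantities."""

import math

import numpy as np
import pytest

from rifseg import models as m
from tests.conftest import random_params


class TestCoTranscriptional:
    def test_steady_state_before_delay(self):
        p = m.ModelParams.from_per_second(alpha=0.6, lam=0.01, v=25, n=1000)
        assert m.conc_co(0.0, p) == pytest.approx(60.0)

    def test_continuity_at_delay(self):
        p = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=3000.0)
        eps = 1e-9
        assert m.conc_co(p.delay, p) == pytest.approx(60.0)
        assert m.conc_co(p.delay - eps, p) == pytest.approx(m.conc_co(p.delay, p), abs=1e-6)

    def test_one_half_life_after_delay(self):
        lam = math.log(2.0) / 2.0
        p = m.ModelParams(alpha=30.0 * lam, lam=lam, v=1500.0, n=1500.0)
        assert m.conc_co(p.delay + 2.0, p) == pytest.approx(15.0)

    def test_negative_time_rejected(self):
        p = m.ModelParams(alpha=1.0, lam=1.0, v=100.0, n=10.0)
        with pytest.raises(ValueError):
            m.conc_co(-0.1, p)


class TestBackgroundVariant:
    def test_bg_zero_reduces_to_co(self, rng):
        for _ in range(20):
            p = random_params(rng, bg=0.0)
            t = rng.uniform(0, 20)
            assert m.conc_co_bg(t, p) == m.conc_co(t, p)

    def test_asymptote_is_bg(self):
        p = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=0.0, bg=5.0)
        assert m.conc_co_bg(1e6, p) == pytest.approx(5.0)

    def test_additivity(self):
        p = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=3000.0, bg=5.0)
        assert m.conc_co_bg(0.0, p) == pytest.approx(65.0)


class TestPostTranscriptional:
    def test_plateau_at_three_prime_end(self):
        p = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=1000.0, L=1000.0)
        assert m.conc_post(0.0, p) == pytest.approx(60.0)

    def test_hand_evaluated_plateau(self):
        p = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=0.0, L=1000.0)
        assert m.conc_post(0.0, p) == pytest.approx(84.0)

    def test_continuity_at_both_breakpoints(self, rng):
        for _ in range(20):
            L = float(rng.uniform(500, 4000))
            p = random_params(rng, n=float(rng.uniform(0, L)), L=L)
            for bp in (p.n / p.v, p.L / p.v):
                left = m.conc_post(max(bp - 1e-9, 0.0), p)
                assert m.conc_post(bp, p) == pytest.approx(left, abs=1e-6)


class TestPreSteadyState:
    def test_zero_before_arrival(self):
        p = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=3000.0, t_rif=1.0)
        assert m.conc_pre_steady(1.0, p) == 0.0

    def test_peak_value(self):
        p = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=0.0, t_rif=1.0)
        assert m.conc_pre_steady(1.0, p) == pytest.approx(60.0 * (1 - math.exp(-0.6)), rel=1e-9)
        assert m.conc_pre_steady(1.0, p) == pytest.approx(27.07, abs=0.01)

    def test_large_t_rif_converges_to_co_shape(self):
        p = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=1500.0, t_rif=200.0)
        pc = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=1500.0)
        # well inside the rise the curve is at steady state, like conc_co
        assert m.conc_pre_steady(100.0, p) == pytest.approx(m.conc_co(0.0, pc), rel=1e-6)

    def test_continuity(self, rng):
        for _ in range(20):
            p = random_params(rng, t_rif=float(rng.uniform(0.2, 10)))
            for bp in (p.n / p.v, p.n / p.v + p.t_rif):
                left = m.conc_pre_steady(max(bp - 1e-9, 0.0), p)
                assert m.conc_pre_steady(bp, p) == pytest.approx(left, abs=1e-6)


class TestRST:
    def test_beta_zero_reduces_to_co(self, rng):
        for _ in range(20):
            p = random_params(rng, beta=0.0)
            p.n_term = p.n * 0.5
            t = rng.uniform(0, 20)
            assert m.conc_rst(t, p) == pytest.approx(m.conc_co(t, p), rel=1e-12)

    def test_pre_rifampicin_plateau(self):
        p = m.ModelParams(alpha=36.0, lam=0.6, v=1500.0, n=3000.0,
                          n_term=1500.0, beta=0.3)
        assert m.conc_rst(0.0, p) == pytest.approx(42.0)

    def test_max_relative_increase_formula(self, rng):
        """Peak increase over the plateau equals beta*(1-exp(-lam*n_term/v))/(1-beta)."""
        for _ in range(10):
            p = random_params(rng, beta=float(rng.uniform(0.1, 0.9)))
            p.n_term = p.n * float(rng.uniform(0.1, 1.0))
            t = np.linspace(0, p.n / p.v, 4000)
            peak = np.max(m.conc_rst(t, p))
            plateau = m.conc_rst(0.0, p)
            expected = p.beta * (1 - math.exp(-p.lam * p.n_term / p.v)) / (1 - p.beta)
            assert (peak - plateau) / plateau == pytest.approx(expected, rel=1e-3)

    def test_continuity(self, rng):
        for _ in range(20):
            p = random_params(rng, beta=float(rng.uniform(0, 1)))
            p.n_term = p.n * float(rng.uniform(0, 1))
            for bp in ((p.n - p.n_term) / p.v, p.n / p.v):
                left = m.conc_rst(max(bp - 1e-9, 0.0), p)
                assert m.conc_rst(bp, p) == pytest.approx(left, abs=1e-6)


class TestTwoPromoter:
    def test_alpha2_zero_reduces_to_co(self, rng):
        for _ in range(20):
            p = random_params(rng, alpha2=0.0)
            t = rng.uniform(0, 20)
            assert m.conc_two_promoter(t, p) == m.conc_co(t, p)

    def test_double_plateau(self):
        p = m.ModelParams(alpha=30.0, lam=0.6, v=1500.0, n=3000.0,
                          alpha2=12.0, n2=600.0)
        assert m.conc_two_promoter(0.0, p) == pytest.approx((30.0 + 12.0) / 0.6)

    def test_symmetry_equal_promoters(self):
        p = m.ModelParams(alpha=30.0, lam=0.6, v=1500.0, n=3000.0,
                          alpha2=30.0, n2=2999.999999)
        pc = m.ModelParams(alpha=30.0, lam=0.6, v=1500.0, n=3000.0)
        for t in (0.0, 1.0, 2.0, 5.0, 10.0):
            assert m.conc_two_promoter(t, p) == pytest.approx(2 * m.conc_co(t, pc), rel=1e-6)


class TestNonNegativityAndMonotony:
    def test_concentrations_nonnegative_and_decay_monotone(self, rng):
        t = np.linspace(0, 30, 200)
        for _ in range(10):
            p = random_params(rng, bg=float(rng.uniform(0, 5)),
                              t_rif=float(rng.uniform(0.5, 5)),
                              beta=float(rng.uniform(0, 0.9)))
            p.L = p.n + float(rng.uniform(0, 2000))
            p.n_term = p.n * 0.5
            for fn in (m.conc_co, m.conc_co_bg, m.conc_post, m.conc_pre_steady, m.conc_rst):
                y = np.asarray(fn(t, p))
                assert np.all(y >= -1e-12)
            # past the delay all models are non-increasing (RST included: its
            # rise ends at n/v)
            tail = t[t >= p.n / p.v + 1e-9]
            for fn in (m.conc_co, m.conc_co_bg, m.conc_rst):
                y = np.asarray(fn(tail, p))
                assert np.all(np.diff(y) <= 1e-12)


class TestDerivedQuantities:
    @pytest.mark.parametrize("lam_per_s, expected_min", [
        (0.003465736, 3.33),
        (0.01155, 1.0),
        (0.00578, 2.0),
    ])
    def test_half_life_from_per_second_decay_constants(self, lam_per_s, expected_min):
        assert m.half_life(m.per_minute(lam_per_s)) == pytest.approx(expected_min, abs=0.01)

    def test_half_life_unit_case(self):
        assert m.half_life(math.log(2.0)) == pytest.approx(1.0)

    @pytest.mark.parametrize("r_synt, expected_pct", [
        (0.0, 0.0),
        (-0.5, 29.3),
        (-3.47, 91.0),
    ])
    def test_termination_percent(self, r_synt, expected_pct):
        assert m.termination_percent(r_synt) == pytest.approx(expected_pct, abs=0.5)

    def test_termination_percent_monotone_and_signed(self):
        rs = np.linspace(-4, 2, 50)
        tp = np.array([m.termination_percent(r) for r in rs])
        assert np.all(np.diff(tp) < 0)
        assert m.termination_percent(1.0) < 0  # never clamped in computation

    def test_round_trip_with_inverse(self):
        for x in (-3.0, -0.5, 0.0, 0.7):
            assert m.synthesis_ratio_from_tp(m.termination_percent(x)) == pytest.approx(x)

    def test_rst_min_distance_published_example(self):
        assert int(m.rst_min_distance(v=25, half_life_min=5, beta=0.5,
                                      threshold=0.075)) == 843

    def test_rst_min_distance_zero_threshold(self):
        assert m.rst_min_distance(25, 5, 0.5, 0.0) == 0.0

    def test_rst_min_distance_undetectable(self):
        # max increase is beta/(1-beta) = 1/9 < 0.2
        assert m.rst_min_distance(25, 5, beta=0.1, threshold=0.2) == math.inf

    def test_rst_min_distance_matches_numeric_maximization(self, rng):
        """Closed form agrees with brute-force maximization of the RST curve."""
        for _ in range(10):
            beta = float(rng.uniform(0.3, 0.9))
            hl = float(rng.uniform(1, 8))
            v = float(rng.uniform(10, 50))
            thr = float(rng.uniform(0.02, 0.9 * beta / (1 - beta)))
            d = m.rst_min_distance(v, hl, beta, thr)
            assert math.isfinite(d)
            lam = math.log(2.0) / hl
            for n_term, should_reach in ((d + 1.0, True), (max(d - 1.0, 0.1), False)):
                p = m.ModelParams(alpha=60 * lam, lam=lam, v=v * 60.0,
                                  n=n_term + 1000.0, n_term=n_term, beta=beta)
                t = np.linspace(0, p.n / p.v, 8000)
                rel = np.max(m.conc_rst(t, p)) / m.conc_rst(0.0, p) - 1.0
                assert (rel >= thr) == should_reach

    def test_fraction_full_length(self):
        assert m.fraction_full_length(0.0, 0.3, 1500.0) == 1.0
        lam = math.log(2.0) / 2.0
        frac = m.fraction_full_length(1000.0, lam, 25.0 * 60.0)
        assert frac == pytest.approx(0.79, abs=0.005)
        # doubling L squares the fraction
        assert m.fraction_full_length(2000.0, lam, 1500.0) == pytest.approx(frac ** 2)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            m.ModelParams(alpha=-1.0, lam=0.5, v=100.0)
        with pytest.raises(ValueError):
            m.ModelParams(alpha=1.0, lam=0.5, v=100.0, n=10.0, beta=1.5)
        with pytest.raises(ValueError):
            m.ModelParams(alpha=1.0, lam=0.5, v=100.0, n=10.0, n_term=20.0)
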