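"""Closed-form survival probabilities, interaction classes and regimes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deathclock.theory import (
    LN2,
    DimensionlessType,
    PopulationMix,
    asymptotic_survival,
    classify_interaction,
    classify_regime,
    cross_section_curves,
    ergodic_signal,
    heterotypic_difference_sign,
    heterotypic_xi,
    homotypic_difference_sign,
    homotypic_lambda,
    tolerance_emission,
    viability_curve_eta,
)

betas = st.floats(0.02, 0.98)
etas = st.floats(0.01, 3.0)


def dt(beta, eta):
    return DimensionlessType(beta, eta)


class TestHomotypicLambda:
    def test_on_viability_curve_equals_half(self):
        # eta = ln2 * beta * (1 - beta) makes the exponent -ln 2 exactly
        assert homotypic_lambda(dt(0.3, LN2 * 0.3 * 0.7)) == pytest.approx(0.5, rel=1e-15)

    def test_large_threshold_limit(self):
        assert homotypic_lambda(dt(0.5, 1e6)) == pytest.approx(1.0)

    def test_nonviable_point_value(self):
        # beta = 0.4, eta = 0.1: below the viability curve
        assert homotypic_lambda(dt(0.4, 0.1)) == pytest.approx(
            1.0 - math.exp(-0.1 / 0.24)
        )
        assert homotypic_lambda(dt(0.4, 0.1)) < 0.5

    def test_monte_carlo_oracle(self, rng):
        # clock process with constant signal 1 - beta: independent check
        beta, eta = 0.4, 0.1
        n = 200_000
        t_star = rng.exponential(beta, size=n)  # t_G = 1
        survived = (1.0 - beta) * t_star < eta
        lam = homotypic_lambda(dt(beta, eta))
        se = math.sqrt(lam * (1 - lam) / n)
        assert abs(survived.mean() - lam) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            DimensionlessType(0.0, 0.1)
        with pytest.raises(ValueError):
            DimensionlessType(0.5, 0.0)


class TestErgodicSignal:
    def test_single_type_recovers_homotypic(self):
        assert ergodic_signal(PopulationMix(5, 0), 0.3, 0.9) == pytest.approx(0.7)

    def test_equal_counts_arithmetic_mean(self):
        assert ergodic_signal(PopulationMix(7, 7), 0.2, 0.8) == pytest.approx(0.5)

    @given(na=st.integers(0, 50), nb=st.integers(0, 50), ba=betas, bb=betas)
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_pure_type_signals(self, na, nb, ba, bb):
        if na + nb == 0:
            return
        s = ergodic_signal(PopulationMix(na, nb), ba, bb)
        lo = min(1 - ba, 1 - bb)
        hi = max(1 - ba, 1 - bb)
        assert lo - 1e-12 <= s <= hi + 1e-12


class TestHeterotypicXi:
    def test_homotypic_signal_recovers_lambda(self):
        t = dt(0.3, 0.2)
        assert heterotypic_xi(t, 1 - 0.3) == pytest.approx(homotypic_lambda(t))

    def test_known_value(self):
        # eta = 0.2, beta = 0.8, signal 0.8 (a winner with beta_W = 0.2)
        assert heterotypic_xi(dt(0.8, 0.2), 0.8) == pytest.approx(
            1.0 - math.exp(-0.2 / 0.64), rel=1e-12
        )

    def test_vanishing_signal_certain_survival(self):
        assert heterotypic_xi(dt(0.5, 0.1), 0.0) == 1.0


class TestDifferenceSigns:
    def test_identical_types_coexist(self):
        t = dt(0.4, 0.3)
        assert heterotypic_difference_sign(t, t) == 0
        assert homotypic_difference_sign(t, t) == 0

    def test_tolerance_orders_winner(self):
        a, b = dt(0.2, 0.4), dt(0.4, 0.4)  # tol 2 vs 1
        assert heterotypic_difference_sign(a, b) == 1
        assert heterotypic_difference_sign(b, a) == -1

    def test_emission_orders_homotypic_difference(self):
        a, b = dt(0.2, 0.1), dt(0.6, 0.1)
        assert homotypic_difference_sign(a, b) == 1  # B emits less
        assert homotypic_difference_sign(b, a) == -1  # antisymmetry

    @given(ba=betas, ea=etas, bb=betas, eb=etas,
           na=st.integers(1, 99), nb=st.integers(1, 99))
    @settings(max_examples=100, derandomize=True)
    def test_heterotypic_sign_matches_xi_difference_at_any_mix(
        self, ba, ea, bb, eb, na, nb
    ):
        a, b = dt(ba, ea), dt(bb, eb)
        s = ergodic_signal(PopulationMix(na, nb), ba, bb)
        diff = heterotypic_xi(a, s) - heterotypic_xi(b, s)
        sign = heterotypic_difference_sign(a, b)
        if abs(diff) > 1e-9:
            assert sign == (1 if diff > 0 else -1)


class TestAsymptoticSurvival:
    def test_winner_keeps_homotypic_lambda(self):
        a, b = dt(0.2, 0.4), dt(0.8, 0.2)
        winner, w_surv, l_surv = asymptotic_survival(a, b)
        assert winner == "A"
        assert w_surv == pytest.approx(homotypic_lambda(a))
        assert l_surv == pytest.approx(1.0 - math.exp(-0.2 / (0.8 * 0.8)))

    def test_eliminated_loser_value(self):
        # loser (0.8, 0.2) against a winner with beta = 0.2: xi_inf < 1/2
        _, _, l_surv = asymptotic_survival(dt(0.2, 0.4), dt(0.8, 0.2))
        assert l_surv == pytest.approx(0.2684, abs=5e-4)
        assert l_surv < 0.5

    def test_coexistence_has_no_winner(self):
        with pytest.raises(ValueError):
            asymptotic_survival(dt(0.3, 0.3), dt(0.6, 0.6))

    @given(ba=betas, ea=etas, bb=betas, eb=etas)
    @settings(max_examples=200, derandomize=True)
    def test_loser_never_beats_winner(self, ba, ea, bb, eb):
        a, b = dt(ba, ea), dt(bb, eb)
        if heterotypic_difference_sign(a, b) == 0:
            return
        _, w_surv, l_surv = asymptotic_survival(a, b)
        assert l_surv <= w_surv + 1e-12


class TestInteractionClasses:
    def test_direct_competition(self):
        # A more tolerant, B emits more (beta_B > beta_A)
        cat, desc = classify_interaction(dt(0.2, 0.4), dt(0.4, 0.4))
        assert cat == "direct competition"
        assert "A direct winner" in desc

    def test_neutral_coexistence_centre(self):
        t = dt(0.4, 0.2)
        assert classify_interaction(t, t)[0] == "neutral coexistence"

    def test_indirect_winner(self):
        # A more tolerant but emits less (beta_A > beta_B)
        cat, desc = classify_interaction(dt(0.6, 0.9), dt(0.3, 0.2))
        assert cat == "indirect competition"
        assert "A indirect winner" in desc

    def test_label_swap_equivariance(self):
        a, b = dt(0.25, 0.5), dt(0.7, 0.3)
        cat_ab, _ = classify_interaction(a, b)
        cat_ba, _ = classify_interaction(b, a)
        assert cat_ab == cat_ba


class TestRegimes:
    def test_complete_cell_competition_example(self):
        label = classify_regime(dt(0.2, 0.4), dt(0.8, 0.2))
        assert label.name == "complete cell competition"
        assert label.winner == "A" and label.loser == "B"
        assert label.loser_eliminated

    def test_identical_types_neutral_coexistence(self):
        t = dt(0.3, 0.3)
        assert classify_regime(t, t).name == "neutral coexistence"

    def test_homotypically_nonviable_pair_excluded(self):
        # cross-section-III fixed type (0.4, 0.1) is homotypically nonviable
        label = classify_regime(dt(0.2, 0.5), dt(0.4, 0.1))
        assert not label.homotypic_viable
        assert label.name == "outside homotypic viability"

    def test_label_swap_preserves_regime_and_relabels_winner(self, rng):
        for _ in range(200):
            a = dt(rng.uniform(0.05, 0.95), rng.uniform(0.05, 1.5))
            b = dt(rng.uniform(0.05, 0.95), rng.uniform(0.05, 1.5))
            lab = classify_regime(a, b)
            swp = classify_regime(b, a)
            assert lab.name == swp.name
            if lab.winner is not None:
                assert {lab.winner, swp.winner} == {"A", "B"}

    def test_mismatched_cycle_times_rejected(self):
        a = DimensionlessType(0.3, 0.3, t_g=1.0)
        b = DimensionlessType(0.5, 0.3, t_g=2.0)
        with pytest.raises(ValueError):
            classify_regime(a, b)
        classify_regime(a, b, allow_mismatched_tg=True)


class TestToleranceEmission:
    def test_known_transformation(self):
        tol, em = tolerance_emission(dt(0.2, 0.2))
        assert tol == pytest.approx(1.0 / LN2)
        assert em == pytest.approx(0.8)
        # emission < tolerance matches homotypic viability
        assert em < tol
        assert homotypic_lambda(dt(0.2, 0.2)) > 0.5

    def test_viability_iff_emission_below_tolerance(self, rng):
        for _ in range(500):
            t = dt(rng.uniform(0.05, 0.95), rng.uniform(0.01, 1.5))
            tol, em = tolerance_emission(t)
            assert (em < tol) == (homotypic_lambda(t) > 0.5)

    def test_complete_competition_iff_inequality_chain(self, rng):
        # regime classifier and tolerance-emission chain must agree exactly
        for _ in range(2000):
            a = dt(rng.uniform(0.05, 0.95), rng.uniform(0.01, 1.5))
            b = dt(rng.uniform(0.05, 0.95), rng.uniform(0.01, 1.5))
            label = classify_regime(a, b)
            tol_a, em_a = tolerance_emission(a)
            tol_b, em_b = tolerance_emission(b)
            if label.winner == "A":
                tol_w, em_w, tol_l, em_l = tol_a, em_a, tol_b, em_b
            elif label.winner == "B":
                tol_w, em_w, tol_l, em_l = tol_b, em_b, tol_a, em_a
            else:
                continue
            chain = em_l < tol_l < em_w < tol_w
            assert chain == (label.name == "complete cell competition")

    def test_high_beta_limit_always_viable(self):
        tol, em = tolerance_emission(dt(0.999, 0.01))
        assert em < tol


class TestCrossSectionCurves:
    def test_section_one_has_no_b_loser_curve(self):
        curves = cross_section_curves(dt(0.2, 0.2))  # tolerance 1 > ln 2
        assert curves["b_loser_beta"] is None

    def test_section_two_b_loser_position(self):
        curves = cross_section_curves(dt(0.8, 0.2))
        assert curves["b_loser_beta"] == pytest.approx(1 - 0.2 / (LN2 * 0.8))
        assert curves["b_loser_beta"] == pytest.approx(0.6394, abs=1e-3)

    def test_curves_meet_at_neutral_coexistence_point(self):
        b = dt(0.8, 0.2)
        curves = cross_section_curves(b)
        # coexistence curve passes through (beta_B, eta_B)
        assert curves["coexistence"](b.beta) == pytest.approx(b.eta)

    def test_coexistence_curve_zeroes_the_difference(self):
        b = dt(0.5, 0.3)
        curves = cross_section_curves(b)
        for beta_a in (0.2, 0.5, 0.8):
            a = dt(beta_a, curves["coexistence"](beta_a))
            assert heterotypic_difference_sign(a, b) == 0

    def test_a_loser_curve_puts_loser_on_boundary(self):
        b = dt(0.3, 0.5)
        curves = cross_section_curves(b)
        for beta_a in (0.3, 0.6):
            eta_a = curves["a_loser"](beta_a)
            a = dt(beta_a, eta_a)
            # on this curve the asymptotic survival of A (as loser) is 1/2
            assert heterotypic_xi(a, 1 - b.beta) == pytest.approx(0.5)
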