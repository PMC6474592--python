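"""Best response, dominance, Nash set, ESS evidence, and the dilemma verdict."""

import numpy as np
import pytest

from abxgame import (
    ModelParams,
    Variant,
    best_response,
    check_ess,
    classify_dilemma,
    cooperative_optimum,
    crossing_point,
    find_symmetric_nash,
    is_dominant,
    pure_payoffs,
)


def pure_curves(params):
    return (
        lambda q: pure_payoffs(q, params).payoff_T,
        lambda q: pure_payoffs(q, params).payoff_U,
    )


class TestBestResponse:
    def test_treat_dominates_in_the_interior(self, baseline):
        assert best_response(0.5, baseline).as_set() == {1.0}

    def test_all_strategies_tie_at_saturation(self, baseline):
        br = best_response(1.0, baseline)
        assert br.is_interval and (br.lo, br.hi) == (0.0, 1.0)

    def test_untreat_wins_past_the_crossing(self, crossing):
        assert best_response(0.9, crossing).as_set() == {0.0}

    def test_agrees_with_grid_argmax(self, baseline, residual, crossing):
        """Analytic best response matches brute-force argmax over a p grid."""
        rng = np.random.default_rng(7)
        p_grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        for params in (baseline, residual, crossing):
            for q in rng.uniform(0, 1, size=100):
                # payoff is affine in p: evaluate the whole grid directly
                pp = pure_payoffs(q, params)
                vals = p_grid * pp.payoff_T + (1 - p_grid) * pp.payoff_U
                best_grid = p_grid[np.argmax(vals)]
                assert best_response(q, params).contains(best_grid, tol=1e-4)


class TestDominance:
    def test_treat_dominates_baseline(self, baseline):
        dominant, strict = is_dominant(1.0, baseline)
        assert dominant and strict

    def test_treat_strictly_dominates_residual(self, residual):
        dominant, strict = is_dominant(1.0, residual)
        assert dominant and strict

    def test_untreat_never_dominates(self, baseline):
        dominant, _ = is_dominant(0.0, baseline)
        assert not dominant

    def test_no_dominant_strategy_when_curves_cross(self, crossing):
        assert not is_dominant(1.0, crossing)[0]
        assert not is_dominant(0.0, crossing)[0]

    def test_empty_grid_rejected(self, baseline):
        with pytest.raises(ValueError):
            is_dominant(1.0, baseline, q_grid=[])


class TestSymmetricNash:
    def test_baseline_all_treat_reported_strict(self, baseline):
        assert find_symmetric_nash(baseline) == [(1.0, True)]

    def test_residual_all_treat_strict(self, residual):
        assert find_symmetric_nash(residual) == [(1.0, True)]

    def test_crossing_interior_equilibrium(self, crossing):
        eq = find_symmetric_nash(crossing)
        interior = [p for p, _ in eq if 0 < p < 1]
        # the payoff curves cross at q'(1 - c/phi) = 0.5 * (1 - 0.1) = 0.45
        assert len(interior) == 1
        assert interior[0] == pytest.approx(0.45, abs=1e-6)
        assert all(p != 1.0 for p, _ in eq)  # all-treat is no longer Nash


class TestESS:
    def test_all_treat_is_ess_baseline(self, baseline):
        report = check_ess(1.0, baseline, mutant_grid=[0.0, 0.25, 0.5, 0.75, 1.0])
        assert report.nash_ok
        assert not report.strict  # every strategy ties at q = 1
        assert report.second_condition_ok
        assert report.invasion_ok
        assert report.barrier_estimate == max(report.epsilon_grid)
        assert report.is_ess
        assert report.notes  # the boundary subtlety is surfaced, not hidden

    def test_all_treat_is_ess_for_phi_grid(self):
        for phi in np.linspace(0.05, 1.0, 20):
            report = check_ess(1.0, ModelParams(phi=phi))
            assert report.is_ess, f"ESS verdict failed at phi={phi}"

    def test_never_treat_is_not_nash(self, baseline):
        report = check_ess(0.0, baseline)
        assert not report.nash_ok
        assert not report.is_ess

    def test_residual_resident_is_strict(self, residual):
        report = check_ess(1.0, residual)
        assert report.strict and report.is_ess

    def test_degenerate_grid_warns_in_notes(self, baseline):
        report = check_ess(1.0, baseline, mutant_grid=[0.5], epsilon_grid=[1e-3])
        assert any("degenerate" in n for n in report.notes)

    def test_epsilon_out_of_range_rejected(self, baseline):
        with pytest.raises(ValueError):
            check_ess(1.0, baseline, epsilon_grid=[0.0, 0.5])


class TestCooperativeOptimum:
    def test_baseline_half_treated_for_any_phi(self):
        for phi in np.linspace(0.05, 1.0, 20):
            q_opt, value = cooperative_optimum(ModelParams(phi=phi))
            assert q_opt == pytest.approx(0.5, abs=1e-12)
            assert value == pytest.approx(phi * (0.25 - 1.0), abs=1e-12)

    def test_residual_below_half_slope_pushes_to_full_treatment(self, residual):
        q_opt, value = cooperative_optimum(residual)
        assert q_opt == 1.0
        assert value == pytest.approx(-residual.lam, abs=1e-12)

    def test_residual_interior_vertex(self):
        params = ModelParams(phi=0.5, variant=Variant.RESIDUAL_LAMBDA, lam=0.4)
        q_opt, _ = cooperative_optimum(params)
        assert q_opt == pytest.approx(0.5 / 0.8, abs=1e-12)  # phi / (2 lam)

    @pytest.mark.parametrize(
        "params",
        [
            ModelParams(phi=0.5),
            ModelParams(phi=0.5, variant=Variant.RESIDUAL_LAMBDA, lam=0.4),
            ModelParams(phi=0.5, variant=Variant.SCALED_K, k=0.7),
            ModelParams(phi=0.5, variant=Variant.CROSSING, q_prime=0.5,
                        side_effect_cost=0.05),
        ],
    )
    def test_matches_fine_grid_search(self, params):
        from abxgame import symmetric_payoff

        q_opt, value = cooperative_optimum(params)
        qs = np.arange(0.0, 1.0 + 1e-9, 1e-6)
        # coarse scan to bracket the optimum, then a 1e-6-step refinement
        vals = np.array([symmetric_payoff(q, params) for q in qs[:: 1000]])
        coarse_best = qs[::1000][np.argmax(vals)]
        fine = np.arange(max(0, coarse_best - 2e-3),
                         min(1, coarse_best + 2e-3) + 1e-9, 1e-6)
        fine_vals = np.array([symmetric_payoff(q, params) for q in fine])
        assert value >= fine_vals.max() - 1e-9
        assert abs(q_opt - fine[np.argmax(fine_vals)]) <= 2e-3 + 1e-6


class TestDilemma:
    def test_baseline_is_a_tragedy(self, baseline):
        report = classify_dilemma(baseline)
        assert report.dominant_strategy == 1.0
        assert report.equilibrium_q == 1.0
        assert report.equilibrium_payoff == pytest.approx(-0.5)
        assert report.cooperative_q == pytest.approx(0.5)
        assert report.cooperative_payoff == pytest.approx(-0.375)
        assert report.is_tragedy

    def test_residual_variant_is_not_a_tragedy(self, residual):
        report = classify_dilemma(residual)
        assert report.dominant_strategy == 1.0
        assert not report.is_tragedy
        # all-treat IS the cooperative optimum here
        assert report.equilibrium_payoff == pytest.approx(report.cooperative_payoff)

    def test_vanishing_phi_keeps_the_ordering(self):
        report = classify_dilemma(ModelParams(phi=1e-9))
        assert report.is_tragedy
        gap = report.cooperative_payoff - report.equilibrium_payoff
        assert gap == pytest.approx(1e-9 / 4, rel=1e-6)

    def test_cooperative_never_below_equilibrium(self, baseline, residual, crossing,
                                                 scaled):
        for params in (baseline, residual, crossing, scaled):
            report = classify_dilemma(params)
            assert report.cooperative_payoff >= report.equilibrium_payoff - 1e-12


class TestCrossingPoint:
    def test_baseline_curves_only_meet_at_the_boundary(self, baseline):
        assert crossing_point(*pure_curves(baseline), params=baseline) is None

    def test_meeting_without_side_effects(self):
        params = ModelParams(phi=0.5, variant=Variant.CROSSING, q_prime=0.5)
        q_cross = crossing_point(*pure_curves(params), params=params)
        assert q_cross == pytest.approx(0.5, abs=1e-6)

    def test_crossing_with_side_effects(self, crossing):
        q_cross = crossing_point(*pure_curves(crossing), params=crossing)
        # -phi q/q' - c = -phi  =>  q = q'(1 - c/phi)
        assert q_cross == pytest.approx(0.45, abs=1e-9)

    def test_identical_curves_are_degenerate(self, baseline):
        curve = lambda q: -0.5 * q
        with pytest.raises(ValueError):
            crossing_point(curve, curve, params=baseline)


class TestAffineGameImplications:
    """ESS inequality implications on randomized affine population games.

    For two-strategy games with payoffs affine in the population state, the
    three classical stability conditions are linked: a strict symmetric
    Nash strategy resists rare invaders; a tie broken in the resident's
    favor against the mutant population also resists invaders; and
    resistance to invaders at vanishing invader frequency recovers the
    Nash property.
    """

    EPS_LADDER = [10.0**-e for e in range(6, 0, -1)]
    MUTANTS = np.linspace(0.0, 1.0, 21)

    def invasion_holds(self, game, p_star, p, eps):
        q_eps = eps * p + (1 - eps) * p_star
        return game.payoff(p_star, q_eps) > game.payoff(p, q_eps)

    def test_strict_nash_implies_invasion_resistance(self, affine_games):
        checked = 0
        for game in affine_games(300):
            for p_star in game.symmetric_candidates():
                strict = all(
                    game.payoff(p_star, p_star) > game.payoff(p, p_star) + 1e-9
                    for p in self.MUTANTS
                    if abs(p - p_star) > 1e-9
                )
                if not strict:
                    continue
                checked += 1
                eps = self.EPS_LADDER[0]  # small invader frequency
                for p in self.MUTANTS:
                    if abs(p - p_star) > 1e-9:
                        assert self.invasion_holds(game, p_star, p, eps)
        assert checked >= 100

    def test_tie_plus_second_condition_implies_invasion_resistance(self, affine_games):
        checked = 0
        for game in affine_games(600):
            for p_star in game.symmetric_candidates():
                mutants = [p for p in self.MUTANTS if abs(p - p_star) > 1e-9]
                tied = [
                    p for p in mutants
                    if abs(game.payoff(p_star, p_star) - game.payoff(p, p_star)) < 1e-12
                ]
                if not tied:
                    continue
                second = all(
                    game.payoff(p_star, p) > game.payoff(p, p) + 1e-12 for p in tied
                )
                nash = all(
                    game.payoff(p_star, p_star) >= game.payoff(p, p_star) - 1e-12
                    for p in mutants
                )
                if not (nash and second):
                    continue
                checked += 1
                for eps in self.EPS_LADDER[:3]:
                    for p in mutants:
                        assert self.invasion_holds(game, p_star, p, eps)
        assert checked >= 20

    def test_invasion_resistance_implies_nash(self, affine_games):
        checked = 0
        for game in affine_games(300):
            for p_star in (0.0, 0.5, 1.0):
                mutants = [p for p in self.MUTANTS if abs(p - p_star) > 1e-9]
                resists_all = all(
                    self.invasion_holds(game, p_star, p, eps)
                    for eps in self.EPS_LADDER
                    for p in mutants
                )
                if not resists_all:
                    continue
                checked += 1
                for p in mutants:
                    assert (
                        game.payoff(p_star, p_star)
                        >= game.payoff(p, p_star) - 1e-9
                    )
        assert checked >= 50
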