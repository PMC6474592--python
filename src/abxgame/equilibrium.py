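"""Equilibrium and evolutionary-stability analysis of the prescribing game.

Because the mixed payoff is affine in a player's own probability p, the best
response at any population state is an extreme point (p = 0 or p = 1) unless
the two pure strategies tie, in which case every p in [0, 1] is a best
response.  This makes Nash and ESS verification essentially one-dimensional:
everything reduces to the sign of the payoff gap

    g(q) = pi_T(q) - pi_U(q),

which for the baseline model is phi * (1 - q) >= 0 — treating is (weakly)
dominant, the unique symmetric Nash strategy is p* = 1, and the all-treat
state is evolutionarily stable.  The cooperative optimum, by contrast, is
reached when only half the patients are treated, which is what makes the
game a tragedy of the commons.

ESS verification follows the classical three-condition scheme for a
candidate resident strategy p* against a mutant p present at frequency
epsilon:

1. p* is a (symmetric) Nash strategy: pi(p*, q*) >= pi(p, q*) at q* = p*;
2. where condition 1 is tight, p* does strictly better against the mutant
   than the mutant does against itself;
3. the invasion inequality: pi(p*, q_eps) > pi(p, q_eps) at the mixed state
   q_eps = eps*p + (1-eps)*p*, for all sufficiently small eps > 0.

Conditions 1+2 are checked analytically from the pure payoffs; condition 3
is checked numerically over grids of mutants and invasion fractions, and the
largest tested eps for which it held is reported as a lower bound on the
invasion barrier delta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .game_model import (
    ModelParams,
    Strategy,
    StrategyLike,
    Variant,
    _p,
    payoff_mixed,
    pure_payoffs,
    symmetric_payoff,
)

__all__ = [
    "BestResponse",
    "ESSCheck",
    "DilemmaReport",
    "best_response",
    "is_dominant",
    "find_symmetric_nash",
    "check_ess",
    "cooperative_optimum",
    "classify_dilemma",
    "crossing_point",
]

#: payoff-equality tolerance in normalized units
PAYOFF_TOL = 1e-12

DEFAULT_EPSILON_GRID = tuple(10.0 ** -e for e in range(6, 0, -1))  # 1e-6 .. 1e-1
DEFAULT_MUTANT_GRID = tuple(np.linspace(0.0, 1.0, 21))


@dataclass(frozen=True)
class BestResponse:
    """The set of payoff-maximizing strategies at a population state.

    Either a single extreme point or, when T and U tie, the whole interval
    [0, 1].
    """

    lo: float
    hi: float

    @property
    def is_interval(self) -> bool:
        return self.hi > self.lo

    def contains(self, p: StrategyLike, tol: float = 0.0) -> bool:
        p = _p(p)
        return self.lo - tol <= p <= self.hi + tol

    def as_set(self) -> set[float]:
        return {self.lo} if not self.is_interval else {self.lo, self.hi}


@dataclass
class ESSCheck:
    """Evidence gathered while testing a candidate strategy for ESS."""

    candidate: float
    nash_ok: bool
    strict: bool
    second_condition_ok: bool
    invasion_ok: bool
    epsilon_grid: tuple[float, ...]
    barrier_estimate: float
    mutant_grid: tuple[float, ...]
    is_ess: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate,
            "nash_ok": self.nash_ok,
            "strict": self.strict,
            "second_condition_ok": self.second_condition_ok,
            "invasion_ok": self.invasion_ok,
            "epsilon_grid": list(self.epsilon_grid),
            "barrier_estimate": self.barrier_estimate,
            "mutant_grid": list(self.mutant_grid),
            "is_ess": self.is_ess,
            "notes": list(self.notes),
        }


@dataclass
class DilemmaReport:
    """Comparison of the selfish equilibrium with the cooperative optimum."""

    dominant_strategy: float | None
    equilibrium_q: float
    equilibrium_payoff: float
    cooperative_q: float
    cooperative_payoff: float
    is_tragedy: bool

    def to_dict(self) -> dict:
        return {
            "dominant_strategy": self.dominant_strategy,
            "equilibrium_q": self.equilibrium_q,
            "equilibrium_payoff": self.equilibrium_payoff,
            "cooperative_q": self.cooperative_q,
            "cooperative_payoff": self.cooperative_payoff,
            "is_tragedy": self.is_tragedy,
        }


def payoff_gap(q: float, params: ModelParams) -> float:
    """g(q) = pi_T(q) - pi_U(q); its sign decides the best response."""
    return pure_payoffs(q, params).gap


def best_response(q: float, params: ModelParams) -> BestResponse:
    """Maximizers of the (affine) payoff in p at population state q."""
    g = payoff_gap(q, params)
    if g > PAYOFF_TOL:
        return BestResponse(1.0, 1.0)
    if g < -PAYOFF_TOL:
        return BestResponse(0.0, 0.0)
    return BestResponse(0.0, 1.0)


def is_dominant(
    strategy: StrategyLike,
    params: ModelParams,
    q_grid: Sequence[float] | int = 101,
) -> tuple[bool, bool]:
    """Whether a strategy is dominant, and whether strictly so.

    A strategy dominates when it is a best response at every population
    state; by affinity it suffices to compare against the pure strategies
    at each grid q.  The strictness flag reports strict dominance on the
    open interior 0 < q < 1 (at the boundary q = 1 the baseline payoffs
    tie, which is exactly the tragedy's endpoint).
    """
    p = _p(strategy)
    if isinstance(q_grid, int):
        qs = np.linspace(0.0, 1.0, q_grid)
    else:
        qs = np.asarray(list(q_grid), dtype=float)
    if qs.size == 0:
        raise ValueError("q_grid must be nonempty")
    dominant = True
    strict_interior = True
    for q in qs:
        own = payoff_mixed(p, q, params)
        best = max(payoff_mixed(0.0, q, params), payoff_mixed(1.0, q, params))
        if own < best - PAYOFF_TOL:
            dominant = False
            strict_interior = False
            break
        if 0.0 < q < 1.0:
            other = min(payoff_mixed(0.0, q, params), payoff_mixed(1.0, q, params))
            if own <= other + PAYOFF_TOL:
                strict_interior = False
    return dominant, dominant and strict_interior


def find_symmetric_nash(params: ModelParams) -> list[tuple[float, bool]]:
    """Symmetric Nash strategies p* (all doctors play p*, so q = p*).

    Returns ``(p_star, strict)`` pairs.  A symmetric state is an
    equilibrium when p* is a best response to itself: g(p*) >= 0 at p* = 1,
    g(p*) <= 0 at p* = 0, or g(p*) = 0 at an interior crossing.  The
    baseline boundary case g(1) = 0 (all strategies tie at q = 1) is
    reported as strict because p* = 1 is the limit of strict best responses
    g(q) > 0 for every q < 1 — the reading under which the all-treat state
    resists invasion.
    """
    equilibria: list[tuple[float, bool]] = []

    g0, g1 = payoff_gap(0.0, params), payoff_gap(1.0, params)
    if g0 <= PAYOFF_TOL:
        equilibria.append((0.0, g0 < -PAYOFF_TOL))
    # interior equilibria: sign changes (or touching zeros) of g on (0, 1)
    curves = (
        lambda q: pure_payoffs(q, params).payoff_T,
        lambda q: pure_payoffs(q, params).payoff_U,
    )
    q_cross = crossing_point(*curves, params=params)
    if q_cross is not None and 0.0 < q_cross < 1.0:
        equilibria.append((q_cross, False))
    if g1 >= -PAYOFF_TOL:
        if g1 > PAYOFF_TOL:
            equilibria.append((1.0, True))
        else:
            # tie at q = 1; strict in the limiting sense iff T strictly
            # better at every interior state
            interior_strict = all(
                payoff_gap(q, params) > PAYOFF_TOL
                for q in np.linspace(0.01, 0.99, 99)
            )
            equilibria.append((1.0, interior_strict))
    return equilibria


def check_ess(
    candidate: StrategyLike,
    params: ModelParams,
    mutant_grid: Sequence[float] = DEFAULT_MUTANT_GRID,
    epsilon_grid: Sequence[float] = DEFAULT_EPSILON_GRID,
) -> ESSCheck:
    """Test a candidate resident strategy for evolutionary stability.

    The Nash condition and the second (tie-breaking) condition are
    evaluated from the pure payoffs; the invasion inequality is evaluated
    at the post-invasion state q = eps*p + (1-eps)*p* for every mutant p in
    ``mutant_grid`` and every eps in ``epsilon_grid``.
    ``barrier_estimate`` is the largest tested eps at which every mutant
    was strictly repelled — a lower bound on the true invasion barrier.
    """
    p_star = _p(candidate)
    mutants = tuple(float(m) for m in mutant_grid)
    epsilons = tuple(sorted(float(e) for e in epsilon_grid))
    if not mutants or not epsilons:
        raise ValueError("mutant_grid and epsilon_grid must be nonempty")
    if any(not (0.0 < e < 1.0) for e in epsilons):
        raise ValueError("epsilon values must lie in (0, 1)")
    notes: list[str] = []
    if len(mutants) < 2:
        notes.append("degenerate mutant grid: single point tested")
    if len(epsilons) < 2:
        notes.append("degenerate epsilon grid: single point tested")

    others = [m for m in mutants if abs(m - p_star) > PAYOFF_TOL]

    # Condition 1: Nash against the resident state q* = p*.
    q_star = p_star
    own = payoff_mixed(p_star, q_star, params)
    gaps = [own - payoff_mixed(m, q_star, params) for m in others]
    nash_ok = all(gap >= -PAYOFF_TOL for gap in gaps)
    strict = nash_ok and all(gap > PAYOFF_TOL for gap in gaps)

    # Condition 2 where condition 1 is tight: the resident must beat the
    # mutant in an all-mutant population.
    second_ok = True
    if nash_ok and not strict:
        for m, gap in zip(others, gaps):
            if gap <= PAYOFF_TOL:
                diff = payoff_mixed(p_star, m, params) - payoff_mixed(m, m, params)
                if diff <= PAYOFF_TOL:
                    second_ok = False
                    break
    elif not nash_ok:
        second_ok = False

    # Condition 3: invasion inequality over the (mutant, epsilon) grid.
    def repelled_at(eps: float) -> bool:
        for m in others:
            q_eps = eps * m + (1.0 - eps) * p_star
            if (
                payoff_mixed(p_star, q_eps, params)
                - payoff_mixed(m, q_eps, params)
                <= PAYOFF_TOL
            ):
                return False
        return True

    barrier = 0.0
    for eps in epsilons:  # ascending; barrier is a contiguous lower bound
        if repelled_at(eps):
            barrier = eps
        else:
            break
    invasion_ok = barrier == epsilons[-1]

    if p_star == 1.0 and nash_ok and not strict:
        notes.append(
            "at q = 1 all strategies are payoff-equal; stability rests on the "
            "invasion route (condition 3) and the limit of strict best "
            "responses at q < 1"
        )

    is_ess = nash_ok and (strict or second_ok) and invasion_ok
    return ESSCheck(
        candidate=p_star,
        nash_ok=nash_ok,
        strict=strict,
        second_condition_ok=second_ok,
        invasion_ok=invasion_ok,
        epsilon_grid=epsilons,
        barrier_estimate=barrier,
        mutant_grid=mutants,
        is_ess=is_ess,
        notes=notes,
    )


def cooperative_optimum(params: ModelParams) -> tuple[float, float]:
    """Maximize the symmetric payoff over q in [0, 1].

    Closed forms: the baseline symmetric payoff phi*[q(1-q) - 1] is a
    downward parabola with vertex q = 1/2; the residual-efficacy variant's
    -lam*q^2 + phi*q - phi has vertex phi/(2*lam), clipped to the boundary
    q = 1 when lam < phi/2.  Other variants fall back to bounded scalar
    minimization refined against a coarse grid.
    """
    v = params.variant
    if v is Variant.BASELINE:
        q_opt = 0.5
    elif v is Variant.SCALED_K:
        q_opt = min(1.0 / (2.0 * params.k), 1.0)
    elif v is Variant.RESIDUAL_LAMBDA:
        q_opt = min(params.phi / (2.0 * params.lam), 1.0)
    else:
        # piecewise-quadratic symmetric payoff: numeric search seeded by a grid
        qs = np.linspace(0.0, 1.0, 1001)
        vals = np.array([symmetric_payoff(q, params) for q in qs])
        q0 = float(qs[np.argmax(vals)])
        lo, hi = max(0.0, q0 - 1e-3), min(1.0, q0 + 1e-3)
        res = minimize_scalar(
            lambda q: -symmetric_payoff(q, params),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        q_opt = float(res.x)
        for boundary in (0.0, 1.0):
            if symmetric_payoff(boundary, params) > symmetric_payoff(q_opt, params):
                q_opt = boundary
    return q_opt, symmetric_payoff(q_opt, params)


def classify_dilemma(params: ModelParams) -> DilemmaReport:
    """Decide whether the game is a tragedy of the commons.

    A tragedy requires (i) a dominant strategy driving the population to a
    symmetric equilibrium and (ii) an attainable symmetric state that pays
    every doctor strictly more than that equilibrium.  The baseline model
    qualifies (equilibrium payoff -phi versus cooperative payoff -0.75*phi);
    the residual-efficacy variant with lam < phi/2 does not, because the
    all-treat outcome is itself the cooperative optimum.
    """
    dominant: float | None = None
    for p in (1.0, 0.0):
        dom, _ = is_dominant(p, params)
        if dom:
            dominant = p
            break

    if dominant is not None:
        eq_q = dominant
        eq_payoff = symmetric_payoff(eq_q, params)
    else:
        # no dominant strategy: take the stable symmetric equilibrium
        # (interior crossing if present, else the boundary equilibrium)
        equilibria = find_symmetric_nash(params)
        interior = [pq for pq, _ in equilibria if 0.0 < pq < 1.0]
        eq_q = interior[0] if interior else equilibria[-1][0]
        eq_payoff = symmetric_payoff(eq_q, params)

    coop_q, coop_payoff = cooperative_optimum(params)
    is_tragedy = (
        dominant is not None and eq_payoff < coop_payoff - PAYOFF_TOL
    )
    return DilemmaReport(
        dominant_strategy=dominant,
        equilibrium_q=eq_q,
        equilibrium_payoff=eq_payoff,
        cooperative_q=coop_q,
        cooperative_payoff=coop_payoff,
        is_tragedy=is_tragedy,
    )


def crossing_point(
    payoff_T_curve: Callable[[float], float],
    payoff_U_curve: Callable[[float], float],
    params: ModelParams | None = None,
    tol: float = 1e-10,
    scan_points: int = 2001,
) -> float | None:
    """Smallest q in (0, 1) where the two payoff curves are equal.

    Uses a scan of the difference curve followed by Brent root-finding on a
    sign change, or a bisection for the boundary of a touching (tangent)
    zero where the curves meet without crossing.  Returns ``None`` when the
    curves never meet in the open interval; raises for curves that coincide
    everywhere (no isolated crossing exists).
    """
    diff = lambda q: payoff_T_curve(q) - payoff_U_curve(q)
    qs = np.linspace(0.0, 1.0, scan_points)
    ds = np.array([diff(q) for q in qs])
    if np.all(np.abs(ds) <= tol):
        raise ValueError("payoff curves are equal everywhere; crossing undefined")

    for i in range(len(qs) - 1):
        a, b = qs[i], qs[i + 1]
        da, db = ds[i], ds[i + 1]
        if da == 0.0 and 0.0 < a < 1.0:
            return float(a)
        if da * db < 0.0:
            root = float(brentq(diff, a, b, xtol=tol))
            if 0.0 < root < 1.0:
                return root
        if abs(db) <= tol and abs(da) > tol and b < 1.0:
            # curves meet and then stay equal: bisect for the first point
            # of contact (|diff| monotonically decreasing on [a, b])
            lo, hi = a, b
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if abs(diff(mid)) <= tol:
                    hi = mid
                else:
                    lo = mid
            return float(hi)
    return None
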