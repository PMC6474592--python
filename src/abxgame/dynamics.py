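"""Replicator dynamics of antibiotic prescribing.

The treated fraction q evolves under the two-strategy replicator equation:
the growth rate of T's frequency is its payoff advantage over the
population-average payoff,

    dq/dt = q * [pi_T(q) - pibar(q)] = q (1 - q) [pi_T(q) - pi_U(q)],

which for the baseline payoffs pi_T = -phi*q, pi_U = -phi reduces to

    dq/dt = phi * q * (1 - q)^2.

The velocity is nonnegative everywhere: prescribing can only drift upward.
Rest points sit at q = 0 (unstable — any trace of prescribing grows) and
q = 1 (a degenerate but attracting rest point: the linearization vanishes
because the advantage of T fades quadratically as resistance saturates, yet
every interior trajectory converges there).  The infection probability phi
only rescales time, so the shape of the flow — including the peak velocity
at q = 1/3 — is independent of phi.

Convergence to q = 1 is algebraic, not exponential: near the attractor
dq/dt ≈ phi (1-q)^2, so 1 - q(t) ~ 1/(phi t).  Reaching a distance 1e-6
from the attractor therefore needs phi*t of order 1e6; callers probing the
global attractor should budget t_max accordingly.

The separable baseline ODE has the closed-form first integral

    ln(q / (1 - q)) + 1 / (1 - q) - phi t = const,

used throughout the tests as an integrator-independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .game_model import ModelParams, Variant, pure_payoffs

__all__ = [
    "Trajectory",
    "RestPoint",
    "RestPointSet",
    "Stability",
    "replicator_rhs",
    "average_payoff",
    "replicator_from_payoffs",
    "variant_rhs",
    "integrate",
    "find_rest_points",
    "classify_rest_point",
    "vector_field",
    "peak_velocity",
    "first_integral",
]


class Stability(str, Enum):
    STABLE_ATTRACTOR = "stable_attractor"
    UNSTABLE = "unstable"
    DEGENERATE_ATTRACTING = "degenerate_attracting"
    DEGENERATE_REPELLING = "degenerate_repelling"


@dataclass(frozen=True)
class RestPoint:
    q_star: float
    derivative: float
    classification: Stability

    @property
    def attracting(self) -> bool:
        return self.classification in (
            Stability.STABLE_ATTRACTOR,
            Stability.DEGENERATE_ATTRACTING,
        )


@dataclass(frozen=True)
class RestPointSet:
    """Rest points of the flow; for phi = 0 the whole interval is at rest."""

    points: tuple[RestPoint, ...]
    entire_interval: bool = False


@dataclass
class Trajectory:
    """A solution q(t) of the replicator equation."""

    times: np.ndarray
    states: np.ndarray
    phi: float
    converged: bool
    terminal_q: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.shape != self.states.shape:
            raise ValueError("times and states must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "q": self.states})


def _check_domain(q: float, phi: float) -> None:
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if not (0.0 <= phi <= 1.0):
        raise ValueError(f"phi must lie in [0, 1], got {phi}")


def replicator_rhs(q: float, phi: float) -> float:
    """Baseline velocity dq/dt = phi * q * (1 - q)^2; nonnegative on the square."""
    _check_domain(q, phi)
    return phi * q * (1.0 - q) ** 2


def average_payoff(q: float, params: ModelParams) -> float:
    """Population-mean payoff pibar(q) = phi * (-q^2 + q - 1) (baseline)."""
    if params.variant is not Variant.BASELINE:
        raise ValueError("closed-form average payoff is defined for the baseline model")
    return params.phi * (-(q**2) + q - 1.0)


def replicator_from_payoffs(
    q: float,
    payoff_T_curve: Callable[[float], float],
    payoff_U_curve: Callable[[float], float],
) -> float:
    """Velocity from the defining form of the replicator equation.

    dq/dt = q * [pi_T(q) - (q pi_T(q) + (1-q) pi_U(q))]
          = q (1 - q) [pi_T(q) - pi_U(q)].

    With the baseline pure payoffs this reduces exactly to
    :func:`replicator_rhs`.
    """
    return q * (1.0 - q) * (payoff_T_curve(q) - payoff_U_curve(q))


def variant_rhs(q: float, params: ModelParams) -> float:
    """Replicator velocity under any model variant's payoff curves."""
    pp = pure_payoffs(q, params)
    return q * (1.0 - q) * pp.gap


def integrate(
    q0: float,
    phi: float,
    t_max: float = 1e4,
    params: ModelParams | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-9,
    qdot_tol: float = 1e-10,
    rest_tol: float = 1e-6,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the replicator equation from q0 with an adaptive RK solver.

    Stops early once the state is within ``rest_tol`` of a rest point and
    the velocity has fallen below ``qdot_tol`` (``converged`` is then
    True); otherwise runs to ``t_max``.  The state is clamped to [0, 1]
    inside the right-hand side, so roundoff excursions outside the
    simplex cannot feed back into the flow.
    """
    _check_domain(q0, phi)
    if t_max <= 0.0:
        raise ValueError(f"t_max must be positive, got {t_max}")

    if params is not None and params.variant is not Variant.BASELINE:
        base_rhs = lambda q: variant_rhs(q, params)
        rest_qs = _rest_locations(phi, params)
    else:
        base_rhs = lambda q: phi * q * (1.0 - q) ** 2
        rest_qs = (0.0, 1.0)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        q = min(max(y[0], 0.0), 1.0)
        return [base_rhs(q)]

    def settled(t: float, y: np.ndarray) -> float:
        q = min(max(y[0], 0.0), 1.0)
        dist = min(abs(q - r) for r in rest_qs)
        # positive until both the velocity and the distance criteria hold
        return max(abs(base_rhs(q)) / qdot_tol, dist / rest_tol) - 1.0

    settled.terminal = True
    settled.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        [q0],
        method="RK45",
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        events=settled,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states = np.clip(sol.y[0], 0.0, 1.0)
    if not np.all(np.isfinite(states)):
        raise RuntimeError("integration produced non-finite states")
    times = sol.t
    converged = bool(sol.status == 1)  # terminated by the settling event
    return Trajectory(
        times=times,
        states=states,
        phi=phi,
        converged=converged,
        terminal_q=float(states[-1]),
    )


def first_integral(q: float, t: float, phi: float) -> float:
    """Conserved quantity of the baseline flow on the open interval.

    ln(q/(1-q)) + 1/(1-q) - phi*t is constant along any baseline
    trajectory with 0 < q < 1; an analytic oracle for the integrator.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("first integral is defined for 0 < q < 1")
    return math.log(q / (1.0 - q)) + 1.0 / (1.0 - q) - phi * t


def _rest_locations(phi: float, params: ModelParams | None) -> tuple[float, ...]:
    """Rest-point q values: boundary points plus interior payoff crossings."""
    locations = [0.0, 1.0]
    if params is not None and params.variant is not Variant.BASELINE:
        from .equilibrium import crossing_point

        q_cross = crossing_point(
            lambda q: pure_payoffs(q, params).payoff_T,
            lambda q: pure_payoffs(q, params).payoff_U,
            params=params,
        )
        if q_cross is not None:
            locations.append(q_cross)
    return tuple(sorted(locations))


def find_rest_points(phi: float, params: ModelParams | None = None) -> RestPointSet:
    """All rest points of dq/dt on [0, 1].

    For phi > 0 the baseline flow rests only at q = 0 and q = 1; variants
    with crossing payoff curves add an interior rest point where the pure
    payoffs tie.  For phi = 0 the velocity vanishes identically and the
    whole interval is flagged as at rest.
    """
    if phi < 0.0:
        raise ValueError(f"phi must be nonnegative, got {phi}")
    if phi == 0.0:
        return RestPointSet(points=(), entire_interval=True)
    points = tuple(
        classify_rest_point(q, phi, params) for q in _rest_locations(phi, params)
    )
    return RestPointSet(points=points)


def classify_rest_point(
    q_star: float,
    phi: float,
    params: ModelParams | None = None,
    probe: float = 1e-6,
) -> RestPoint:
    """Linear stability of a rest point, with one-sided probes when degenerate.

    The baseline derivative d(qdot)/dq = phi (1-q)(1-3q) is positive at
    q = 0 (unstable) and exactly zero at q = 1, where one-sided sign tests
    take over: the velocity is positive just left of 1, so the flow enters
    from the occupied side and the point is degenerate but attracting.
    """
    _check_domain(q_star, phi)
    if params is not None and params.variant is not Variant.BASELINE:
        rhs = lambda q: variant_rhs(q, params)
        h = 1e-7
        lo, hi = max(0.0, q_star - h), min(1.0, q_star + h)
        deriv = (rhs(hi) - rhs(lo)) / (hi - lo)
    else:
        rhs = lambda q: phi * q * (1.0 - q) ** 2
        deriv = phi * (1.0 - q_star) * (1.0 - 3.0 * q_star)
    if abs(rhs(q_star)) > 1e-9:
        raise ValueError(f"q = {q_star} is not a rest point (qdot = {rhs(q_star)})")

    deriv_tol = 1e-8
    if deriv > deriv_tol:
        cls = Stability.UNSTABLE
    elif deriv < -deriv_tol:
        cls = Stability.STABLE_ATTRACTOR
    else:
        attracting = True
        if q_star - probe >= 0.0:
            attracting &= rhs(q_star - probe) > 0.0
        if q_star + probe <= 1.0:
            attracting &= rhs(q_star + probe) < 0.0
        cls = (
            Stability.DEGENERATE_ATTRACTING
            if attracting
            else Stability.DEGENERATE_REPELLING
        )
    return RestPoint(q_star=q_star, derivative=deriv, classification=cls)


def vector_field(
    phi_grid: Sequence[float] | int = 101,
    q_grid: Sequence[float] | int = 101,
    params: ModelParams | None = None,
) -> pd.DataFrame:
    """Tabulate qdot over the (phi, q) product grid.

    Returns a DataFrame with columns ``phi``, ``q``, ``qdot`` — the data
    behind the three-dimensional velocity surface of the baseline game.
    """
    phis = np.linspace(0.0, 1.0, phi_grid) if isinstance(phi_grid, int) else np.asarray(phi_grid, float)
    qs = np.linspace(0.0, 1.0, q_grid) if isinstance(q_grid, int) else np.asarray(q_grid, float)
    if np.any((phis < 0) | (phis > 1)) or np.any((qs < 0) | (qs > 1)):
        raise ValueError("grids must lie within [0, 1]")
    P, Q = np.meshgrid(phis, qs, indexing="ij")
    if params is not None and params.variant is not Variant.BASELINE:
        # re-parameterize phi along the grid; phi = 0 rests everywhere
        qdot = np.array(
            [
                [
                    0.0
                    if p == 0.0
                    else variant_rhs(q, params.with_(phi=p))
                    for q in qs
                ]
                for p in phis
            ]
        )
    else:
        qdot = P * Q * (1.0 - Q) ** 2
    return pd.DataFrame(
        {"phi": P.ravel(), "q": Q.ravel(), "qdot": qdot.ravel()}
    )


def peak_velocity(phi: float) -> tuple[float, float]:
    """Location and size of the fastest prescribing drift.

    d/dq [phi q (1-q)^2] = phi (1-q)(1-3q) has its interior root at
    q = 1/3 regardless of phi; the peak velocity there is 4*phi/27.
    """
    if not (0.0 < phi <= 1.0):
        raise ValueError(f"phi must lie in (0, 1] for a defined argmax, got {phi}")
    q_at_max = 1.0 / 3.0
    return q_at_max, replicator_rhs(q_at_max, phi)
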