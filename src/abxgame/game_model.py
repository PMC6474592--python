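"""Payoff model of the antibiotic prescribing population game.

A population of ``n`` prescribing doctors repeatedly faces symptomatic
patients who have a bacterial infection with probability ``phi``.  Each
doctor chooses the pure strategy T (treat with antibiotics) with some
probability ``p`` — a mixed strategy on [0, 1].  The population state is the
treated fraction ``q``: the proportion of symptomatic patients currently on
antibiotics.  Treating is individually attractive (it removes the morbidity
risk of an untreated infection) but raises ``q`` and with it community-level
resistance, which erodes the benefit of treatment for everyone.

Payoffs are doctors' utilities, equal to minus the expected morbidity risk
of their own patients.  In normalized units (all payoffs divided by the
untreated morbidity risk ``r_U``) the mixed-strategy payoff is

    pi(p, q) = phi * [p * (1 - r_q) - 1],

where ``r_q`` is the relative morbidity risk of treated versus untreated
patients.  The model variants differ only in the shape of ``r_q``:

* ``BASELINE``        — r_q = q (resistance grows linearly, full loss at q=1)
* ``SCALED_K``        — r_q = k*q, 0 < k < 1 (efficacy never fully lost)
* ``RESIDUAL_LAMBDA`` — treated payoff is -lam*q with 0 < lam < phi, i.e.
                        r_q = (lam/phi)*q (treatment stays strictly better
                        than no treatment even at q = 1)
* ``CROSSING``        — efficacy is exhausted already at q' < 1:
                        r_q = min(q/q', 1); an optional side-effect cost
                        pushes the treated payoff below the untreated one
                        for large q, so the payoff curves cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "Variant",
    "ModelParams",
    "Strategy",
    "StrategyProfile",
    "PopulationState",
    "PayoffPair",
    "relative_risk",
    "payoff_raw",
    "payoff_mixed",
    "pure_payoffs",
    "symmetric_payoff",
    "profile_payoff",
    "load_params",
]


class Variant(str, Enum):
    """Functional form of the relative morbidity risk r_q."""

    BASELINE = "baseline"
    SCALED_K = "scaled_k"
    RESIDUAL_LAMBDA = "residual_lambda"
    CROSSING = "crossing"


@dataclass(frozen=True)
class ModelParams:
    """All constants of the game.

    Parameters
    ----------
    phi : float
        Probability in (0, 1] that a symptomatic patient has a bacterial
        infection.
    n : int
        Number of prescribing doctors (>= 2).  Only enters through the
        mapping from a strategy profile to the treated fraction ``q``.
    r_U : float
        Baseline (untreated) morbidity risk, > 0.  Payoffs are reported in
        units of ``r_U``; the raw scale is available via
        :func:`payoff_raw`.
    variant : Variant
        Which relative-risk curve to use.
    k : float, optional
        Resistance scaling constant in (0, 1); required for ``SCALED_K``.
    lam : float, optional
        Residual-efficacy slope in (0, phi); required for
        ``RESIDUAL_LAMBDA``.
    q_prime : float, optional
        Efficacy-exhaustion point in (0, 1); required for ``CROSSING``.
    side_effect_cost : float
        Nonnegative extra disutility borne by treated patients; used by the
        ``CROSSING`` variant to make the payoff curves genuinely cross
        rather than merely meet.
    """

    phi: float = 0.5
    n: int = 2
    r_U: float = 1.0
    variant: Variant = Variant.BASELINE
    k: float | None = None
    lam: float | None = None
    q_prime: float | None = None
    side_effect_cost: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.phi <= 1.0):
            raise ValueError(f"phi must lie in (0, 1], got {self.phi}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not self.r_U > 0.0:
            raise ValueError(f"r_U must be positive, got {self.r_U}")
        if self.side_effect_cost < 0.0:
            raise ValueError(
                f"side_effect_cost must be nonnegative, got {self.side_effect_cost}"
            )
        v = Variant(self.variant)
        object.__setattr__(self, "variant", v)
        if v is Variant.SCALED_K:
            if self.k is None or not (0.0 < self.k < 1.0):
                raise ValueError(f"SCALED_K requires 0 < k < 1, got k={self.k}")
        if v is Variant.RESIDUAL_LAMBDA:
            if self.lam is None or not (0.0 < self.lam < self.phi):
                raise ValueError(
                    f"RESIDUAL_LAMBDA requires 0 < lam < phi={self.phi}, got lam={self.lam}"
                )
        if v is Variant.CROSSING:
            if self.q_prime is None or not (0.0 < self.q_prime < 1.0):
                raise ValueError(
                    f"CROSSING requires 0 < q_prime < 1, got q_prime={self.q_prime}"
                )

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class Strategy:
    """A mixed strategy: the probability p of prescribing antibiotics.

    p = 1 is the pure strategy T (always treat); p = 0 is U (never treat).
    """

    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"strategy probability must lie in [0, 1], got {self.p}")


StrategyLike = Union[Strategy, float, int]


def _p(strategy: StrategyLike) -> float:
    """Coerce a Strategy or bare probability to a validated float."""
    p = strategy.p if isinstance(strategy, Strategy) else float(strategy)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"strategy probability must lie in [0, 1], got {p}")
    return p


@dataclass(frozen=True)
class StrategyProfile:
    """An ordered assignment of one mixed strategy per doctor."""

    strategies: tuple[float, ...]

    def __init__(self, strategies: Iterable[StrategyLike]):
        object.__setattr__(
            self, "strategies", tuple(_p(s) for s in strategies)
        )
        if len(self.strategies) < 2:
            raise ValueError("a profile needs at least two players")

    def __len__(self) -> int:
        return len(self.strategies)

    def excluding(self, i: int) -> tuple[float, ...]:
        """The incomplete profile p_{-i}: everyone's strategy except player i's."""
        self._check_index(i)
        return self.strategies[:i] + self.strategies[i + 1 :]

    def treated_fraction(self) -> float:
        """Map the profile to the population state q as the mean strategy.

        In the mean-field reading each doctor's patients are treated with
        probability p_j, so the expected treated fraction over the whole
        population is the average of all n strategies (player i included).
        """
        return sum(self.strategies) / len(self.strategies)

    def _check_index(self, i: int) -> None:
        if not (0 <= i < len(self.strategies)):
            raise IndexError(
                f"player index {i} out of range for {len(self.strategies)} players"
            )


@dataclass(frozen=True)
class PopulationState:
    """The treated fraction q at (dimensionless) time t."""

    q: float
    t: float = 0.0

    def __post_init__(self) -> None:
        _check_q(self.q)
        if self.t < 0.0:
            raise ValueError(f"time must be nonnegative, got {self.t}")


@dataclass(frozen=True)
class PayoffPair:
    """Normalized utilities of the two pure strategies at a given q."""

    payoff_T: float
    payoff_U: float

    @property
    def gap(self) -> float:
        """Advantage of always treating: payoff_T - payoff_U."""
        return self.payoff_T - self.payoff_U


def _check_q(q: float) -> None:
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"treated fraction q must lie in [0, 1], got {q}")


def relative_risk(q: float, params: ModelParams) -> float:
    """Relative morbidity risk r_q = r_T(q) / r_U of treated patients.

    Zero at q = 0 (no resistance, antibiotics fully effective) and, in the
    baseline model, unity at q = 1 (resistance has made treatment useless).
    """
    _check_q(q)
    v = params.variant
    if v is Variant.BASELINE:
        return q
    if v is Variant.SCALED_K:
        return params.k * q
    if v is Variant.RESIDUAL_LAMBDA:
        # chosen so that the pure-T payoff is exactly -lam*q
        return (params.lam / params.phi) * q
    if v is Variant.CROSSING:
        return min(q / params.q_prime, 1.0)
    raise AssertionError(f"unhandled variant {v}")  # pragma: no cover


def payoff_raw(p: StrategyLike, q: float, params: ModelParams) -> float:
    """Expected utility on the raw (unnormalized) morbidity scale.

    pi(p, q) = p * (-r_T(q) * phi) + (1 - p) * (-r_U * phi), with
    r_T(q) = r_q * r_U.  Dividing by r_U recovers :func:`payoff_mixed`.
    """
    p = _p(p)
    r_T = relative_risk(q, params) * params.r_U
    base = p * (-r_T * params.phi) + (1.0 - p) * (-params.r_U * params.phi)
    if params.variant is Variant.CROSSING:
        base -= p * params.side_effect_cost * params.r_U
    return base


def payoff_mixed(p: StrategyLike, q: float, params: ModelParams) -> float:
    """Normalized expected utility pi(p, q) = phi * [p (1 - r_q) - 1].

    Affine in p at fixed q; for the baseline model it lies in [-phi, 0].
    The ``CROSSING`` variant additionally charges the side-effect cost on
    the treated fraction p.
    """
    p = _p(p)
    base = params.phi * (p * (1.0 - relative_risk(q, params)) - 1.0)
    if params.variant is Variant.CROSSING:
        base -= p * params.side_effect_cost
    return base


def pure_payoffs(q: float, params: ModelParams) -> PayoffPair:
    """Payoffs of the pure strategies T and U at treated fraction q.

    Baseline: pi(1, q) = -phi*q and pi(0, q) = -phi.  The U payoff is
    independent of q in every variant: untreated patients are unaffected by
    community resistance.
    """
    return PayoffPair(
        payoff_T=payoff_mixed(1.0, q, params),
        payoff_U=payoff_mixed(0.0, q, params),
    )


def symmetric_payoff(q: float, params: ModelParams) -> float:
    """Payoff to every doctor when all play p = q.

    Baseline: phi * [q(1-q) - 1], the quantity whose maximum at q = 1/2 is
    the cooperative optimum.  Equals q*pi_T(q) + (1-q)*pi_U(q).
    """
    pp = pure_payoffs(q, params)
    return q * pp.payoff_T + (1.0 - q) * pp.payoff_U


def profile_payoff(i: int, profile: StrategyProfile, params: ModelParams) -> float:
    """Payoff to player i under a full strategy profile.

    The treated fraction is the mean of all n strategies; player i then
    earns payoff_mixed(p_i, q).
    """
    profile._check_index(i)
    if len(profile) != params.n:
        raise ValueError(
            f"profile has {len(profile)} players but params.n = {params.n}"
        )
    q = profile.treated_fraction()
    return payoff_mixed(profile.strategies[i], q, params)


# ---------------------------------------------------------------------------
# plain-text configuration

_CONFIG_KEYS = {
    "phi": ("phi", float),
    "n": ("n", int),
    "r_u": ("r_U", float),
    "variant": ("variant", Variant),
    "k": ("k", float),
    "lambda": ("lam", float),
    "lam": ("lam", float),
    "q_prime": ("q_prime", float),
    "side_effect_cost": ("side_effect_cost", float),
}


def load_params(path: str | Path | None = None, **overrides) -> ModelParams:
    """Build :class:`ModelParams` from a ``key = value`` config file.

    Lines starting with ``#`` (or blank) are ignored.  Recognized keys:
    phi, n, r_U, variant, k, lambda, q_prime, side_effect_cost.  Keyword
    overrides (e.g. from CLI flags) take precedence over the file.
    """
    fields: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip().lower()
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            name, cast = _CONFIG_KEYS[key]
            fields[name] = cast(value.strip())
    for key, value in overrides.items():
        if value is not None:
            fields[key] = value
    return ModelParams(**fields)
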