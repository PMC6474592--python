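import numpy as np
import pytest

from abxgame import ModelParams, Variant


@pytest.fixture
def baseline():
    return ModelParams(phi=0.5)


@pytest.fixture
def residual():
    # residual efficacy below half the infection probability: lam < phi/2
    return ModelParams(phi=0.5, variant=Variant.RESIDUAL_LAMBDA, lam=0.2)


@pytest.fixture
def crossing():
    # efficacy exhausted at q' = 0.5, with a small side-effect cost so the
    # treated and untreated payoff curves genuinely cross
    return ModelParams(
        phi=0.5, variant=Variant.CROSSING, q_prime=0.5, side_effect_cost=0.05
    )


@pytest.fixture
def scaled():
    return ModelParams(phi=0.5, variant=Variant.SCALED_K, k=0.4)


class AffineGame:
    """A two-strategy population game with payoffs affine in the state q.

    pi(p, q) = p * pi_T(q) + (1 - p) * pi_U(q) with pi_T = a + b q and
    pi_U = c + d q.  Used as an implementation-independent oracle for the
    ESS inequality implications.
    """

    def __init__(self, a, b, c, d):
        self.a, self.b, self.c, self.d = a, b, c, d

    def gap(self, q):
        return (self.a - self.c) + (self.b - self.d) * q

    def payoff(self, p, q):
        return p * (self.a + self.b * q) + (1 - p) * (self.c + self.d * q)

    def symmetric_candidates(self):
        """Symmetric Nash strategies: extreme points and interior root of the gap."""
        out = []
        if self.gap(1.0) >= 0:
            out.append(1.0)
        if self.gap(0.0) <= 0:
            out.append(0.0)
        slope = self.b - self.d
        if slope != 0:
            root = -(self.a - self.c) / slope
            if 0 < root < 1:
                out.append(root)
        return out


@pytest.fixture
def affine_games():
    rng = np.random.default_rng(20190419)

    def make(n):
        return [AffineGame(*rng.uniform(-1, 1, size=4)) for _ in range(n)]

    return make
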