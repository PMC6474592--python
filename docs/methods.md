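# Methods

## Model

A symmetric population game G = ⟨N, S, π⟩ with N = {1, …, n} prescribing
doctors (n ≥ 2), two pure strategies T (treat with antibiotics) and U
(don't), and mixed strategies p ∈ [0, 1] (the probability of choosing T).
The population state is the treated fraction q ∈ [0, 1]. Doctors are
assumed to minimize the expected morbidity of their own patients only; all
doctors share the same information and respond identically. A symptomatic
patient has a bacterial infection with probability ϕ ∈ (0, 1].

Raw expected utility: π(p, q) = p(−r_T(q)·ϕ) + (1−p)(−r_U·ϕ), with r_U > 0
the untreated morbidity risk and r_T(q) = r_q·r_U the treated risk.
Utilities are invariant to positive scaling, so all reported payoffs are
normalized by r_U:

    π(p, q) = ϕ [ p (1 − r_q) − 1 ].

`payoff_raw` exposes the unnormalized form; dividing it by r_U reproduces
`payoff_mixed` exactly (a tested identity).

### Relative-risk variants

| variant | r_q | rationale |
|---|---|---|
| `baseline` | q | resistance grows linearly with prescribing and saturates at q = 1 |
| `scaled_k` | kq, 0 < k < 1 | efficacy degraded but never fully lost |
| `residual_lambda` | (λ/ϕ)q, 0 < λ < ϕ | chosen so the pure-T payoff is exactly −λq; treatment stays strictly better than no treatment even at q = 1 |
| `crossing` | min(q/q′, 1), 0 < q′ < 1 | efficacy exhausted already at q′; an optional side-effect cost c ≥ 0 is charged on the treated fraction, π(p,q) = ϕ[p(1−r_q)−1] − pc |

The crossing form is a design choice: the scenario only requires that the
T and U payoff curves meet at some q′ < 1 and cross when side effects
exist. The piecewise-linear form above meets U's −ϕ at q = q′ when c = 0
and crosses it at q = q′(1 − c/ϕ) when 0 < c < ϕ. The crossing solver
takes the payoff curves as callables, so any monotone alternative can be
substituted without touching the equilibrium code.

### Profile → state mapping

How the treated fraction relates to a finite strategy profile is a
modelling choice; we use the mean-field mapping q = (1/n)·Σⱼ pⱼ over all
players including i. This makes the ESS mixture state
q = ϵp + (1−ϵ)p\* literal and is exact in the large-population reading the
analysis operates in. The alternative (excluding player i's own patients)
differs by O(1/n) and changes no qualitative result.

## Equilibrium analysis

Payoffs are affine in a player's own p, so the best response at any q is
determined by the sign of the payoff gap g(q) = π_T(q) − π_U(q): {1} if
positive, {0} if negative, the whole interval [0, 1] on a tie (ties are
reported as the interval, never broken to an arbitrary point). Payoff
equality uses an absolute tolerance of 1e-12 in normalized units; every
analytic shortcut is cross-validated in the tests against brute-force grid
search over p.

Symmetric Nash strategies are fixed points of the best response on the
diagonal q = p: boundary candidates p = 0 (needs g(0) ≤ 0) and p = 1
(needs g(1) ≥ 0) plus interior zeros of g located by the crossing solver.
**Boundary subtlety:** in the baseline game g(1) = 0 — at full saturation
every strategy earns −ϕ — so the all-treat equilibrium is not strict in
the literal one-shot sense. It is, however, the limit of strict best
responses (g(q) > 0 for every q < 1), and it strictly repels every rare
mutant (condition 3 below). We report `strict = True` for this limiting
case and surface the subtlety in the ESS report's notes rather than
resolving it silently; a genuinely strict interior tie would be reported
non-strict.

ESS verification follows the three-condition scheme for a resident p\*
against mutants p at invasion fraction ϵ:

1. Nash: π(p\*, q\*) ≥ π(p, q\*) at q\* = p\* (analytic, from pure payoffs);
2. where 1 is tight: π(p\*, p) > π(p, p) — the resident beats the mutant
   in an all-mutant population;
3. invasion: π(p\*, q_ϵ) > π(p, q_ϵ) at q_ϵ = ϵp + (1−ϵ)p\*, checked
   numerically over a mutant grid (default: 21 evenly spaced strategies)
   and a logarithmic ϵ ladder (default 1e-6 … 1e-1).

`barrier_estimate` is the largest *tested* ϵ up to which every mutant was
strictly repelled — a lower bound on the invasion barrier δ, never a claim
about its true value. Degenerate (single-point) grids are accepted but
flagged in the report's notes.

The dilemma classifier computes the dominant strategy (if any), the
symmetric equilibrium state and payoff, and the cooperative optimum
(argmax of the symmetric payoff q·π_T(q) + (1−q)·π_U(q)); `is_tragedy`
requires both a dominant strategy and a strictly better attainable
symmetric payoff. Cooperative optima use closed forms where the symmetric
payoff is quadratic (baseline vertex 1/2; residual vertex ϕ/(2λ) clipped
at 1; scaled vertex 1/(2k) clipped at 1) and bounded scalar minimization
seeded by a 1001-point grid for the piecewise-quadratic crossing variant,
with boundary comparison.

## Replicator dynamics

The two-strategy replicator equation, q̇ = q[π_T(q) − π̄(q)] with
π̄ = qπ_T + (1−q)π_U, factorizes as q(1−q)[π_T(q) − π_U(q)] and with the
baseline payoffs reduces to

    q̇ = ϕ q (1 − q)².

The reduction is enforced as a test at 1e-12 on a dense grid, guarding the
algebra of the derivation (an intermediate expansion is easy to get a sign
wrong in; the implementation works from the definition plus the average
payoff ϕ(−q² + q − 1), which reproduces the closed form exactly).

Properties of the baseline flow, all under test: q̇ ≥ 0 with equality only
at q ∈ {0, 1} (or ϕ = 0, where the whole interval is at rest); ϕ rescales
time without changing the flow's shape; the peak velocity sits at q = 1/3
with value 4ϕ/27; trajectories are non-decreasing; and the separable ODE
has the first integral ln(q/(1−q)) + 1/(1−q) − ϕt, used as an
integrator-independent oracle (conserved to better than 1e-6 along test
trajectories integrated at rtol 1e-11).

**Integration.** Adaptive Runge–Kutta (RK45) at rtol = atol = 1e-9. The
state is clamped to [0, 1] inside the right-hand side so roundoff
excursions cannot feed back. Integration stops early via a terminal event
once |q̇| < 1e-10 *and* the state is within 1e-6 of a rest point
(`converged = True`); default horizon t_max = 1e4 dimensionless time
units. Convergence to q = 1 is algebraic, 1 − q(t) ~ 1/(ϕt), so reaching
a distance 1e-6 of the attractor needs ϕt ≈ 1e6; the global-attraction
test uses t_max = 1e8 (the adaptive solver crosses such horizons in ~100
steps because step sizes grow with t near the degenerate attractor). At
the default horizon a ϕ = 0.5 trajectory therefore terminates near
q ≈ 0.9998 with `converged = False` — the honest finite-time reading of
"converges to 1".

**Rest points and stability.** For ϕ > 0 the baseline flow rests exactly
at q = 0 and q = 1; variants add an interior rest point wherever the pure
payoff curves cross (located by the crossing solver, consistent with the
q(1−q)g(q) factorization). Classification is by the sign of dq̇/dq —
baseline closed form ϕ(1−q)(1−3q), central finite difference (h = 1e-7)
for variants — with threshold 1e-8. Where the derivative vanishes (q = 1:
the advantage of T fades quadratically) one-sided sign probes at ±1e-6
(clipped to the domain) decide: flow entering from every occupied side ⇒
`degenerate_attracting`. This matches the phase-line picture: q = 0
unstable (derivative ϕ > 0), q = 1 attracting though not hyperbolic, and
for the crossing variant with c > 0 a hyperbolically stable interior
point at q′(1 − c/ϕ) with both boundaries unstable.

## Numerical and design choices

- Payoff-equality tolerance 1e-12 (normalized units); crossing solver
  bisection/Brent tolerance 1e-10 over a 2001-point scan.
- Vector-field grids default to 101 × 101 over [0, 1]²; payoff tables to
  101 rows (an even grid; any spacing ≥ 2 points is accepted).
- CSV outputs: comma-separated, header row, '.' decimal, 12 significant
  digits; data on stdout/files, progress on stderr; file outputs paired
  with a JSON manifest (parameters, command, seed, version). Identical
  parameters reproduce identical data bytes; the manifest carries a
  timestamp and lives in a separate file so it never perturbs the data.
- Randomized checks (grid cross-validations, the affine-game implication
  suite) run from fixed recorded seeds.
- Problem sizes in the test suite (grid resolutions, trajectory horizons,
  300–600 random games) are chosen so the full analysis reruns at desk
  scale in seconds while still crossing every qualitative boundary of the
  model.

## What the synthetic inputs do and don't show

The package needs no external data: inputs are parameters, and the
"fixtures" are parameter sweeps and payoff tables generated by the model
itself. Randomized affine two-strategy games exercise the ESS inequality
implications well beyond the prescribing game's specific payoffs. None of
this validates the model's *empirical* premises — that prescribing-induced
resistance is linear in q, that doctors weigh only their own patients'
morbidity, or that morbidity risks are homogeneous across doctors.
Passing tests certify the game-theoretic and dynamical conclusions given
the payoff structure, not the payoff structure itself.

## Known limitations

- Deterministic, infinite-population dynamics only: no Moran or
  Wright–Fisher imitation noise, no finite-population ESS corrections.
- Two pure strategies; no asymmetric or multi-population extensions.
- The crossing variant's functional form is one representative of the
  scenario it models; conclusions specific to its shape (e.g. the exact
  interior equilibrium location) are form-dependent, though its
  qualitative structure (meet, then cross under side effects) is not.
- Payoffs are static in time: resistance feeds back only through q, with
  no reservoir or decay dynamics of its own.
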