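# abxgame

Evolutionary game-theoretic analysis of antibiotic prescribing.

## The problem

Doctors deciding whether to prescribe antibiotics to a symptomatic patient
face a social dilemma. Treating protects the patient in front of them —
especially since the patient has a bacterial infection only with probability
ϕ — but every prescription raises the population's treated fraction *q* and
with it community-level antibiotic resistance, eroding the value of
treatment for everyone. `abxgame` models this as a symmetric *n*-player
population game and asks: what will individually rational prescribers do,
is that behavior evolutionarily stable, how does prescribing drift over
time, and is the outcome a tragedy of the commons?

The package is for modellers in antimicrobial-resistance policy,
behavioral epidemiology, and evolutionary game theory who want the full
analysis pipeline — payoffs, equilibria, ESS verification, replicator
dynamics — as tested, scriptable components rather than one-off algebra.

## The model

Each doctor prescribes with probability *p* ∈ [0, 1] (pure strategies:
T = treat, U = don't treat). In units of the untreated morbidity risk, a
doctor's expected payoff at treated fraction *q* is

    π(p, q) = ϕ [ p (1 − r_q) − 1 ],

where r_q is the relative morbidity risk of treated patients. The baseline
model takes r_q = q (resistance grows linearly and saturates), giving pure
payoffs π_T = −ϕq and π_U = −ϕ. Variants cover efficacy that is never
fully lost (r_q = kq), a residual-efficacy payoff π_T = −λq with
0 < λ < ϕ, and early exhaustion at q′ < 1 with a side-effect cost that
makes the payoff curves cross.

Key baseline results, all computed (not asserted) by the package:

- T is a dominant strategy: π_T − π_U = ϕ(1 − q) > 0 for q < 1.
- The unique symmetric Nash strategy is p\* = 1, and it is evolutionarily
  stable: rare mutants are strictly repelled at every tested invasion
  fraction.
- The replicator dynamic is dq/dt = ϕ q (1 − q)², nonnegative everywhere:
  prescribing only drifts upward, fastest at q = 1/3, from every interior
  state to the global attractor q = 1 (q = 0 is unstable).
- Everyone would do better at the cooperative optimum q = 1/2 (payoff
  −0.75ϕ versus −ϕ at equilibrium) — a tragedy of the commons. With
  residual efficacy λ < ϕ/2 the all-treat outcome is itself collectively
  optimal and the tragedy verdict flips.

## Worked example

```sh
abxgame report --phi 0.5
```

prints (abridged) for the baseline game at ϕ = 0.5:

```json
{
  "dilemma": {
    "dominant_strategy": 1.0,
    "equilibrium_q": 1.0,
    "equilibrium_payoff": -0.5,
    "cooperative_q": 0.5,
    "cooperative_payoff": -0.375,
    "is_tragedy": true
  },
  "symmetric_nash": [{"p_star": 1.0, "strict": true}],
  "peak_velocity": {"q_at_max": 0.3333333333333333, "qdot_max": 0.07407407407407408}
}
```

Read: always-treat is dominant, so the population settles at q = 1 where
every doctor earns −0.5; had they all treated half their patients they
would each earn −0.375, hence `is_tragedy`. The rest points come back as
q = 0 unstable (d q̇/dq = ϕ = 0.5 > 0) and q = 1 attracting (the
linearization vanishes there, so the verdict rests on one-sided sign
probes). Prescribing drifts upward fastest at q = 1/3 at rate
4ϕ/27 ≈ 0.074.

Integrating the dynamics from 10% initial prescribing:

```sh
abxgame simulate --phi 0.5 --q0 0.1 --t-max 10000 --out traj.csv
# terminal q = 0.999800 (converged=False)
```

Convergence to q = 1 is algebraic — 1 − q(t) ≈ 1/(ϕt) — so after
t = 10⁴ the state sits ~2·10⁻⁴ below the attractor; longer horizons push
it arbitrarily close (the library stops once |q̇| < 10⁻¹⁰ within 10⁻⁶ of a
rest point).

Same analysis for the residual-efficacy variant, by config file or flags:

```sh
abxgame report --phi 0.5 --variant residual_lambda --lambda 0.2
# dilemma.is_tragedy: false
```

Other subcommands: `payoff-table` (the two payoff lines over a q grid),
`equilibrium`, `ess-check` (full invasion evidence with mutant and ϵ
grids), `vector-field` (the q̇ surface over (ϕ, q)), `rest-points`. All
accept `--config key=value-file`, `--out`, `--format {csv,json}`; file
outputs carry a JSON manifest echoing the effective parameters.

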