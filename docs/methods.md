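# Methods

## Glucose–insulin dynamics

Each virtual patient follows a Bergman-minimal-class ODE system (per-minute
rates):

```
dG/dt  = EGP − (S_G + X)·G + k_abs·Q2 / V_G
dX/dt  = k_a·(β_I·I − X)
dI/dt  = −k_e·I + u/60
dQ1/dt = −k_abs·Q1
dQ2/dt = k_abs·(Q1 − Q2)
dGi/dt = (G − Gi)/τ_cgm
```

`G` is plasma glucose (mg/dL), `X` the remote insulin effect (1/min), `I` a
scaled plasma-insulin compartment (U), `Q1/Q2` gut carbohydrate (mg), `Gi`
interstitial glucose, `u` the infusion rate (U/h). `V_G = 1.7 dL/kg × body
weight`. A meal of `c` grams deposits `1000·c·f` mg into `Q1`
(bioavailability `f`). Integration is classical RK4 with 1-minute substeps
(halving the substep moves 24-h glucose by far less than the 0.5 mg/dL
consistency bound we test); plasma glucose is floored at 20 mg/dL and gut
compartments at zero. The simulator sits behind the plain
`step_dynamics(state, params, rate, dt)` function plus the `GlucoseEnv`
reset/step API, so an external engine with richer physiology can be swapped
in by reimplementing those two surfaces.

**Equilibrium pinning.** At sampling time we draw the cohort parameters and
an *insulin drive ratio* `r` (insulin-mediated over insulin-independent
clearance at basal), then set endogenous production
`EGP = G_b·S_G·(1+r)` and steady-state insulin sensitivity
`S_I = G_b·r / ((1+r)·I_b)` so that the programmed basal rate holds glucose
exactly at the patient's basal target `G_b`. Two consequences we rely on:
basal equilibrium is exact (not fitted), and under the pump's action cap of
`a_max = 2×basal` the lowest *reachable* steady state is
`G_b·(1+r)/(1+2r)`, which stays above ~72 mg/dL for every admissible
parameter draw. Because `G` relaxes monotonically toward its moving
equilibrium, no dosing policy can drive plasma glucose below that floor —
hypoglycemia elimination is a structural property of capped basal-rate
control in this model, consistent with clinical temp-basal limits.

## Cohort parameter ranges (uniform draws)

| parameter | child | adolescent | adult | units |
|---|---|---|---|---|
| body weight | 25–45 | 45–70 | 60–95 | kg |
| basal rate | 0.30–0.60 | 0.60–1.00 | 0.80–1.40 | U/h |
| S_G (glucose effectiveness) | 0.0035–0.0060 | 0.0030–0.0050 | 0.0035–0.0060 | 1/min |
| k_a (insulin action) | 0.015–0.030 | 0.012–0.025 | 0.015–0.030 | 1/min |
| k_e (insulin clearance) | 0.10–0.18 | 0.10–0.18 | 0.10–0.18 | 1/min |
| k_abs (carb absorption) | 0.025–0.040 | 0.020–0.035 | 0.015–0.030 | 1/min |
| bioavailability | 0.75–0.90 | 0.75–0.90 | 0.75–0.90 | — |
| basal glucose target | 120–140 | 115–135 | 115–135 | mg/dL |
| insulin drive ratio r | 1.00–1.30 | 1.10–1.40 | 1.00–1.35 | — |

Children are lighter and absorb carbohydrate faster (higher glycemic
variability per gram); adolescents get the weakest insulin action rate,
reflecting their typically poorest control. Meal scenarios place
`meals_per_day` meals in the 06:00–21:00 window (one per equal slot,
uniform within the middle 80%), with per-cohort carb ranges of 20–40 g
(child), 35–60 g (adolescent), 40–70 g (adult).

**CGM.** First-order lag τ = 10 min, additive Gaussian noise SD 5 mg/dL,
clamp [39, 400] mg/dL, one reading per 5-minute step.

## Reward

`r = α·dev + β·ins + γ·stab + η·risk`, all components ≤ 0, with the forms
given in the README. Defaults: α=1, β=0.1, γ=0.5, η=1, hypoglycemia
multiplier 3, normalizers 100 mg/dL (deviation), 50 mg/dL (per-step
stability), 100 risk units. These defaults satisfy every qualitative
property we assert: hypoglycemia dominance (a deviation below range is
penalized at least as hard as the equal deviation above), linearity in the
weights, and zero total only at the ideal transition. The risk score is the
standard log-transformed blood-glucose risk function (zero at 112.5 mg/dL,
asymmetric toward hypoglycemia, clamped to [20, 600] mg/dL); the per-step
deviation target defaults to 112.5 mg/dL for consistency with it.
Exploration is *not* a reward term: it is SAC's entropy temperature,
auto-tuned toward a target entropy of −1 (one action dimension).

## Agent

Actor and twin critics are GRU stacks over per-step observation features
(k=12-step CGM/insulin/carb histories, normalized, plus sin/cos clock time;
39 − 1 = 38 features) followed by fully connected heads; defaults are 2 GRU
layers × 128 units, batch 256, sequence length 72 with 12-step burn-in,
discount 0.99, learning rates 3e-4, Polyak 0.005, dropout 0.1 on the
post-GRU layers (training only). The action is a tanh-squashed Gaussian
scaled to `[0, a_max]`; the policy mode of an untrained actor sits at
`a_max/2`, i.e. exactly the programmed basal, so learning starts from the
baseline controller. Replay stores episode segments and samples fixed
windows that never cross segment boundaries. Because no deep-learning
framework is part of this package's dependency footprint, the networks and
exact reverse-mode gradients are implemented in `glucofed.nn` (float64,
finite-difference-checked in the test suite); training is therefore
bit-reproducible from the seeds.

The soft Bellman target uses the minimum of the two Polyak-averaged target
critics minus `α·log π` at a fresh policy sample; the actor ascends
`min_i Q_i − α·log π` with critic weights frozen (gradient flows through
the action only).

## Federation

Synchronous rounds over in-process clients. Updates carry the full flat
parameter vector (actor, critics, targets, temperature — so a broadcast
makes clients bitwise identical); the transmitted "gradient" of the round
is recoverable as the delta from the round-start global, whose norm is
logged. Aggregation weights: uniform, sample-proportional, or
risk-adjusted `w_i ∝ n_i(1 + λ·r̃_i)` with λ=0.5 and `r̃` min-max-normalized
within the round; all-equal risks degrade gracefully to
sample-proportional. After each round the broadcast global policy is scored
deterministically on every client's held-out validation scenario; the mean
blood-glucose risk of that rollout is the per-round validation curve used
for early stopping and reported by the acceptance script.

## Problem sizes

The full protocol (10 patients per cohort, 5-day episodes ⇒ 1440-step
episodes, 300 training epochs across 30 rounds) is exposed as
`full_config()` and takes hours on one CPU. The package's own experiments
and tests use the reduced `smoke_config()` protocol: 1 GRU layer × 32
units, batch 32, sequence 8 (burn-in 2), discount 0.98, learning rate 1e-3,
3 rounds × 4 local epochs × 576 steps (6912 environment steps per client)
with 250 updates per epoch, 1-day episodes, and held-out patients *and*
held-out meal-scenario seeds for evaluation. The shorter discount horizon
(~4 h) matches the insulin action time constant and lets the critic resolve
the dose–response delay within the reduced update budget.

## What the generator does and does not emulate

The synthetic cohorts reproduce the qualitative physiology that matters for
the control problem: cohort-ordered body weight and basal needs, delayed
insulin action, meal-driven excursions, noisy lagged CGM, and inter-patient
heterogeneity. They do not include exercise, stress, circadian insulin
sensitivity, sensor dropout or compression artifacts, intra-patient
day-to-day variability, or the nonlinear sub-models of regulatory-grade
simulators. Passing results therefore demonstrate that the learning and
federation machinery works and that the safety structure (pump cap +
asymmetric reward) behaves as designed — not that the learned policies
would transfer to real patients or to a regulatory-grade simulator.

## Numerical and design notes

- All randomness flows from named seed streams derived by SHA-256 from the
  master seed; every derived seed is below 2^31.
- Glucose-range binning: 70 and 180 mg/dL are inclusive in the target
  range, 50 belongs to 50–70, 250 to 180–250. Reports can be computed on
  plasma glucose (default, the simulator's ground truth) or on CGM values.
- Degenerate inputs: zero-weight rewards, empty cohorts, zero-meal
  scenarios, and empty evaluation traces (mean risk 0 by convention) are
  all defined and tested; out-of-range actions are clipped and flagged
  rather than rejected.
- Whether the action is basal modulation or bolus dosing was an open
  interface choice; this package models capped basal-rate control, the
  variant under which the structural hypoglycemia floor holds.
- The log-std head is bounded to [−5, 2] via tanh rather than clipping so
  its gradient never vanishes abruptly; elementwise `min` of the twin
  critics routes the subgradient to the attaining critic.

## Known limitations

- The behavioral acceptance run is stochastic-optimization at small scale;
  its point values (e.g. overall TIR near 76–80% on held-out adults) vary
  by a few percentage points across seeds even though the qualitative
  outcomes (zero hypoglycemia, TIR above baseline, falling validation risk)
  are stable.
- Clients run in-process; there is no network transport, stragglers are
  modeled only as excluded failures, and no defense against adversarial
  updates (differential privacy, robust aggregation) is implemented.
- The privacy contract is structural (updates contain only parameters and
  scalars, enforced and canary-tested), not cryptographic.
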