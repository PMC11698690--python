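# Methods

## The task

`stakestep` models behaviour in a stakes-modulated two-step decision task.
Each of 200 trials begins with a cue announcing low or high stakes (50/50;
high-stake second-stage rewards are multiplied by 5), then starts in one of
two first-stage states (fair coin). Both states offer the same choice
between two spaceships; each spaceship deterministically reaches a red or a
purple planet, where a payoff between 0 and 9 points is delivered. Planet
payoffs evolve as independent Gaussian random walks (step SD 2.0 points)
with reflecting boundaries at [0, 9], rounded to whole points for display.
Because the two start states are equivalent in outcome, a planner that
exploits the transition structure transfers learning across states; a
model-free learner does not. Deterministic transitions follow the task
variant this package targets; a stochastic transition matrix is accepted in
the configuration for generality.

Unstated presentation details are configuration choices: payoff walks start
uniformly inside the bounds, the two spaceships keep fixed screen positions
per state (a flag randomizes left/right per trial), and agents learn from
the base (unmultiplied) payoff by default — the stake manipulation then
enters the model only through the mixing weight, matching the model
equations, with a flag to learn from the delivered payoff for sensitivity
analysis.

## Dual-system model

The model-free system is SARSA(λ) over four states (two first-stage states
with actions a_A, a_B; two planets with a single forced action):

- Traces reset at each trial start. Stage 1 increments ε(s₁,a₁) by 1,
  applies δ₁ = Q_MF(s₂,a_C) − Q_MF(s₁,a₁) to all pairs via
  Q ← Q + α·δ·ε, then decays all traces by λ. Stage 2 increments
  ε(s₂,a_C), applies δ₂ = r − Q_MF(s₂,a_C) the same way (reaching the
  first-stage pair through its λ-decayed trace), and decays again.
- The model-based system computes Q_MB(s₁,a) = Σ_p P(p|s₁,a)·Q_MF(p);
  with deterministic transitions this is a lookup. At the second stage the
  systems coincide.
- Net values mix by a stake-conditional weight: Q_net = ω·Q_MB +
  (1−ω)·Q_MF with ω = ω_low or ω_high per the trial's cue.
- Choice follows a softmax, p(a) ∝ exp[β(Q_net(a) + π·rep(a) + ρ·resp(a))].
  rep(a) = 1 when a leads to the planet chosen on the previous trial
  (choice identity is defined by outcome, the task's defining equivalence);
  resp(a) = 1 when a's physical key matches the previous key press. β is
  read as multiplying the whole bracket; the second-stage forced action
  contributes log 1 = 0 to the likelihood.

Q values start at 0 and payoffs stay on the raw 0–9 point scale (both
configurable). The "exhaustive" variant gives every parameter separate
low-/high-stake values (12 parameters) evaluated per trial over one shared
value table; with tied values it reproduces the 7-parameter likelihood
bit-for-bit.

### MAP fitting

Per-subject maximum a posteriori estimation under empirical priors:
Beta(2,2) on α, λ, ω_low, ω_high; Gamma(3, 0.2) on β; N(0,1) on π and ρ.
The Gamma prior is read as shape–scale (mode (3−1)·0.2 = 0.4); a
shape–rate switch is exposed because the parameterization is a convention.
The response stickiness ρ defaults to the N(0,1) reading; a Beta(2,2)
alternative is selectable. Optimization is bounded L-BFGS-B on the native
scale with box edges nudged a machine margin inside the prior support
(densities vanish at the Beta boundaries, so the log posterior returns a
−∞ sentinel there rather than raising). Restart initial points are drawn
from the priors; 100 restarts by default, ties broken by first occurrence.
The likelihood trial loop is compiled with numba; the test suite checks it
to 1e−9 against a literal hand-stepped pure-Python reference.

## Risk-sensitive utility model

Each first-stage pair carries an expected return R(s,a) and a risk
(return-variance) estimate h(s,a), combined as

    U(s,a) = R(s,a) − μ · sign(R(s,a)) · √h(s,a),   sign(0) = 0,

so positive μ penalises variance on gains (risk aversion) and negative μ
rewards it. Choice is softmax in β_u·U over the two first-stage actions.
The update dynamics are: stage-1 TD error δ₁ = Γ·R(planet) − R(s₁,a₁) and
stage-2 error δ₂ = r − R(planet), each clipped to ±δ_limit before moving
its R by η·δ; the first-stage risk tracks the squared total first-stage
error δ_eff = clip(δ₁) + Γ·clip(δ₂) through h ← h + η(δ_eff² − h), which
keeps h ≥ 0 for η ∈ [0, 1]. Risk is estimated for first-stage pairs only
(the forced second-stage action carries no risk trade-off). The precise
update rule is one defensible member of the mean–variance TD family; it is
isolated in `utility_update` so an alternative rule can be swapped in.

Parameters are bounded μ ∈ [−2, 2], β_u ∈ [0, 10], η ∈ [0, 1], Γ ∈ [0, 1],
δ_limit ∈ [0.1, 10] (all configurable) and fitted separately for low- and
high-stake trials: learning always runs over every trial in order, and the
stake filter selects which trials' choice probabilities enter the fitness.
(An alternative mode that freezes learning to the filtered subset exists
but is off by default.) The fitter is a real-valued genetic algorithm —
fitness = choice log-likelihood, tournament selection (size 3), uniform
crossover (rate 0.5), Gaussian mutation (SD 10% of each bound width,
clipped to bounds), elitism (5) — with study-scale defaults of population
1000 over 100 generations. Elitism makes the running best fitness
non-decreasing, and the best individual ever evaluated is returned.

## Synthetic cohorts

Subject-level parameters are drawn from truncated Gaussians per group;
subject seeds derive from the group seed by a fixed splitting rule so
every subject is individually reproducible. The shipped presets
(`data/presets.json`) emulate the qualitative study pattern: non-users
ω_low ≈ 0.35 / ω_high ≈ 0.55 (Δω ≈ 0.2), users ω_low ≈ ω_high ≈ 0.45
(Δω ≈ 0); utility presets give both groups μ_high > μ_low with a smaller
rise in the user group. The effect sizes are package choices calibrated so
the full simulate → fit → ANOVA pipeline detects the Stakes × Group
interaction with roughly 80% power at n = 40 per group; β is centred at
1.0 (0–9 point scale), where simulated choices are informative without
collapsing into perseveration.

What the generator does *not* emulate: reaction times, attention lapses,
within-session parameter drift, missing trials, or any coupling between
questionnaire severity and task behaviour beyond an optional synthetic
covariate. Passing recovery and power tests therefore demonstrate internal
consistency of the pipeline under the model's own assumptions, not that
the model captures all structure in real data.

## Group-level statistics

The analysis battery takes a per-subject table (ω_low/ω_high from the
dual-system fit, μ_low/μ_high from the stake-separated utility fits) and
runs: a 2×2 mixed ANOVA with stakes within-subject and group
between-subject (pingouin backend; with n subjects each effect is tested
on (1, n−2) degrees of freedom), Mann-Whitney U tests between groups (per
stake and on the high−low difference) and Wilcoxon signed-rank tests
within groups — two-sided, normal approximation with continuity and tie
correction, with all-tied inputs flagged as degenerate rather than
crashing — Spearman correlations with Bonferroni adjustment over the
requested family (family size always reported), and the Fisher z test
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)). Although both factors
could be described as grouping factors, stakes is within-subject by
construction, and the mixed reading reproduces the (1, n−2) df pattern of
the follow-up design.

Split-half cross-validation refits the model on two disjoint halves of
each subject's trials — first/second 100 (first half keeps the extra trial
for odd counts) or odd/even-numbered — and correlates half-estimates
across subjects. The shipped reliability check refits each 100-trial half
with a single tied mixing weight: halves hold only ~50 trials per stake,
too few to resolve two separate weights, and the overall ω is the quantity
whose stability the cross-validation is meant to establish.

## Problem sizes and numerical choices

The validation suite uses: 10-trial random sessions × 100 parameter draws
for the likelihood oracles (tolerance 1e−9); a 101³ grid at 0.01
resolution against a 30-trial, 3-free-parameter MAP fit (tolerance 1e−3
log-posterior); 50 prior-drawn agents × 200 trials with 10 restarts for
hybrid recovery; 20 agents at μ = ±0.8 with a reduced GA (population 100,
30 generations) for utility recovery; 20 end-to-end runs per arm at
n = 40/group with 4 restarts per fit for the interaction power and null
calibration; and 40 subjects with 4-restart tied-ω half-fits for
split-half reliability. Restart counts beyond 10 were checked to leave
estimates unchanged on these problem sizes. All randomness flows from
explicit integer seeds; no stage reads global random state.

## Known limitations

- The utility model's R/h update rule is one member of a family; fitted μ
  values are comparable within this package, not across rule variants.
- With fixed screen positions and the default transition map, rep(a) and
  resp(a) coincide, so π and ρ are identified only jointly in that
  configuration; enable key shuffling to separate them.
- MAP estimates of bounded parameters shrink toward the prior modes for
  weakly identified subjects (low β); rank-based group statistics are used
  downstream partly for this reason.
- The GA is a global heuristic: with small populations it can return
  boundary values for weakly constrained parameters (Γ, δ_limit); μ and
  β_u are the reliably recovered quantities.
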