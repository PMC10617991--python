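# Methods

## Model

Two stinging strategies are modeled as discounted infinite-horizon decision
problems, with all costs and rewards expressed in units of the starvation
penalty (so the penalty is exactly −1).

**Predation.** The state is starvation s ∈ [0, 1], discretized as
s_i = i/(n_states − 1). Per event the agent chooses an intensity a ∈ [0, 1]
(fraction of nematocysts fired), pays c(a, s) = c₀(s)·a, and succeeds with
probability p(a) = p_M·a·(2 − a), which is concave with p(0) = 0 and
p(1) = p_M. Success moves one grid index toward satiation, failure one index
toward starvation; the landing state's reward r(s′) accrues. The
most-starved index is absorbing with V = 0 and landing reward −1. The model
assumes: one prey encounter per event, a single scalar physiological state,
strictly local (one-step) state transitions, and a stationary environment.

**Defense.** Two states: safety L and absorbing danger D (V(D) = 0).
Success keeps the agent in L (+1), failure moves it to D (−1). Stinging
never changes starvation; starvation acts only parametrically through
c₀(s). The closed form for p(a) = p_M·a·(2 − a) and linear cost is
a*(s) = K(s) − √(K(s)² − C(s)) with K = ε/c₀(s), ε = (2 − γ)/γ,
C = −1/(p_M γ) + 2ε/c₀(s), interior iff c₀(s) < 2p_M(2 − γ). The interior
root satisfies a² − 2Ka + (2K − 1/(γp_M)) = 0, which the solver checks to
10⁻¹⁰. Outside the existence region the optimum is a ∈ {0, 1}, resolved by
comparing the pinned-action values V(a) = (2p(a) − 1 − c₀a)/(1 − γp(a)).

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `n_states` | 21 | starvation grid (step 0.05); smooth policies at negligible cost |
| `gamma` | 0.99 | per-event discount (effective horizon ~100 events); one value used for both problems |
| `pM` | 0.8 | success ceiling at full discharge |
| `c0_base` | 1 | full-discharge cost, in starvation-penalty units |
| `slope` | 0 | linear starvation-dependence of c₀(s) = c0_base + slope·s |
| `action_grid` | 1001 | candidate actions for the argmax (resolution 10⁻³) |
| reward examples | 10·atan(1 − s), 5·cos(sπ/2) | built-in non-increasing desirability curves |

The linear c₀(s) family is the minimal monotone parameterization of a cost
that rises with starvation (regenerating capsules is plausibly more
expensive for a starved animal); `constant` is the slope = 0 special case.

## Numerical choices

- **Value iteration**: sup-norm tolerance 10⁻⁹, cap 10⁵ sweeps (the γ = 0.99
  contraction needs ~2200). Non-convergence is flagged, never silent. Ties
  in the action argmax break toward the smallest action. An optional warm
  start (`V0`) accelerates parameter scans.
- **Boundary conventions**: a success in the least-starved state self-loops
  (satiation cannot exceed its maximum); the absorbing state's landing
  reward is the starvation penalty −1 regardless of the reward form, since
  the built-in example curves reach 0 rather than the normalized penalty at
  s = 1.
- **Asymptotic policy**: assuming a*(s) varies slowly across neighboring
  states, the coupled first-order conditions close into the per-state
  relation c′(a*)/p′(a*) = (r(s−Δ) − r(s+Δ))/(1 − γ) (re-derived
  symbolically from the four-equation closure). Interior roots are
  bracketed to 10⁻⁸; if none exists the endpoint maximizing the surrogate
  p(a)·q(s) − c(a, s) is used, with q(s) the right-hand side above. Reward
  differences are one-sided (scaled to the central two-step span) at the
  grid edges.
- **Defense fixed point**: scalar iteration to 10⁻¹², contraction factor
  γ·p_M; used as the numeric cross-check of the closed form (they agree to
  within the 10⁻³ action-grid resolution across admissible parameters).

## Where the asymptotic approximation is valid

The closure is accurate when the implied actions are moderate, because
q = c′/p′ diverges as a → 1 (p′ → 0): tiny policy differences then translate
into large q differences and the slowly-varying assumption loses force. At
the default γ = 0.99 with the built-in rewards the reward differential
dwarfs 1 − γ, the exact policy saturates near a ≈ 0.9–1, and the cohort
pools against the satiation boundary where the exact value function
flattens — a boundary layer the translation-invariant closure cannot see.
The test suite quantifies this: at γ = 0.65 (moderate regime) the
approximation tracks value iteration within 0.05 across the bulk of the
grid for both reward examples, while at γ = 0.99 the sup-norm gap over all
interior states is large near the satiation edge (the acceptance test that
asserts 0.05 at the defaults fails and documents the measured gap). The
approximation can also select a self-consistent interior solution in a
different basin from the global optimum when incentives are weak (flat
rewards at low γ), which is why it is validated against the value-iteration
oracle rather than trusted standalone.

## Steady state of the optimal agent

Under the optimal policy the cohort settles where drift balances,
p(a*(s*)) ≈ 1/2, i.e. a*(s*) ≈ 0.36 for p_M = 0.8. The location of s* is
therefore controlled by the ratio of the per-event reward differential to
1 − γ: the asymptotic relation gives a*(s) ≈ 1 − c₀(1 − γ)/(2p_M·(r(s−Δ) −
r(s+Δ))), so s* moves up as the grid is refined (smaller Δ) or γ is lowered,
and down toward the satiation boundary as (r(s−Δ) − r(s+Δ))/(1 − γ) grows.
At the default 21-state grid with γ = 0.99 that ratio is large, the policy
saturates, and the simulated long-run mean starvation sits near 0.07 (the
acceptance script computes it) — close to the satiation boundary rather
than at an interior steady state. A random stinger from s = 0.9, by
contrast, is captured by the nearby absorbing boundary within ~16–21 events
(median over 200 agents) even though its mean success probability exceeds
1/2. These two simulated facts pull the grid/discount choice in opposite
directions — an interior steady state wants a fine grid or low discount,
fast random-agent collapse wants a coarse grid — so both are reported at
the single default parameterization rather than tuned per quantity.

## Synthetic behavioral data

The generator emulates a discharge assay: n = 10 animals per feeding
condition, conditions at 0–5 days of food deprivation, each animal
contributing a bounded count. Condition means follow λ·a*(s(days)) with the
last day mapped to s = 0.5 (day 0 at s = 0); counts are binomial on a
configurable capsules-at-risk denominator (default 200), beta-binomial with
intraclass correlation 0.05 by default to mimic animal-to-animal
variability. Three profiles cover the behavioral contrast: rising discharge
(predation model, cos-form reward), flat discharge (defense, constant
cost), and slightly falling discharge (defense, cost slope 0.4). The
generator does **not** emulate: a real per-trial denominator (unobservable
in gelatin-coverslip assays — counts have no true "capsules at risk"),
correlations across conditions within an animal (each condition is drawn
independently), day-to-day environmental drift, or stimulus-identity
effects. Passing recovery tests therefore show the fitting pipeline is
consistent under the stated noise model, not that real assay noise is
beta-binomial.

## Fitting

For a candidate cost (c₀_base, slope) the model is solved (defense: closed
form; predation: value iteration with warm start), days are mapped to
starvation, and the scale λ minimizing the weighted squared error has the
closed form λ = Σw·y·a / Σw·a², with weights 1/SEM² of the condition means
(uniform if SEMs are unavailable). The cost search is a coarse grid plus
Nelder-Mead refinement. With ~6 conditions the three free parameters trade
off along a nearly flat ridge (smaller base cost + steeper slope + smaller
λ give almost the same curve): the free fit recovers parameters essentially
exactly on noise-free data but its slope estimate is high-variance under
realistic noise. `fix_c0_base` anchors the base cost — naturally at the
value already used by the constant-cost model, since both cost functions
share c₀(0) — and fits only (slope, λ); this well-conditioned variant is
what the recovery tests exercise (sign recovery in ≥ 90% of replicates,
median slope error within 25%). A shared-cost mode fits one (c₀_base,
slope) jointly across a predatory and a defensive dataset, each with its
own λ; per-dataset fitting remains available.

## Known limitations

- Policies (and hence the steady state) are resolution-dependent: reward
  differentials scale with the grid step while the discharge cost does not.
  Comparisons across grids are only meaningful at matched Δ/(1 − γ).
- The asymptotic relation is a diagnostic tool, valid in the moderate-action
  bulk; it is not a substitute for value iteration near boundaries or at
  high discounts.
- The defensive model has no recovery from danger and no multi-step threat
  escalation; the predatory model has no environment learning (the
  environment's p, c, r are known to the agent).
- Fitted cost parameters carry no uncertainty intervals beyond residual
  reporting.
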