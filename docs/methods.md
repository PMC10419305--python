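# Methods

`obesnet` simulates the spread of obesity through a social network with a
hybrid model: an agent-based component generates and maintains the contact
network, a per-agent system-dynamics component (Theory of Planned
Behaviour, TPB) turns social and environmental pressure into dieting
decisions, and an energy-balance component turns those decisions into
weight change. A simultaneous-perturbation stochastic-approximation (SPSA)
optimiser calibrates the model's gain parameters against aggregate BMI
series. This note documents the model equations, the defaults and why
they were chosen, the synthetic-data generator, and the numerical and
design decisions that were genuinely open.

## 1. Simulation clock and update order

One iteration is one month of model time. Within a month the order is
fixed: **network slot → behaviour step → energy/weight update →
demographics** (age advance, entrants, deaths). Changing this order is a
breaking change; all results depend on it. A warm-up phase (default 24
months) runs the network and behaviour steps with weights and demographics
frozen, so the contact topology is stationary before outcomes are
recorded.

## 2. The emergent contact network

Agents occupy fixed uniform-random positions on a `Z × Z` map. Each slot
every agent issues `offers_per_step` link offers. An agent q is a
*candidate* for p when both of:

* propinquity — Euclidean distance `d(p, q) < Ra`;
* homophily — `theta_bmiadj[g(p) → g(q)] · |BMI(p) − BMI(q)| ≤ theta_trigger`
  (a deterministic indicator; four gender-pair weights, zero weight
  disables the BMI constraint for that pair).

Offers are targeted among candidates, and accepted by the offeree, with
the *memory probability*

    π(p, q) = min(1, baseline_prob + theta_mem · α(p, q)),

where `α(p, q)` is the windowed edge weight: contacts between p and q in
the last `M` slots divided by `M`. Each agent accepts at most `S`
(`s_max`) offers per slot; excess offers are resolved in uniformly random
order. Accepted interactions are appended to both agents' histories, and
the *network neighbourhood* of an agent is every partner with `α > 0`
(a configurable minimum-weight threshold exists and defaults to 0). All
topography metrics are computed on the induced simple undirected graph.

Numerical conventions:

* distance is plain Euclidean on the bounded square — no torus wrap;
* offers may repeat a partner within a slot (they count as repeated
  contacts in the log but collapse to one edge);
* **mean local clustering is averaged over nodes with at least two
  neighbours.** The per-node quantity — realised over possible links
  among the node's neighbours — is 0/0 below degree two; we exclude such
  nodes rather than count them as zero. Transitivity is the global
  closed-to-total triplet ratio; assortativities are Pearson correlations
  of degree (or BMI) over the two ends of every edge, counted in both
  orientations; a zero-variance correlation is reported as NaN, not 0.

### The topography fingerprint preset

`presets.fingerprint_network()` is the network parameterisation shipped to
reproduce the topography of the calibrated model: median (across monthly
snapshots) mean local clustering ≈ 0.67, transitivity ≈ 0.63 and average
degree ≈ 9.35 on a 1000-agent population. In this preset the social range
spans the map (`Ra = Z = 25`), so candidacy is governed by the BMI
homophily window; an interval-overlap constraint of this kind yields the
required high triadic closure, and the acceptance baseline (0.42) plus
memory gain (1.5) set the edge-coverage level that centres clustering and
transitivity jointly.

A structural limitation, established by a systematic scan of the full
parameter space (`Ra, Z, S, M, offers_per_step, theta_trigger, theta_mem,
baseline_prob`): in this offer/acceptance family, high clustering requires
near-saturated coverage of the candidate sets, which ties an agent's
degree to its candidate count; candidate counts are spatially and
BMI-correlated between linked agents, which puts edge-end degree
assortativity at ≈ 0.7–0.8 wherever clustering exceeds 0.6. Every
decorrelating mechanism the model offers (capacity competition under a
binding `S`, memory lock-in noise, coverage thinning, window length)
lowers assortativity only together with clustering. A degree
assortativity as low as ≈ 0.34 *simultaneously* with clustering ≈ 0.67 is
therefore outside the reachable set of this model class on uniform
positions, and the shipped preset reports ≈ 0.76. Users who care about
degree assortativity should treat it as a diagnostic, not a tunable
target.

## 3. The behaviour (TPB) component

Each agent carries two non-negative stocks, Intention `I` and Behaviour
`B`, integrated by explicit Euler at the one-month step:

    I ← max(0, I·(1 − λ_I) + F_att + F_norms + F_pbc − a)
    B ← max(0, B·(1 − λ_B) + a_delayed),     a = f_act · I

with per-month decays `λ_I = 0.2, λ_B = 0.3`, activation fraction
`f_act = 0.1`/month, and `a_delayed` the activation injected `theta_lag`
months earlier (a FIFO buffer; lag 0 delivers the same month).
The three inflows:

* **attitudes** `F_att = θ_att · (education/5) · min(1, max(0, (BMI−25)/5))`
  — education-moderated reaction to the agent's own overweight;
* **norms** — let `m` be the age-proximity-weighted mean BMI of *living
  same-gender* network neighbours, with weights `w_i = 1/(1 + |Δage_i|/10)`,
  and `d = BMI − m`. Then `F_norms = θ_norms[gender, age-group] · d` if
  `d > sv(BMI)`, else 0;
* **pbc** `F_pbc = θ_pbc · pbc`, with
  `pbc = pbc_default · (1 + tanh(success/5))`, where `success` is net kg
  lost over completed diets. The tanh keeps the feedback bounded in
  (0, 2·default).

The **satisficing value** — the minimum BMI excess an agent must perceive
before social pressure registers — is

    sv(b) = theta_sv · max(0, (b − 20)/10)²,

which at the default scale `theta_sv = 1` is 0 at BMI 20, 1 at BMI 30 and
4 at BMI 40: heavier individuals need a larger gap before reacting.

An agent in the NORMAL state starts DIETING when `B ≥ behaviour_threshold`
(default 20) **and** `d > sv(BMI)` against its same-gender neighbourhood;
both conditions are required. The Behaviour stock resets on transition and
the diet length is geometric with mean
`theta_diet_time · (1 + tanh(success/5))` months, minimum one month.

Open choices made here, flagged for users: the phrase "weighted by age"
for the norms input is ambiguous between the neighbour's age and age
*distance*; we weight by proximity to the focal agent's age, because the
gain `θ_norms` already varies with the focal agent's own age group, which
would double-count a pure own-age weighting. The decay rates, activation
fraction and behaviour threshold are free parameters — the underlying
stock-flow diagram fixes the structure, not the constants. Their defaults
were chosen so that, with the shipped norms gains (which are of order 1-5
per month), dieting is *episodic*: under a static calorie environment
roughly 7% of agents start a diet per year and the population mean BMI
drifts by about -0.25/yr (social pressure only ever pushes weight down;
upward pressure enters through the external-factor term, which is rising
in realistic scenarios). Smaller thresholds or weaker decays make dieting
near-continuous and implausibly collapse the BMI distribution. The
same-gender restriction on norms is hard-wired (the configuration that
performed best in calibration experiments).

The splittable gains (`theta_norms`, `theta_pbc`, `theta_attitude`,
`theta_sv`, `theta_diet_time`, `theta_extfactor`) are stored internally as
full gender × age-group grids; a scalar in the config is broadcast.
`theta_lag` (integer months) and the network parameters are global:
per-group activation lags would need per-agent buffers and the network
parameters are pairwise or structural, so the splitting cascade excludes
them.

## 4. Energy balance

Expenditure: `BMR = α + β·height_m + γ·weight_kg` (kcal/day), with
coefficients per gender × age band, and `TEE = PAL × BMR`. The shipped
coefficient table follows the Henry-style weight-and-height equations used
in UK dietary reference work (converted from MJ to kcal at 239.006
kcal/MJ) with bands 10–18, 18–30, 30–60, 60+ for each gender; it is an
editable CSV-backed config, not a clinical instrument. The PAL multiplier
takes one of three values — low 1.49, medium 1.63, high 1.78 — assigned
from (BMI, age): high for age < 30 with BMI < 25, low for age ≥ 60 or
BMI ≥ 30, medium otherwise. The category is re-derived monthly.

Intake is anchored at expenditure plus an external-pressure term:

    intake = TEE + theta_extfactor[gender, age-group] · (APCCC(year) − APCCC(baseline)),

where APCCC is the national average per-capita calorie consumption series
(kcal/person/day). Anchoring at TEE is a deliberate identifiability
choice: under baseline conditions every agent is in exact energy balance,
so all secular weight change is attributed to the external-factor
deviation, the network, and dieting. A DIETING agent multiplies intake by
`(1 − diet_restriction)` (default 0.10) — but only in months where a
Bernoulli draw with `adherence_prob` (default 0.7) succeeds; lapse months
revert to NORMAL intake, producing the cyclical loss/plateau pattern of
real dieting.

Weight update: `Δweight = (intake − TEE) · 30.44/7700` kg per month
(30.44 days/month, 7700 kcal per kg of body-weight change — a standard
energy-density constant). BMI is clamped to (10, 80).

## 5. Demographics, scenarios, aggregation

The default run starts from 1000 agents and applies annual quotas of 12
sixteen-year-old entrants and 7 deaths, scheduled evenly over months
(`floor(R·j/12) − floor(R·(j−1)/12)` events in month j). Death selection
is age-weighted, probability ∝ `exp((age − 50)/15)`, without replacement;
the model needs an age gradient, not a life table. Entrant BMI is Normal
around a configurable mean (default 22, sd 3).

Scenarios form the 3 × 3 grid of {falling, static, rising} trends in (a)
the APCCC series and (b) the entrant BMI mean; a trend multiplies the
quantity by `(1 ± annual_rate · rate_multiplier)^(years elapsed)` with
`annual_rate` defaulting to 0.005/yr and `rate_multiplier = 2` for
doubled-rate runs. The **network-off counterfactual** zeroes the norms
flow and drops the neighbourhood condition from the diet trigger (the
threshold alone then gates dieting); nothing else changes, so comparing
the two runs isolates the network effect. Run comparisons are reported as
percent-of-reference: `100·(b − a)/a` per (year, gender, age-group) cell.

Aggregation: mean and median BMI per year × gender × age group (groups
16–20, 21–30, 31–45, 46–60, 61–75, 76+), recorded at the initial year and
after each simulated year, with cell counts. Empty cells are NaN and are
excluded from calibration losses (both sides must be present).

## 6. SPSA calibration

The loss is the sum of squared errors of simulated vs reference mean and
median BMI over every cell, equally weighted. One SPSA iteration draws a
±1 perturbation vector Δ, evaluates the loss at `θ ± c_k Δ` and updates

    θ ← θ − a_k · ĝ,   ĝ = (L⁺ − L⁻)/(2 c_k) · Δ⁻¹ (elementwise),
    a_k = a/(A + k + 1)^α,   c_k = c/(k + 1)^γ.

Defaults: `a = 0.16, A = 100, c = 0.1, α = 0.602, γ = 0.101`, 3000
iterations, with the final estimate the elementwise **median of the last
100 iterates** (damping the jitter of individual steps). Two numerical
choices:

* **Bounded transform.** All parameters are optimised through a logit map
  onto fixed bounds (e.g. extfactor gains in (0, 1), norms gains in
  (0, 10)), so perturbed evaluations always stay feasible. The integer
  activation lag is optimised as a continuous value in (0, 12) and rounded
  on unpack — its gradient contribution is therefore piecewise flat.
* **Common random numbers.** The two perturbed evaluations of one
  iteration share the simulation seed by default, which removes most of
  the simulation noise from `L⁺ − L⁻`; a flag restores independent seeds.

The gain numerator `a` must match the loss scale: the update is
`a_k · ΔL/(2c_k)` in logit space, so losses of order 10³ (typical for a
200-agent, 5-year SSE) need `a` of order 10⁻³, not the 0.16 appropriate to
O(1)–O(10) losses. The scaled-down parameter-recovery test uses
`a = 0.02`, chosen by a pilot run before its assertions were frozen.

The refinement cascade — deciding which global gain to split by gender,
age group or both — is deliberately manual: `split_parameter` rewrites the
vector layout with children initialised to the parent value (so the loss
is unchanged at the split), and the experimenter re-runs the descent. The
homophily ablation is a canned paired experiment: identical parameter sets
except `theta_bmiadj` pinned to zero, scored by replicated runs with
shared seeds.

Replicated testing runs the calibrated set over fresh random populations,
pools the raw per-agent BMI values per cell across replicates for the
combined series, and reports the median of per-replicate losses as the
combined score.

## 7. The synthetic-data generator

`generate_population` emulates the statistical shape of national
individual-level survey records: a six-group adult age pyramid with
weights (0.08, 0.16, 0.25, 0.24, 0.18, 0.09) — the two youngest groups
jointly ≈ 24% of the population — a 50/50 gender split, per-stratum Normal
BMI with means rising from ≈ 24 (youngest males) to ≈ 28 and sd 3.8–4.8,
gender-specific Normal heights (1.75 ± 0.07 m, 1.62 ± 0.065 m), and a
five-level education distribution. "Balanced" sampling is implemented as
stratified allocation over age-group × gender cells (largest remainder)
with each cell's BMI draws split evenly across the tertiles of its Normal
— so requested marginals are hit almost exactly even at n = 200.
`make_reference` forward-simulates the full model under known parameters
and aggregates, giving a synthetic calibration target for recovery
experiments.

What the generator does **not** emulate: survey design effects and
weighting, household/geographic clustering of positions (positions are
uniform), the right skew of real BMI distributions (Normals are used, so
tails are thinner), secular cohort trends within a stratum, and any
correlation between education and BMI. Passing tests on synthetic data
therefore demonstrate that the machinery is self-consistent and that
parameters are recoverable under the model's own assumptions — not that
the shipped defaults describe any real population.

## 8. Problem sizes used by the test suite

The suite exercises the full pipeline at sizes chosen to keep the
feedback loop tight while remaining in the regime where the statistics are
stable: topography fingerprint at n = 1000 (30 warm-up + 24 snapshot
months); conservation and demographic bookkeeping at n = 1000 over 10
years; parameter recovery at n = 200 agents, a 5-year horizon and 300
SPSA iterations (tail 50); optimiser unit checks on analytic losses
(10⁴ perturbations, 3000-iteration quadratic bowl); ablation and
replicated-testing harnesses at n = 80–120. The acceptance script re-runs
the satisficing anchors and the n = 1000 fingerprint protocol from
scratch.

## 9. Known limitations

* Single proxy network: no multiplexity, no directed ties, no social
  media layer; positions and hence propinquity are static for life.
* The degree-assortativity ceiling discussed in §2.
* TPB constants (decays, activation, threshold) are weakly identified
  from aggregate BMI series alone; the calibration moves the flow gains,
  and recovery experiments show only aggregate gains are reliably
  recoverable at desk scale.
* Energy balance is linear with a fixed energy density; no metabolic
  adaptation, macronutrient composition or exercise interventions.
* Mortality is a stylised age-weighted lottery, not vital statistics; no
  migration.
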