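# Methods

`nestflow` simulates a colony of worker agents moving and interacting inside
a bounded nest and analyses the resulting interaction streams three ways:
static motif structure (feed-forward loops / triangle transitivity), motif
significance against a spatially explicit null, and time-ordered information
diffusion. This note records the model, its parameters, the numerical
choices, and what the synthetic experiments can and cannot show.

## The agent-based model

**Arena and agents.** The nest is a continuous square of `grid_size` = 50
patches per side. `n_agents` = 100 agents start at uniform-random positions
with uniform-random headings. Each agent carries two fixed behavioural
traits: an activity level `A_i` (dimensionless rate, population mean
`a_m` = 1) and a turning index `T_i` (degrees, population mean `t_m` = 60).
Defaults follow values typical of social-insect colonies: with `a_m` = 1
roughly half of a variable-activity population is active on a given step,
and a 60-degree per-step turning standard deviation is comparable to
observed ant walking paths.

**Activation.** On every step each agent is independently active iff an
`Exp(mean 1)` draw falls below `A_i`, i.e. with probability `1 − exp(−A_i)`.
Note the asymmetry this rule creates between the two "half the colony is
active" readings: for a *variable* population with `A ~ Exp(1)` the expected
active fraction is exactly `E[1 − e^(−A)] = 1/2`, whereas a *uniform*
population at `A_i = 1` is active with probability `1 − e^(−1) ≈ 0.632`.
The rule is implemented exactly as stated and the difference is left intact;
it is one reason uniform-activity colonies generate more interaction events.

**Movement.** An active agent updates its heading by `δθ ~ Normal(0, T_i)`
degrees (wrapped mod 360) and advances one body length (0.5 patches). A move
that would cross a wall has the offending coordinate set to the wall, and
the heading is mirrored in that wall (x-wall: `θ → 180 − θ`; y-wall:
`θ → −θ`; both at a corner) — a billiard bounce. The bounce matters: if the
heading is instead left pointing into the wall (`boundary="clamp"`, kept as
a variant), near-straight walkers linger on walls and pile up in corners,
where they form persistent contact cliques. That regime inflates interaction
counts in the variable-turning conditions above the uniform condition's —
inverting the interaction-rate ordering the model is meant to produce — and
strips straight walkers of their role in linking distant regions of the
nest. With the bounce, straight walkers keep traversing the nest and
interaction rates order correctly (uniform-activity conditions highest).
Movement is independent across agents, so the update is vectorised; the
interaction phase below does use a fresh random agent order each step, which
sets the within-step order of logged events.

**Interactions.** After all agents have moved, agents are visited in a fresh
uniform-random order; each may initiate at most one directed interaction
with a partner drawn uniformly from the agents within the interaction radius
(0.5 patches, inclusive). Who initiates and who ends up as signaller are
governed by two orthogonal rules:

- initiation: `by_activity` (only currently active agents initiate; the
  default) or `random_half` (any agent with a neighbour initiates with
  probability 0.5);
- direction: `active_outgoing` (initiator signals; default), `random` (fair
  coin), `relative_activity` (`i` signals with probability
  `A_i / (A_i + A_j)`), or `to_active` (initiator receives).

A receiver may be chosen by several initiators in one step; nothing in the
interaction rule forbids it. The log records `(t, signaller, receiver)` per
event, time-ordered, with within-step order equal to initiation order.

**Trait distributions.** Five conditions: `uniform` (all agents at the
means), `activity_variable` (`A ~ Exp(mean a_m)`), `ti_variable`,
`uncorrelated` (both vary independently) and `correlated` (both vary, paired
by perfectly opposite rank — the most active agent walks the straightest
path — then shuffled over agent ids). Variable turning indices are drawn as
`x ~ Exp(mean t_m)` and reflected about the mean, `T = 2 t_m − x`, redrawing
when the reflection would be negative. The reflection produces the intended
left-skewed shape — most agents sinuous (near `2 t_m`), a few straight — on
`(0, 2 t_m]`. The exact transform behind "most agents high, a few low" is
not recoverable from the published description; the reflection is the
simplest rule with the stated shape and near-`t_m` mean, and it is isolated
in `traits.assign_turning` so an alternative is a one-line swap.

**Randomness.** One master seed per run, split via `SeedSequence` into
independent child streams (traits, placement, activation, movement noise,
order shuffles, interaction choices). Identical configurations give
byte-identical logs. Experiment drivers derive per-run seeds
counter-style from a master seed and record them, so any run is
re-creatable in isolation; derived seeds stay below 2^31.

## Network construction

Events up to a window end `t_end` are aggregated into a weighted digraph
(weight = event count). Binarisation is per dyad: one-sided or
strict-majority flow gives a single directed edge; equal non-zero counts
give a mutual edge; silence leaves the dyad absent. `grow_to_density`
advances the window one step at a time (the finest stride, hence the
minimal window) until the binary network holds a target number of edges. By
default a mutual edge counts as **one** edge (a connected dyad); arc
counting (mutual = 2) is available behind a flag. Because a connected dyad
never disconnects, the dyad count is nondecreasing in the window and the
minimal window is well-defined; the arcs count can fluctuate, so the scan
checks every step boundary. Density targets follow the schedule
150, 300, …, 1500 (condition-contrast experiment) or a fixed 1000 edges
(rule-variant factorial, TSP, and null ensembles).

## Triangle statistics

A triangle is a node triple with all three dyads connected; its class is
determined by the number of mutual dyads and the orientation of the
asymmetric ones (030T, 030C, 120D, 120U, 120C, 210, 300). The census
enumerates triangles via adjacency-set intersection; unit tests pin it to an
exhaustive per-triple classification by an independent library oracle.

Triangle transitivity is `t_tri = 4 (P_t − 0.75)` with `P_t` the transitive
proportion, so random orientation gives 0 (three of the four orientations of
a unidirectional triangle are transitive) and an all-feed-forward network
gives 1. Following the dominance-hierarchy convention, triangles containing
mutual dyads are resolved into all orientations of those dyads with equal
weight: 120D and 120U count as transitive (weight 1), 120C splits 1/2:1/2,
and 210 and 300 contribute 3/4. This weighting is the default because it is
the variant that reproduces the published magnitudes on simulated colonies
(the strict 030T-vs-030C restriction, kept as `scheme="strict"`, yields
systematically higher values — about 0.8 where the weighted statistic gives
about 0.55 — once mutual-dyad triangles are common). Networks with no
eligible triangle propagate NaN, which the experiment summaries exclude
with a count.

Triad significance profiles standardise each class count of an observed
network against the mean and sample standard deviation of a null ensemble
and scale the Z-vector to unit norm. The null of interest is *spatially
explicit*: 100 independent uniform-condition simulations, each grown to the
same edge count — not an Erdős–Rényi graph — so the profile isolates the
effect of behavioural variation from geometry and density. A class with
zero null variance scores 0 when the observation matches the null mean and
is an explicit error otherwise.

## Information diffusion

The signaller of a log's first event is the seed. Events are replayed in
time order (within a step, logged order); a naive receiver of an event from
an informed signaller becomes informed immediately and can transmit later
in the same step — events are atomic, and no end-of-step quarantine is
stated anywhere, so none is invented (a strict end-of-step variant would
only delay hops by fractions of a step relative to `T50` ≈ 700).
`T50` is the earliest step with at least `ceil(n/2)` informed; efficiency is
the number of events with an informed-at-the-time signaller and `t ≤ T50`
(fewer = more efficient). Runs that never reach 50% report missing values
and are excluded from cell means with a logged count.

Because uniform-activity colonies interact more often, a fixed 20% of
events are removed uniformly at random (exactly `round(0.2 · n_events)`,
order preserved) from runs of the `uniform` **and** `ti_variable` conditions
before diffusion — both have uniform activity levels — equalising
interaction rates without reshaping the interaction patterning.

## Experiment design and summaries

- Experiment i: 5 conditions × `n_runs`; each run is assigned one density
  target by blocked order (with 100 runs, runs 1–10 → 150, …, 91–100 →
  1500), one binary network per run.
- Experiment ii: {uniform, activity-variable} × four rule variants — the
  2 × 2 factorial of initiation (activity / coin) and direction (activity /
  coin), where "activity-determined direction" means `active_outgoing` under
  activity initiation and `relative_activity` under coin initiation — at
  1000 edges.
- Experiment iii: 5 conditions, diffusion with the thinning control.

The published analysis fitted variance-weighted least squares with
information-criterion model averaging. On these balanced, independently
seeded designs the reported coefficients are condition contrasts, so
`nestflow` reports cell means, mean contrasts against the uniform reference
cell, an OLS of `t_tri` on condition × standardised density, and the
difference-of-differences interaction for the factorial; the variance
modelling would change standard errors, not these point estimates. This is
a deliberate simplification.

## Problem sizes and tolerances

Acceptance-style checks run 30 simulations per cell (20 for the pooled
six-cell mean) instead of the study's 100, chosen so the whole suite
completes on a single CPU in minutes. At that replication the Monte-Carlo
standard error is about 0.015 for `t_tri` cell means and about 0.04–0.06
for log-scale diffusion summaries, so tests assert agreement within ±0.05
and ±0.12 respectively (≈3 standard errors). Null-vs-observed TSP checks
assert sign patterns, not magnitudes.

## What the generator does and does not emulate

The simulation reproduces the *mechanisms* said to shape insect interaction
networks — activity-gated movement, contact-radius interactions,
directionality tied to activity, spatial fidelity from path sinuosity — in
an idealised arena: no pheromones, no tasks, no births/deaths, traits fixed
for a run, perfectly observed interactions. Passing tests therefore show
that the implementation reproduces the model's published behaviour, not
that real colonies behave this way; in particular the diffusion process is
deterministic per contact (every informed-to-naive event transmits), which
upper-bounds real transmission fidelity.

## Known limitations

- The variable-turning transform and the boundary-heading rule are
  reconstructions of under-specified model details; both are isolated
  behind flags (`assign_turning`, `SimConfig.boundary`) and the defaults
  are the variants that reproduce the published interaction-rate ordering
  and diffusion behaviour.
- `grow_to_density` treats a mutual edge as one edge; the original count is
  ambiguous. At 1000 edges the two conventions differ by the number of
  mutual dyads (typically a few dozen), which shifts `t_tri` cell means by
  far less than a sampling standard error.
- The static-network diffusion variant is exploratory only and makes no
  claim of matching any published procedure.
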