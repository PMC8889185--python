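# nestflow

Agent-based simulation of worker interaction networks in an insect colony,
with the analysis stack to ask two questions: **which patterns of
among-individual behavioural variation generate feed-forward loops** in the
colony's directed interaction network, and **what that variation does to the
speed and efficiency of information flow**.

`nestflow` is aimed at researchers in collective behaviour and network
ecology who want a scriptable, fully reproducible implementation of this
model — e.g. to generate *spatially explicit null models* for motif analysis
of empirical contact networks, instead of Erdős–Rényi graphs that ignore
spatial constraints on who can meet whom.

## The model in brief

`N = 100` agents walk a bounded 50 × 50-patch nest for `t = 5000` steps.
Agent `i` carries an activity level `A_i` and a turning index `T_i`
(degrees). Each step it is active iff an `Exp(mean 1)` draw is below `A_i`
(probability `1 − e^(−A_i)`); an active agent turns by
`δθ ~ N(0, T_i)`, advances one body length (0.5 patches), and bounces off
walls. After movement, each active agent with a neighbour within 0.5
patches directs an interaction at one random neighbour — by default the
active agent is the signaller. Five trait conditions (uniform,
activity-variable, TI-variable, uncorrelated, correlated) control how
`A_i` and `T_i` are distributed, with `A_m = 1`, `T_m = 60`.

The time-ordered event log `(t, signaller, receiver)` is aggregated over a
growing window and binarised by dyad majority into a directed network of a
target edge count. Triangles are classified into the seven complete-triad
classes; triangle transitivity

    t_tri = 4 (P_t − 3/4)

rescales the transitive (feed-forward) proportion `P_t` so that random edge
orientation gives 0 and an all-feed-forward network gives 1. Triad
significance profiles are unit-norm vectors of class-wise Z-scores against
an ensemble of uniform-condition simulations. A susceptible–informed
diffusion replayed over the raw event stream yields `T50` (steps until half
the colony is informed) and transmission efficiency (outgoing interactions
from informed agents until `T50`).

See `docs/methods.md` for the full model description, parameter rationale
and numerical choices.

## Worked example

```python
from nestflow import (SimConfig, run_simulation, grow_to_density,
                      triangle_census, triangle_transitivity)

log = run_simulation(SimConfig(condition="activity_variable", seed=1))
print(len(log), "events")
net = grow_to_density(log, 1000)          # smallest window with 1000 dyads
print("window:", net.t_end, "steps")
census = triangle_census(net)
print(census.counts)
print("t_tri = %.3f" % triangle_transitivity(census).t_tri)
```

prints

```
7285 events
window: 2995 steps
{'030T': 932, '030C': 50, '120D': 188, '120U': 541, '120C': 244, '210': 310, '300': 50}
t_tri = 0.547
```

Read: in a colony whose workers *vary* in activity, the first ~3000 steps
of interactions already connect 1000 dyads, and the resulting network is
saturated with feed-forward loops — 932 transitive vs 50 cyclic
unidirectional triangles, `t_tri ≈ 0.55`, where a uniform colony sits near
0. The same pipeline is scriptable from a shell:

```sh
nestflow simulate --condition activity --seed 1 --out run.csv
nestflow netbuild --log run.csv --target-edges 1000 --out net.csv
nestflow motifs   --log run.csv --target-edges 1000 --out census.csv
nestflow diffuse  --log run.csv --seed 1 --out diff.csv
nestflow experiment 2 --runs 10 --seed 1 --out exp2.csv
```

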