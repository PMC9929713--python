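# moodpomdp

Computational-psychiatry models of mood updating as belief-state planning.

An agent lives in an environment that is either **stressful** or **not
stressful** but can only sense it through noisy interoceptive **signals**
(stress or pleasure). Its actions are sensory gain control — amplify or
attenuate either signal channel, or wait — and its goal is to minimise
surprisal: reward is the log prior preference of an outcome plus the log
evidence the agent's own model assigns to it, so planning by the Bellman
optimality equation is the no-epistemic-value special case of active
inference. The agent's posterior belief `b = (p, 1 − p)` over the hidden
state is its *mood*: `p` is how stressful it currently takes the world to
be.

Formally this is a two-state, two-observation, five-action POMDP
(T[a,s,s′], Z[a,s′,o], R[a,s], γ). The optimal policy is computed by
fixed-grid value iteration over the belief simplex with convex-combination
interpolation (an upper bound on the true optimal value function), with an
exact finite-horizon alpha-vector solver as the testing oracle. The solved
policy is rendered as a **belief network**: nodes are the reachable
beliefs, each labelled with its optimal action; edges are the
signal-triggered Bayes updates, weighted by their predictive probability.
Terminal strongly connected components of that network are *mood traps* —
belief sets no sequence of signals can escape.

Four canonical parameterizations ship as fixtures, differing only in their
transition and likelihood tensors:

* **healthy** — sharp, state-congruent likelihoods. Six belief nodes; the
  agent amplifies belief-consistent signals when certain and attenuates
  belief-inconsistent signals when uncertain, and can always move between
  confident-calm and confident-stressed moods.
* **depression** — stress signals expected in every state under every
  action. After enough stress signals the belief enters a terminal
  high-stress loop in which pleasure signals are attenuated and can no
  longer restore a calm mood.
* **mania** — the exact mirror image of depression: a terminal
  low-stress loop resistant to stress signals.
* **anxiety** — low-precision likelihoods (every row flatter than its
  healthy counterpart). The agent amplifies belief-consistent signals even
  when uncertain and ends in a single intermediate-belief node that is
  closed under both signals: a self-maintaining uncertainty trap, and the
  lowest expected reward of the four.

## Worked example

```python
from moodpomdp import (make_depression, solve_grid, extract_policy,
                       build_policy_graph, absorbing_components,
                       node_summary_table)

model = make_depression()
V = solve_grid(model, resolution=20)        # belief-grid value iteration
policy = extract_policy(model, V)           # greedy one-step lookahead
graph = build_policy_graph(model, policy)   # reachable belief network
print(node_summary_table(graph).head(3))
print([sorted(t) for t in absorbing_components(graph)])
```

The same pipeline for all four moods, from the shell:

```bash
moodpomdp report --out report/
```

prints

```
      mood  mean_stress_probability  mean_stress_unweighted  total_expected_reward  n_nodes
   healthy                 0.488451                0.527357             -19.117845        6
depression                 0.862642                0.710966             -20.498915       12
     mania                 0.137358                0.289034             -20.498915       12
   anxiety                 0.599546                0.549627             -26.437658        4
```

Reading the numbers: `mean_stress_probability` is the long-run,
occupancy-weighted probability the agent assigns to a stressful world
(stationary distribution of its belief network) — near one half for the
healthy agent, pushed toward certainty of stress in depression, mirrored
in mania, and stuck at an uncertain 0.60 in anxiety.
`total_expected_reward` is the solved value (nats of negative surprisal,
discounted at γ = 0.95) at the uniform start belief: highest for the
healthy agent, equal for the mirror-image pair depression/mania, and
lowest for anxiety, whose flat likelihoods make every outcome ambiguous.
`n_nodes` counts the reachable belief states; the healthy network has the
canonical six.

Other subcommands: `moodpomdp solve` (store a value function),
`moodpomdp graph` (GraphML/DOT/CSV export of the belief network),
`moodpomdp simulate` (seeded trajectory and occupancy histogram). Run any
of them with `--help`.

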