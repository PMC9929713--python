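# Methods

## The model

`moodpomdp` implements a discrete partially observable Markov decision
process (POMDP) in which the hidden environment is either *stressful* or
*not stressful*, the agent registers binary interoceptive *signals*
(stress or pleasure), and its actions are forms of sensory gain control:
amplify or attenuate either signal channel, or wait. The agent never
observes the environment directly; it maintains a Bayesian belief
b = (p, 1 − p) over the two states, and this belief *is* the model's
notion of mood: p is the probability the agent assigns to living in a
stressful world.

The generative model is specified by

* a transition tensor T[a, s, s′] — environment persistence. Actions are
  interoceptive, so they do not move the world: in all shipped models T is
  action-independent, parameterized by one stay-probability per state;
* a likelihood tensor Z[a, s′, o] — the probability of registering signal
  o in the arrived-at state s′ under gain-control action a (the update
  order is transition-then-observe);
* a reward matrix R[a, s] (nats, see below) and a discount γ.

### Action semantics: channel gain control

With only two observations, any rule that flattens one signal's likelihood
column across states necessarily flattens the complementary column
identically, so "attenuate stress" and "attenuate pleasure" cannot both be
defined as column-flattening — they would be the same operator. The
operators used instead act on one signal *channel*:

* `amplify_X` multiplies the odds of registering X by a gain g > 1 in
  every state (the channel is turned up: X is registered more readily);
* `attenuate_X` multiplies the probability of registering X by a factor
  κ < 1 in every state (the channel is damped);
* `wait` leaves the baseline likelihood untouched.

Rows are renormalized over the complementary signal. Both operators
commute with the stress↔pleasure mirror, so a mirrored model has exactly
mirrored action effects. Gains may differ per channel: a mood can be able
to damp one channel while barely modulating the other.

### Reward: surprisal and preference

Reward is the expected negative surprisal of outcomes under the agent's
own generative model, plus a log prior preference over outcomes:

    r(o; a, s′) = ln C(o) + ln Z[a, s′, o]
    R[a, s]     = Σ_{s′} T[a, s, s′] Σ_o Z[a, s′, o] · r(o; a, s′)

The first term is the pragmatic (risk) component — preferred signals are
rewarding per se; the second is the negative ambiguity component — a sharp
likelihood yields outcomes with high model evidence, a flat likelihood
pays an entropy penalty. This is exactly expected free energy with no
epistemic (information-seeking) term, so maximizing discounted reward by
the Bellman optimality equation is the planning-as-inference special case
of active inference. The pure preference component is also exposed
separately as `surprisal_reward`.

One subtlety: raising the preference C(o) does *not* uniformly raise the
preference reward; the derivative with respect to C(o) is positive exactly
where Z[a, s, o] > C(o) (the test suite asserts this sign condition rather
than a naive monotonicity).

Natural logarithms are used throughout (nats). All rewards are ≤ 0; values
are therefore negative, and "higher reward" means closer to zero.

The per-step reward logged in simulations is R[a_t, s_t]. Its conditional
expectation equals the belief-MDP reward by construction, which makes the
Monte-Carlo mean discounted return an unbiased estimate of the executed
policy's value — the consistency check the test suite performs.

## Solvers

`exact_finite_horizon` computes the exact finite-horizon value as an
alpha-vector set by exhaustive cross-sum backups. Pruning removes
duplicates, pointwise-dominated vectors and (for two states) every vector
that is nowhere maximal on the belief segment, which keeps the sets small
at the instance sizes it is meant for (≤ 3 states, ≤ 5 actions, horizon
≲ 8; a resource guard raises beyond a configurable cap). It exists as the
independent oracle for the grid solver.

`solve_grid` is the production solver: value iteration on a regular belief
lattice (for two states, the uniform partition of [0, 1] at resolution k;
default k = 20) with convex-combination interpolation — linear between the
two bracketing grid points, the unique convex combination. Successor
values are interpolated, so each sweep is the interpolated Bellman
operator; iteration stops when the sup-norm change is ≤ ε (default 1e-8,
max 10,000 sweeps; a non-converged result is flagged, never silent).
Standard properties hold and are tested:

* the converged grid values upper-bound the true optimal values at grid
  points (interpolating a convex function overestimates it, and the
  Bellman operator preserves convexity);
* sweep-matched runs upper-bound the exact finite-horizon value;
* doubling the resolution tightens the bound at shared grid points;
* residuals contract at rate γ.

The upper bound tightens as the grid refines; iterating the interpolated
backup to its fixed point is what "minimising the bound" amounts to here —
no separate outer optimization exists.

Policies are greedy one-step lookahead against a value function. Ties
(within 1e-12) break toward the earliest action in the canonical order
(attenuate_pleasure, amplify_pleasure, attenuate_stress, amplify_stress,
wait), making solved policies, graphs and simulations reproducible.

The multi-state generalization of the grid (Freudenthal lattice with
barycentric interpolation) is specified in the grid generator, but only
the two-state interpolation path is implemented and exercised.

## Belief networks

`build_policy_graph` expands breadth-first from the start belief (default
uniform — the maximum-entropy choice, recorded with every graph): at each
node the policy's action is taken, and each signal with positive
predictive probability spawns a successor belief, merged into an existing
node when within 0.02 (sup-norm) of it. The merge tolerance reconstructs
the coarse published networks; it is recorded in every output. Edges carry
the signal label and its predictive probability, so out-edge probabilities
sum to one and the graph is a finite Markov chain over beliefs.

Terminal strongly connected components of this chain ("absorbing
components") formalize being *stuck*: once the belief enters one, no
sequence of signals leads out. Long-run occupancy is computed analytically
— absorption probabilities into each terminal component by a linear solve
on the transient part, stationary distributions within components by power
iteration on the lazy chain (P + I)/2, which converges for periodic cycles
too — and cross-checked against a direct linear solve and against
empirical trajectories.

## The four mood parameterizations

Differences between moods live entirely in T and Z (and hence in the
reward derived from them). The shipped numeric values are frozen in
fixture files; `scripts/calibrate_fixtures.py` regenerates and re-verifies
them. They were chosen by a coarse search over the builder knobs so that
the solved models reproduce the canonical qualitative structure:

| mood | baseline Z(stress∣s, wait) | stay(s/n) | gains (g, κ) per channel |
|---|---|---|---|
| healthy | 0.80 / 0.20 | 0.88 / 0.88 | 10, 0.2 (both) |
| depression | 0.84 / 0.72 | 0.95 / 0.60 | stress 1.2, 0.9; pleasure 1.5, 0.55 |
| mania | mirror of depression | | |
| anxiety | 0.535 / 0.505 | 0.83 / 0.72 | 2, 0.85 (both) |

Preferences are C(pleasure) = 0.51 in every fixture and the discount is
0.95 (it must be < 1 for the infinite-horizon solution to exist). The
preference asymmetry is deliberately small: the ambiguity term must
dominate for the healthy agent to amplify belief-consistent signals when
certain and attenuate belief-inconsistent signals when uncertain; a strong
pleasure preference collapses the policy into permanent stress
attenuation. Pleasure remains (weakly) preferred, which gives the healthy
agent its slight pleasure-seeking tilt (mean p(stress) ≈ 0.49 < 0.5).

Design notes on the archetypes:

* **healthy** — sharp, state-congruent baseline; strong symmetric gain
  control. Six reachable belief nodes; amplification at the certain nodes,
  attenuation of the belief-inconsistent signal at the uncertain ones; a
  single terminal component spanning both certainty poles (moods remain
  mutually reachable).
* **depression** — stress signals likely in *both* states under *every*
  action (the minimum of Z(stress∣s, a) exceeds the healthy baseline's
  stress rate in the calm state); a sticky stressful world and a fragile
  calm one; the stress channel barely controllable, the pleasure channel
  strongly attenuable. The solved policy attenuates pleasure everywhere,
  and every node above p = 0.5 forms one terminal component: pleasure
  signals, damped and weakly informative, can no longer pull the belief
  back across one half. The degree of pleasure attenuation is moderate
  (κ = 0.55): an agent that silenced its pleasure channel completely would
  enjoy a likelihood so sharp that its expected reward would *exceed* the
  healthy agent's — state-insensitive certainty is cheap under an
  ambiguity-based reward. With moderate attenuation the depressed model's
  certainty is blunter and its value lands between healthy and anxiety.
* **mania** — constructed as the exact mirror of depression (states,
  signals, and stress/pleasure action pairs swapped across every tensor),
  so all its properties are the reflections of depression's, including an
  identical total expected reward. Mirroring swaps the preference vector
  embedded in the reward; this is accepted as part of "the opposite of
  depression".
* **anxiety** — every likelihood row strictly flatter (higher entropy)
  than its healthy counterpart: no signal is ever very informative. The
  solved policy amplifies the belief-consistent signal even when
  uncertain — amplification is the only way to buy sharpness from a flat
  baseline — and the belief converges along the environment prior toward a
  single intermediate node (p ≈ 0.60) whose both signal successors merge
  back into it: a self-maintaining uncertainty trap. With nearly
  uninformative signals the reachable set contains no confident nodes at
  all, which is what makes anxiety's expected reward the lowest.

In the depressed and manic graphs the uniform start node is the only node
on the healthy side of one half: under these monotone belief dynamics a
terminal component strictly above 0.5 and reachable confident-calm nodes
are mutually exclusive (the damped pleasure update's fixed point is the
trap's floor). The published depressed network retains a few transient
calm nodes; this implementation trades them for a strict trap.

## Simulation

The environment is an exogenous two-state Markov chain (default stay
probability 0.9, or an explicit schedule); signals are drawn from the
agent's likelihood at the arrived-at state, so simulation and inference
share one generative model and impossible observations cannot occur. All
randomness flows from a single seeded generator per run; the seed is
recorded in every artifact. The rollout engine is vectorized across
episodes and shared by single-trajectory and Monte-Carlo entry points.

Occupancy summaries come in two flavours: empirical histograms of
p(stress) over a trajectory (20 bins, burn-in 500 by default), and the
deterministic stationary occupancy of the policy-graph chain. The mood
comparison report uses the deterministic chain analysis; its mean stress
probability is occupancy-weighted, with the unweighted node mean reported
alongside. "Total expected reward" is the solved value at the uniform
start belief, with a Monte-Carlo estimate available as a cross-check.

### Problem sizes

Defaults were chosen so a full four-mood pipeline runs in seconds: grid
resolution 20 (21 belief points), ≤ 500 graph nodes, 10,000-step
trajectories, and 2,000 episodes × 300 steps for Monte-Carlo checks
(γ³⁰⁰ ≈ 2·10⁻⁷, so truncation bias is far below sampling error). The
Monte-Carlo/value consistency check solves at resolution 200: the grid
value is an upper bound whose interpolation bias scales like h²/(1 − γ),
and at k = 20 that bias is comparable to the Monte-Carlo standard error,
which would confound the comparison; at k = 200 it is negligible.

## Calibration

The study's probability values are a free design parameter, so the frozen
fixture numbers are themselves a calibration artifact. The procedure —
shipped as `scripts/calibrate_fixtures.py --check` and re-run by the test
suite's acceptance layer — searched coarse grids and random draws over the
builder knobs and accepted a configuration only if all structural targets
held simultaneously (six healthy nodes; the amplify/attenuate banding; the
three disorder traps; the stress-probability and reward orderings). The
chosen values are frozen in the fixture files; they are inputs to the
package, not tuned per run.

## What the synthetic environments do and do not show

The simulated environment is a stationary two-state chain, and the mood
fixtures are archetypes at the corners of the expectation/precision
schema. Passing tests show that the *mechanism* — gain-control actions
selected by Bellman optimality under a surprisal-based reward — produces
the qualitative phenomenology (mood inertia, pleasure attenuation in
depression, uncertainty traps in anxiety) and that the numerics (solver
bounds, Bayes updates, chain analyses) are correct. They do not show that
these parameter values describe any patient population, that real
interoceptive signals are binary, or that clinical mood states are
cleanly separable archetypes; fitting the tensors to behavioural or
physiological data is outside the package's scope.

## Known limitations

* Two states and two observations only for mirroring and grid
  interpolation (the general simplex grid is generated but not
  interpolated).
* No epistemic value: policies never act to gain information for its own
  sake, matching the modelling assumption, so exploration phenomena are
  out of reach.
* The merge tolerance is a reconstruction of the published networks'
  coarseness, and node counts depend on it; it is recorded in every
  output for that reason.
* Preferences are fixed and shared across moods (up to mirroring); mood
  differences are carried entirely by the transition and likelihood
  tensors.
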