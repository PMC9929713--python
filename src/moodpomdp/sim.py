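"""Stochastic environments, agent rollouts and occupancy summaries.

The environment is a two-state Markov chain (stressful / not stressful)
that fluctuates independently of the agent's actions; the agent's actions
shape only which signals it registers.  A rollout threads the solved greedy
policy through the environment: act, let the environment move, sample a
signal from the likelihood of the arrived-at state, update the belief by
Bayes' rule, log the reward.  Occupancy summaries — the frequency density
of the belief in [0, 1] and its mean — are computed either empirically from
trajectories or analytically from the stationary distribution of the
policy-graph Markov chain; the latter is the deterministic default for the
mood comparisons.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .graph import PolicyGraph, absorbing_components, build_policy_graph
from .model import MoodPOMDP, _belief_array
from .moods import load_fixture
from .solve import GridValueFunction, Policy, extract_policy, solve_grid

DEFAULT_STAY = 0.9
DEFAULT_BINS = 20
DEFAULT_BURN_IN = 500


@dataclasses.dataclass(frozen=True)
class EnvironmentConfig:
    """Two-state environment chain: size, persistence and seed.

    ``schedule`` (state labels or indices) overrides the stochastic chain;
    ``start_state`` pins the initial state (default: uniform draw).
    """

    n_steps: int
    stay_probability: float = DEFAULT_STAY
    seed: int | None = None
    start_state: int | str | None = None
    schedule: Sequence | None = None

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0.0 <= self.stay_probability <= 1.0:
            raise ValueError("stay_probability must be in [0, 1]")


def _resolve_state(s, state_labels) -> int:
    if isinstance(s, str):
        return tuple(state_labels).index(s)
    return int(s)


def generate_environment(
    config: EnvironmentConfig,
    state_labels: tuple[str, ...] = ("stressful", "not_stressful"),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """State-index sequence of the environment chain, shape (n_steps,).

    Identical seeds give identical sequences.  Signals are emitted later,
    during the rollout, because they depend on the agent's current action.
    """
    if config.schedule is not None:
        seq = np.array([_resolve_state(s, state_labels) for s in config.schedule], dtype=int)
        if len(seq) < config.n_steps:
            raise ValueError("schedule shorter than n_steps")
        return seq[: config.n_steps]
    if len(state_labels) != 2:
        raise ValueError("the environment chain is two-state")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    states = np.empty(config.n_steps, dtype=int)
    if config.start_state is None:
        s = int(rng.integers(2))
    else:
        s = _resolve_state(config.start_state, state_labels)
    stay = config.stay_probability
    for t in range(config.n_steps):
        states[t] = s
        if rng.random() >= stay:
            s = 1 - s
    return states


@dataclasses.dataclass
class TrajectoryRecord:
    """Per-step log of one rollout.

    ``states[t]`` is the environment state the agent acted *from*,
    ``observations[t]`` the signal emitted by the arrived-at state,
    ``beliefs[t]`` the belief after the Bayes update and ``rewards[t]``
    the expected immediate reward R[a_t, s_t] (an unbiased per-step sample
    of the belief-MDP objective).
    """

    states: np.ndarray
    actions: np.ndarray
    observations: np.ndarray
    beliefs: np.ndarray  # (n_steps, S), post-update
    rewards: np.ndarray
    model_hash: str
    seed: int | None
    config: EnvironmentConfig | None

    @property
    def n_steps(self) -> int:
        return len(self.actions)

    @property
    def p_stress(self) -> np.ndarray:
        return self.beliefs[:, 0]

    def discounted_return(self, discount: float) -> float:
        w = discount ** np.arange(self.n_steps)
        return float(w @ self.rewards)

    def to_frame(self, model: MoodPOMDP) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(self.n_steps),
                "state": [model.state_labels[s] for s in self.states],
                "action": [model.action_labels[a] for a in self.actions],
                "observation": [model.observation_labels[o] for o in self.observations],
                "p_stress": self.p_stress,
                "reward": self.rewards,
            }
        )


@dataclasses.dataclass
class OccupancySummary:
    """Frequency density of the belief and its headline statistics."""

    histogram: np.ndarray
    bin_edges: np.ndarray
    mean_stress_probability: float
    total_expected_reward: float
    node_occupancy: dict[int, float] | None = None


def _sample_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """Vectorized draw from N categorical rows, probs (N, K)."""
    u = rng.random(probs.shape[0])
    cdf = np.cumsum(probs, axis=1)
    return (u[:, None] > cdf).sum(axis=1)


def _simulate_batch(
    model: MoodPOMDP,
    policy: Policy | Callable,
    n_episodes: int,
    n_steps: int,
    rng: np.random.Generator,
    b0: np.ndarray,
    env_states: np.ndarray | None = None,
):
    """Lock-step vectorized rollout engine shared by all simulation entry points.

    When ``env_states`` is given (n_episodes, n_steps + 1) the environment
    follows that exogenous chain; otherwise each next state is sampled from
    the model's own transition tensor given the chosen action
    (self-consistent rollout).
    """
    S, A, O = model.n_states, model.n_actions, model.n_observations
    B = np.tile(np.asarray(b0, float), (n_episodes, 1))
    if env_states is not None:
        cur = env_states[:, 0].astype(int)
    else:
        cur = _sample_categorical(rng, np.tile(B[0], (n_episodes, 1)))
    states = np.empty((n_episodes, n_steps), dtype=int)
    actions = np.empty((n_episodes, n_steps), dtype=int)
    observations = np.empty((n_episodes, n_steps), dtype=int)
    rewards = np.empty((n_episodes, n_steps))
    beliefs = np.empty((n_episodes, n_steps, S))
    act_fn = policy.action_indices if hasattr(policy, "action_indices") else None
    for t in range(n_steps):
        if act_fn is not None:
            a = act_fn(B)
        else:
            a = np.array([model.action_index(policy(b)) for b in B])
        states[:, t] = cur
        actions[:, t] = a
        rewards[:, t] = model.reward[a, cur]
        if env_states is not None:
            nxt = env_states[:, t + 1].astype(int)
        else:
            nxt = _sample_categorical(rng, model.transition[a, cur, :])
        obs = _sample_categorical(rng, model.likelihood[a, nxt, :])
        observations[:, t] = obs
        prior = np.einsum("ns,nsq->nq", B, model.transition[a])
        like = model.likelihood[a, :, :][np.arange(n_episodes), :, obs]
        numer = prior * like
        B = numer / numer.sum(axis=1, keepdims=True)
        beliefs[:, t, :] = B
        cur = nxt
    return states, actions, observations, beliefs, rewards


def run_agent(
    model: MoodPOMDP,
    policy: Policy | Callable,
    env: EnvironmentConfig,
    b0=None,
) -> TrajectoryRecord:
    """Roll the solved agent through one seeded environment realization."""
    rng = np.random.default_rng(env.seed)
    b0v = model.uniform_belief().probs if b0 is None else _belief_array(model, b0)
    chain = generate_environment(
        dataclasses.replace(env, n_steps=env.n_steps + 1), model.state_labels, rng=rng
    )
    states, actions, observations, beliefs, rewards = _simulate_batch(
        model, policy, 1, env.n_steps, rng, b0v, env_states=chain[None, :]
    )
    return TrajectoryRecord(
        states=states[0],
        actions=actions[0],
        observations=observations[0],
        beliefs=beliefs[0],
        rewards=rewards[0],
        model_hash=model.model_hash(),
        seed=env.seed,
        config=env,
    )


def estimate_discounted_return(
    model: MoodPOMDP,
    policy: Policy | Callable,
    b0=None,
    n_episodes: int = 2000,
    n_steps: int = 300,
    seed: int | None = 0,
):
    """Monte-Carlo estimate of the policy value at ``b0``.

    Episodes follow the model's own generative process (states from the
    transition tensor, signals from the likelihood), so the mean discounted
    return is an unbiased estimate of the executed policy's value.
    Returns (mean, standard_error, per_episode_returns).
    """
    rng = np.random.default_rng(seed)
    b0v = model.uniform_belief().probs if b0 is None else _belief_array(model, b0)
    _, _, _, _, rewards = _simulate_batch(
        model, policy, n_episodes, n_steps, rng, b0v, env_states=None
    )
    w = model.discount ** np.arange(n_steps)
    returns = rewards @ w
    mean = float(returns.mean())
    se = float(returns.std(ddof=1) / np.sqrt(n_episodes))
    return mean, se, returns


def belief_occupancy(
    traj: TrajectoryRecord,
    n_bins: int = DEFAULT_BINS,
    burn_in: int = DEFAULT_BURN_IN,
    discount: float | None = None,
) -> OccupancySummary:
    """Histogram of post-burn-in p_stress values, normalized to sum to 1."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if burn_in >= traj.n_steps:
        raise ValueError("burn_in leaves no samples")
    p = traj.p_stress[burn_in:]
    hist, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    hist = hist / hist.sum()
    total = traj.discounted_return(discount) if discount is not None else float(traj.rewards.sum())
    return OccupancySummary(
        histogram=hist,
        bin_edges=edges,
        mean_stress_probability=float(p.mean()),
        total_expected_reward=total,
    )


# ---------------------------------------------------------------------------
# stationary occupancy of the policy-graph chain
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ComponentOccupancy:
    nodes: frozenset[int]
    reach_probability: float
    conditional: dict[int, float]


@dataclasses.dataclass
class StationaryOccupancy:
    """Long-run node occupancy of the belief network.

    ``probs[i]`` is the overall occupancy of node i: the stationary
    distribution within each terminal component, weighted by the
    probability of being absorbed there from the start node.
    """

    probs: np.ndarray
    components: list[ComponentOccupancy]

    def p_stress_mean(self, graph: PolicyGraph) -> float:
        ps = np.array([n.p_stress for n in graph.nodes])
        return float(self.probs @ ps)


def _stationary_of(P: np.ndarray, tol: float = 1e-12, max_iter: int = 1_000_000) -> np.ndarray:
    """Stationary distribution by power iteration on the lazy chain.

    The lazy chain (P + I)/2 has the same stationary distribution and is
    aperiodic, so power iteration converges even on periodic cycles.
    """
    n = P.shape[0]
    lazy = 0.5 * (P + np.eye(n))
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = pi @ lazy
        if np.max(np.abs(new - pi)) <= tol:
            return new / new.sum()
        pi = new
    return pi / pi.sum()


def graph_stationary_occupancy(graph: PolicyGraph) -> StationaryOccupancy:
    """Analytic long-run occupancy of the policy-graph Markov chain.

    Multiple terminal components are handled by absorbing-chain analysis:
    the reported occupancy is the within-component stationary distribution
    weighted by the probability of reaching that component from the start.
    """
    n = graph.n_nodes
    ids = [node.id for node in graph.nodes]
    pos = {nid: i for i, nid in enumerate(ids)}
    P = np.zeros((n, n))
    for e in graph.edges:
        P[pos[e.source], pos[e.target]] += e.probability
    rowsums = P.sum(axis=1)
    for i in range(n):  # unexpanded (truncated) nodes become self-loops
        if rowsums[i] <= 0:
            P[i, i] = 1.0
        else:
            P[i] /= rowsums[i]

    terminals = absorbing_components(graph)
    term_nodes = set().union(*terminals, frozenset())
    transient = [i for i, nid in enumerate(ids) if nid not in term_nodes]
    reach = np.zeros(len(terminals))
    start = pos[graph.start]
    if graph.start in term_nodes:
        for c, comp in enumerate(terminals):
            reach[c] = 1.0 if graph.start in comp else 0.0
    else:
        tpos = {i: k for k, i in enumerate(transient)}
        Q = P[np.ix_(transient, transient)]
        Bmat = np.zeros((len(transient), len(terminals)))
        for c, comp in enumerate(terminals):
            cols = [pos[nid] for nid in comp]
            Bmat[:, c] = P[np.ix_(transient, cols)].sum(axis=1)
        F = np.linalg.solve(np.eye(len(transient)) - Q, Bmat)
        reach = F[tpos[start]]

    probs = np.zeros(n)
    components = []
    for c, comp in enumerate(terminals):
        cols = [pos[nid] for nid in sorted(comp)]
        sub = P[np.ix_(cols, cols)]
        sub = sub / sub.sum(axis=1, keepdims=True)  # internal edges only
        pi = _stationary_of(sub)
        conditional = {nid: float(p) for nid, p in zip(sorted(comp), pi)}
        components.append(
            ComponentOccupancy(nodes=comp, reach_probability=float(reach[c]), conditional=conditional)
        )
        for nid, p in conditional.items():
            probs[pos[nid]] += reach[c] * p
    return StationaryOccupancy(probs=probs, components=components)


# ---------------------------------------------------------------------------
# solved pipeline and mood comparison
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SolvedMood:
    """A mood model taken through solve → policy → graph with one setting set."""

    name: str
    model: MoodPOMDP
    value_function: GridValueFunction
    policy: Policy
    graph: PolicyGraph


def solve_mood(
    mood: str | MoodPOMDP,
    resolution: int = 20,
    epsilon: float = 1e-8,
    max_sweeps: int = 10_000,
    merge_tol: float = 0.02,
    max_nodes: int = 500,
    b0=None,
) -> SolvedMood:
    model = load_fixture(mood) if isinstance(mood, str) else mood
    V = solve_grid(model, resolution=resolution, epsilon=epsilon, max_sweeps=max_sweeps)
    policy = extract_policy(model, V)
    graph = build_policy_graph(model, policy, b0=b0, merge_tol=merge_tol, max_nodes=max_nodes)
    return SolvedMood(name=model.name, model=model, value_function=V, policy=policy, graph=graph)


def mood_comparison_report(
    solved: Sequence[SolvedMood],
    n_episodes: int = 0,
    n_steps: int = 300,
    seed: int | None = 0,
) -> pd.DataFrame:
    """One row per mood: mean stress probability and total expected reward.

    ``mean_stress_probability`` is the occupancy-weighted mean of node
    p_stress under the stationary distribution of the policy-graph chain
    (the unweighted node mean is reported alongside);
    ``total_expected_reward`` is the solved value function at the start
    belief.  With ``n_episodes > 0`` a Monte-Carlo estimate of the value is
    appended as a check.
    """
    if not solved:
        raise ValueError("no solved moods supplied")
    resolutions = {sm.value_function.resolution for sm in solved}
    merges = {sm.graph.merge_tol for sm in solved}
    if len(resolutions) != 1 or len(merges) != 1:
        raise ValueError(
            f"mismatched solver/graph settings across rows: resolutions={resolutions}, "
            f"merge tolerances={merges}"
        )
    rows = []
    for sm in solved:
        occ = graph_stationary_occupancy(sm.graph)
        ps = np.array([n.p_stress for n in sm.graph.nodes])
        b0 = sm.graph.b0
        row = {
            "mood": sm.name,
            "mean_stress_probability": occ.p_stress_mean(sm.graph),
            "mean_stress_unweighted": float(ps.mean()),
            "total_expected_reward": sm.value_function.value(b0),
            "n_nodes": sm.graph.n_nodes,
        }
        if n_episodes:
            mc, se, _ = estimate_discounted_return(
                sm.model, sm.policy, b0, n_episodes=n_episodes, n_steps=n_steps, seed=seed
            )
            row["mc_return"] = mc
            row["mc_se"] = se
        rows.append(row)
    return pd.DataFrame(rows)
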