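"""Belief-state networks: reachable beliefs under the optimal policy.

The published mood networks are directed graphs whose nodes are the belief
states the agent can actually reach from its starting belief, annotated
with the optimal action there, and whose edges are the observation-triggered
belief transitions, weighted by the predictive probability of each signal.
Terminal strongly connected components of this graph are the formal
counterpart of the "stuck in a loop" phenomenology of depression, mania and
anxiety: once the belief enters such a component no sequence of signals can
take it out.
"""

from __future__ import annotations

import csv
import dataclasses
from typing import Callable, Union

import networkx as nx
import numpy as np
import pandas as pd

from .model import BeliefState, MoodPOMDP, _belief_array, belief_update

DEFAULT_MERGE_TOL = 0.02
DEFAULT_MAX_NODES = 500
_EDGE_PROB_FLOOR = 1e-12


@dataclasses.dataclass(frozen=True)
class GraphNode:
    id: int
    belief: np.ndarray
    action: str
    order: int  # breadth-first discovery order

    @property
    def p_stress(self) -> float:
        return float(self.belief[0])


@dataclasses.dataclass(frozen=True)
class GraphEdge:
    source: int
    target: int
    observation: str
    probability: float


@dataclasses.dataclass
class PolicyGraph:
    nodes: list[GraphNode]
    edges: list[GraphEdge]
    start: int
    merge_tol: float
    b0: np.ndarray
    truncated: bool
    model_hash: str

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_edges(self, node_id: int) -> list[GraphEdge]:
        return [e for e in self.edges if e.source == node_id]

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(
            start=self.start,
            merge_tol=self.merge_tol,
            truncated=self.truncated,
            model_hash=self.model_hash,
        )
        absorbing = set().union(*absorbing_components(self), frozenset())
        for n in self.nodes:
            g.add_node(
                n.id,
                p_stress=n.p_stress,
                action=n.action,
                is_absorbing=n.id in absorbing,
                belief=",".join(repr(float(x)) for x in n.belief),
            )
        for e in self.edges:
            g.add_edge(
                e.source, e.target, observation=e.observation, probability=e.probability
            )
        return g


def build_policy_graph(
    model: MoodPOMDP,
    policy: Callable[[np.ndarray], str],
    b0=None,
    merge_tol: float = DEFAULT_MERGE_TOL,
    max_nodes: int = DEFAULT_MAX_NODES,
) -> PolicyGraph:
    """Breadth-first expansion of the belief set reachable under ``policy``.

    From each node's belief the optimal action is taken; every observation
    with positive predictive probability spawns a successor belief, which is
    merged into an existing node when within ``merge_tol`` (sup-norm) of it,
    else becomes a new node.  Expansion stops when the frontier is empty or
    ``max_nodes`` is reached (the graph is then flagged truncated).
    """
    if merge_tol <= 0:
        raise ValueError("merge_tol must be positive")
    b0v = model.uniform_belief().probs if b0 is None else _belief_array(model, b0)
    beliefs: list[np.ndarray] = [b0v]
    nodes: list[GraphNode] = []
    edges: list[GraphEdge] = []
    frontier = [0]
    expanded: set[int] = set()
    truncated = False

    def merge_target(b: np.ndarray) -> int | None:
        for i, existing in enumerate(beliefs):
            if np.max(np.abs(existing - b)) <= merge_tol:
                return i
        return None

    while frontier:
        nid = frontier.pop(0)
        if nid in expanded:
            continue
        expanded.add(nid)
        b = beliefs[nid]
        action = policy(b)
        ai = model.action_index(action)
        nodes.append(GraphNode(id=nid, belief=b, action=model.action_labels[ai], order=len(nodes)))
        prior = b @ model.transition[ai]
        for oi, obs in enumerate(model.observation_labels):
            p = float(prior @ model.likelihood[ai, :, oi])
            if p <= _EDGE_PROB_FLOOR:
                continue
            succ = belief_update(model, b, ai, oi).probs
            target = merge_target(succ)
            if target is None:
                if len(beliefs) >= max_nodes:
                    truncated = True
                    continue
                target = len(beliefs)
                beliefs.append(succ)
                frontier.append(target)
            elif target not in expanded and target not in frontier:
                frontier.append(target)
            edges.append(GraphEdge(source=nid, target=target, observation=obs, probability=p))

    nodes.sort(key=lambda n: n.id)
    return PolicyGraph(
        nodes=nodes,
        edges=edges,
        start=0,
        merge_tol=merge_tol,
        b0=b0v,
        truncated=truncated,
        model_hash=model.model_hash(),
    )


def _simple_digraph(graph: PolicyGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(n.id for n in graph.nodes)
    for e in graph.edges:
        if g.has_edge(e.source, e.target):
            g[e.source][e.target]["probability"] += e.probability
        else:
            g.add_edge(e.source, e.target, probability=e.probability)
    return g


def absorbing_components(graph: PolicyGraph) -> list[frozenset[int]]:
    """Terminal strongly connected components — belief sets with no escape.

    Returned in deterministic order (ascending smallest node id); their
    union is exactly the set of nodes from which no escape exists.
    """
    g = _simple_digraph(graph)
    cond = nx.condensation(g)
    terminal = [
        frozenset(cond.nodes[c]["members"])
        for c in cond.nodes
        if cond.out_degree(c) == 0
    ]
    return sorted(terminal, key=min)


def node_summary_table(graph: PolicyGraph) -> pd.DataFrame:
    """One row per node (id, p_stress, action, is_absorbing), by p_stress."""
    absorbing = set().union(*absorbing_components(graph), frozenset())
    rows = [
        {
            "node": n.id,
            "p_stress": n.p_stress,
            "action": n.action,
            "is_absorbing": n.id in absorbing,
        }
        for n in graph.nodes
    ]
    df = pd.DataFrame(rows, columns=["node", "p_stress", "action", "is_absorbing"])
    return df.sort_values(["p_stress", "node"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_graphml(graph: PolicyGraph, path) -> None:
    nx.write_graphml(graph.to_networkx(), path)


def write_dot(graph: PolicyGraph, path) -> None:
    """Minimal DOT writer (no third-party renderer required)."""
    absorbing = set().union(*absorbing_components(graph), frozenset())
    lines = ["digraph policy {", "  rankdir=LR;"]
    for n in graph.nodes:
        shape = "doublecircle" if n.id in absorbing else "circle"
        label = f"{n.action}\\np(stress)={n.p_stress:.3f}"
        lines.append(f'  n{n.id} [label="{label}", shape={shape}];')
    for e in graph.edges:
        label = f"{e.observation} ({e.probability:.3f})"
        lines.append(f'  n{e.source} -> n{e.target} [label="{label}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_node_table(graph: PolicyGraph, path) -> None:
    node_summary_table(graph).to_csv(path, index=False)
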