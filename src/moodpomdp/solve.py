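"""Bellman-optimal planning in belief space.

Two solution representations are provided:

* :func:`exact_finite_horizon` — the exact finite-horizon solution as a set
  of alpha-vectors (one linear piece per undominated conditional plan),
  built by exhaustive cross-sum backups with dominance pruning.  Intended
  for small instances; it is the oracle the grid solver is tested against.
* :func:`solve_grid` — the fixed-grid approximation used for the mood
  models: beliefs are discretized on a regular simplex lattice, value
  iteration is run on the grid with convex-combination interpolation, and
  the converged values upper-bound the true optimal value function at the
  grid points.

Greedy one-step lookahead against either representation yields the policy.
Ties between actions are broken toward the earliest action in the model's
canonical action order (within ``TIE_TOL``), so solved policies and the
graphs built from them are reproducible.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Sequence, Union

import numpy as np
import yaml

from .model import BeliefState, MoodPOMDP, _belief_array

TIE_TOL = 1e-12
SOLVER_FORMAT = "moodpomdp-value/1"


class SolverResourceError(RuntimeError):
    """Exact solve would exceed the configured alpha-vector cap."""


# ---------------------------------------------------------------------------
# value-function representations
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AlphaVectorSet:
    """Piecewise-linear convex value function: V(b) = max_k <vectors[k], b>."""

    vectors: np.ndarray  # (K, S)
    actions: np.ndarray  # (K,) action indices
    horizon: int
    discount: float

    def value(self, b) -> float:
        b = np.asarray(b, dtype=float)
        return float((self.vectors @ b).max())

    def value_batch(self, B: np.ndarray) -> np.ndarray:
        return (np.asarray(B, float) @ self.vectors.T).max(axis=1)

    def __len__(self) -> int:
        return len(self.vectors)


@dataclasses.dataclass(frozen=True)
class GridValueFunction:
    """Values on a regular belief lattice with convex-combination interpolation.

    Only the two-state path is exercised by the mood models; there the grid
    is the uniform partition of [0, 1] in the first state's probability and
    interpolation is linear between the two bracketing points (the unique
    convex combination).  The multi-state generalization is barycentric
    interpolation within the enclosing simplex cell of the Freudenthal
    lattice.
    """

    points: np.ndarray  # (G, S) grid beliefs
    values: np.ndarray  # (G,)
    resolution: int
    sweeps: int
    residual: float
    converged: bool
    epsilon: float
    discount: float
    model_hash: str = ""

    def value(self, b) -> float:
        return float(self.value_batch(np.asarray(b, float)[None, :])[0])

    def value_batch(self, B: np.ndarray) -> np.ndarray:
        B = np.asarray(B, dtype=float)
        if self.points.shape[1] != 2:
            raise NotImplementedError("interpolation implemented for two-state models")
        return np.interp(B[:, 0], self.points[:, 0], self.values)

    def __len__(self) -> int:
        return len(self.values)


ValueFn = Union[AlphaVectorSet, GridValueFunction, Callable[[np.ndarray], np.ndarray]]


def _value_batch(V: ValueFn) -> Callable[[np.ndarray], np.ndarray]:
    if hasattr(V, "value_batch"):
        return V.value_batch  # type: ignore[union-attr]
    return V  # plain callable on (N, S) -> (N,)


# ---------------------------------------------------------------------------
# backup
# ---------------------------------------------------------------------------

def backup_q_values(model: MoodPOMDP, B: np.ndarray, V: ValueFn) -> np.ndarray:
    """One-step lookahead Q(b, a) for a batch of beliefs, shape (N, A).

    Q(b, a) = sum_s b(s) R[a, s] + gamma * sum_o P(o | b, a) V(b').
    Observation branches with zero predictive probability contribute 0.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    vfun = _value_batch(V)
    N = B.shape[0]
    Q = np.empty((N, model.n_actions))
    for a in range(model.n_actions):
        prior = B @ model.transition[a]  # (N, S')
        q = B @ model.reward[a]
        for o in range(model.n_observations):
            numer = prior * model.likelihood[a, :, o]  # (N, S')
            p = numer.sum(axis=1)
            pos = p > 0.0
            if np.any(pos):
                b_next = numer[pos] / p[pos, None]
                q = q + model.discount * np.where(pos, p, 0.0) * _scatter(vfun, b_next, pos, N)
        Q[:, a] = q
    return Q


def _scatter(vfun, b_next, mask, n):
    out = np.zeros(n)
    out[mask] = vfun(b_next)
    return out


def _greedy(Q: np.ndarray, tie_tol: float = TIE_TOL) -> np.ndarray:
    """First action within ``tie_tol`` of the row maximum (canonical order)."""
    qmax = Q.max(axis=1, keepdims=True)
    return np.argmax(Q >= qmax - tie_tol, axis=1)


def bellman_backup(model: MoodPOMDP, b, V: ValueFn, tie_tol: float = TIE_TOL):
    """Optimal one-step value and maximizing action at a single belief."""
    bv = _belief_array(model, b)
    Q = backup_q_values(model, bv[None, :], V)[0]
    a = int(_greedy(Q[None, :], tie_tol)[0])
    return float(Q[a]), model.action_labels[a]


# ---------------------------------------------------------------------------
# exact finite-horizon solve
# ---------------------------------------------------------------------------

def _prune(vectors: np.ndarray, actions: np.ndarray, tol: float = 1e-12):
    """Drop duplicate, pointwise-dominated and never-maximal vectors.

    For two-state models the surviving set is the exact upper envelope:
    every vector attains the maximum somewhere on the belief segment
    (checked at the endpoints and at all pairwise crossing points).
    """
    # exact duplicates
    order = np.lexsort(vectors.T[::-1])
    vectors, actions = vectors[order], actions[order]
    keep = np.ones(len(vectors), dtype=bool)
    for i in range(1, len(vectors)):
        if np.allclose(vectors[i], vectors[i - 1], rtol=0.0, atol=tol) and actions[i] == actions[i - 1]:
            keep[i] = False
    vectors, actions = vectors[keep], actions[keep]

    # pointwise dominance
    keep = np.ones(len(vectors), dtype=bool)
    for i in range(len(vectors)):
        if not keep[i]:
            continue
        dominated = np.all(vectors <= vectors[i] + tol, axis=1) & keep
        dominated[i] = False
        strictly = dominated & np.any(vectors < vectors[i] - tol, axis=1)
        keep[strictly] = False
    vectors, actions = vectors[keep], actions[keep]

    if vectors.shape[1] != 2 or len(vectors) <= 2:
        return vectors, actions

    # upper-envelope prune for the 1-D belief segment
    slopes = vectors[:, 0] - vectors[:, 1]
    inter = vectors[:, 1]
    ps = [0.0, 1.0]
    for i, j in itertools.combinations(range(len(vectors)), 2):
        ds = slopes[i] - slopes[j]
        if abs(ds) > tol:
            p = (inter[j] - inter[i]) / ds
            if 0.0 < p < 1.0:
                ps.append(p)
    ps = np.asarray(ps)
    vals = inter[None, :] + np.outer(ps, slopes)  # (P, K)
    maxima = vals.max(axis=1, keepdims=True)
    useful = np.any(vals >= maxima - 1e-11, axis=0)
    return vectors[useful], actions[useful]


def exact_finite_horizon(
    model: MoodPOMDP,
    horizon: int,
    max_vectors: int = 100_000,
) -> AlphaVectorSet:
    """Exact value of acting optimally for ``horizon`` steps.

    Classic exhaustive backup: for each action, every combination of
    observation-conditioned continuation vectors is cross-summed onto the
    immediate reward vector, then the union over actions is pruned.  Raises
    :class:`SolverResourceError` if the unpruned candidate count would
    exceed ``max_vectors``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    A, S, O = model.n_actions, model.n_states, model.n_observations
    gamma = model.discount
    vectors = model.reward.copy()  # horizon-1 set: one vector per action
    actions = np.arange(A)
    vectors, actions = _prune(vectors, actions)
    for _ in range(horizon - 1):
        K = vectors.shape[0]
        if A * K**O > max_vectors:
            raise SolverResourceError(
                f"cross-sum would produce {A * K**O} vectors (cap {max_vectors})"
            )
        cand_v, cand_a = [], []
        for a in range(A):
            # back-projections g_{a,o,k}(s) = gamma * sum_s' T[a,s,s'] Z[a,s',o] alpha_k(s')
            proj = [
                gamma * (model.transition[a] @ (model.likelihood[a, :, o, None] * vectors.T))
                for o in range(O)
            ]  # each (S, K)
            for combo in itertools.product(range(K), repeat=O):
                v = model.reward[a].copy()
                for o, k in enumerate(combo):
                    v = v + proj[o][:, k]
                cand_v.append(v)
                cand_a.append(a)
        vectors = np.asarray(cand_v)
        actions = np.asarray(cand_a)
        vectors, actions = _prune(vectors, actions)
    return AlphaVectorSet(vectors=vectors, actions=actions, horizon=horizon, discount=gamma)


# ---------------------------------------------------------------------------
# fixed-grid value iteration
# ---------------------------------------------------------------------------

def simplex_grid(n_states: int, resolution: int) -> np.ndarray:
    """Regular lattice on the probability simplex, (G, S).

    For two states this is the uniform partition of [0, 1] into
    ``resolution`` intervals (resolution + 1 points).
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if n_states == 2:
        x = np.linspace(0.0, 1.0, resolution + 1)
        return np.column_stack([x, 1.0 - x])
    pts = [
        np.array(c, dtype=float) / resolution
        for c in _compositions(resolution, n_states)
    ]
    return np.asarray(pts)


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _compositions(total - head, parts - 1):
            yield (head, *tail)


def solve_grid(
    model: MoodPOMDP,
    resolution: int = 20,
    epsilon: float = 1e-8,
    max_sweeps: int = 10_000,
    v0: np.ndarray | None = None,
) -> GridValueFunction:
    """Fixed-grid value iteration with convex-combination interpolation.

    Synchronous sweeps of the interpolated Bellman operator until the
    sup-norm change is at most ``epsilon`` or ``max_sweeps`` is reached (the
    result is then flagged non-converged, never silently truncated).  The
    converged grid values upper-bound the exact optimal value at the grid
    points; sweep-matched runs upper-bound the exact finite-horizon value.
    """
    if model.n_states != 2:
        raise NotImplementedError("grid interpolation implemented for two-state models")
    if not model.discount < 1.0:
        raise ValueError("discount must be < 1 for the infinite-horizon solution")
    points = simplex_grid(model.n_states, resolution)
    values = np.zeros(len(points)) if v0 is None else np.asarray(v0, float).copy()
    xs = points[:, 0]
    residual = np.inf
    sweeps = 0
    while sweeps < max_sweeps:
        interp = lambda B: np.interp(np.asarray(B, float)[:, 0], xs, values)  # noqa: E731
        new = backup_q_values(model, points, interp).max(axis=1)
        residual = float(np.max(np.abs(new - values)))
        values = new
        sweeps += 1
        if residual <= epsilon:
            break
    return GridValueFunction(
        points=points,
        values=values,
        resolution=resolution,
        sweeps=sweeps,
        residual=residual,
        converged=residual <= epsilon,
        epsilon=epsilon,
        discount=model.discount,
        model_hash=model.model_hash(),
    )


# ---------------------------------------------------------------------------
# policy
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Policy:
    """Greedy one-step lookahead against a value function.

    Deterministic and total over the belief simplex; ties broken toward the
    earliest action in canonical order (tie-break rule ``"canonical_order"``).
    """

    model: MoodPOMDP
    value_function: ValueFn
    tie_tol: float = TIE_TOL
    tie_break: str = "canonical_order"

    def action_indices(self, B: np.ndarray) -> np.ndarray:
        Q = backup_q_values(self.model, B, self.value_function)
        return _greedy(Q, self.tie_tol)

    def action_index(self, b) -> int:
        bv = _belief_array(self.model, b)
        return int(self.action_indices(bv[None, :])[0])

    def __call__(self, b) -> str:
        return self.model.action_labels[self.action_index(b)]


def extract_policy(model: MoodPOMDP, V: ValueFn, tie_tol: float = TIE_TOL) -> Policy:
    """The greedy policy induced by a solved value function."""
    return Policy(model=model, value_function=V, tie_tol=tie_tol)


# ---------------------------------------------------------------------------
# artifact round-trip
# ---------------------------------------------------------------------------

def value_function_to_dict(V: GridValueFunction) -> dict:
    return {
        "format": SOLVER_FORMAT,
        "model_hash": V.model_hash,
        "resolution": V.resolution,
        "epsilon": V.epsilon,
        "discount": V.discount,
        "sweeps": V.sweeps,
        "residual": V.residual,
        "converged": bool(V.converged),
        "points": V.points.tolist(),
        "values": V.values.tolist(),
    }


def save_value_function(V: GridValueFunction, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(value_function_to_dict(V), fh, sort_keys=False)


def load_value_function(path) -> GridValueFunction:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format") != SOLVER_FORMAT:
        raise ValueError(f"unsupported solver artifact format {doc.get('format')!r}")
    return GridValueFunction(
        points=np.asarray(doc["points"], float),
        values=np.asarray(doc["values"], float),
        resolution=int(doc["resolution"]),
        sweeps=int(doc["sweeps"]),
        residual=float(doc["residual"]),
        converged=bool(doc["converged"]),
        epsilon=float(doc["epsilon"]),
        discount=float(doc["discount"]),
        model_hash=str(doc["model_hash"]),
    )
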