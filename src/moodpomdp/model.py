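"""Labelled POMDP containers, validation and Bayesian belief updating.

The generative model is a discrete partially observable Markov decision
process (POMDP): hidden environment states (here: stressful / not
stressful), signal observations (stress / pleasure signals), interoceptive
control actions (attenuating, amplifying or passively receiving signals),
an (action, state) reward matrix in negative-surprisal units (nats) and a
geometric discount.  The agent never sees the environment state; it holds a
*belief state* — a posterior probability vector over hidden states — which
in this model plays the role of the agent's mood.  Everything downstream
(planning, policy graphs, simulation) consumes the two primitives defined
here: the predictive observation probability and the Bayes belief update.

Conventions
-----------
* ``transition[a, s, s2]`` — probability the environment moves to ``s2``
  given it is in ``s`` and the agent takes action ``a``.
* ``likelihood[a, s2, o]`` — probability of registering signal ``o`` in the
  arrived-at state ``s2`` under action ``a`` (transition-then-observe).
* ``reward[a, s]`` — expected immediate reward for taking ``a`` in ``s``.
* Probability rows must sum to 1 within ``PROB_TOL``; nothing is
  renormalized silently (see :func:`renormalized`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Iterator, Sequence, Union

import numpy as np
import yaml

PROB_TOL = 1e-9
MODEL_FORMAT = "moodpomdp-model/1"

#: canonical label orders, fixed so tensor indices are reproducible across
#: runs and file round-trips
CANONICAL_STATES = ("stressful", "not_stressful")
CANONICAL_OBSERVATIONS = ("stress_signal", "pleasure_signal")
CANONICAL_ACTIONS = (
    "attenuate_pleasure",
    "amplify_pleasure",
    "attenuate_stress",
    "amplify_stress",
    "wait",
)


class LabelError(KeyError):
    """Unknown state/observation/action label."""


class ImpossibleObservationError(ValueError):
    """Bayes update conditioned on an observation with zero predictive probability."""


class ModelValidationError(ValueError):
    """A model spec file (or constructed model) violates the POMDP invariants."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(str(report))


def _as_prob_vector(x, n: int, what: str) -> np.ndarray:
    p = np.asarray(x, dtype=float).reshape(-1)
    if p.shape != (n,):
        raise ValueError(f"{what}: expected length {n}, got {p.shape}")
    if np.any(p < -PROB_TOL) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"{what}: not a probability vector (sum={p.sum()!r})")
    return np.clip(p, 0.0, None)


@dataclasses.dataclass(frozen=True)
class BeliefState:
    """Posterior probability over hidden environment states.

    In this model the belief doubles as the agent's internal emotional
    state: ``p_stress`` is the probability it assigns to the environment
    being stressful.
    """

    probs: np.ndarray
    state_labels: tuple[str, ...] = CANONICAL_STATES

    def __post_init__(self):
        p = _as_prob_vector(self.probs, len(self.state_labels), "belief")
        if abs(p.sum() - 1.0) > PROB_TOL:
            p = p / p.sum()  # repair float drift only; gross errors raised above
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "state_labels", tuple(self.state_labels))

    @property
    def p_stress(self) -> float:
        """Probability mass on the 'stressful' state (state 0 if unlabelled)."""
        try:
            i = self.state_labels.index("stressful")
        except ValueError:
            i = 0
        return float(self.probs[i])

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)

    def __getitem__(self, label: Union[str, int]) -> float:
        if isinstance(label, str):
            if label not in self.state_labels:
                raise LabelError(label)
            return float(self.probs[self.state_labels.index(label)])
        return float(self.probs[label])

    def __len__(self) -> int:
        return len(self.probs)


@dataclasses.dataclass(frozen=True)
class MoodPOMDP:
    """Full generative model of mood updating.

    ``transition`` has shape (A, S, S), ``likelihood`` (A, S, O) and
    ``reward`` (A, S), with axes following the label tuples.
    """

    state_labels: tuple[str, ...]
    observation_labels: tuple[str, ...]
    action_labels: tuple[str, ...]
    transition: np.ndarray
    likelihood: np.ndarray
    reward: np.ndarray
    discount: float
    name: str = ""

    def __post_init__(self):
        for field in ("state_labels", "observation_labels", "action_labels"):
            object.__setattr__(self, field, tuple(getattr(self, field)))
        for field in ("transition", "likelihood", "reward"):
            arr = np.asarray(getattr(self, field), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, field, arr)
        object.__setattr__(self, "discount", float(self.discount))

    # -- sizes ------------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_observations(self) -> int:
        return len(self.observation_labels)

    @property
    def n_actions(self) -> int:
        return len(self.action_labels)

    # -- label lookup ------------------------------------------------------
    def state_index(self, s: Union[str, int]) -> int:
        return self._index(s, self.state_labels, "state")

    def observation_index(self, o: Union[str, int]) -> int:
        return self._index(o, self.observation_labels, "observation")

    def action_index(self, a: Union[str, int]) -> int:
        return self._index(a, self.action_labels, "action")

    @staticmethod
    def _index(x, labels: tuple[str, ...], kind: str) -> int:
        if isinstance(x, str):
            try:
                return labels.index(x)
            except ValueError:
                raise LabelError(f"unknown {kind} label {x!r}; known: {labels}") from None
        i = int(x)
        if not 0 <= i < len(labels):
            raise LabelError(f"{kind} index {i} out of range 0..{len(labels) - 1}")
        return i

    def uniform_belief(self) -> BeliefState:
        return BeliefState(np.full(self.n_states, 1.0 / self.n_states), self.state_labels)

    def belief(self, probs) -> BeliefState:
        return BeliefState(np.asarray(probs, dtype=float), self.state_labels)

    def model_hash(self) -> str:
        """Content hash over labels, tensors (shortest-repr floats) and discount."""
        doc = {
            "states": list(self.state_labels),
            "observations": list(self.observation_labels),
            "actions": list(self.action_labels),
            "transition": self.transition.tolist(),
            "likelihood": self.likelihood.tolist(),
            "reward": self.reward.tolist(),
            "discount": self.discount,
        }
        blob = json.dumps(doc, sort_keys=True, separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Violation:
    location: str
    message: str

    def __str__(self) -> str:
        return f"{self.location}: {self.message}"


@dataclasses.dataclass
class ValidationReport:
    violations: list[Violation] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, location: str, message: str) -> None:
        self.violations.append(Violation(location, message))

    def __iter__(self) -> Iterator[Violation]:
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)

    def __str__(self) -> str:
        if self.ok:
            return "valid model (no violations)"
        return "\n".join(str(v) for v in self.violations)


def validate_model(model: MoodPOMDP) -> ValidationReport:
    """Check every structural invariant; never raises, reports all violations."""
    rep = ValidationReport()
    for kind, labels in (
        ("state_labels", model.state_labels),
        ("observation_labels", model.observation_labels),
        ("action_labels", model.action_labels),
    ):
        if len(labels) == 0:
            rep.add(kind, "empty label list")
        if len(set(labels)) != len(labels):
            rep.add(kind, f"duplicate labels in {labels}")

    A, S, O = model.n_actions, model.n_states, model.n_observations
    if model.transition.shape != (A, S, S):
        rep.add("transition", f"shape {model.transition.shape} != {(A, S, S)}")
    if model.likelihood.shape != (A, S, O):
        rep.add("likelihood", f"shape {model.likelihood.shape} != {(A, S, O)}")
    if model.reward.shape != (A, S):
        rep.add("reward", f"shape {model.reward.shape} != {(A, S)}")
    if rep.violations:
        return rep  # row checks would be meaningless on mis-shaped tensors

    for name, tensor in (("transition", model.transition), ("likelihood", model.likelihood)):
        neg = np.argwhere(tensor < 0)
        for idx in neg:
            rep.add(f"{name}[{', '.join(map(str, idx))}]", "negative probability")
        sums = tensor.sum(axis=-1)
        bad = np.argwhere(np.abs(sums - 1.0) > PROB_TOL)
        for idx in bad:
            rep.add(
                f"{name}[{', '.join(map(str, idx))}, :]",
                f"row sums to {sums[tuple(idx)]!r}, expected 1",
            )

    nonfinite = np.argwhere(~np.isfinite(model.reward))
    for idx in nonfinite:
        rep.add(f"reward[{idx[0]}, {idx[1]}]", "non-finite reward entry")

    if not (0.0 <= model.discount < 1.0):
        rep.add("discount", f"{model.discount!r} outside [0, 1)")
    return rep


def renormalized(model: MoodPOMDP) -> MoodPOMDP:
    """Explicitly renormalize probability rows (never done implicitly)."""
    T = np.asarray(model.transition, dtype=float)
    Z = np.asarray(model.likelihood, dtype=float)
    T = T / T.sum(axis=-1, keepdims=True)
    Z = Z / Z.sum(axis=-1, keepdims=True)
    return dataclasses.replace(model, transition=T, likelihood=Z)


# ---------------------------------------------------------------------------
# belief machinery
# ---------------------------------------------------------------------------

def _belief_array(model: MoodPOMDP, b) -> np.ndarray:
    if isinstance(b, BeliefState):
        arr = b.probs
    else:
        arr = _as_prob_vector(b, model.n_states, "belief")
    if abs(arr.sum() - 1.0) > 1e-6:
        raise ValueError(f"belief does not sum to 1: {arr!r}")
    return arr


def predictive_observation_prob(model: MoodPOMDP, b, a, o) -> float:
    """P(o | b, a) = sum_s2 Z[a, s2, o] * sum_s T[a, s, s2] * b(s)."""
    ai = model.action_index(a)
    oi = model.observation_index(o)
    bv = _belief_array(model, b)
    prior = bv @ model.transition[ai]
    return float(prior @ model.likelihood[ai, :, oi])


def belief_update(model: MoodPOMDP, b, a, o) -> BeliefState:
    """Bayes posterior over the arrived-at state after acting and observing.

    b'(s2) proportional to Z[a, s2, o] * sum_s T[a, s, s2] * b(s).

    Raises :class:`ImpossibleObservationError` when the observation has zero
    predictive probability under (b, a) — never returns NaN.
    """
    ai = model.action_index(a)
    oi = model.observation_index(o)
    bv = _belief_array(model, b)
    numer = model.likelihood[ai, :, oi] * (bv @ model.transition[ai])
    total = numer.sum()
    if total <= 0.0:
        raise ImpossibleObservationError(
            f"observation {model.observation_labels[oi]!r} has zero predictive "
            f"probability under action {model.action_labels[ai]!r} at belief {bv}"
        )
    return BeliefState(numer / total, model.state_labels)


def relabel(
    model: MoodPOMDP,
    state_perm: Sequence[int],
    observation_perm: Sequence[int],
    action_perm: Sequence[int],
    new_labels: tuple[Sequence[str], Sequence[str], Sequence[str]] | None = None,
) -> MoodPOMDP:
    """Apply consistent permutations to every axis of every tensor.

    ``state_perm[i]`` is the old index that lands at new position ``i``.
    When ``new_labels`` is None the labels are carried along with the
    permutation (a pure reordering); otherwise the new label tuples are used
    (a relabelling, e.g. mirroring stress onto pleasure).
    """
    sp = np.asarray(state_perm, int)
    op = np.asarray(observation_perm, int)
    ap = np.asarray(action_perm, int)
    T = model.transition[np.ix_(ap, sp, sp)]
    Z = model.likelihood[np.ix_(ap, sp, op)]
    R = model.reward[np.ix_(ap, sp)]
    if new_labels is None:
        labels = (
            tuple(model.state_labels[i] for i in sp),
            tuple(model.observation_labels[i] for i in op),
            tuple(model.action_labels[i] for i in ap),
        )
    else:
        labels = tuple(tuple(x) for x in new_labels)  # type: ignore[assignment]
    return MoodPOMDP(
        state_labels=labels[0],
        observation_labels=labels[1],
        action_labels=labels[2],
        transition=T,
        likelihood=Z,
        reward=R,
        discount=model.discount,
        name=model.name,
    )


# ---------------------------------------------------------------------------
# model spec files
# ---------------------------------------------------------------------------

_OPTIONAL_KEYS = {"name", "metadata"}
_REQUIRED_KEYS = {
    "format",
    "states",
    "observations",
    "actions",
    "transition",
    "likelihood",
    "reward",
    "discount",
}


def model_to_dict(model: MoodPOMDP) -> dict:
    return {
        "format": MODEL_FORMAT,
        "name": model.name,
        "states": list(model.state_labels),
        "observations": list(model.observation_labels),
        "actions": list(model.action_labels),
        "transition": model.transition.tolist(),
        "likelihood": model.likelihood.tolist(),
        "reward": model.reward.tolist(),
        "discount": model.discount,
    }


def model_from_dict(doc: dict, source: str = "<dict>") -> MoodPOMDP:
    unknown = set(doc) - _REQUIRED_KEYS - _OPTIONAL_KEYS
    missing = _REQUIRED_KEYS - set(doc)
    rep = ValidationReport()
    for k in sorted(unknown):
        rep.add(source, f"unknown key {k!r}")
    for k in sorted(missing):
        rep.add(source, f"missing key {k!r}")
    if doc.get("format") != MODEL_FORMAT and "format" in doc:
        rep.add(source, f"unsupported format {doc.get('format')!r}, expected {MODEL_FORMAT!r}")
    if rep.violations:
        raise ModelValidationError(rep)
    model = MoodPOMDP(
        state_labels=tuple(doc["states"]),
        observation_labels=tuple(doc["observations"]),
        action_labels=tuple(doc["actions"]),
        transition=np.asarray(doc["transition"], dtype=float),
        likelihood=np.asarray(doc["likelihood"], dtype=float),
        reward=np.asarray(doc["reward"], dtype=float),
        discount=float(doc["discount"]),
        name=str(doc.get("name", "")),
    )
    report = validate_model(model)
    if not report.ok:
        raise ModelValidationError(report)
    return model


def write_model(model: MoodPOMDP, path) -> None:
    """Write the model spec as YAML.

    Floats are emitted in Python shortest-repr form, which round-trips
    bit-identically (stronger than 17 significant digits).
    """
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def read_model(path) -> MoodPOMDP:
    """Read and validate a model spec file; invalid rows raise with indices."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        rep = ValidationReport()
        rep.add(str(path), "not a mapping document")
        raise ModelValidationError(rep)
    return model_from_dict(doc, source=str(path))
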