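"""The four canonical mood parameterizations and surprisal-based reward.

A mood, in this model, is a set of prior beliefs about the interoceptive
consequences of action: the likelihood tensor says how readily stressful and
pleasurable environments produce stress and pleasure signals under each
sensory-control action, and the transition tensor says how persistent the
agent believes the environment to be.  The four archetypes differ only in
those two tensors:

* healthy     — sharp, state-congruent likelihoods: stressful environments
                yield stress signals, non-stressful ones pleasure signals.
* depression  — stress signals expected with high probability in *every*
                state and under *every* action (action-independent stress
                prior), and a sticky stressful environment.
* mania       — the exact mirror image of depression (states, signals and
                stress/pleasure actions swapped).
* anxiety     — low-precision likelihoods: every likelihood row is closer to
                uniform than the healthy counterpart, so no signal is ever
                very informative.

Action semantics are channel gain control on the two signal channels:
``amplify_X`` multiplies the odds of registering signal X in every state
(gain > 1); ``attenuate_X`` multiplies the probability of registering X in
every state (suppression factor < 1); ``wait`` leaves the baseline
likelihood untouched.  Rows are renormalized over the complementary signal,
so both operators are exact mirror images of themselves under the
stress/pleasure swap.

Reward is the expected negative surprisal of outcomes: the log prior
preference of the signal plus the log evidence the agent's own model assigns
to it.  Minimizing expected free energy with no epistemic term is then
ordinary Bellman optimality against this matrix.

The canonical numeric values live in versioned fixture files
(``fixtures/*.yaml``); the calibration search that produced them ships as
``scripts/calibrate_fixtures.py``.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np

from .model import (
    CANONICAL_ACTIONS,
    CANONICAL_OBSERVATIONS,
    CANONICAL_STATES,
    MoodPOMDP,
    model_from_dict,
    relabel,
)

MOOD_LABELS = ("healthy", "depression", "mania", "anxiety")


@dataclasses.dataclass(frozen=True)
class PreferenceDistribution:
    """Prior preference C(o) over observations; plays the role of reward.

    Entries must be strictly positive (log-preferences must be finite) and
    sum to one.
    """

    probs: np.ndarray
    observation_labels: tuple[str, ...] = CANONICAL_OBSERVATIONS

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float).reshape(-1)
        if p.shape != (len(self.observation_labels),):
            raise ValueError("preference length does not match observation labels")
        if np.any(p <= 0.0):
            raise ValueError("infinite surprisal: preference entries must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"preferences must sum to 1, got {p.sum()!r}")
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "observation_labels", tuple(self.observation_labels))

    def __getitem__(self, o) -> float:
        if isinstance(o, str):
            o = self.observation_labels.index(o)
        return float(self.probs[o])

    def log(self) -> np.ndarray:
        return np.log(self.probs)


@dataclasses.dataclass(frozen=True)
class MoodParameterization:
    """A mood archetype before reward construction."""

    mood_label: str
    transition: np.ndarray
    likelihood: np.ndarray
    preferences: PreferenceDistribution
    discount: float

    def to_model(self, name: str | None = None) -> MoodPOMDP:
        R = free_energy_reward(self.preferences, self.likelihood, self.transition)
        return MoodPOMDP(
            state_labels=CANONICAL_STATES,
            observation_labels=CANONICAL_OBSERVATIONS,
            action_labels=CANONICAL_ACTIONS,
            transition=np.asarray(self.transition, float),
            likelihood=np.asarray(self.likelihood, float),
            reward=R,
            discount=self.discount,
            name=name or self.mood_label,
        )


def surprisal_reward(preferences: PreferenceDistribution, likelihood) -> np.ndarray:
    """Preference-only reward: R[a, s] = sum_o Z[a, s, o] * ln C(o).

    This is the pragmatic (risk) component of expected free energy — the
    expected log prior preference of the signal generated in state ``s``
    under action ``a``.  All entries are finite and non-positive.
    """
    Z = np.asarray(likelihood, dtype=float)
    logc = preferences.log()
    if Z.shape[-1] != logc.shape[0]:
        raise ValueError("likelihood observation axis does not match preferences")
    return Z @ logc


def free_energy_reward(preferences: PreferenceDistribution, likelihood, transition) -> np.ndarray:
    """Expected free energy (negated, no epistemic term) as an (A, S) matrix.

    The per-outcome reward is ln C(o) + ln Z[a, s', o]: the log preference
    for the signal plus the log evidence the agent's model assigns to it —
    so sharp, preference-congruent likelihoods score best and flat
    (ambiguous) likelihoods are penalized by their entropy.  The matrix is
    indexed by the state the action is taken *in*, so the outcome term is
    averaged over the transition: R[a, s] = sum_s' T[a, s, s'] *
    sum_o Z[a, s', o] (ln C(o) + ln Z[a, s', o]).
    """
    Z = np.asarray(likelihood, dtype=float)
    T = np.asarray(transition, dtype=float)
    logc = preferences.log()
    with np.errstate(divide="ignore", invalid="ignore"):
        zlogz = np.where(Z > 0.0, Z * np.log(np.where(Z > 0.0, Z, 1.0)), 0.0)
    per_arrival = Z @ logc + zlogz.sum(axis=-1)  # (A, S')
    return np.einsum("ast,at->as", T, per_arrival)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _amplify(col: np.ndarray, gain: float) -> np.ndarray:
    """Multiply the odds of the signal by ``gain`` in every state."""
    odds = col / (1.0 - col)
    new = gain * odds
    return new / (1.0 + new)

def _attenuate(col: np.ndarray, kappa: float) -> np.ndarray:
    """Multiply the probability of the signal by ``kappa`` in every state."""
    return kappa * col


def _per_channel(value, what: str) -> tuple[float, float]:
    """Accept a scalar (both channels) or a (stress, pleasure) pair."""
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size == 1:
        return float(arr[0]), float(arr[0])
    if arr.size == 2:
        return float(arr[0]), float(arr[1])
    raise ValueError(f"{what}: expected scalar or (stress, pleasure) pair")


def action_likelihoods(
    base_stress: np.ndarray,
    amplify_gain,
    attenuate_factor,
    action_strength: float = 1.0,
) -> np.ndarray:
    """Build the (A, S, O) likelihood tensor from a baseline stress column.

    ``base_stress[s]`` is P(stress_signal | s) under ``wait``.
    ``amplify_gain`` and ``attenuate_factor`` may be scalars or
    (stress, pleasure) pairs — a mood can be able to damp one channel while
    barely touching the other (depression's immutable stress expectation).
    ``action_strength`` in [0, 1] scales how far every action moves the
    likelihood away from baseline (log-scaled so that mirrored actions stay
    exact mirrors); 0 makes every action behave like ``wait``.
    """
    base_stress = np.asarray(base_stress, dtype=float)
    m = float(action_strength)
    g_st, g_pl = _per_channel(amplify_gain, "amplify_gain")
    k_st, k_pl = _per_channel(attenuate_factor, "attenuate_factor")
    g_st, g_pl, k_st, k_pl = (x**m for x in (g_st, g_pl, k_st, k_pl))
    stress = base_stress
    pleasure = 1.0 - base_stress
    cols = {}
    # each operator edits one signal channel; the other channel is the complement
    cols["wait"] = stress
    cols["amplify_stress"] = _amplify(stress, g_st)
    cols["attenuate_stress"] = _attenuate(stress, k_st)
    cols["amplify_pleasure"] = 1.0 - _amplify(pleasure, g_pl)
    cols["attenuate_pleasure"] = 1.0 - _attenuate(pleasure, k_pl)
    Z = np.empty((len(CANONICAL_ACTIONS), base_stress.shape[0], 2))
    for ai, a in enumerate(CANONICAL_ACTIONS):
        Z[ai, :, 0] = cols[a]
        Z[ai, :, 1] = 1.0 - cols[a]
    return Z


def build_mood_parameterization(
    mood_label: str,
    *,
    stress_signal_given_stressful: float,
    stress_signal_given_not_stressful: float,
    stay_stressful: float,
    stay_not_stressful: float,
    amplify_gain: float,
    attenuate_factor: float,
    action_strength: float = 1.0,
    preference_pleasure: float = 0.7,
    discount: float = 0.95,
) -> MoodParameterization:
    """Assemble a mood archetype from its interpretable knobs."""
    base = np.array([stress_signal_given_stressful, stress_signal_given_not_stressful])
    Z = action_likelihoods(base, amplify_gain, attenuate_factor, action_strength)
    T1 = np.array(
        [
            [stay_stressful, 1.0 - stay_stressful],
            [1.0 - stay_not_stressful, stay_not_stressful],
        ]
    )
    T = np.repeat(T1[None, :, :], len(CANONICAL_ACTIONS), axis=0)
    prefs = PreferenceDistribution(np.array([1.0 - preference_pleasure, preference_pleasure]))
    return MoodParameterization(mood_label, T, Z, prefs, discount)


# ---------------------------------------------------------------------------
# mirroring
# ---------------------------------------------------------------------------

def _mirror_label(label: str) -> str:
    if "pleasure" in label:
        return label.replace("pleasure", "stress")
    if "stress" in label:
        return label.replace("stress", "pleasure")
    return label


def mirror_model(model: MoodPOMDP) -> MoodPOMDP:
    """Swap stressful and pleasurable roles consistently across all tensors.

    States, observations and stress/pleasure action pairs are exchanged
    (``wait`` maps to itself); the tensors are permuted accordingly and the
    original labels are kept, so the mirror of a depression model is a mania
    model over the same vocabulary.  The operation is an involution.
    """
    if model.n_states != 2 or model.n_observations != 2:
        raise ValueError("mirror_model requires two states and two observations")
    action_perm = []
    for a in model.action_labels:
        partner = _mirror_label(a)
        if partner not in model.action_labels:
            raise ValueError(f"action {a!r} has no mirror partner {partner!r}")
        action_perm.append(model.action_labels.index(partner))
    mirrored = relabel(
        model,
        state_perm=[1, 0],
        observation_perm=[1, 0],
        action_perm=action_perm,
        new_labels=(model.state_labels, model.observation_labels, model.action_labels),
    )
    name = {"depression": "mania", "mania": "depression"}.get(model.name, model.name)
    return dataclasses.replace(mirrored, name=name)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _fixture_dir():
    return resources.files("moodpomdp") / "fixtures"


def available_moods() -> tuple[str, ...]:
    """Mood labels with a shipped canonical fixture."""
    return MOOD_LABELS


def load_fixture(mood_label: str) -> MoodPOMDP:
    """Load one of the canonical, calibration-frozen mood models."""
    if mood_label not in MOOD_LABELS:
        raise KeyError(f"unknown mood {mood_label!r}; available: {MOOD_LABELS}")
    import yaml

    path = _fixture_dir() / f"{mood_label}.yaml"
    doc = yaml.safe_load(path.read_text())
    doc.pop("metadata", None)
    return model_from_dict(doc, source=str(path))


def make_healthy() -> MoodPOMDP:
    return load_fixture("healthy")


def make_depression() -> MoodPOMDP:
    return load_fixture("depression")


def make_mania() -> MoodPOMDP:
    return load_fixture("mania")


def make_anxiety() -> MoodPOMDP:
    return load_fixture("anxiety")


def row_entropies(model: MoodPOMDP) -> np.ndarray:
    """Shannon entropy (nats) of every likelihood row, shape (A, S)."""
    Z = model.likelihood
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Z > 0.0, Z * np.log(np.where(Z > 0.0, Z, 1.0)), 0.0)
    return -terms.sum(axis=-1)
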