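import numpy as np
import pytest

from moodpomdp import (
    make_anxiety,
    make_depression,
    make_healthy,
    make_mania,
)
from moodpomdp.model import MoodPOMDP
from moodpomdp.solve import extract_policy, solve_grid
from moodpomdp.graph import build_policy_graph


def random_pomdp(rng: np.random.Generator, n_actions: int = 2,
                 n_states: int = 2, n_obs: int = 2,
                 discount: float = 0.9) -> MoodPOMDP:
    """A random valid POMDP with generic labels (Dirichlet rows)."""
    T = rng.dirichlet(np.ones(n_states), size=(n_actions, n_states))
    Z = rng.dirichlet(np.ones(n_obs), size=(n_actions, n_states))
    R = rng.uniform(-1.0, 1.0, size=(n_actions, n_states))
    return MoodPOMDP(
        state_labels=tuple(f"s{i}" for i in range(n_states)),
        observation_labels=tuple(f"o{i}" for i in range(n_obs)),
        action_labels=tuple(f"a{i}" for i in range(n_actions)),
        transition=T,
        likelihood=Z,
        reward=R,
        discount=discount,
        name="random",
    )


@pytest.fixture(scope="session")
def healthy():
    return make_healthy()


@pytest.fixture(scope="session")
def depression():
    return make_depression()


@pytest.fixture(scope="session")
def mania():
    return make_mania()


@pytest.fixture(scope="session")
def anxiety():
    return make_anxiety()


@pytest.fixture(scope="session")
def all_moods(healthy, depression, mania, anxiety):
    return {
        "healthy": healthy,
        "depression": depression,
        "mania": mania,
        "anxiety": anxiety,
    }


@pytest.fixture(scope="session")
def solved_moods(all_moods):
    """Every mood taken through solve (k=20) -> greedy policy -> graph."""
    out = {}
    for name, model in all_moods.items():
        V = solve_grid(model, resolution=20)
        policy = extract_policy(model, V)
        graph = build_policy_graph(model, policy)
        out[name] = (model, V, policy, graph)
    return out
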