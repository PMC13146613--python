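"""Shared fixtures and small ground-truth builders."""

from __future__ import annotations

import numpy as np
import pytest

import camnet as cm
from camnet.synthetic import make_cpt


@pytest.fixture
def ctni_spec():
    return cm.VariableSpec(
        name="cTnI", category="biochemical_profile", states=["0", "1"],
        thresholds=[17.5], right_closed=True, unit="pg/mL",
    )


@pytest.fixture
def age_spec():
    return cm.VariableSpec(
        name="age", category="demography",
        states=["0", "1", "2", "3"], thresholds=[30.0, 50.0, 70.0],
    )


def strong_random_net(n_nodes: int, seed: int, card: int = 2) -> cm.CausalNetwork:
    """Random DAG with monotone log-odds CPTs (strong marginal effects)."""
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(n_nodes)]
    parents = {}
    for i, v in enumerate(names):
        pool = names[:i]
        k = int(rng.integers(0, min(2, len(pool)) + 1))
        parents[v] = (
            tuple(sorted(rng.choice(pool, size=k, replace=False))) if k else ()
        )
    cpts = {}
    for v in names:
        pc = tuple(card for _ in parents[v])
        base = rng.uniform(0.15, 0.45)
        effects = [
            [0.0, float(rng.uniform(1.2, 2.4) * rng.choice([-1, 1]))]
            for _ in parents[v]
        ]
        cpts[v] = make_cpt(card, pc, [1 - base, base], effects)
    return cm.CausalNetwork(parents, {v: card for v in names}, cpts)


def toy_chain_net() -> cm.CausalNetwork:
    """A -> B -> C with strong effects."""
    return cm.CausalNetwork(
        {"A": (), "B": ("A",), "C": ("B",)},
        {"A": 2, "B": 2, "C": 2},
        {
            "A": np.array([0.5, 0.5]),
            "B": np.array([[0.85, 0.15], [0.2, 0.8]]),
            "C": np.array([[0.9, 0.1], [0.25, 0.75]]),
        },
    )


def toy_collider_net() -> cm.CausalNetwork:
    """A -> C <- B with strong monotone effects."""
    c = make_cpt(2, (2, 2), [0.88, 0.12], [[0.0, 2.2], [0.0, 1.8]])
    return cm.CausalNetwork(
        {"A": (), "B": (), "C": ("A", "B")},
        {"A": 2, "B": 2, "C": 2},
        {"A": np.array([0.5, 0.5]), "B": np.array([0.45, 0.55]), "C": c},
    )
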