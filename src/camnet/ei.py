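"""Effective information: interventional causal-effect strength in nats.

For source A with N_A states and target C, each state of A is clamped by a
do-intervention with equal probability 1/N_A.  EI(A->C) is the mean
Kullback-Leibler divergence between the interventional target distribution
and the uniform-intervention mixture:

    EI(A->C) = (1/N_A) sum_i KL( P(C | do(A=a_i)) || P(C | U_A) ),
    P(C | U_A) = (1/N_A) sum_i P(C | do(A=a_i)).

EI is 0 when C is not a descendant of A and is bounded by ln N_C.  All
computations use the fitted (posterior-mean) CPTs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CausalNetwork


@dataclass
class EIRecord:
    source: str
    target: str
    ei: float
    direction_tag: str = "other"  # into_outcome | out_of_outcome | other


def intervention_distribution(
    network: CausalNetwork, node: str, state: int, target: str
) -> np.ndarray:
    """Distribution of ``target`` under do(node = state) on the mutilated
    network (truncated factorization)."""
    if target == node:
        raise ValueError("cannot clamp the target itself")
    return network.intervene(node, state).infer(target)


def effective_information(
    network: CausalNetwork, source: str, target: str
) -> EIRecord:
    """EI(source -> target) in nats; 0 when target is not a descendant."""
    if source == target:
        raise ValueError("source and target must differ")
    if not network.is_descendant(target, of=source):
        return EIRecord(source, target, 0.0)
    n_a = network.cards[source]
    dists = np.array(
        [
            intervention_distribution(network, source, a, target)
            for a in range(n_a)
        ]
    )
    mixture = dists.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(dists > 0, dists * np.log(dists / mixture), 0.0)
    ei = float(terms.sum() / n_a)
    return EIRecord(source, target, max(ei, 0.0))


def ei_table(network: CausalNetwork, outcome: str) -> list[EIRecord]:
    """EI(X -> outcome) and EI(outcome -> X) for every other node X, sorted
    descending; zero entries are omitted."""
    if outcome not in network.cards:
        raise KeyError(outcome)
    records = []
    for x in network.nodes:
        if x == outcome:
            continue
        into = effective_information(network, x, outcome)
        into.direction_tag = "into_outcome"
        out = effective_information(network, outcome, x)
        out.direction_tag = "out_of_outcome"
        records.extend(r for r in (into, out) if r.ei > 0.0)
    return sorted(records, key=lambda r: -r.ei)
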