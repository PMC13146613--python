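"""Synthetic discrete cohorts from ground-truth causal networks.

The generators stand in for real emergency-department medical records so
that every pipeline stage (structure search, direction identification,
coarse-graining, diagnosis, EI, sensitivity) is testable end to end:

* :func:`ed_like_truth` — a 54-predictor, seven-category cohort shaped
  like a large urban emergency-department AMI population (state spaces and
  guideline-style discretization thresholds included), with a binary AMI
  outcome whose Markov boundary has exactly 12 members and an AMI
  prevalence calibrated to 2731/6001 (~45.5%);
* :func:`mimic_like_truth` — a compact 6-predictor triage schema (binary
  symptoms, 3-state systolic blood pressure and respiratory rhythm);
* :func:`random_network` / :func:`six_node_truth` — small ground truths
  for oracle and recovery tests.

Sampling is ancestral in topological order and fully determined by the
seed.  CPTs follow a log-odds parameterization: each parent state adds a
shift to the child's state-index log-odds, so "effect strength" is a
single dial per edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import CohortTable
from .network import CausalNetwork, Factor
from .schema import Schema, VariableSpec

#: Canonical fixture seed used by regression tests.
FIXTURE_SEED = 20240031


@dataclass
class GeneratorConfig:
    """Ground truth plus sampling instructions for one synthetic cohort."""

    network: CausalNetwork
    schema: Schema
    n: int
    seed: int = 0
    missing_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for v, r in self.missing_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"masking rate for {v} outside [0, 1]")


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Ancestral sampling of a cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    draws = config.network.sample(config.n, rng)
    values = np.column_stack([draws[name] for name in config.schema.names])
    missing = np.zeros(values.shape, dtype=bool)
    for name, rate in config.missing_rates.items():
        j = config.schema.names.index(name)
        missing[:, j] = rng.random(config.n) < rate
    return CohortTable(config.schema, values, missing)


# --------------------------------------------------------------------------
# CPT construction: log-odds shifts per parent state
# --------------------------------------------------------------------------

def make_cpt(card: int, parent_cards, base, effects) -> np.ndarray:
    """CPT where parent state s of parent p adds ``effects[p][s]`` to the
    log-odds of each successive child state.

    ``base`` is the child distribution when every parent is in state 0
    (or the marginal, for roots).
    """
    base = np.asarray(base, dtype=float)
    base = base / base.sum()
    logp = np.log(np.clip(base, 1e-12, None))
    parent_cards = tuple(parent_cards)
    shape = parent_cards + (card,)
    cpt = np.empty(shape)
    k = np.arange(card)
    for cfg in np.ndindex(parent_cards) if parent_cards else [()]:
        shift = sum(effects[i][s] for i, s in enumerate(cfg))
        logits = logp + shift * k
        ex = np.exp(logits - logits.max())
        cpt[cfg] = ex / ex.sum()
    return cpt


def _binary_cpt(p0: float, parent_effects=(), parent_cards=()) -> np.ndarray:
    return make_cpt(2, parent_cards, [1 - p0, p0], list(parent_effects))


# --------------------------------------------------------------------------
# ED-like 54-variable schema
# --------------------------------------------------------------------------

# (name, category, states, thresholds, right_closed)
_ED_VARIABLES = [
    ("age", "demography", 4, [30.0, 50.0, 70.0], True),
    ("sex", "demography", 2, None, True),
    ("smoking", "lifestyle", 2, None, True),
    ("alcohol", "lifestyle", 2, None, True),
    ("CAD", "past_medical_history", 2, None, True),
    ("CD", "past_medical_history", 2, None, True),
    ("HTN", "past_medical_history", 2, None, True),
    ("diabetes", "past_medical_history", 2, None, True),
    ("DYS", "past_medical_history", 2, None, True),
    ("CRI", "past_medical_history", 2, None, True),
    ("TD", "past_medical_history", 2, None, True),
    ("PCI", "past_medical_history", 2, None, True),
    ("VHD", "past_medical_history", 2, None, True),
    ("CVD", "past_medical_history", 2, None, True),
    ("nutrition", "past_medical_history", 2, None, True),
    ("chest_pain", "symptom", 2, None, True),
    ("A_ryth", "symptom", 2, None, True),
    ("CS", "symptom", 2, None, True),
    ("numbness", "symptom", 2, None, True),
    ("PR", "symptom", 2, None, True),
    ("dyspnea", "symptom", 2, None, True),
    ("UA", "biochemical_profile", 3, [90.0, 420.0], False),
    ("Cr", "biochemical_profile", 3, [53.0, 140.0], False),
    ("TG", "biochemical_profile", 3, [0.45, 1.69], False),
    ("TC", "biochemical_profile", 3, [2.86, 5.98], False),
    ("ALB", "biochemical_profile", 3, [35.0, 50.0], False),
    ("urea", "biochemical_profile", 3, [2.5, 7.5], False),
    ("ESR", "biochemical_profile", 2, [20.0], True),
    ("HGB", "biochemical_profile", 3, [110.0, 160.0], False),
    ("WBC", "biochemical_profile", 3, [4.0, 10.0], False),
    ("LYM", "biochemical_profile", 3, [0.8, 3.5], False),
    ("NEUT", "biochemical_profile", 3, [50.0, 70.0], False),
    ("PLT", "biochemical_profile", 3, [150.0, 450.0], False),
    ("Hcy", "biochemical_profile", 2, [15.0], True),
    ("K", "biochemical_profile", 3, [3.5, 5.5], False),
    ("Na", "biochemical_profile", 3, [136.0, 146.0], False),
    ("TBIL", "biochemical_profile", 3, [3.42, 20.0], False),
    ("cTnI", "biochemical_profile", 2, [17.5], True),
    ("CKMB", "biochemical_profile", 3, [0.6, 6.3], False),
    ("Ddimer", "biochemical_profile", 2, [0.5], True),
    ("TT", "biochemical_profile", 3, [9.0, 19.0], False),
    ("INR", "biochemical_profile", 3, [0.9, 1.1], False),
    ("FIB", "biochemical_profile", 3, [200.0, 400.0], False),
    ("PH", "biochemical_profile", 3, [7.35, 7.45], False),
    ("PO2", "biochemical_profile", 3, [80.0, 110.0], False),
    ("PCO2", "biochemical_profile", 3, [35.0, 45.0], False),
    ("Lac", "biochemical_profile", 3, [0.5, 1.6], False),
    ("STSA", "ecg", 2, None, True),
    ("TWA", "ecg", 2, None, True),
    ("RWA", "ecg", 2, None, True),
    ("LVE", "other_examine", 2, [50.0], False),
    ("SBP", "other_examine", 3, [90.0, 140.0], False),
    ("pulse", "other_examine", 3, [60.0, 100.0], False),
    ("ResRhy", "other_examine", 3, [10.0, 24.0], False),
]

#: Ground-truth edges of the ED-like network (cause, effect, log-odds shift
#: per unit parent state).  AMI's parents are handled separately so its
#: marginal prevalence can be calibrated exactly.
_ED_EDGES = [
    ("sex", "smoking", 1.6),
    ("sex", "alcohol", 1.8),
    ("smoking", "DYS", 0.9),
    ("DYS", "HTN", 0.8),
    ("HTN", "CVD", 1.0),
    ("HTN", "CRI", 0.9),
    ("age", "CAD", 0.7),
    ("age", "CD", 0.6),
    ("age", "diabetes", 0.5),
    ("age", "nutrition", 0.4),
    ("CAD", "PCI", 1.8),
    ("CAD", "RWA", 1.0),
    ("CD", "PR", 1.3),
    ("CD", "pulse", 0.6),
    ("CD", "LVE", -1.4),
    ("HTN", "SBP", 0.9),
    ("CRI", "Cr", 1.6),
    ("CRI", "UA", 1.0),
    ("DYS", "TG", 1.1),
    ("DYS", "TC", 0.8),
    ("smoking", "STSA", 0.3),
]

#: AMI parents with their log-odds weights (per unit parent state).
_AMI_PARENTS = [
    ("sex", 0.45),
    ("smoking", 0.7),
    ("DYS", 1.3),
    ("CVD", 0.8),
    ("CD", 1.0),
]

#: AMI children: (child, log-odds shift per AMI state).
_AMI_CHILDREN = [
    ("chest_pain", 2.1),
    ("numbness", -1.5),
    ("dyspnea", 1.25),
    ("ALB", -1.1),
    ("HGB", 0.9),
    ("STSA", 1.5),
    ("TWA", 1.6),
]

#: Baseline state distributions (parents all in state 0 / marginal for roots).
_ED_BASES = {
    "age": [0.09, 0.07, 0.50, 0.34],
    "sex": [0.43, 0.57],
    "smoking": [0.80, 0.20],
    "alcohol": [0.88, 0.12],
    "CAD": [0.40, 0.60],
    "CD": [0.80, 0.20],
    "HTN": [0.45, 0.55],
    "diabetes": [0.70, 0.30],
    "DYS": [0.55, 0.45],
    "CRI": [0.95, 0.05],
    "TD": [0.78, 0.22],
    "PCI": [0.90, 0.10],
    "VHD": [0.96, 0.04],
    "CVD": [0.90, 0.10],
    "nutrition": [0.97, 0.03],
    "chest_pain": [0.894, 0.106],
    "A_ryth": [0.99, 0.01],
    "CS": [0.99, 0.01],
    "numbness": [0.852, 0.148],
    "PR": [0.95, 0.05],
    "dyspnea": [0.894, 0.106],
    "UA": [0.02, 0.88, 0.10],
    "Cr": [0.10, 0.85, 0.05],
    "TG": [0.03, 0.84, 0.13],
    "TC": [0.08, 0.89, 0.03],
    "ALB": [0.115, 0.88, 0.005],
    "urea": [0.02, 0.87, 0.11],
    "ESR": [0.90, 0.10],
    "HGB": [0.289, 0.689, 0.022],
    "WBC": [0.05, 0.80, 0.15],
    "LYM": [0.10, 0.89, 0.01],
    "NEUT": [0.06, 0.58, 0.36],
    "PLT": [0.15, 0.84, 0.01],
    "Hcy": [0.81, 0.19],
    "K": [0.08, 0.91, 0.01],
    "Na": [0.06, 0.91, 0.03],
    "TBIL": [0.01, 0.89, 0.10],
    "cTnI": [0.955, 0.045],
    "CKMB": [0.01, 0.95, 0.04],
    "Ddimer": [0.785, 0.215],
    "TT": [0.01, 0.96, 0.03],
    "INR": [0.03, 0.89, 0.08],
    "FIB": [0.02, 0.87, 0.11],
    "PH": [0.02, 0.94, 0.04],
    "PO2": [0.10, 0.86, 0.04],
    "PCO2": [0.12, 0.86, 0.02],
    "Lac": [0.01, 0.91, 0.08],
    "STSA": [0.908, 0.092],
    "TWA": [0.980, 0.020],
    "RWA": [0.997, 0.003],
    "LVE": [0.01, 0.99],
    "SBP": [0.01, 0.63, 0.36],
    "pulse": [0.07, 0.86, 0.07],
    "ResRhy": [0.001, 0.985, 0.014],
}

_ED_N = 6001
_ED_PREVALENCE = 2731 / 6001


def _ed_schema() -> Schema:
    specs = [
        VariableSpec(
            name=n, category=c,
            states=[str(s) for s in range(k)],
            thresholds=t, right_closed=rc,
        )
        for n, c, k, t, rc in _ED_VARIABLES
    ]
    specs.append(VariableSpec("AMI", "outcome", ["0", "1"]))
    return Schema(specs)


def _calibrated_outcome_cpt(parents_joint: Factor, weights, prevalence) -> np.ndarray:
    """Binary-outcome CPT sigma(c + sum_p w_p s_p) with intercept c solved
    so the implied marginal equals ``prevalence``."""
    names = parents_joint.vars
    w = dict(weights)
    probs = parents_joint.table

    def marginal(c: float) -> float:
        total = 0.0
        for cfg in np.ndindex(probs.shape):
            shift = sum(w[p] * s for p, s in zip(names, cfg))
            total += probs[cfg] * expit(c + shift)
        return total - prevalence

    c = brentq(marginal, -15.0, 15.0, xtol=1e-12)
    shape = probs.shape + (2,)
    cpt = np.empty(shape)
    for cfg in np.ndindex(probs.shape):
        shift = sum(w[p] * s for p, s in zip(names, cfg))
        p1 = expit(c + shift)
        cpt[cfg] = (1.0 - p1, p1)
    return cpt


def _ancestor_joint(net_parents, cpts, targets) -> Factor:
    """Joint distribution of ``targets`` in a (partial) network, by factor
    products over the ancestral closure."""
    closure = set()
    stack = list(targets)
    while stack:
        v = stack.pop()
        if v in closure:
            continue
        closure.add(v)
        stack.extend(net_parents[v])
    factors = [
        Factor(tuple(net_parents[v]) + (v,), cpts[v]) for v in closure
    ]
    joint = reduce(Factor.multiply, factors)
    for v in closure - set(targets):
        joint = joint.marginalize(v)
    # reorder axes to targets order
    order = [joint.vars.index(t) for t in targets]
    return Factor(targets, np.transpose(joint.table, axes=order))


def ed_like_truth(seed: int = FIXTURE_SEED) -> tuple[CausalNetwork, Schema]:
    """Ground-truth network + schema emulating the 54-variable ED cohort.

    The AMI node has 5 parents and 7 children; its Markov boundary has
    exactly 12 members (sex, smoking, DYS, CVD, CD, chest pain, numbness,
    dyspnea, ALB, HGB, STSA, TWA) and its marginal prevalence is calibrated
    to 2731/6001.  All edges respect the knowledge constraints.  The truth
    itself is deterministic; ``seed`` is accepted for interface symmetry
    with the cohort samplers.
    """
    schema = _ed_schema()
    parents: dict[str, tuple[str, ...]] = {v.name: () for v in schema}
    effects: dict[str, list] = {v.name: [] for v in schema}
    for cause, effect, w in _ED_EDGES:
        parents[effect] = parents[effect] + (cause,)
        card = schema[cause].n_states
        effects[effect].append([w * s for s in range(card)])
    parents["AMI"] = tuple(p for p, _ in _AMI_PARENTS)
    for child, w in _AMI_CHILDREN:
        parents[child] = parents[child] + ("AMI",)
        effects[child].append([0.0, w])

    cards = schema.cardinalities()
    cpts = {}
    for v in schema.names:
        if v == "AMI":
            continue
        pc = tuple(cards[p] for p in parents[v])
        cpts[v] = make_cpt(cards[v], pc, _ED_BASES[v], effects[v])
    pj = _ancestor_joint(
        {k: v for k, v in parents.items() if k != "AMI"},
        cpts,
        tuple(p for p, _ in _AMI_PARENTS),
    )
    cpts["AMI"] = _calibrated_outcome_cpt(pj, _AMI_PARENTS, _ED_PREVALENCE)
    return CausalNetwork(parents, cards, cpts), schema


def ed_like_cohort(
    n: int = _ED_N, seed: int = FIXTURE_SEED, missing_rates=None
) -> CohortTable:
    net, schema = ed_like_truth()
    cfg = GeneratorConfig(net, schema, n, seed, missing_rates or {})
    return generate_cohort(cfg)


# --------------------------------------------------------------------------
# Triage-only (MIMIC-like) schema
# --------------------------------------------------------------------------

_MIMIC_PREVALENCE = 1462 / 3605
_MIMIC_N = 3605


def mimic_like_truth(seed: int = FIXTURE_SEED) -> tuple[CausalNetwork, Schema]:
    """6-predictor triage schema: sex, three binary symptoms, 3-state SBP
    and respiratory rhythm, plus the binary AMI outcome."""
    specs = [
        VariableSpec("sex", "demography", ["0", "1"]),
        VariableSpec("chest_pain", "symptom", ["0", "1"]),
        VariableSpec("numbness", "symptom", ["0", "1"]),
        VariableSpec("dyspnea", "symptom", ["0", "1"]),
        VariableSpec(
            "SBP", "other_examine", ["0", "1", "2"],
            thresholds=[90.0, 140.0], right_closed=False,
        ),
        VariableSpec(
            "ResRhy", "other_examine", ["0", "1", "2"],
            thresholds=[10.0, 24.0], right_closed=False,
        ),
        VariableSpec("AMI", "outcome", ["0", "1"]),
    ]
    schema = Schema(specs)
    cards = schema.cardinalities()
    parents = {
        "sex": (), "SBP": (), "numbness": (),
        "AMI": ("sex",),
        "chest_pain": ("AMI",),
        "dyspnea": ("AMI",),
        "ResRhy": ("AMI",),
    }
    cpts = {
        "sex": np.array([0.445, 0.555]),
        "SBP": np.array([0.015, 0.555, 0.43]),
        "numbness": np.array([0.999, 0.001]),
        "chest_pain": _binary_cpt(0.26, [[0.0, 1.0]], (2,)),
        "dyspnea": _binary_cpt(0.16, [[0.0, -1.8]], (2,)),
        "ResRhy": make_cpt(3, (2,), [0.002, 0.93, 0.068], [[0.0, -0.6]]),
    }
    pj = _ancestor_joint(
        {k: v for k, v in parents.items() if k != "AMI"}, cpts, ("sex",)
    )
    cpts["AMI"] = _calibrated_outcome_cpt(pj, [("sex", 0.25)], _MIMIC_PREVALENCE)
    return CausalNetwork(parents, cards, cpts), schema


def mimic_like_cohort(n: int = _MIMIC_N, seed: int = FIXTURE_SEED) -> CohortTable:
    net, schema = mimic_like_truth()
    return generate_cohort(GeneratorConfig(net, schema, n, seed))


# --------------------------------------------------------------------------
# Small ground truths for oracle and recovery tests
# --------------------------------------------------------------------------

def generic_schema(cards: dict[str, int], outcome: str) -> Schema:
    """Plain schema for ad-hoc networks: everything 'other_examine' except
    the designated binary outcome."""
    specs = []
    for name, k in cards.items():
        if name == outcome:
            specs.append(VariableSpec(name, "outcome", [str(s) for s in range(k)]))
        else:
            specs.append(
                VariableSpec(name, "other_examine", [str(s) for s in range(k)])
            )
    return Schema(specs)


def network_cohort(
    net: CausalNetwork, n: int, seed: int, outcome: str | None = None
) -> CohortTable:
    """Sample a cohort from any network with an auto-generated schema."""
    outcome = outcome or net.nodes[-1]
    schema = generic_schema({v: net.cards[v] for v in net.nodes}, outcome)
    return generate_cohort(GeneratorConfig(net, schema, n, seed))


def random_network(
    n_nodes: int,
    seed: int,
    max_parents: int = 2,
    card: int = 2,
    concentration: float = 0.4,
) -> CausalNetwork:
    """Random DAG (topological order v0..vk) with Dirichlet CPT rows.

    A small Dirichlet concentration yields sharp, identifiable CPTs.
    """
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(n_nodes)]
    parents = {}
    for i, v in enumerate(names):
        pool = names[:i]
        k = int(rng.integers(0, min(max_parents, len(pool)) + 1))
        parents[v] = tuple(sorted(rng.choice(pool, size=k, replace=False))) if k else ()
    cards = {v: card for v in names}
    cpts = {}
    for v in names:
        shape = tuple(cards[p] for p in parents[v]) + (cards[v],)
        rows = rng.dirichlet([concentration] * cards[v], size=int(np.prod(shape[:-1]) or 1))
        cpts[v] = rows.reshape(shape)
    return CausalNetwork(parents, cards, cpts)


def six_node_truth(seed: int = 0) -> tuple[CausalNetwork, Schema]:
    """Six-variable ED-like subnetwork with strong effects, used for
    end-to-end structure-recovery checks."""
    specs = [
        VariableSpec("sex", "demography", ["0", "1"]),
        VariableSpec("smoking", "lifestyle", ["0", "1"]),
        VariableSpec("DYS", "past_medical_history", ["0", "1"]),
        VariableSpec("CVD", "past_medical_history", ["0", "1"]),
        VariableSpec("AMI", "outcome", ["0", "1"]),
        VariableSpec("chest_pain", "symptom", ["0", "1"]),
    ]
    schema = Schema(specs)
    rng = np.random.default_rng(seed)

    def jitter(x):
        return float(x + rng.uniform(-0.15, 0.15))

    parents = {
        "sex": (),
        "smoking": ("sex",),
        "DYS": ("smoking",),
        "CVD": ("DYS",),
        "AMI": ("DYS", "CVD"),
        "chest_pain": ("AMI",),
    }
    cpts = {
        "sex": np.array([0.45, 0.55]),
        "smoking": _binary_cpt(0.18, [[0.0, jitter(1.9)]], (2,)),
        "DYS": _binary_cpt(0.30, [[0.0, jitter(1.8)]], (2,)),
        "CVD": _binary_cpt(0.10, [[0.0, jitter(1.7)]], (2,)),
        "AMI": make_cpt(
            2, (2, 2), [0.72, 0.28], [[0.0, jitter(1.6)], [0.0, jitter(1.4)]]
        ),
        "chest_pain": _binary_cpt(0.11, [[0.0, jitter(2.2)]], (2,)),
    }
    cards = {v.name: 2 for v in specs}
    return CausalNetwork(parents, cards, cpts), schema


def anm_pair(
    f,
    n: int,
    seed: int,
    x_probs=None,
    noise_values=(-1, 0, 1),
    noise_probs=(0.1, 0.8, 0.1),
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a discrete additive-noise pair y = f(x) + e with e independent
    of x; ``f`` maps x-state -> integer."""
    rng = np.random.default_rng(seed)
    if x_probs is None:
        x_probs = [1.0 / 3] * 3
    x = rng.choice(len(x_probs), size=n, p=np.asarray(x_probs) / np.sum(x_probs))
    e = rng.choice(noise_values, size=n, p=noise_probs)
    y = np.array([f(int(v)) for v in x]) + e
    return x, y
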