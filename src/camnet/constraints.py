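"""Medical-knowledge constraints on admissible causal edges.

Two constraint families are encoded, both derived purely from variable
categories:

1. No causality *within* demography, and none *within* the clinical
   manifestations (symptom, biochemical profile, ECG, other examinations) —
   manifestations are short-horizon consequences of underlying disease, not
   causes of one another.
2. No causality *against the temporal tier order*
   demography -> lifestyle -> past medical history -> outcome ->
   clinical manifestations: a variable occurring later cannot cause an
   earlier one.

Within-tier edges among lifestyle variables and among past-medical-history
variables remain admissible (chronic conditions can cause one another).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .schema import MANIFESTATION_CATEGORIES, Schema

#: Tier index per category; manifestations share the final tier.
TIER_OF_CATEGORY = {
    "demography": 0,
    "lifestyle": 1,
    "past_medical_history": 2,
    "outcome": 3,
    "symptom": 4,
    "biochemical_profile": 4,
    "ecg": 4,
    "other_examine": 4,
}


@dataclass
class ConstraintSet:
    """Forbidden ordered (cause, effect) pairs plus the tier of each variable."""

    forbidden: set[tuple[str, str]] = field(default_factory=set)
    tier_of: dict[str, int] = field(default_factory=dict)

    def is_allowed(self, cause: str, effect: str) -> bool:
        for v in (cause, effect):
            if v not in self.tier_of:
                raise KeyError(f"unknown variable {v!r}")
        return (cause, effect) not in self.forbidden

    def merge_pairs(self, pairs) -> "ConstraintSet":
        """New constraint set with extra forbidden pairs merged in."""
        extra = {(a, b) for a, b in pairs if a != b}
        return ConstraintSet(self.forbidden | extra, dict(self.tier_of))


def build_constraints(schema: Schema) -> ConstraintSet:
    """Derive the forbidden-edge set from schema categories alone."""
    tier_of = {}
    for v in schema:
        if v.category not in TIER_OF_CATEGORY:
            raise ValueError(f"{v.name}: category {v.category!r} has no tier")
        tier_of[v.name] = TIER_OF_CATEGORY[v.category]

    forbidden: set[tuple[str, str]] = set()
    specs = list(schema)
    for a in specs:
        for b in specs:
            if a.name == b.name:
                continue
            within_demo = a.category == "demography" and b.category == "demography"
            within_manifest = (
                a.category in MANIFESTATION_CATEGORIES
                and b.category in MANIFESTATION_CATEGORIES
            )
            against_time = tier_of[a.name] > tier_of[b.name]
            if within_demo or within_manifest or against_time:
                forbidden.add((a.name, b.name))
    return ConstraintSet(forbidden, tier_of)


def is_allowed(edge: tuple[str, str], constraints: ConstraintSet) -> bool:
    """True iff the ordered edge is not forbidden."""
    return constraints.is_allowed(*edge)


def read_forbidden_tsv(path) -> set[tuple[str, str]]:
    """Read a two-column TSV of extra forbidden (cause, effect) pairs."""
    pairs = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            pairs.add((a, b))
    return pairs
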