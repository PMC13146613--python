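"""Discrete variable schemas for emergency-department cohort tables.

Every variable in a cohort is categorical, coded by a 0-based state index.
Continuous measurements (labs, vitals) carry ordered numeric thresholds that
map a raw value onto a state, mirroring guideline-style discretization
("cTnI 0: <=17.5 / 1: >17.5 pg/mL").  A schema is the ordered list of
variable specs; it designates exactly one binary outcome variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: Recognised variable categories, in clinical temporal-tier order.
CATEGORIES = (
    "demography",
    "lifestyle",
    "past_medical_history",
    "symptom",
    "biochemical_profile",
    "ecg",
    "other_examine",
    "outcome",
)

#: Categories treated as short-horizon clinical manifestations.
MANIFESTATION_CATEGORIES = frozenset(
    {"symptom", "biochemical_profile", "ecg", "other_examine"}
)


class SchemaError(ValueError):
    """Raised for malformed variable specs or schema/cohort mismatches."""


@dataclass
class VariableSpec:
    """One discrete variable: its state space and optional discretization rule.

    Parameters
    ----------
    name : str
        Short identifier used as the cohort column name.
    category : str
        One of :data:`CATEGORIES`.
    states : list of str
        Ordered state labels (length >= 2); the state *index* is what is
        stored in cohort tables.
    thresholds : list of float, optional
        Ordered cut points mapping a raw measurement to a state index;
        ``len(thresholds) == len(states) - 1``.
    right_closed : bool
        If True (default) bins are ``(-inf, t1], (t1, t2], ...`` so a value
        exactly at a cut point falls in the *lower* state (the "<=" printed
        convention); if False bins are left-closed ``[t_i, t_{i+1})`` (the
        "<" convention).
    long_name : str
        Free-text description.
    unit : str
        Measurement unit of the raw value, if any.
    """

    name: str
    category: str
    states: list[str]
    thresholds: list[float] | None = None
    right_closed: bool = True
    long_name: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"{self.name}: unknown category {self.category!r}"
            )
        if len(self.states) < 2:
            raise SchemaError(f"{self.name}: needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise SchemaError(f"{self.name}: duplicate state labels")
        if self.thresholds is not None:
            t = list(self.thresholds)
            if len(t) != len(self.states) - 1:
                raise SchemaError(
                    f"{self.name}: {len(t)} thresholds for "
                    f"{len(self.states)} states"
                )
            if any(a >= b for a, b in zip(t, t[1:])):
                raise SchemaError(f"{self.name}: thresholds not increasing")
        if self.category == "outcome" and len(self.states) != 2:
            raise SchemaError(f"{self.name}: outcome must be binary")

    @property
    def n_states(self) -> int:
        return len(self.states)


def discretize(raw_value: float, spec: VariableSpec) -> int:
    """Map a raw measurement to the state index of ``spec``.

    Boundary values follow ``spec.right_closed``: with the default "<="
    convention a value exactly at a cut point is assigned the lower state.
    """
    import math

    if not isinstance(raw_value, (int, float)) or not math.isfinite(raw_value):
        raise ValueError(f"non-finite raw value: {raw_value!r}")
    if spec.thresholds is None:
        raise SchemaError(f"{spec.name}: no discretization thresholds")
    idx = 0
    for t in spec.thresholds:
        if raw_value > t if spec.right_closed else raw_value >= t:
            idx += 1
        else:
            break
    return idx


@dataclass
class Schema:
    """Ordered collection of :class:`VariableSpec` with one binary outcome."""

    variables: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        outcomes = [v for v in self.variables if v.category == "outcome"]
        if len(outcomes) != 1:
            raise SchemaError(
                f"schema must have exactly one outcome variable, "
                f"found {len(outcomes)}"
            )

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def outcome(self) -> VariableSpec:
        return next(v for v in self.variables if v.category == "outcome")

    def cardinalities(self) -> dict[str, int]:
        return {v.name: v.n_states for v in self.variables}

    # ---------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {"variables": [asdict(v) for v in self.variables]}

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        return cls([VariableSpec(**v) for v in d["variables"]])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Schema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
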