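"""Outcome inference and a scikit-learn compatible diagnosis classifier.

``infer_outcome`` returns the exact posterior of the binary outcome given
any partial evidence assignment (unobserved variables are marginalised
out).  :class:`CausalNetworkClassifier` wraps structure-aware parameter
fitting and posterior inference behind the sklearn estimator API so the
network composes with pipelines and model selection; missing evidence at
prediction time is encoded as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import CohortTable
from .graph import PDAG
from .network import CausalNetwork, fit_parameters
from .schema import Schema


@dataclass
class DiagnosisResult:
    """Posterior outcome probability and thresholded label for one patient."""

    p_ami: float
    label: int
    threshold: float
    evidence_used: tuple[str, ...]


def infer_outcome(
    network: CausalNetwork,
    evidence: dict[str, int],
    outcome: str = "AMI",
    threshold: float = 0.5,
) -> DiagnosisResult:
    """Exact posterior Pr{outcome = 1 | evidence}; ties at the threshold
    classify positive (favouring sensitivity in triage)."""
    if outcome in evidence:
        raise ValueError("evidence must not assign the outcome itself")
    post = network.infer(outcome, evidence)
    p = float(post[1])
    return DiagnosisResult(p, int(p >= threshold), threshold, tuple(sorted(evidence)))


class PosteriorCache:
    """Memoises outcome posteriors per unique evidence configuration."""

    def __init__(self, network: CausalNetwork, outcome: str):
        self.network = network
        self.outcome = outcome
        self._cache: dict[tuple, float] = {}

    def p_outcome(self, evidence: dict[str, int]) -> float:
        key = tuple(sorted(evidence.items()))
        p = self._cache.get(key)
        if p is None:
            p = float(self.network.infer(self.outcome, evidence)[1])
            self._cache[key] = p
        return p


class CausalNetworkClassifier(ClassifierMixin, BaseEstimator):
    """Discrete Bayesian-network classifier with exact missing-data inference.

    Parameters
    ----------
    dag : PDAG or iterable of (parent, child), optional
        Network structure over the predictor columns plus the outcome.  If
        None, the structure is learned at fit time by constrained greedy
        BIC search (requires ``schema``); any reversible edges are oriented
        by a consistent extension.
    schema : Schema, optional
        Variable schema (categories drive the knowledge constraints).
    outcome : str
        Name of the binary outcome node (default ``"AMI"``).
    prior_strength : float
        Dirichlet pseudo-count for CPT estimation.
    threshold : float
        Probability cut for the positive label; ties classify positive.

    Attributes
    ----------
    network_ : CausalNetwork
    markov_boundary_ : set of str
    classes_ : ndarray
    feature_names_in_ : ndarray of str
    """

    def __init__(
        self,
        dag=None,
        schema: Schema | None = None,
        outcome: str = "AMI",
        prior_strength: float = 1.0,
        threshold: float = 0.5,
    ):
        self.dag = dag
        self.schema = schema
        self.outcome = outcome
        self.prior_strength = prior_strength
        self.threshold = threshold

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if self.schema is not None:
            schema = self.schema
        else:
            schema = _schema_from_data(X, y, self.outcome)
        cols = {c: np.asarray(X[c], dtype=np.int64) for c in X.columns}
        values = np.column_stack(
            [cols[n] if n != self.outcome else y for n in schema.names]
        )
        cohort = CohortTable(schema, values)
        dag = self.dag
        if dag is None:
            from .constraints import build_constraints
            from .search import search_mec

            cpdag = search_mec(cohort, build_constraints(schema))
            dag = cpdag.consistent_extension()
        elif not isinstance(dag, PDAG):
            dag = PDAG(schema.names, dag)
        if dag.undirected:
            dag = dag.consistent_extension()
        self.network_ = fit_parameters(dag, cohort, self.prior_strength)
        self.markov_boundary_ = self.network_.markov_boundary(self.outcome)
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    # ------------------------------------------------------------- predict
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = pd.DataFrame(X)
        cache = PosteriorCache(self.network_, self.outcome)
        cols = list(X.columns)
        arr = X.to_numpy()
        out = np.empty(len(X))
        for i in range(len(X)):
            ev = {
                c: int(v)
                for c, v in zip(cols, arr[i])
                if v is not None and not (isinstance(v, float) and np.isnan(v)) and not pd.isna(v)
            }
            out[i] = cache.p_outcome(ev)
        return np.column_stack([1.0 - out, out])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return (p >= self.threshold).astype(np.int64)


def _schema_from_data(X: pd.DataFrame, y, outcome: str) -> Schema:
    """Fallback schema: state counts from observed maxima, flat categories."""
    from .schema import VariableSpec

    specs = []
    for c in X.columns:
        k = int(np.nanmax(np.asarray(X[c], dtype=float))) + 1
        specs.append(
            VariableSpec(
                name=str(c),
                category="other_examine",
                states=[str(s) for s in range(max(k, 2))],
            )
        )
    specs.append(
        VariableSpec(name=outcome, category="outcome", states=["0", "1"])
    )
    return Schema(specs)
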