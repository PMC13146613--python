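"""Partial-information validation protocols and diagnostic metrics.

Three protocols probe robustness to missing evidence at test time, with
training always on fully observed data:

* **A** — the testing folds keep every variable except the outcome;
* **B** — the testing folds keep only the Markov boundary of the outcome;
* **C** — the testing folds keep only the complement of the Markov
  boundary (outcome also excluded).

Ten-fold simple random cross-validation; metrics are accuracy,
sensitivity, specificity, precision, F1 and log loss (mean +/- sd across
folds).  The guideline baseline classifies positive iff troponin is
elevated AND (chest pain OR ST-segment abnormality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np

from .cohort import CohortTable
from .diagnosis import PosteriorCache
from .graph import PDAG
from .network import fit_parameters

METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1", "log_loss")

_CLIP = 1e-15


@dataclass
class MetricRecord:
    """Six diagnostic metrics plus the confusion counts for one test set."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    log_loss: float
    tp: int
    fp: int
    tn: int
    fn: int
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRICS}


def compute_metrics(y_true, y_pred, p_pred=None) -> MetricRecord:
    """Standard metric definitions; probabilities clipped at 1e-15 for the
    log loss.  When no positive predictions exist, precision and F1 are
    reported as 0 and flagged."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = len(y_true)
    flags = []
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    if tp + fp:
        prec = tp / (tp + fp)
    else:
        prec, flags = 0.0, flags + ["no_positive_predictions"]
    f1 = (
        2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    )
    if p_pred is None:
        ll = float("nan")
    else:
        p = np.clip(np.asarray(p_pred, dtype=float), _CLIP, 1 - _CLIP)
        ll = float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))
    return MetricRecord(acc, sens, spec, prec, f1, ll, tp, fp, tn, fn, flags)


@dataclass
class ValidationReport:
    """Per-fold metrics with mean and sd for one protocol run."""

    protocol: str
    per_fold: list[MetricRecord]
    mean: dict[str, float]
    sd: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": self.mean,
            "sd": self.sd,
        }


def run_protocol(
    dag: PDAG,
    cohort: CohortTable,
    protocol: str,
    folds: int = 10,
    seed: int = 0,
    prior_strength: float = 1.0,
    threshold: float = 0.5,
) -> ValidationReport:
    """Cross-validated diagnosis under protocol A, B or C.

    Folds are a simple random partition driven by ``seed``; training uses
    all variables, testing evidence is masked per protocol.
    """
    protocol = protocol.upper()
    if protocol not in ("A", "B", "C"):
        raise ValueError("protocol must be A, B or C")
    if not cohort.is_fully_observed():
        raise ValueError("validation requires a fully observed cohort")
    outcome = cohort.schema.outcome.name
    if dag is None or dag.undirected:
        raise ValueError("a fully directed DAG is required before validation")

    mb = sorted(_markov_boundary(dag, outcome))
    predictors = [c for c in cohort.columns if c != outcome]
    if protocol == "A":
        keep = predictors
    elif protocol == "B":
        keep = [c for c in predictors if c in mb]
    else:
        keep = [c for c in predictors if c not in mb]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.n)
    fold_idx = np.array_split(perm, folds)
    records = []
    for test_idx in fold_idx:
        mask = np.ones(cohort.n, dtype=bool)
        mask[test_idx] = False
        train = cohort.subset_rows(mask)
        net = fit_parameters(dag, train, prior_strength)
        cache = PosteriorCache(net, outcome)
        test = cohort.subset_rows(test_idx)
        p = np.array(
            [
                cache.p_outcome(
                    {c: int(test.column(c)[i]) for c in keep}
                )
                for i in range(test.n)
            ]
        )
        y = test.column(outcome)
        records.append(compute_metrics(y, (p >= threshold).astype(int), p))
    mean = {m: float(np.mean([getattr(r, m) for r in records])) for m in METRICS}
    sd = {m: float(np.std([getattr(r, m) for r in records], ddof=1)) for m in METRICS}
    return ValidationReport(protocol, records, mean, sd)


def _markov_boundary(dag: PDAG, node: str) -> set[str]:
    mb = dag.parents(node) | dag.children(node)
    for c in dag.children(node):
        mb |= dag.parents(c)
    mb.discard(node)
    return mb


def standard_criterion_baseline(counts) -> MetricRecord:
    """Metrics of the guideline rule applied to a 2x4 summary table.

    ``counts[outcome][j]`` with columns
    0: troponin elevated & (chest pain or STSA),
    1: troponin elevated & neither,
    2: troponin normal & (chest pain or STSA),
    3: troponin normal & neither.
    The rule predicts positive only in column 0.  Log loss is undefined for
    a hard rule and reported as NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 4):
        raise ValueError("expected a 2x4 count table")
    if (counts < 0).any():
        raise ValueError("negative cell count")
    tp = counts[1, 0]
    fp = counts[0, 0]
    fn = counts[1, 1:].sum()
    tn = counts[0, 1:].sum()
    n = counts.sum()
    flags = []
    prec = tp / (tp + fp) if tp + fp else 0.0
    if tp + fp == 0:
        flags.append("no_positive_predictions")
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    return MetricRecord(
        (tp + tn) / n, sens, spec, prec, f1, float("nan"),
        int(tp), int(fp), int(tn), int(fn), flags,
    )
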