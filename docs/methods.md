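# Methods

This note records the models, numerical choices and open design decisions
behind `camnet`, and what the synthetic study conditions do and do not show
about real emergency-department data.

## Data model

All variables are categorical with 0-based state codes.  Continuous
measurements are discretized by guideline-style ordered thresholds stored in
the schema; the boundary convention is recorded per variable
(`right_closed=True` for "≤ t" bins, `False` for "< t" bins), so a troponin
of exactly 17.5 pg/mL codes as non-elevated while a uric acid of exactly
90 μmol/L falls into the middle band.  Missing cells are a boolean mask in
memory and the token `NA` on disk; missingness is only meaningful in testing
data — every estimator requires fully observed training cohorts.
Descriptive statistics use the Pearson chi-square without continuity
correction; the Yates-corrected statistic does not reproduce the reference
cohort tables (e.g. sex vs AMI: 68.199 uncorrected).

## Knowledge constraints

Constraints are a pure function of variable categories: both directions are
forbidden within demography and within the four manifestation categories
(symptom, biochemistry, ECG, other examinations), and any edge pointing from
a later temporal tier to a strictly earlier one is forbidden, with the tier
order demography → lifestyle → past history → outcome → manifestations.
Edges among lifestyle variables and among past-history variables stay
admissible: chronic conditions do cause one another (hypertension →
cerebrovascular disease).  Constraints act as hard filters — a forbidden
edge is never scored — and the explicit tier rule already subsumes any
special-casing of edges into the outcome.

## Structure search

The score is the decomposable BIC `2L − k ln N` (natural logarithms; `L` in
nats) with maximum-likelihood plug-in probabilities and
`k = Σᵢ (rᵢ−1)·Πₚ r_p`.  The Bayesian (Dirichlet posterior-mean) estimates
are reserved for the diagnostic CPTs; plug-in MLE is the standard choice
inside a score and keeps the score exactly decomposable.

The search runs over equivalence classes with Insert(x, y, T) and
Delete(x, y, H) operators whose validity (clique and semi-directed-path
conditions) and score deltas are evaluated on the CPDAG itself, alternating
a forward (insertion) and a backward (deletion) phase until neither
improves the score, then propagating constraint-forced orientations with
Meek's rules.  An earlier implementation restricted the forward phase to
single directed-edge insertions on a DAG representative; it was abandoned
because it provably stalls on collider-generated data — after the first
edge is (arbitrarily) oriented, the explaining-away dependence drags in a
spurious third adjacency that single-move deletion cannot undo, and the
search terminates with a complete skeleton.  Scoring insertions against the
equivalence class removes the arbitrary orientation and restores agreement
with exhaustive BIC maximisation on every small-cohort benchmark in the
test suite.  Subset sizes |T|, |H| are capped at 3; in tier-constrained
clinical graphs the undirected neighbourhoods are small and the cap has
never bound in testing.

Ties between equally scoring operators break lexicographically by
(child, parent) so runs are bit-reproducible.  Three Meek rules are
implemented as the default closure; the standard fourth rule exists behind
`use_rule4=True` but is off by default, matching the three-rule closure
used throughout the pipeline.

## Direction identification (discrete ANM)

For an undirected edge the discrete regression initialises `f⁰(x) =
argmax_y n(x, y)` (ties to the smallest y) and sweeps the states of X,
replacing `f(x)` by the state of Y that minimises the dependence measure
DM = −p of the Pearson chi-square between X and the residual `Y − f(X)`.
Candidates range over *all* observed states of Y, not only the conditional
mode: freezing the candidate at the mode can stall the iteration without
decreasing DM.  Residuals live on the integers (no modular wrap-around).
Residual levels with expected count below 5 are pooled into an adjacent
level before testing; a constant residual is treated as perfectly
independent (p = 1).  The acceptance level is α = 0.05.

An orientation is only tested if it creates no new v-structure and no cycle
in the current class.  When the structure forces a unique orientation the
residual test still acts as a veto (`forced_by_structure` on success,
`unresolved` on failure); when both orientations are structurally
admissible, a direction is accepted only if exactly one passes.  Edges are
processed in lexicographic passes with the Meek closure re-applied between
passes.  Because the independence test operates at its nominal 5% level,
a fraction of truly-additive-noise simulations must reject by chance; the
test suite asserts recovery rates with binomial slack around that level
rather than demanding every seed pass.

## Coarse-graining

Unresolved edges are absorbed into macro variables.  The member set is
found by breadth-first search over supersets of the edge's endpoints,
ordered by size then lexicographically, accepting the first set whose
contraction (i) inherits no conflicting edge directions from outside
nodes, (ii) creates no directed cycle, and (iii) creates no v-structure
without a counterpart among the original nodes.  Overlapping member sets
for distinct unresolved edges merge into a single macro variable.  Macro
states enumerate member-state tuples row-major in member-list order; a
macro cell is missing iff any member cell is missing.  Member-level causal
detail inside a macro node is deliberately lost — that is the price of a
unique, acyclic network.

## Diagnosis engine

CPT cells are symmetric-Dirichlet posterior means
`(n + s/r)/(n_cfg + s)` with `prior_strength s = 1` by default (Laplace
type); `s → 0` recovers the MLE and an unobserved parent configuration
yields a uniform row.  Inference is exact variable elimination with a
greedy min-fill ordering; the ED-scale networks here (≤55 sparse discrete
nodes) eliminate in milliseconds, so no approximate inference is provided.
Posteriors are cached per unique evidence configuration, which makes
protocol-style batch prediction linear in the number of distinct
configurations.  Ties at the 0.5 threshold classify positive, favouring
sensitivity in triage.  The Markov boundary (parents ∪ children ∪
co-parents) is computed structurally; its sufficiency —
Pr{AMI | boundary} = Pr{AMI | everything} — is exact by the Markov
property and is verified to 1e−12 row-by-row in the tests.

A scikit-learn estimator (`CausalNetworkClassifier`) wraps structure-aware
fitting and posterior inference (NaN = missing evidence) so the network
composes with sklearn model selection; the rest of the pipeline is not
fit/predict shaped and is exposed as plain functions over explicit graph
and network objects.

## Validation protocols

Ten-fold *simple random* (unstratified) cross-validation: training folds
keep all variables; testing evidence keeps everything (A), only the Markov
boundary (B), or only its complement (C).  Metrics are accuracy,
sensitivity, specificity, precision, F1 and log loss with probabilities
clipped at 1e−15; when no positive predictions exist, precision and F1 are
reported as 0 and flagged.  The guideline baseline classifies positive iff
troponin is elevated and chest pain or an ST-segment abnormality is
present; from the published 2×4 count table this rule's precision (0.516)
and specificity (0.995) reproduce exactly, while the published accuracy
and sensitivity for the same rule are inconsistent with the same counts
(recomputation gives 0.545 and 0.0059) and are therefore documented as an
open inconsistency rather than asserted.

## Effective information

EI(A→C) averages, over equal-probability do-interventions on A, the KL
divergence between each interventional distribution of C and their uniform
mixture; computed on the fitted posterior-mean CPTs (the fitted network
*is* the model whose causal strength is being reported), in nats, with
`0·ln(0/q) = 0`.  The mixture dominates each component, so the divergence
is always finite, `0 ≤ EI ≤ ln N_C`, and EI is exactly 0 when the target
is not a descendant of the source.

## Confounder sensitivity

The unobserved-confounder model perturbs the propensity with
`g̃ | X ~ Beta(g m, (1−g) m)`, `m = 1/α − 1` (so `Var(g̃|X) = g(1−g)α`),
and shifts the outcome by `δ(logit g̃ − E[logit g̃ | T, X])`; the induced
ATE bias has the closed digamma form implemented verbatim, which is linear
in δ and therefore inverted exactly for a target bias (default 0.1).
Conditioning on the realised treatment tilts the Beta to
`(gm + T, (1−g)m + 1 − T)`.  The conditional logit variance is integrated
by Monte Carlo (2,000 draws per unique (g, T) pair, fixed seed) using the
gamma representation `logit g̃ = ln Γ_a − ln Γ_b`, which avoids the
catastrophic saturation of direct beta draws near 0/1; the trigamma
closed form `ψ₁(a) + ψ₁(b)` serves as an independent cross-check in the
tests.  Nuisance models g(X) and Q(T, X) are Laplace-smoothed discrete
conditional frequencies (the cohorts are categorical throughout), with g
clipped to [0.01, 0.99].  An observed covariate Z is placed on the Austen
axes by refitting both nuisances without Z: α_Z = E[(g_full − g_red)²] /
E[g_red(1−g_red)] via the Beta variance identity, and R²_Z is the
outcome-model improvement from Z.  The robustness verdict holds when every
covariate point lies strictly below the interpolated curve.  The α grid is
99 points on 0.01…0.99.

## Synthetic study conditions

The ED-like generator emulates the shape of a 6,001-patient cohort:
54 predictors in seven categories with the published state spaces and
guideline thresholds, a binary AMI outcome whose Markov boundary contains
exactly 12 variables (sex, smoking, dyslipidaemia, cerebrovascular
disease, cardiac dysfunction, chest pain, numbness, dyspnea, albumin,
hemoglobin, ST-segment and T-wave abnormality), and an AMI prevalence
calibrated exactly to 2731/6001 by root-finding the outcome intercept
against the ancestral joint of its parents.  CPTs use a log-odds
parameterisation — each parent state adds a shift to the child's
state-index log-odds — so effect strength is a single dial per edge;
baseline state frequencies are set to plausible ED magnitudes.  The
triage-like generator produces the 6-predictor schema (binary symptoms,
3-state SBP and respiratory rhythm) at prevalence 1462/3605.

What passing tests show: the pipeline recovers structure, parameters,
boundaries and effects from data whose generating process satisfies its
assumptions (faithful discrete Bayesian network, additive-noise
mechanisms, no unobserved confounding).  What they do not show: robustness
to EMR measurement error, temporal dynamics, selection bias or model
misspecification in real cohorts — the generator deliberately omits those
features, and real-data conclusions require the corresponding records.

## Problem sizes and determinism

Test and acceptance workloads are sized for a single CPU: oracle
equivalences use ≤6-node networks (inference vs full-joint enumeration to
1e−10; search vs exhaustive DAG enumeration, 543 DAGs at 4 nodes);
simulation recoveries use n = 5,000 (direction identification), 20,000
(skeleton recovery) and 50,000 (CPT error) samples; Markov-boundary
sufficiency is checked row-by-row on generated ED cohorts.  Every sampler
takes an explicit integer seed and all reported numbers are deterministic
given it.

## Known limitations

* Greedy equivalence search is asymptotically consistent but not exact at
  finite n; weak edges (log-odds shifts ≲ 0.3 at n ≈ 6,000) fall below the
  BIC penalty and are omitted.
* The discrete ANM assumes an acyclic additive mechanism per edge;
  genuinely coupled pairs are (correctly) left unresolved and
  coarse-grained, at the cost of member-level interpretability.
* Exact inference scales with induced treewidth; the clinical networks
  here are tree-like, but densely connected graphs would need an
  approximate engine.
* The sensitivity analysis inherits the logit-linear outcome-shift and
  Beta-propensity assumptions; it quantifies a specific confounder family,
  not all possible confounding.
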