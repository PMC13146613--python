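"""Austen-plot sensitivity analysis for unobserved confounding.

The analysis asks how strong an *unobserved* confounder U of a binary
treatment T and outcome Y would have to be to shift the average treatment
effect by a fixed bias.  Confounder strength has two axes:

* ``alpha`` in (0, 1) — influence on the treatment.  The true propensity
  is modelled as a Beta perturbation of the estimated one,
  ``g~ | X ~ Beta(g (1/alpha - 1), (1 - g)(1/alpha - 1))``; larger alpha
  means a wider perturbation (Var(g~|X) = g(1-g) alpha).
* ``R^2_Y,par`` in [0, 1] — partial variance in Y explained by U beyond
  (T, X), under the logit-linear outcome shift
  ``E[Y|T,X,U] = Q(T,X) + delta (logit g~ - E[logit g~ | T, X])``.

The induced ATE bias has the closed digamma form

    bias = delta * E[ psi(g m + 1) - psi((1-g) m) - psi(g m)
                      + psi((1-g) m + 1) ],   m = 1/alpha - 1.

For a grid of alpha the delta achieving a target bias is solved exactly
(bias is linear in delta) and converted to R^2_Y,par; observed covariates
are placed on the same axes by refitting the nuisance models without them.
Nuisance models g(X) and Q(T,X) are discrete conditional-frequency
estimates with Laplace smoothing (the cohort is categorical throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

__all__ = [
    "SensitivityInputs",
    "SensitivityCurve",
    "BiasUnattainableError",
    "estimate_nuisance",
    "confounding_bias",
    "delta_for_bias",
    "partial_r2",
    "covariate_influence",
    "austen_plot",
]


class BiasUnattainableError(ValueError):
    """The digamma bracket is numerically degenerate; no delta achieves the
    requested bias."""


@dataclass
class SensitivityInputs:
    """Treatment/outcome series, discrete covariates and nuisance estimates."""

    t: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame
    g: np.ndarray  # Pr(T=1 | X) per sample, clipped inside (0, 1)
    q: np.ndarray  # E[Y | T, X] per sample

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.y) == len(self.g) == len(self.q) == len(self.covariates) == n):
            raise ValueError("input lengths disagree")
        if np.any((self.g <= 0) | (self.g >= 1)):
            raise ValueError("propensities must lie strictly inside (0, 1)")


@dataclass
class SensitivityCurve:
    """Austen-plot locus: R^2 needed at each alpha for a fixed ATE bias."""

    bias_level: float
    alphas: np.ndarray
    r2_curve: np.ndarray
    covariate_points: dict[str, tuple[float, float]]
    robust: bool
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "bias_level": self.bias_level,
            "alphas": self.alphas.tolist(),
            "r2_curve": self.r2_curve.tolist(),
            "covariate_points": {
                k: list(v) for k, v in self.covariate_points.items()
            },
            "robust": self.robust,
            "flags": self.flags,
        }


def estimate_nuisance(
    t, y, covariates: pd.DataFrame, smoothing: float = 1.0,
    clip: tuple[float, float] = (0.01, 0.99),
) -> SensitivityInputs:
    """Discrete conditional-frequency estimates of g(X) and Q(T, X).

    Laplace-smoothed cell frequencies over the exact covariate
    configuration; g is clipped to ``clip`` to keep the Beta perturbation
    well defined.
    """
    t = np.asarray(t, dtype=int)
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(covariates).reset_index(drop=True)
    cfg = _config_codes(X)
    g = _grouped_mean(cfg, t, smoothing, prior=0.5)
    cfg_t = cfg * 2 + t
    q = _grouped_mean(cfg_t, y, smoothing, prior=float(y.mean()))
    g = np.clip(g, clip[0], clip[1])
    return SensitivityInputs(t, y, X, g, q)


def _config_codes(X: pd.DataFrame) -> np.ndarray:
    if X.shape[1] == 0:
        return np.zeros(len(X), dtype=np.int64)
    cols = [np.asarray(X[c], dtype=np.int64) for c in X.columns]
    cards = [int(c.max()) + 1 for c in cols]
    return np.ravel_multi_index(cols, cards)


def _grouped_mean(codes, values, smoothing, prior) -> np.ndarray:
    codes = np.asarray(codes)
    uniq, inv = np.unique(codes, return_inverse=True)
    sums = np.bincount(inv, weights=values, minlength=len(uniq))
    cnts = np.bincount(inv, minlength=len(uniq))
    est = (sums + smoothing * prior) / (cnts + smoothing)
    return est[inv]


def _bracket(g: np.ndarray, alpha: float) -> np.ndarray:
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    m = 1.0 / alpha - 1.0
    return (
        digamma(g * m + 1.0)
        - digamma((1.0 - g) * m)
        - digamma(g * m)
        + digamma((1.0 - g) * m + 1.0)
    )


def confounding_bias(g, alpha: float, delta: float) -> float:
    """ATE bias induced by a confounder of strengths (alpha, delta)."""
    g = np.asarray(g, dtype=float)
    return float(delta * _bracket(g, alpha).mean())


def delta_for_bias(g, alpha: float, bias_level: float) -> float:
    """Invert :func:`confounding_bias` in its (linear) delta argument."""
    g = np.asarray(g, dtype=float)
    b = _bracket(g, alpha).mean()
    if not np.isfinite(b) or b <= 0:
        raise BiasUnattainableError(
            f"degenerate digamma bracket ({b}) at alpha={alpha}"
        )
    return float(bias_level / b)


def partial_r2(
    delta: float,
    g,
    alpha: float,
    inputs: SensitivityInputs,
    n_draws: int = 2000,
    seed: int = 0,
) -> float:
    """Partial variance in Y explained by the hypothetical confounder.

    The outcome shift is delta * (logit g~ - E[logit g~ | T, X]) with
    g~ | X ~ Beta(g m, (1-g) m); conditioning on the realised treatment
    tilts the Beta to (g m + T, (1-g) m + 1 - T).  The conditional variance
    of logit g~ is integrated by Monte Carlo with a fixed seed, de-duplicated
    over unique (g, T) pairs.  The ratio is clipped into [0, 1].
    """
    g = np.asarray(g, dtype=float)
    resid_var = float(np.mean((inputs.y - inputs.q) ** 2))
    if resid_var <= 0:
        raise ValueError("degenerate outcome: zero residual variance")
    m = 1.0 / alpha - 1.0
    t = np.asarray(inputs.t, dtype=int)
    a = g * m + t
    b = (1.0 - g) * m + 1 - t
    rng = np.random.default_rng(seed)
    pairs, inv = np.unique(np.column_stack([a, b]), axis=0, return_inverse=True)
    var_u = np.empty(len(pairs))
    for i, (ai, bi) in enumerate(pairs):
        # logit of Beta(a, b) == ln Gamma(a) - ln Gamma(b); sampling the two
        # gammas avoids catastrophic saturation of beta draws near 0/1
        ga = np.clip(rng.gamma(ai, size=n_draws), 1e-300, None)
        gb = np.clip(rng.gamma(bi, size=n_draws), 1e-300, None)
        var_u[i] = np.var(np.log(ga) - np.log(gb))
    explained = delta**2 * float(var_u[inv].mean())
    return float(np.clip(explained / resid_var, 0.0, 1.0))


def trigamma_partial_r2(delta, g, alpha, inputs) -> float:
    """Closed-form counterpart of :func:`partial_r2` using the trigamma
    identity Var(logit g~) = psi1(a) + psi1(b); used as a cross-check."""
    g = np.asarray(g, dtype=float)
    m = 1.0 / alpha - 1.0
    t = np.asarray(inputs.t, dtype=int)
    a = g * m + t
    b = (1.0 - g) * m + 1 - t
    var_u = polygamma(1, a) + polygamma(1, b)
    resid_var = float(np.mean((inputs.y - inputs.q) ** 2))
    return float(np.clip(delta**2 * var_u.mean() / resid_var, 0.0, 1.0))


def covariate_influence(
    inputs: SensitivityInputs, Z: str, smoothing: float = 1.0
) -> tuple[float, float]:
    """(alpha_Z, R^2_Z): the observed covariate Z placed on the Austen axes.

    The nuisance models are refitted without Z; the spread of the full
    propensity around the reduced one calibrates alpha_Z through the Beta
    variance identity Var(g~|X) = g(1-g) alpha, and the outcome-model
    improvement from Z gives R^2_Z.
    """
    if Z not in inputs.covariates.columns:
        raise KeyError(Z)
    X_red = inputs.covariates.drop(columns=[Z])
    red = estimate_nuisance(inputs.t, inputs.y, X_red, smoothing)
    denom = float(np.mean(red.g * (1.0 - red.g)))
    alpha_z = float(np.mean((inputs.g - red.g) ** 2) / denom) if denom > 0 else 0.0
    alpha_z = float(np.clip(alpha_z, 0.0, 1.0))
    base = float(np.mean((inputs.y - red.q) ** 2))
    full = float(np.mean((inputs.y - inputs.q) ** 2))
    r2_z = float(np.clip((base - full) / base, 0.0, 1.0)) if base > 0 else 0.0
    return alpha_z, r2_z


def austen_plot(
    inputs: SensitivityInputs,
    bias_level: float = 0.1,
    alphas=None,
    n_draws: int = 2000,
    seed: int = 0,
    plot_path=None,
) -> SensitivityCurve:
    """Sensitivity curve plus observed-covariate points.

    The verdict is robust when every covariate point lies strictly below
    the interpolated curve (closer to the origin than any confounder able
    to induce ``bias_level``).
    """
    if alphas is None:
        alphas = np.linspace(0.01, 0.99, 99)
    alphas = np.asarray(alphas, dtype=float)
    flags: list[str] = []
    r2 = np.full(len(alphas), np.nan)
    for i, a in enumerate(alphas):
        try:
            d = delta_for_bias(inputs.g, a, bias_level)
        except BiasUnattainableError:
            flags.append(f"bias unattainable at alpha={a:.3g}")
            continue
        r2[i] = partial_r2(d, inputs.g, a, inputs, n_draws=n_draws, seed=seed)
    points = {
        z: covariate_influence(inputs, z)
        for z in inputs.covariates.columns
    }
    ok = ~np.isnan(r2)
    robust = True
    for z, (az, rz) in points.items():
        curve_at = float(np.interp(az, alphas[ok], r2[ok]))
        if rz >= curve_at:
            robust = False
    curve = SensitivityCurve(bias_level, alphas, r2, points, robust, flags)
    if plot_path is not None:
        _render(curve, plot_path)
    return curve


def _render(curve: SensitivityCurve, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ok = ~np.isnan(curve.r2_curve)
    ax.plot(curve.alphas[ok], curve.r2_curve[ok], "k-", label=f"bias = {curve.bias_level}")
    for z, (az, rz) in curve.covariate_points.items():
        ax.plot(az, rz, "o", ms=5)
        ax.annotate(z, (az, rz), fontsize=7)
    ax.set_xlabel(r"$\alpha$ (influence on treatment)")
    ax.set_ylabel(r"$R^2_{Y,\mathrm{par}}$ (influence on outcome)")
    ax.set_xlim(0, 1)
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
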