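"""Causal-effect estimators and directionality diagnostics.

Given harmonized per-variant associations with an exposure (β_GX) and an
outcome (β_GY), the single-instrument causal estimate is the Wald ratio
β_XY = β_GY / β_GX. Multi-instrument combiners:

* ``ivw_mre`` — inverse-variance-weighted meta-analysis with a
  multiplicative random-effects scale floored at 1 (the SE never shrinks
  below the fixed-effect SE);
* ``ivw_additive`` — DerSimonian–Laird additive random effects, offered as
  an alternative combiner for strongly heterogeneous instruments;
* ``mr_egger`` — weighted regression of β_GY on β_GX with a free
  intercept; an intercept distinguishable from zero signals directional
  horizontal pleiotropy;
* ``weighted_median`` — median of the ratio estimates under
  inverse-variance weights, consistent when at least half the weight comes
  from valid instruments; SE by seeded parametric bootstrap.

``steiger_filter`` checks that an instrument explains more variance in the
exposure than in the outcome (i.e. that it acts on the outcome *through*
the exposure), and ``binary_trait_r2`` supplies the pseudo-R² needed to
make that comparison against a case-control outcome.

All confidence intervals are 95% intervals using the 1.96 normal quantile;
p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigurationError, InsufficientInstrumentsError

__all__ = [
    "MREstimate",
    "SteigerResult",
    "wald_ratio",
    "ivw_mre",
    "ivw_additive",
    "mr_egger",
    "weighted_median",
    "steiger_filter",
    "binary_trait_r2",
]

Z95 = 1.96


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds or SD scale."""

    method: str
    beta_xy: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_instruments: int

    @property
    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) = exp of the log-scale estimate and CI.
        Overflowing bounds saturate at inf."""

        def _exp(x: float) -> float:
            try:
                return math.exp(x)
            except OverflowError:
                return math.inf

        return (_exp(self.beta_xy), _exp(self.ci_low), _exp(self.ci_high))


@dataclass(frozen=True)
class SteigerResult:
    r2_gx: float
    r2_gy: float
    direction_ok: bool
    z: float
    pvalue: float


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _estimate(method: str, b: float, se: float, k: int, pvalue: float | None = None) -> MREstimate:
    p = _normal_p(b / se) if pvalue is None else pvalue
    return MREstimate(
        method=method,
        beta_xy=b,
        se=se,
        ci_low=b - Z95 * se,
        ci_high=b + Z95 * se,
        pvalue=p,
        n_instruments=k,
    )


def wald_ratio(
    beta_gx: float,
    se_gx: float,
    beta_gy: float,
    se_gy: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument Wald estimate β_GY / β_GX.

    The SE uses the first-order delta method |se_gy / beta_gx| (the
    outcome-variance term dominates for strong instruments); pass
    ``second_order=True`` to add the exposure-variance term
    β_GY²·se_GX²/β_GX⁴.
    """
    if beta_gx == 0:
        raise ZeroDivisionError("Wald ratio undefined: beta_gx is zero")
    b = beta_gy / beta_gx
    var = (se_gy / beta_gx) ** 2
    if second_order:
        var += beta_gy**2 * se_gx**2 / beta_gx**4
    return _estimate("wald", b, math.sqrt(var), 1)


def _check_k(k: int, minimum: int, what: str) -> None:
    if k < minimum:
        if minimum == 2:
            raise InsufficientInstrumentsError(
                f"{what} needs >= 2 instruments (got {k}); use wald_ratio for one"
            )
        raise InsufficientInstrumentsError(f"{what} needs >= {minimum} instruments (got {k})")


def ivw_mre(estimates: list[tuple[float, float]]) -> MREstimate:
    """Inverse-variance-weighted combination with multiplicative random
    effects.

    Point estimate Σwb/Σw with w = 1/se²; residual scale
    φ = max(1, Q/(k−1)) where Q = Σ w (b − b̂)²; SE = sqrt(φ/Σw).
    """
    _check_k(len(estimates), 2, "ivw_mre")
    b = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ConfigurationError("all standard errors must be positive")
    w = 1.0 / se**2
    bhat = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - bhat) ** 2))
    phi = max(1.0, q / (len(b) - 1))
    se_hat = math.sqrt(phi / float(np.sum(w)))
    return _estimate("ivw_mre", bhat, se_hat, len(b))


def ivw_additive(estimates: list[tuple[float, float]]) -> MREstimate:
    """DerSimonian–Laird additive random-effects combination (supplementary
    combiner for strongly heterogeneous instruments)."""
    _check_k(len(estimates), 2, "ivw_additive")
    b = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    w = 1.0 / se**2
    bhat_fe = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - bhat_fe) ** 2))
    k = len(b)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    bhat = float(np.sum(w_star * b) / np.sum(w_star))
    se_hat = math.sqrt(1.0 / float(np.sum(w_star)))
    return _estimate("ivw_additive", bhat, se_hat, k)


def mr_egger(
    pairs: list[tuple[float, float, float]],
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression.

    ``pairs`` are (beta_gx, beta_gy, se_gy) triples. Pairs are first
    re-oriented so every beta_gx >= 0 (both betas sign-flipped together);
    then beta_gy is regressed on beta_gx with weights 1/se_gy² and a free
    intercept. The residual scale is floored at 1, as in :func:`ivw_mre`
    (k−2 degrees of freedom). Returns (slope, intercept) estimates; the
    intercept is the directional-pleiotropy test. p-values use the t
    distribution with k−2 df when the residual scale exceeds 1, the normal
    otherwise.
    """
    _check_k(len(pairs), 3, "mr_egger")
    bx = np.array([p[0] for p in pairs], dtype=float)
    by = np.array([p[1] for p in pairs], dtype=float)
    sy = np.array([p[2] for p in pairs], dtype=float)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx = bx * flip
    by = by * flip
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    k = len(bx)
    phi = max(1.0, float(fit.scale))
    # statsmodels reports SEs under the estimated scale; re-floor at 1
    bse = fit.bse * math.sqrt(phi / float(fit.scale))
    df = k - 2

    def pval(z: float) -> float:
        if phi > 1.0:
            return float(2.0 * stats.t.sf(abs(z), df))
        return _normal_p(z)

    intercept = _estimate(
        "egger_intercept", float(fit.params[0]), float(bse[0]), k,
        pvalue=pval(fit.params[0] / bse[0]),
    )
    slope = _estimate(
        "egger_slope", float(fit.params[1]), float(bse[1]), k,
        pvalue=pval(fit.params[1] / bse[1]),
    )
    return slope, intercept


def weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by linear interpolation of the ordered estimates at
    normalized cumulative weight 0.5 (cumulative weights taken at bin
    midpoints, (S_i − w_i/2)/S_k)."""
    order = np.argsort(b)
    b = np.asarray(b, dtype=float)[order]
    w = np.asarray(w, dtype=float)[order]
    s = np.cumsum(w)
    c = (s - 0.5 * w) / s[-1]
    return float(np.interp(0.5, c, b))


def weighted_median(
    estimates: list[tuple[float, float]],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median estimator with inverse-variance weights and a seeded
    parametric-bootstrap SE (each ratio re-drawn from Normal(b_i, se_i²))."""
    _check_k(len(estimates), 3, "weighted_median")
    b = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    w = 1.0 / se**2
    point = weighted_median_point(b, w)
    rng = np.random.default_rng(seed)
    draws = b[None, :] + se[None, :] * rng.standard_normal((n_boot, len(b)))
    boots = np.array([weighted_median_point(row, w) for row in draws])
    se_hat = float(np.std(boots, ddof=1))
    if se_hat == 0.0:
        # degenerate (all estimates identical); report a vanishing SE
        se_hat = float(np.finfo(float).tiny)
        p = 1.0 if point == 0.0 else 0.0
        return MREstimate("weighted_median", point, se_hat, point, point, p, len(b))
    return _estimate("weighted_median", point, se_hat, len(b))


def steiger_filter(r2_gx: float, n_x: int, r2_gy: float, n_y: int) -> SteigerResult:
    """Directionality check: does the variant explain more variance in the
    exposure than in the outcome?

    z compares the Fisher-transformed correlations √R²_GX and √R²_GY with
    independent-sample variances 1/(n−3).
    """
    for r2 in (r2_gx, r2_gy):
        if not 0.0 <= r2 < 1.0:
            raise ConfigurationError(f"r2 {r2} outside [0, 1)")
    if n_x <= 3 or n_y <= 3:
        raise ConfigurationError("Steiger test needs n > 3 in both samples")
    z = (math.atanh(math.sqrt(r2_gx)) - math.atanh(math.sqrt(r2_gy))) / math.sqrt(
        1.0 / (n_x - 3) + 1.0 / (n_y - 3)
    )
    return SteigerResult(
        r2_gx=r2_gx,
        r2_gy=r2_gy,
        direction_ok=r2_gx > r2_gy,
        z=z,
        pvalue=_normal_p(z),
    )


def binary_trait_r2(
    beta: float,
    se: float,
    n_case: int,
    n_control: int,
    eaf: float | None = None,
) -> float:
    """Approximate variance explained by one variant in a case-control
    trait, on a pseudo-R² scale comparable with a quantitative R²:
    z²/(z² + n_eff) with z = beta/se and n_eff = 4/(1/n_case + 1/n_control).

    ``eaf`` is accepted for signature symmetry with the quantitative
    diagnostic but is not used by this observed-scale approximation.
    """
    if n_case <= 0 or n_control <= 0:
        raise ConfigurationError("case and control counts must be positive")
    z = beta / se
    n_eff = 4.0 / (1.0 / n_case + 1.0 / n_control)
    return z * z / (z * z + n_eff)
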