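"""Core Mendelian randomisation estimators on summarised data.

All estimators regress SNP-outcome effects on SNP-exposure effects with
weights equal to the inverse variance of the outcome effect estimate
(the summary-data instrumental-variable method of Johnson; the univariate
case of the multivariable summarised-data approach of Burgess):

* ``ivw``   — weighted regression through the origin; the conventional MR
  estimate. Valid when no SNP has a direct (horizontal-pleiotropic) path to
  the outcome.
* ``mvmr``  — adds SNP-covariate effect columns to the design, adjusting for
  *measured* pleiotropy.
* ``egger`` — unconstrained intercept; the intercept estimates directional
  (unbalanced) pleiotropy and the slope is a pleiotropy-corrected causal
  estimate under the InSIDE assumption (instrument strength independent of
  direct effects).

Exposure-side uncertainty (se_x) is ignored in the weights throughout; it
is retained in the data model for the parametric resampling scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    EstimationError,
    InsufficientSnpsError,
    ParameterError,
    SingularInstrumentError,
)
from .summary_data import EffectWithCI, HarmonisedInstrument, to_effect_with_ci

__all__ = [
    "MrEstimate", "HeterogeneityResult", "wald_ratio", "ivw", "mvmr",
    "egger", "cochran_q", "heterogeneity_p",
]


@dataclass(frozen=True)
class MrEstimate:
    """A causal effect of the exposure on the outcome, log-odds per SD.

    ``intercept`` fields are populated only for the Egger method, where the
    intercept (with its t-based p-value on J-2 df) is the test for
    directional pleiotropy.
    """

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    covariates: tuple = ()
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def to_effect_with_ci(self, level: float = 0.95) -> EffectWithCI:
        return to_effect_with_ci(self.beta, self.se, level)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran Q over per-SNP Wald ratios."""

    q: float
    df: int
    p: float


def wald_ratio(bx: float, by: float, se_y: float):
    """Per-SNP causal estimate by/bx with first-order SE se_y/|bx|.

    Exposure uncertainty is ignored (first-order approximation).
    """
    if bx == 0:
        raise EstimationError("Wald ratio undefined: exposure beta is zero")
    if se_y <= 0:
        raise ParameterError(f"se_y must be positive, got {se_y}")
    return by / bx, se_y / abs(bx)


def _weights(instr: HarmonisedInstrument) -> np.ndarray:
    return 1.0 / instr.se_y**2


def ivw(instr: HarmonisedInstrument, scale_by_dispersion: bool = False) -> MrEstimate:
    """Inverse-variance-weighted estimate: weighted regression of by on bx
    constrained through the origin.

    beta = sum(w bx by) / sum(w bx^2), se = sqrt(1 / sum(w bx^2)), with
    w = 1/se_y^2 and a normal-approximation p-value. With
    ``scale_by_dispersion`` the SE is multiplied by the square root of the
    (>=1-truncated) residual dispersion, a random-effects-flavoured
    alternative.
    """
    w = _weights(instr)
    sxx = float(np.sum(w * instr.bx**2))
    if sxx <= 0:
        raise SingularInstrumentError("all exposure betas are zero")
    beta = float(np.sum(w * instr.bx * instr.by) / sxx)
    se = math.sqrt(1.0 / sxx)
    if scale_by_dispersion and instr.j > 1:
        rss = float(np.sum(w * (instr.by - beta * instr.bx) ** 2))
        se *= math.sqrt(max(1.0, rss / (instr.j - 1)))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return MrEstimate("ivw", beta, se, p, instr.j)


def mvmr(instr: HarmonisedInstrument, covariate_subset=None) -> MrEstimate:
    """Multivariable MR: weighted regression of by on [bx, covariate betas]
    with no intercept; returns the exposure coefficient and its SE from the
    weighted normal equations.
    """
    labels = list(instr.covariate_labels if covariate_subset is None else covariate_subset)
    cols = instr.covariate_index(labels)
    p_dim = 1 + len(labels)
    if instr.j < p_dim:
        raise InsufficientSnpsError(
            f"mvmr with {len(labels)} covariates needs J >= {p_dim}, got J={instr.j}")
    X = np.column_stack([instr.bx, instr.bc[:, cols]])
    w = _weights(instr)
    xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(xw) < p_dim:
        r = np.abs(np.diag(np.linalg.qr(xw, mode="r")))
        bad = [(["exposure"] + labels)[i] for i in np.where(r < 1e-10 * max(r.max(), 1.0))[0]]
        raise SingularInstrumentError(f"collinear design columns: {bad or labels}")
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * instr.by)
    cov = np.linalg.inv(xtwx)
    coef = cov @ xtwy
    beta, se = float(coef[0]), math.sqrt(float(cov[0, 0]))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return MrEstimate("mvmr", beta, se, p, instr.j, covariates=tuple(labels))


def egger(instr: HarmonisedInstrument) -> MrEstimate:
    """MR-Egger: weighted regression of by on bx with an unconstrained
    intercept.

    SNPs are first re-oriented so every exposure beta is non-negative (the
    intercept is not invariant to allele orientation). Slope and intercept
    SEs use the weighted residual dispersion on J-2 df with t inference,
    the convention of standard weighted least squares.
    """
    if instr.j < 3:
        raise InsufficientSnpsError(f"Egger regression needs J >= 3, got J={instr.j}")
    s = np.where(instr.bx < 0, -1.0, 1.0)
    x = instr.bx * s
    y = instr.by * s
    w = _weights(instr)
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    if np.linalg.matrix_rank(X * np.sqrt(w)[:, None]) < 2:
        raise SingularInstrumentError("exposure betas are constant; Egger slope undefined")
    cov_u = np.linalg.inv(xtwx)
    coef = cov_u @ (X.T @ (w * y))
    resid = y - X @ coef
    df = instr.j - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    cov = cov_u * sigma2
    slope, intercept = float(coef[1]), float(coef[0])
    se_slope = math.sqrt(float(cov[1, 1]))
    se_int = math.sqrt(float(cov[0, 0]))
    p_slope = float(2 * stats.t.sf(abs(slope) / se_slope, df)) if se_slope > 0 else 0.0
    p_int = float(2 * stats.t.sf(abs(intercept) / se_int, df)) if se_int > 0 else 0.0
    return MrEstimate("egger", slope, se_slope, p_slope, instr.j,
                      intercept=intercept, intercept_se=se_int, intercept_p=p_int)


def cochran_q(instr: HarmonisedInstrument, theta: float) -> HeterogeneityResult:
    """Cochran Q over per-SNP Wald ratios around a causal effect ``theta``.

    Q = sum (r_j - theta)^2 / se_r_j^2 with r_j = by_j/bx_j and first-order
    se_r_j = se_y_j/|bx_j|; df = J-1; p from the upper chi-square tail.
    """
    if instr.j < 2:
        raise InsufficientSnpsError(f"Cochran Q needs J >= 2, got J={instr.j}")
    if np.any(instr.bx == 0):
        raise EstimationError("Wald ratio undefined: an exposure beta is zero")
    r = instr.by / instr.bx
    se_r = instr.se_y / np.abs(instr.bx)
    q = float(np.sum(((r - theta) / se_r) ** 2))
    df = instr.j - 1
    return HeterogeneityResult(q=q, df=df, p=heterogeneity_p(q, df))


def heterogeneity_p(q: float, df: int) -> float:
    """Upper-tail chi-square probability of a heterogeneity statistic."""
    if q < 0 or df < 1:
        raise ParameterError("need q >= 0 and df >= 1")
    return float(stats.chi2.sf(q, df))


def estimate(instr: HarmonisedInstrument, method: str, covariate_subset=None) -> MrEstimate:
    """Dispatch by method label ('ivw', 'mvmr', 'egger')."""
    if method == "ivw":
        return ivw(instr)
    if method == "mvmr":
        return mvmr(instr, covariate_subset)
    if method == "egger":
        return egger(instr)
    raise ParameterError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Vectorised closed-form kernels used by the resampling module. Arrays have
# SNPs on the last axis; leading axes index resamples.

def _bcast(w, like):
    return np.broadcast_to(w, like.shape)


def ivw_batch(bx, by, w):
    sxx = np.sum(w * bx * bx, axis=-1)
    return np.sum(w * bx * by, axis=-1) / sxx


def egger_batch(bx, by, w):
    """Weighted simple-regression slope/intercept with bx >= 0 orientation."""
    s = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * s, by * s
    w = _bcast(w, x)
    sw = np.sum(w, axis=-1)
    mx = np.sum(w * x, axis=-1) / sw
    my = np.sum(w * y, axis=-1) / sw
    dx = x - mx[..., None]
    sxx = np.sum(w * dx * dx, axis=-1)
    slope = np.sum(w * dx * (y - my[..., None]), axis=-1) / sxx
    return slope, my - slope * mx


def mvmr_batch(bx, bc, by, w):
    """Exposure coefficient from batched weighted normal equations.

    bx, by: (..., J); bc: (..., J, M); w broadcastable to bx.
    """
    X = np.concatenate([bx[..., None], bc], axis=-1)
    w = _bcast(w, bx)
    xtwx = np.einsum("...jp,...j,...jq->...pq", X, w, X)
    xtwy = np.einsum("...jp,...j->...p", X, w * by)
    return np.linalg.solve(xtwx, xtwy[..., None])[..., 0, 0]
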