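"""Fixed-effects inverse-variance meta-analysis and observational-scale
conversion.

The observational literature often reports disease odds ratios comparing the
top versus bottom tertile of an exposure distribution. For a normally
distributed exposure the means of the top and bottom tertiles are separated
by ~2.18 SDs, which converts a tertile-contrast OR to a per-SD OR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "MetaResult", "fixed_effect_meta", "tertile_sd_factor",
    "tertile_or_to_per_sd", "per_sd_or_to_tertile",
]


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effects estimate with heterogeneity summaries."""

    beta: float
    se: float
    k: int
    q: float
    i2: float  # percentage in [0, 100]

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.beta) / self.se))


def fixed_effect_meta(betas, ses) -> MetaResult:
    """Inverse-variance weighted fixed-effects pooling.

    beta = sum(w_i b_i) / sum(w_i) with w_i = 1/se_i^2;
    se = sqrt(1 / sum(w_i)); Q = sum w_i (b_i - beta)^2;
    I^2 = max(0, (Q - (k-1)) / Q) * 100 (0 when Q == 0).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.ndim != 1 or betas.shape != ses.shape:
        raise ParameterError(
            f"betas and ses must be equal-length vectors, got {betas.shape} vs {ses.shape}")
    if betas.size == 0:
        raise ParameterError("empty input")
    if not np.all(ses > 0):
        raise ParameterError("all ses must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (betas - beta) ** 2))
    k = int(betas.size)
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return MetaResult(beta=beta, se=se, k=k, q=q, i2=i2)


def tertile_sd_factor() -> float:
    """Separation, in SD units, of the top and bottom tertile means of a
    standard normal distribution.

    The mean of the top tertile is E[Z | Z > q] = 3 phi(q) with
    q = Phi^{-1}(2/3); by symmetry the bottom tertile mean is its negative,
    so the separation is 6 phi(q) ~= 2.18.
    """
    q = stats.norm.ppf(2.0 / 3.0)
    return float(6.0 * stats.norm.pdf(q))


def tertile_or_to_per_sd(or_tertile: float) -> float:
    """Convert a top-vs-bottom-tertile OR to a per-SD OR."""
    if or_tertile <= 0:
        raise ParameterError(f"odds ratio must be positive, got {or_tertile}")
    return math.exp(math.log(or_tertile) / tertile_sd_factor())


def per_sd_or_to_tertile(or_per_sd: float) -> float:
    """Inverse of :func:`tertile_or_to_per_sd`."""
    if or_per_sd <= 0:
        raise ParameterError(f"odds ratio must be positive, got {or_per_sd}")
    return math.exp(math.log(or_per_sd) * tertile_sd_factor())
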