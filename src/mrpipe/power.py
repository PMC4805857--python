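"""Statistical power for summary-data Mendelian randomisation designs.

Prospective power follows the Brion non-centrality approximation: the MR
test statistic is approximately normal with mean
``|effect| * sqrt(n * R2 * v)``, where R2 is the exposure variance explained
by the instrument and v = case_fraction * (1 - case_fraction) for a binary
outcome (1 for a continuous outcome). Retrospective power evaluates the same
normal formula at an observed estimate and SE: the complement of the false
non-rejection rate at the point estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ParameterError

__all__ = ["PowerSpec", "prospective_power", "retrospective_power"]


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs for a prospective MR power calculation.

    ``true_effect`` is the hypothesised causal effect per SD of exposure:
    log-OR for a binary outcome, SD units for a continuous one.
    ``case_fraction`` is None for continuous outcomes.
    """

    n: float
    r2: float
    true_effect: float
    alpha: float = 0.05
    case_fraction: float | None = None

    def __post_init__(self):
        if self.n <= 0:
            raise ParameterError(f"n must be positive, got {self.n}")
        if not 0 < self.r2 < 1:
            raise ParameterError(f"r2 must be in (0,1), got {self.r2}")
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0,1), got {self.alpha}")
        if self.case_fraction is not None and not 0 < self.case_fraction < 1:
            raise ParameterError(
                f"case_fraction must be in (0,1), got {self.case_fraction}")


def _two_sided_power(ncp: float, alpha: float) -> float:
    za = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(ncp - za) + stats.norm.cdf(-ncp - za))


def prospective_power(spec: PowerSpec) -> float:
    """Design-based power of the two-sided MR test."""
    v = 1.0
    if spec.case_fraction is not None:
        v = spec.case_fraction * (1.0 - spec.case_fraction)
    ncp = abs(spec.true_effect) * math.sqrt(spec.n * spec.r2 * v)
    return _two_sided_power(ncp, spec.alpha)


def retrospective_power(beta_hat: float, se: float, alpha: float = 0.05) -> float:
    """Power evaluated at an observed estimate and its SE.

    The complement of the false rejection rate with the true effect set to
    the point estimate.
    """
    if se <= 0:
        raise ParameterError(f"se must be positive, got {se}")
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0,1), got {alpha}")
    return _two_sided_power(abs(beta_hat) / se, alpha)
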