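"""Empirical inference by resampling summary statistics, and the
leave-k-SNPs-out sensitivity scan.

Two resampling schemes are provided:

* ``parametric`` (default): every beta (exposure, outcome, covariate) is
  perturbed by independent normal noise with that statistic's reported SE —
  i.e. each resample is a draw from the summary statistics' sampling
  distributions. This avoids having to derive an analytic SE for the
  recomputed estimator.
* ``nonparametric``: each resample draws J SNPs with replacement from the
  instrument.

The sensitivity scan repeatedly removes k SNPs at random, re-estimates, and
reports the proportion of replicate estimates falling outside the
normal-theory CI of the full-data estimate; more than 5% outside flags the
result as sensitive to SNP selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientSnpsError, ParameterError
from .estimators import egger_batch, estimate, ivw_batch, mvmr_batch
from .summary_data import HarmonisedInstrument, z_quantile

__all__ = ["ResampleResult", "SensitivityResult", "bootstrap", "leave_k_out_scan"]

_MIN_SNPS = {"ivw": 1, "egger": 3}


@dataclass
class ResampleResult:
    """Empirical distribution summary of a resampled MR statistic."""

    estimates: np.ndarray
    point_estimate: float
    ci_low: float
    ci_high: float
    p_empirical: float
    b: int
    seed: int
    scheme: str
    level: float
    method: str


@dataclass
class SensitivityResult:
    """Outcome of the leave-k-SNPs-out stability scan."""

    n_reps: int
    k_excluded: int
    prop_outside: float
    flagged: bool
    estimate: float
    ci_low: float
    ci_high: float
    seed: int
    method: str


def _min_snps(method: str, n_covariates: int) -> int:
    if method == "mvmr":
        return n_covariates + 1
    return _MIN_SNPS.get(method, 1)


def _batch_estimates(method, bx, by, w, bc=None):
    if method == "ivw":
        return ivw_batch(bx, by, w)
    if method == "egger":
        return egger_batch(bx, by, w)[0]
    if method == "mvmr":
        return mvmr_batch(bx, bc, by, w)
    raise ParameterError(f"unknown method {method!r}")


def bootstrap(instr: HarmonisedInstrument, method: str = "ivw", b: int = 10_000,
              seed: int = 0, scheme: str = "parametric", level: float = 0.95,
              covariate_subset=None) -> ResampleResult:
    """Recompute an MR estimator over ``b`` resamples of the summary data.

    Returns the empirical quantile CI at ``level`` and a two-sided
    sign-based empirical p-value, clamped below at 2/b.
    """
    if b < 100:
        raise ParameterError(f"b must be >= 100, got {b}")
    if scheme not in ("parametric", "nonparametric"):
        raise ParameterError(f"unknown scheme {scheme!r}")
    labels = list(instr.covariate_labels if covariate_subset is None else covariate_subset)
    cols = instr.covariate_index(labels) if method == "mvmr" else None
    point = estimate(instr, method, labels if method == "mvmr" else None).beta

    rng = np.random.default_rng(seed)
    j = instr.j
    if scheme == "parametric":
        bx = instr.bx + rng.standard_normal((b, j)) * instr.se_x
        by = instr.by + rng.standard_normal((b, j)) * instr.se_y
        w = 1.0 / instr.se_y**2
        bc = None
        if method == "mvmr":
            bc = (instr.bc[:, cols]
                  + rng.standard_normal((b, j, len(cols))) * instr.se_c[:, cols])
        est = _batch_estimates(method, bx, by, w, bc)
    else:
        need = _min_snps(method, len(labels))
        if j < need:
            raise InsufficientSnpsError(
                f"nonparametric resampling of '{method}' needs J >= {need}, got J={j}")
        idx = rng.integers(0, j, size=(b, j))
        if need > 1:
            # redraw resamples carrying too few distinct SNPs for the method
            for _ in range(1000):
                distinct = np.sort(idx, axis=1)
                n_distinct = 1 + np.count_nonzero(np.diff(distinct, axis=1), axis=1)
                bad = np.where(n_distinct < need)[0]
                if bad.size == 0:
                    break
                idx[bad] = rng.integers(0, j, size=(bad.size, j))
            else:
                raise InsufficientSnpsError(
                    "could not draw resamples with enough distinct SNPs")
        bx, by = instr.bx[idx], instr.by[idx]
        w = 1.0 / instr.se_y[idx] ** 2
        bc = instr.bc[:, cols][idx] if method == "mvmr" else None
        est = _batch_estimates(method, bx, by, w, bc)

    lo, hi = np.quantile(est, [(1 - level) / 2, (1 + level) / 2])
    p = 2.0 * min(np.mean(est <= 0), np.mean(est >= 0))
    p = float(min(1.0, max(2.0 / b, p)))
    return ResampleResult(estimates=est, point_estimate=point, ci_low=float(lo),
                          ci_high=float(hi), p_empirical=p, b=b, seed=seed,
                          scheme=scheme, level=level, method=method)


def leave_k_out_scan(instr: HarmonisedInstrument, method: str = "ivw",
                     covariate_subset=None, k: int = 6, n_reps: int = 10_000,
                     seed: int = 0, level: float = 0.95) -> SensitivityResult:
    """Stability of the causal estimate under random exclusion of k SNPs.

    The full-data estimate and its normal-theory CI are computed once; each
    replicate removes k distinct SNPs chosen uniformly at random,
    re-estimates, and tests whether the replicate estimate falls inside the
    CI. A result is flagged when more than 5% fall outside.
    """
    if not 0 <= k < instr.j:
        raise ParameterError(f"k must satisfy 0 <= k < J={instr.j}, got {k}")
    if n_reps < 100:
        raise ParameterError(f"n_reps must be >= 100, got {n_reps}")
    labels = list(instr.covariate_labels if covariate_subset is None else covariate_subset)
    full = estimate(instr, method, labels if method == "mvmr" else None)
    z = z_quantile(level)
    lo, hi = full.beta - z * full.se, full.beta + z * full.se
    keep = instr.j - k
    if _min_snps(method, len(labels) if method == "mvmr" else 0) > keep:
        raise ParameterError(f"removing {k} of {instr.j} SNPs leaves too few for '{method}'")

    if k == 0:
        prop = 0.0
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_reps, instr.j)), axis=1)[:, :keep]
        bx, by = instr.bx[idx], instr.by[idx]
        w = 1.0 / instr.se_y[idx] ** 2
        bc = None
        if method == "mvmr":
            cols = instr.covariate_index(labels)
            bc = instr.bc[:, cols][idx]
        est = _batch_estimates(method, bx, by, w, bc)
        prop = float(np.mean((est < lo) | (est > hi)))
    return SensitivityResult(n_reps=n_reps, k_excluded=k, prop_outside=prop,
                             flagged=prop > 0.05, estimate=full.beta,
                             ci_low=lo, ci_high=hi, seed=seed, method=method)
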