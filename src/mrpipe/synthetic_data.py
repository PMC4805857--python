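"""Synthetic two-sample summary statistics with known ground truth.

The generator emulates the causal diagram of a multi-SNP MR study: J
independent SNPs affect a standardised exposure with effects ``true_bx``
(drawn as absolute normals, scaled so the instrument explains ``r2`` of the
exposure variance — 4.2% for 31 SNPs by default). The latent SNP-outcome
effect on the log-odds scale is

    theta * true_bx_j  +  sum_m gamma_m * true_bc_{j,m}  +  alpha_j

where ``true_bc`` are SNP-covariate effects (nonzero on a random pleiotropic
subset), ``gamma`` the covariate-to-outcome paths (measured pleiotropy),
and ``alpha_j ~ N(mu_alpha, sigma_alpha)`` direct horizontal pleiotropy
drawn independently of instrument strength, so the InSIDE assumption holds
by construction. Observed betas add normal sampling noise at the reported
SEs; genotypes are implicitly standardised to unit variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ParameterError
from .summary_data import HarmonisedInstrument, SnpAssociation, write_summary_table

__all__ = [
    "SimulationTruth", "LabelledInstrument", "DEFAULT_COVARIATES",
    "generate", "generate_replicates", "generate_null_suite",
    "to_association_tables", "write_trait_tables",
]

DEFAULT_COVARIATES = ("SBP", "DBP", "HDL", "TG")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of one synthetic two-sample MR dataset.

    Defaults mimic a 31-SNP instrument for a standardised exposure
    explaining ~4.2% of its variance, a binary outcome measured in a
    ~200k-sample case-control meta-analysis (log-odds SE scale 0.007), and
    exposure/covariate effects from large quantitative-trait meta-analyses
    (SE scale 0.0025).
    """

    theta: float = 0.17
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    gamma: tuple = ()
    j: int = 31
    r2: float = 0.042
    se_x_scale: float = 0.0025
    se_y_scale: float = 0.007
    se_c_scale: float | None = None
    sigma_c: float = 0.015
    pleiotropic_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.j < 1:
            raise ParameterError(f"j must be >= 1, got {self.j}")
        if self.sigma_alpha < 0:
            raise ParameterError("sigma_alpha must be >= 0")
        if not 0 < self.r2 < 1:
            raise ParameterError(f"r2 must be in (0,1), got {self.r2}")
        for name in ("se_x_scale", "se_y_scale"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.pleiotropic_fraction <= 1:
            raise ParameterError("pleiotropic_fraction must be in [0,1]")
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))


@dataclass
class LabelledInstrument:
    """A harmonised instrument together with the latent truth behind it."""

    instrument: HarmonisedInstrument
    truth: SimulationTruth
    true_bx: np.ndarray
    true_alpha: np.ndarray
    true_bc: np.ndarray


def _gamma(truth: SimulationTruth, n_labels: int) -> np.ndarray:
    g = np.asarray(truth.gamma, dtype=float)
    if g.size == 0:
        return np.zeros(n_labels)
    if g.size != n_labels:
        raise ParameterError(
            f"gamma has length {g.size} but {n_labels} covariate labels given")
    return g


def _latents(truth: SimulationTruth, n_labels: int, rng: np.random.Generator):
    j = truth.j
    scale = np.sqrt(truth.r2 / j)
    true_bx = np.abs(rng.normal(0.0, scale, j))
    se_x = truth.se_x_scale * rng.uniform(0.7, 1.3, j)
    se_y = truth.se_y_scale * rng.uniform(0.7, 1.3, j)
    se_c_scale = truth.se_c_scale if truth.se_c_scale is not None else truth.se_x_scale
    se_c = se_c_scale * rng.uniform(0.7, 1.3, (j, n_labels))
    pleio = rng.random(j) < truth.pleiotropic_fraction
    true_bc = np.where(pleio[:, None], rng.normal(0.0, truth.sigma_c, (j, n_labels)), 0.0)
    alpha = rng.normal(truth.mu_alpha, truth.sigma_alpha, j)
    return true_bx, se_x, se_y, se_c, true_bc, alpha


def _assemble(truth, covariate_labels, latents, noise_rng, noise):
    true_bx, se_x, se_y, se_c, true_bc, alpha = latents
    gamma = _gamma(truth, len(covariate_labels))
    latent_by = truth.theta * true_bx + true_bc @ gamma + alpha
    if noise:
        bx = true_bx + noise_rng.standard_normal(truth.j) * se_x
        by = latent_by + noise_rng.standard_normal(truth.j) * se_y
        bc = true_bc + noise_rng.standard_normal(se_c.shape) * se_c
    else:
        bx, by, bc = true_bx.copy(), latent_by.copy(), true_bc.copy()
    snp_ids = [f"rs{1000 + i}" for i in range(truth.j)]
    instr = HarmonisedInstrument(snp_ids, bx, se_x, by, se_y,
                                 list(covariate_labels), bc, se_c)
    return LabelledInstrument(instr, truth, true_bx, alpha, true_bc)


def generate(truth: SimulationTruth, covariate_labels=DEFAULT_COVARIATES,
             noise: bool = True) -> LabelledInstrument:
    """Draw one synthetic dataset. With ``noise=False`` the observed betas
    equal the latent values (reported SEs unchanged), giving the
    deterministic limit used for exact-recovery checks."""
    rng = np.random.default_rng(truth.seed)
    return _assemble(truth, covariate_labels, _latents(truth, len(covariate_labels), rng),
                     rng, noise)


def generate_replicates(truth: SimulationTruth, n_reps: int,
                        covariate_labels=DEFAULT_COVARIATES, noise_seed: int = 0):
    """Datasets sharing one latent configuration (drawn from ``truth.seed``)
    with independent measurement noise per replicate.

    Fixing the latents makes conditional biases visible: e.g. with a drawn
    covariate-pleiotropy pattern held fixed, IVW is biased while MVMR
    adjusting for that covariate is not.
    """
    latents = _latents(truth, len(covariate_labels), np.random.default_rng(truth.seed))
    out = []
    for i in range(n_reps):
        noise_rng = np.random.default_rng((noise_seed, i))
        out.append(_assemble(truth, covariate_labels, latents, noise_rng, True))
    return out


def generate_null_suite(n_datasets: int, seed: int, **overrides):
    """Independent datasets with theta = 0 and no directional pleiotropy,
    for type-I-error studies of the IVW, Egger, and Q tests."""
    if n_datasets < 1:
        raise ParameterError("n_datasets must be >= 1")
    overrides.pop("theta", None)
    overrides.pop("mu_alpha", None)
    labels = overrides.pop("covariate_labels", DEFAULT_COVARIATES)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, n_datasets)
    return [generate(SimulationTruth(theta=0.0, mu_alpha=0.0, seed=int(s), **overrides),
                     labels)
            for s in seeds]


def to_association_tables(li: LabelledInstrument, n_flipped: int = 0,
                          seed: int = 0, flip_covariates: bool = False):
    """Express a labelled instrument as per-trait association lists, with
    the allele encoding of ``n_flipped`` random outcome rows reversed
    (effect/other swapped, beta negated) to exercise harmonisation.

    Returns (exposure, outcome, covariates, flipped_ids).
    """
    instr = li.instrument
    rng = np.random.default_rng(seed)
    flipped = set()
    if n_flipped:
        if n_flipped > instr.j:
            raise ParameterError("cannot flip more rows than SNPs")
        flipped = set(rng.choice(instr.j, size=n_flipped, replace=False).tolist())
    exposure = [SnpAssociation(s, "A", "G", b, se, "exposure")
                for s, b, se in zip(instr.snp_ids, instr.bx, instr.se_x)]

    def _maybe_flip(rec, i):
        return rec.flip() if i in flipped else rec

    outcome = [_maybe_flip(SnpAssociation(s, "A", "G", b, se, "outcome"), i)
               for i, (s, b, se) in enumerate(zip(instr.snp_ids, instr.by, instr.se_y))]
    covariates = {}
    for m, label in enumerate(instr.covariate_labels):
        rows = [SnpAssociation(s, "A", "G", b, se, label)
                for s, b, se in zip(instr.snp_ids, instr.bc[:, m], instr.se_c[:, m])]
        if flip_covariates:
            rows = [_maybe_flip(r, i) for i, r in enumerate(rows)]
        covariates[label] = rows
    return exposure, outcome, covariates, sorted(instr.snp_ids[i] for i in flipped)


def write_trait_tables(li: LabelledInstrument, outdir, delimiter: str = "\t",
                       n_flipped: int = 0, seed: int = 0) -> dict:
    """Write one summary table per trait plus truth.json; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, covariates, flipped = to_association_tables(
        li, n_flipped=n_flipped, seed=seed)
    paths = {}
    for name, rows in [("exposure", exposure), ("outcome", outcome),
                       *covariates.items()]:
        path = outdir / f"{name}.tsv"
        write_summary_table(rows, path, delimiter)
        paths[name] = str(path)
    truth_path = outdir / "truth.json"
    payload = asdict(li.truth)
    payload["flipped_outcome_rows"] = flipped
    truth_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths["truth"] = str(truth_path)
    return paths
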