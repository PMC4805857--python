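"""End-to-end orchestration: harmonise, estimate, resample, scan, power.

``run_full_analysis`` executes the full analysis sequence on a conforming
input set and writes a results table (one row per method, OR with CI),
per-SNP Wald-ratio data for forest/funnel plots, sensitivity and power
tables, and a JSON run manifest with the seed and input digests. Outputs are
deterministic given the config, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import MrPipeError, ParameterError, PipelineStageError
from .estimators import cochran_q, egger, ivw, mvmr, wald_ratio
from .power import retrospective_power
from .resampling import bootstrap, leave_k_out_scan
from .summary_data import (
    HarmonisedInstrument,
    harmonise,
    read_summary_table,
    to_effect_with_ci,
    z_quantile,
)

logger = logging.getLogger(__name__)

STAGE_EXIT_CODES = {
    "read": 2, "harmonise": 3, "estimate": 4, "resample": 5,
    "sensitivity": 6, "power": 7, "write": 8,
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    exposure: str
    outcome: str
    covariates: dict = field(default_factory=dict)  # label -> path
    covariate_subset: list | None = None
    methods: tuple = ("ivw", "mvmr", "egger")
    bootstrap_reps: int = 10_000
    sensitivity_reps: int = 10_000
    k_exclude: int = 6
    scheme: str = "parametric"
    seed: int = 0
    level: float = 0.95
    output_dir: str = "mr_output"
    allow_missing_covariates: bool = False

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise ParameterError(f"level must be in (0,1), got {self.level}")
        self.methods = tuple(self.methods)
        unknown = set(self.methods) - {"ivw", "mvmr", "egger"}
        if unknown:
            raise ParameterError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def input_paths(self) -> dict:
        paths = {"exposure": self.exposure, "outcome": self.outcome}
        paths.update({f"covariate:{k}": v for k, v in self.covariates.items()})
        return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _or_row(est, level):
    eff = est.to_effect_with_ci(level)
    return {
        "method": est.method,
        "covariates": ",".join(est.covariates),
        "n_snps": est.n_snps,
        "beta": est.beta, "se": est.se, "p": est.p,
        "or": round(eff.or_value, 4),
        "or_ci_low": round(eff.ci_low, 4),
        "or_ci_high": round(eff.ci_high, 4),
        "intercept": est.intercept, "intercept_se": est.intercept_se,
        "intercept_p": est.intercept_p,
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Run the full analysis sequence; returns paths and key results.

    Any stage error aborts with :class:`PipelineStageError`; files written
    so far are removed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_tsv(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
        return path

    try:
        return _run(config, outdir, written, _write_tsv)
    except PipelineStageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except MrPipeError as exc:
        raise PipelineStageError(name, str(exc)) from exc
    except OSError as exc:
        raise PipelineStageError(name, str(exc)) from exc


def _run(config, outdir, written, _write_tsv):
    level = config.level
    alpha = 1.0 - level

    def read_inputs():
        exposure = read_summary_table(config.exposure, "exposure")
        outcome = read_summary_table(config.outcome, "outcome")
        covs = {label: read_summary_table(path, label)
                for label, path in config.covariates.items()}
        return exposure, outcome, covs

    exposure, outcome, covs = _stage("read", read_inputs)
    logger.info("read %d exposure, %d outcome SNPs, %d covariate traits",
                len(exposure), len(outcome), len(covs))

    instr: HarmonisedInstrument = _stage(
        "harmonise", harmonise, exposure, outcome, covs,
        allow_missing_covariates=config.allow_missing_covariates)
    logger.info("harmonised instrument: %d of %d SNPs retained",
                instr.j, len(exposure))
    _stage("write", lambda: written.append(outdir / "harmonised.tsv") or
           instr.write_tsv(outdir / "harmonised.tsv"))

    # per-SNP Wald ratios (forest/funnel export)
    z = z_quantile(level)
    ratios = [wald_ratio(bx, by, se) for bx, by, se in zip(instr.bx, instr.by, instr.se_y)]
    wald_df = pd.DataFrame({
        "snp": instr.snp_ids,
        "bx": instr.bx, "se_x": instr.se_x, "by": instr.by, "se_y": instr.se_y,
        "ratio": [r for r, _ in ratios], "se_ratio": [s for _, s in ratios],
    })
    wald_df["ci_low"] = wald_df["ratio"] - z * wald_df["se_ratio"]
    wald_df["ci_high"] = wald_df["ratio"] + z * wald_df["se_ratio"]
    wald_df["precision"] = 1.0 / wald_df["se_ratio"]
    _stage("write", _write_tsv, wald_df, "wald_ratios.tsv")

    subset = (list(config.covariates.keys()) if config.covariate_subset is None
              else list(config.covariate_subset))
    estimates = {}
    for method in config.methods:
        if method == "ivw":
            estimates[method] = _stage("estimate", ivw, instr)
        elif method == "mvmr":
            estimates[method] = _stage("estimate", mvmr, instr, subset)
        else:
            estimates[method] = _stage("estimate", egger, instr)
        logger.info("%s: beta=%.4f se=%.4f", method, estimates[method].beta,
                    estimates[method].se)

    rows = [_or_row(est, level) for est in estimates.values()]
    het = None
    if "ivw" in estimates and instr.j >= 2:
        het = _stage("estimate", cochran_q, instr, estimates["ivw"].beta)
        for row in rows:
            if row["method"] == "ivw":
                row["q"], row["q_df"], row["q_p"] = het.q, het.df, het.p

    boot = None
    if "egger" in estimates:
        boot = _stage("resample", bootstrap, instr, "egger",
                      b=config.bootstrap_reps, seed=config.seed,
                      scheme=config.scheme, level=level)
        for row in rows:
            if row["method"] == "egger":
                row["boot_or_ci_low"] = round(math.exp(boot.ci_low), 4)
                row["boot_or_ci_high"] = round(math.exp(boot.ci_high), 4)
                row["boot_p"] = boot.p_empirical
    results_df = pd.DataFrame(rows)
    _stage("write", _write_tsv, results_df, "results.tsv")

    sens_rows = []
    for method, est in estimates.items():
        if config.k_exclude >= instr.j:
            raise PipelineStageError(
                "sensitivity", f"k_exclude={config.k_exclude} >= J={instr.j}")
        scan = _stage("sensitivity", leave_k_out_scan, instr, method,
                      covariate_subset=subset if method == "mvmr" else None,
                      k=config.k_exclude, n_reps=config.sensitivity_reps,
                      seed=config.seed, level=level)
        sens_rows.append({"method": method, "k_excluded": scan.k_excluded,
                          "n_reps": scan.n_reps, "prop_outside": scan.prop_outside,
                          "flagged": scan.flagged})
    _stage("write", _write_tsv, pd.DataFrame(sens_rows), "sensitivity.tsv")

    power_rows = [{"method": m, "retrospective_power":
                   _stage("power", retrospective_power, est.beta, est.se, alpha)}
                  for m, est in estimates.items()]
    _stage("write", _write_tsv, pd.DataFrame(power_rows), "power.tsv")

    manifest = {
        "package": "mrpipe",
        "version": __version__,
        "seed": config.seed,
        "level": level,
        "methods": list(config.methods),
        "covariate_subset": subset,
        "n_snps_exposure": len(exposure),
        "n_snps_harmonised": instr.j,
        "inputs": {name: {"path": str(path), "sha256": _sha256(path)}
                   for name, path in config.input_paths().items()},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    manifest_path = outdir / "manifest.json"
    written.append(manifest_path)
    _stage("write", manifest_path.write_text,
           json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "output_dir": str(outdir),
        "instrument": instr,
        "estimates": estimates,
        "heterogeneity": het,
        "egger_bootstrap": boot,
        "sensitivity": sens_rows,
        "power": power_rows,
        "files": {p.name: str(p) for p in written},
    }
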