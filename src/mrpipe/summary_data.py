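"""Data model, file I/O, allele harmonisation, and scale conversions for
two-sample summary statistics.

A two-sample Mendelian randomisation analysis combines per-SNP association
estimates from separate GWAS of an exposure (here, a quantitative trait in
SD units) and an outcome (log-odds for a binary disease endpoint), plus
optional covariate traits used to adjust for measured pleiotropy. Before any
regression, all traits must be expressed per copy of the *same* effect
allele for each SNP; this module performs that alignment.

Binary-outcome effects are stored as log-odds throughout; odds-ratio
conversion happens only at the presentation boundary via
:func:`to_effect_with_ci`.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyInstrumentError,
    HarmonisationError,
    ParameterError,
    SummaryTableError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REQUIRED_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se")


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's effect estimate and SE for one trait.

    ``beta`` is the additive effect per copy of ``effect_allele``: SD units
    for quantitative traits, log-odds for binary traits.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    trait: str = ""
    source: str = ""

    def __post_init__(self):
        if self.effect_allele not in _COMPLEMENT or self.other_allele not in _COMPLEMENT:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta is not finite")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be positive and finite, got {self.se}")

    def flip(self) -> "SnpAssociation":
        """Re-express the association on the opposite allele (sign change)."""
        return SnpAssociation(
            self.snp_id, self.other_allele, self.effect_allele,
            -self.beta, self.se, self.trait, self.source,
        )


@dataclass
class HarmonisedInstrument:
    """Allele-aligned summary statistics for J SNPs across traits.

    All betas refer to the same effect allele per SNP. ``bc``/``se_c`` are
    J x M matrices over ``covariate_labels`` (M may be zero).
    """

    snp_ids: list
    bx: np.ndarray
    se_x: np.ndarray
    by: np.ndarray
    se_y: np.ndarray
    covariate_labels: list = field(default_factory=list)
    bc: np.ndarray | None = None
    se_c: np.ndarray | None = None

    def __post_init__(self):
        self.snp_ids = list(self.snp_ids)
        j = len(self.snp_ids)
        for name in ("bx", "se_x", "by", "se_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (j,):
                raise ValidationError(f"{name} has shape {arr.shape}, expected ({j},)")
            setattr(self, name, arr)
        self.covariate_labels = list(self.covariate_labels)
        m = len(self.covariate_labels)
        if self.bc is None:
            self.bc = np.zeros((j, 0))
        if self.se_c is None:
            self.se_c = np.zeros((j, 0))
        self.bc = np.asarray(self.bc, dtype=float).reshape(j, m)
        self.se_c = np.asarray(self.se_c, dtype=float).reshape(j, m)
        if j < 1:
            raise EmptyInstrumentError("instrument has no SNPs")
        for name, arr in (("se_x", self.se_x), ("se_y", self.se_y), ("se_c", self.se_c)):
            if arr.size and not np.all(arr > 0):
                raise ValidationError(f"{name} contains non-positive entries")
        for name, arr in (("bx", self.bx), ("by", self.by), ("bc", self.bc)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite entries")

    @property
    def j(self) -> int:
        return len(self.snp_ids)

    @property
    def m(self) -> int:
        return len(self.covariate_labels)

    def covariate_index(self, labels) -> np.ndarray:
        try:
            return np.array([self.covariate_labels.index(l) for l in labels], dtype=int)
        except ValueError as exc:
            raise ParameterError(f"unknown covariate label: {exc}") from exc

    def subset(self, idx) -> "HarmonisedInstrument":
        """New instrument restricted to the SNPs at integer positions ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return HarmonisedInstrument(
            [self.snp_ids[i] for i in idx],
            self.bx[idx], self.se_x[idx], self.by[idx], self.se_y[idx],
            list(self.covariate_labels), self.bc[idx], self.se_c[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"snp": self.snp_ids, "bx": self.bx, "se_x": self.se_x,
                "by": self.by, "se_y": self.se_y}
        for m, label in enumerate(self.covariate_labels):
            data[f"bc_{label}"] = self.bc[:, m]
            data[f"se_c_{label}"] = self.se_c[:, m]
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read_tsv(cls, path) -> "HarmonisedInstrument":
        df = pd.read_csv(path, sep="\t")
        needed = {"snp", "bx", "se_x", "by", "se_y"}
        missing = needed - set(df.columns)
        if missing:
            raise SummaryTableError(f"{path}: missing columns {sorted(missing)}")
        labels = [c[3:] for c in df.columns if c.startswith("bc_")]
        bc = np.column_stack([df[f"bc_{l}"] for l in labels]) if labels else None
        se_c = np.column_stack([df[f"se_c_{l}"] for l in labels]) if labels else None
        return cls(list(df["snp"]), df["bx"].to_numpy(), df["se_x"].to_numpy(),
                   df["by"].to_numpy(), df["se_y"].to_numpy(), labels, bc, se_c)


@dataclass(frozen=True)
class EffectWithCI:
    """A log-scale effect with its odds-ratio presentation."""

    beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    level: float

    def __post_init__(self):
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValidationError("CI does not bracket the point estimate")


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_summary_table(path, trait: str) -> list:
    """Read per-SNP summary statistics from a TSV/CSV file.

    The file must have a header with columns
    ``snp effect_allele other_allele beta se`` (an ``eaf`` column and any
    extras are ignored). Delimiter (tab or comma) is auto-detected and CRLF
    line endings are accepted. Malformed rows are reported together with
    their line numbers.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    lines = io.StringIO(text)
    first = lines.readline()
    if not first.strip():
        raise SummaryTableError(f"{path}: empty file")
    delim = _detect_delimiter(first)
    lines.seek(0)
    reader = csv.DictReader(lines, delimiter=delim)
    fieldnames = [f.strip().lower() for f in (reader.fieldnames or [])]
    reader.fieldnames = fieldnames
    missing = [c for c in REQUIRED_COLUMNS if c not in fieldnames]
    if missing:
        raise SummaryTableError(f"{path}: missing required column(s) {missing}")

    records, problems = [], []
    for lineno, row in enumerate(reader, start=2):
        try:
            rec = SnpAssociation(
                snp_id=(row["snp"] or "").strip(),
                effect_allele=(row["effect_allele"] or "").strip().upper(),
                other_allele=(row["other_allele"] or "").strip().upper(),
                beta=float(row["beta"]),
                se=float(row["se"]),
                trait=trait,
                source=str(path),
            )
        except ValidationError:
            raise
        except (TypeError, ValueError, KeyError) as exc:
            problems.append(f"line {lineno}: {exc}")
            continue
        records.append(rec)
    if problems:
        raise SummaryTableError(f"{path}: malformed rows: " + "; ".join(problems))
    return records


def write_summary_table(records, path, delimiter: str = "\t") -> None:
    """Write SnpAssociation records in the standard summary-table layout."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow([r.snp_id, r.effect_allele, r.other_allele,
                             repr(float(r.beta)), repr(float(r.se))])


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def _orientation(exp_ea, exp_oa, ea, oa):
    """+1 if (ea, oa) measures the same allele as the exposure, -1 if the
    opposite, None if the allele pairs cannot be reconciled.

    Letter matching first, then strand-complement fallback.
    """
    if (ea, oa) == (exp_ea, exp_oa):
        return 1
    if (ea, oa) == (exp_oa, exp_ea):
        return -1
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (exp_ea, exp_oa):
        return 1
    if (cea, coa) == (exp_oa, exp_ea):
        return -1
    return None


def harmonise(exposure, outcome, covariates=None,
              allow_missing_covariates: bool = False) -> HarmonisedInstrument:
    """Align outcome and covariate associations to the exposure effect allele.

    SNPs are kept in exposure order. Where the outcome (or a covariate)
    reports the exposure's other allele, the beta sign is flipped. Allele
    pairs that cannot be reconciled by letter matching or strand complement
    are dropped with a warning; palindromic SNPs (A/T, G/C) are aligned by
    letter matching and dropped if their letters conflict, since no allele
    frequencies are assumed.

    Covariate rows missing for a SNP raise :class:`HarmonisationError`
    unless ``allow_missing_covariates`` is set, in which case beta 0 with a
    huge SE (weight-exclusion) is imputed.
    """
    covariates = covariates or {}
    out_by_id = {r.snp_id: r for r in outcome}
    cov_by_id = {label: {r.snp_id: r for r in rows} for label, rows in covariates.items()}
    labels = list(covariates.keys())

    snp_ids, bx, se_x, by, se_y = [], [], [], [], []
    bc_rows, se_c_rows = [], []
    missing_outcome = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            missing_outcome.append(exp.snp_id)
            continue
        sign = _orientation(exp.effect_allele, exp.other_allele,
                            out.effect_allele, out.other_allele)
        if sign is None:
            kind = "palindromic " if _is_palindromic(exp.effect_allele, exp.other_allele) else ""
            logger.warning("dropping %sSNP %s: outcome alleles %s/%s irreconcilable with %s/%s",
                           kind, exp.snp_id, out.effect_allele, out.other_allele,
                           exp.effect_allele, exp.other_allele)
            continue
        row_bc, row_se_c, ok = [], [], True
        for label in labels:
            cov = cov_by_id[label].get(exp.snp_id)
            if cov is None:
                if not allow_missing_covariates:
                    raise HarmonisationError(
                        f"SNP {exp.snp_id} missing from covariate '{label}' "
                        f"(use allow_missing_covariates to impute a zero-weight cell)")
                row_bc.append(0.0)
                row_se_c.append(1e6)
                continue
            csign = _orientation(exp.effect_allele, exp.other_allele,
                                 cov.effect_allele, cov.other_allele)
            if csign is None:
                logger.warning("dropping SNP %s: covariate '%s' alleles irreconcilable",
                               exp.snp_id, label)
                ok = False
                break
            row_bc.append(csign * cov.beta)
            row_se_c.append(cov.se)
        if not ok:
            continue
        snp_ids.append(exp.snp_id)
        bx.append(exp.beta)
        se_x.append(exp.se)
        by.append(sign * out.beta)
        se_y.append(out.se)
        bc_rows.append(row_bc)
        se_c_rows.append(row_se_c)

    if missing_outcome and not snp_ids:
        raise EmptyInstrumentError(
            f"no exposure SNP found in the outcome set (missing: {missing_outcome[:5]}...)")
    if missing_outcome:
        raise HarmonisationError(
            f"{len(missing_outcome)} exposure SNP(s) absent from the outcome set: "
            f"{missing_outcome}")
    if not snp_ids:
        raise EmptyInstrumentError("no SNPs survived harmonisation")
    m = len(labels)
    return HarmonisedInstrument(
        snp_ids, bx, se_x, by, se_y, labels,
        np.array(bc_rows, dtype=float).reshape(len(snp_ids), m),
        np.array(se_c_rows, dtype=float).reshape(len(snp_ids), m),
    )


def instrument_to_associations(instr: HarmonisedInstrument,
                               effect_allele: str = "A",
                               other_allele: str = "G"):
    """Express a harmonised instrument back as per-trait association lists
    (all on the same nominal allele pair). Useful for round-tripping."""
    exposure = [SnpAssociation(s, effect_allele, other_allele, b, se, "exposure")
                for s, b, se in zip(instr.snp_ids, instr.bx, instr.se_x)]
    outcome = [SnpAssociation(s, effect_allele, other_allele, b, se, "outcome")
               for s, b, se in zip(instr.snp_ids, instr.by, instr.se_y)]
    covs = {}
    for m, label in enumerate(instr.covariate_labels):
        covs[label] = [SnpAssociation(s, effect_allele, other_allele, b, se, label)
                       for s, b, se in zip(instr.snp_ids, instr.bc[:, m], instr.se_c[:, m])]
    return exposure, outcome, covs


def z_quantile(level: float) -> float:
    """Standard-normal quantile for a two-sided interval at ``level``."""
    if not 0 < level < 1:
        raise ParameterError(f"level must be in (0,1), got {level}")
    return float(stats.norm.ppf((1 + level) / 2))


def ci_to_se(or_low: float, or_high: float, level: float = 0.95) -> float:
    """Recover the log-scale SE from a published OR confidence interval.

    se = (ln(or_high) - ln(or_low)) / (2 z), with z the two-sided normal
    quantile at ``level``.
    """
    if or_low <= 0:
        raise ParameterError(f"or_low must be positive, got {or_low}")
    if or_high < or_low:
        raise ParameterError("or_high must be >= or_low")
    z = z_quantile(level)
    return (math.log(or_high) - math.log(or_low)) / (2 * z)


def to_effect_with_ci(beta: float, se: float, level: float = 0.95) -> EffectWithCI:
    """Present a log-scale effect as an OR with a symmetric-on-log-scale CI."""
    if se < 0:
        raise ParameterError(f"se must be non-negative, got {se}")
    z = z_quantile(level)
    return EffectWithCI(
        beta=float(beta), se=float(se), or_value=math.exp(beta),
        ci_low=math.exp(beta - z * se), ci_high=math.exp(beta + z * se),
        level=level,
    )
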