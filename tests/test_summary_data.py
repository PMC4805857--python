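"""Parsing, allele harmonisation, and OR/CI scale conversions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrpipe import (
    HarmonisedInstrument,
    SnpAssociation,
    ci_to_se,
    harmonise,
    read_summary_table,
    to_effect_with_ci,
    write_summary_table,
)
from mrpipe.errors import (
    EmptyInstrumentError,
    ParameterError,
    SummaryTableError,
    ValidationError,
)
from mrpipe.summary_data import instrument_to_associations
from mrpipe.synthetic_data import SimulationTruth, generate, to_association_tables


def snp(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, trait="x"):
    return SnpAssociation(snp_id, ea, oa, beta, se, trait)


class TestReadSummaryTable:
    def test_well_formed_tsv(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "snp\teffect_allele\tother_allele\tbeta\tse\n"
            "rs1\tA\tG\t0.1\t0.01\n"
            "rs2\tC\tT\t-0.2\t0.02\n"
            "rs3\tG\tA\t0.05\t0.03\n")
        recs = read_summary_table(path, "urate")
        assert len(recs) == 3
        assert recs[0].snp_id == "rs1" and recs[0].beta == pytest.approx(0.1)
        assert all(r.trait == "urate" for r in recs)

    def test_zero_se_raises_validation_error_naming_snp(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("snp\teffect_allele\tother_allele\tbeta\tse\n"
                        "rs9\tA\tG\t0.1\t0\n")
        with pytest.raises(ValidationError, match="rs9"):
            read_summary_table(path, "urate")

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("snp\teffect_allele\tbeta\tse\nrs1\tA\t0.1\t0.01\n")
        with pytest.raises(SummaryTableError, match="other_allele"):
            read_summary_table(path, "urate")

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("snp\teffect_allele\tother_allele\tbeta\tse\n"
                        "rs1\tA\tG\t0.1\t0.01\n"
                        "rs2\tA\tG\tnot_a_number\t0.01\n")
        with pytest.raises(SummaryTableError, match="line 3"):
            read_summary_table(path, "urate")

    @pytest.mark.parametrize("delimiter,newline", [("\t", "\n"), (",", "\n"),
                                                   ("\t", "\r\n"), (",", "\r\n")])
    def test_roundtrip_any_delimiter_and_line_ending(self, tmp_path, delimiter, newline):
        records = [snp("rs1", beta=0.123456789), snp("rs2", "C", "T", -0.2, 0.5)]
        path = tmp_path / "t.txt"
        write_summary_table(records, path, delimiter)
        if newline == "\r\n":
            path.write_bytes(path.read_bytes().replace(b"\n", b"\r\n"))
        got = read_summary_table(path, "x")
        assert [(r.snp_id, r.effect_allele, r.other_allele, r.beta, r.se)
                for r in got] == [(r.snp_id, r.effect_allele, r.other_allele,
                                   r.beta, r.se) for r in records]


class TestHarmonise:
    def test_swapped_alleles_flip_sign(self):
        instr = harmonise([snp("rs1", "A", "G", 0.1, 0.01)],
                          [snp("rs1", "G", "A", 0.02, 0.01, "y")])
        assert instr.by[0] == pytest.approx(-0.02)

    def test_identical_alleles_unchanged(self):
        instr = harmonise([snp("rs1", "A", "G", 0.1, 0.01)],
                          [snp("rs1", "A", "G", 0.02, 0.01, "y")])
        assert instr.by[0] == pytest.approx(0.02)

    def test_strand_complement_fallback(self):
        # outcome reported on the opposite strand: T/C complements A/G
        instr = harmonise([snp("rs1", "A", "G", 0.1, 0.01)],
                          [snp("rs1", "T", "C", 0.02, 0.01, "y")])
        assert instr.by[0] == pytest.approx(0.02)
        instr = harmonise([snp("rs1", "A", "G", 0.1, 0.01)],
                          [snp("rs1", "C", "T", 0.02, 0.01, "y")])
        assert instr.by[0] == pytest.approx(-0.02)

    def test_irreconcilable_palindromic_snp_dropped_with_warning(self, caplog):
        exposure = [snp("rs1", "A", "T", 0.1, 0.01), snp("rs2", "A", "G", 0.2, 0.01)]
        outcome = [snp("rs1", "G", "C", 0.02, 0.01, "y"),
                   snp("rs2", "A", "G", 0.03, 0.01, "y")]
        with caplog.at_level("WARNING"):
            instr = harmonise(exposure, outcome)
        assert instr.snp_ids == ["rs2"]
        assert any("rs1" in rec.message for rec in caplog.records)

    def test_empty_intersection_raises(self):
        with pytest.raises(EmptyInstrumentError):
            harmonise([snp("rs1")], [snp("rs2", trait="y")])

    def test_scrambled_31snp_set_recovers_ground_truth(self):
        li = generate(SimulationTruth(seed=5))
        exposure, outcome, covs, flipped = to_association_tables(li, n_flipped=5, seed=9)
        assert len(flipped) == 5
        instr = harmonise(exposure, outcome, covs)
        truth = li.instrument
        assert instr.snp_ids == truth.snp_ids
        np.testing.assert_allclose(instr.by, truth.by)
        np.testing.assert_allclose(instr.bx, truth.bx)
        np.testing.assert_allclose(instr.bc, truth.bc)

    def test_missing_covariate_row_errors_unless_allowed(self):
        exposure = [snp("rs1"), snp("rs2")]
        outcome = [snp("rs1", trait="y"), snp("rs2", trait="y")]
        covs = {"SBP": [snp("rs1", trait="SBP")]}
        with pytest.raises(Exception, match="SBP"):
            harmonise(exposure, outcome, covs)
        instr = harmonise(exposure, outcome, covs, allow_missing_covariates=True)
        assert instr.bc[1, 0] == 0.0
        assert instr.se_c[1, 0] >= 1e5  # effectively zero weight

    def test_idempotent_on_own_output(self):
        li = generate(SimulationTruth(seed=6))
        instr = harmonise(*to_association_tables(li, n_flipped=8, seed=2)[:3])
        exposure, outcome, covs = instrument_to_associations(instr)
        again = harmonise(exposure, outcome, covs)
        np.testing.assert_array_equal(again.bx, instr.bx)
        np.testing.assert_array_equal(again.by, instr.by)
        np.testing.assert_array_equal(again.bc, instr.bc)

    def test_double_flip_is_identity(self):
        li = generate(SimulationTruth(seed=7))
        _, outcome, _, _ = to_association_tables(li)
        flipped_twice = [r.flip().flip() for r in outcome]
        assert [(r.beta, r.effect_allele) for r in flipped_twice] == \
               [(r.beta, r.effect_allele) for r in outcome]


class TestScaleConversions:
    def test_degenerate_interval_gives_zero_se(self):
        assert ci_to_se(1.0, 1.0, 0.95) == pytest.approx(0.0)

    def test_published_egger_ci(self):
        # frozen from the closed form (ln(hi) - ln(lo)) / (2 z_0.975)
        assert ci_to_se(0.9191, 1.1968, 0.95) == pytest.approx(0.067351, abs=5e-6)

    def test_or_presentation_matches_calculator(self):
        eff = to_effect_with_ci(0.0, 0.1, 0.95)
        assert eff.or_value == pytest.approx(1.0)
        assert eff.ci_low == pytest.approx(0.8219, rel=2e-4)
        assert eff.ci_high == pytest.approx(1.2166, rel=2e-4)

    def test_printed_or_and_ci_are_consistent(self):
        # the conventional-MR row: 1.1766 (1.0763 to 1.2861)
        se = ci_to_se(1.0763, 1.2861, 0.95)
        eff = to_effect_with_ci(math.log(1.1766), se, 0.95)
        assert eff.ci_low == pytest.approx(1.0763, rel=2e-4)
        assert eff.ci_high == pytest.approx(1.2861, rel=2e-4)

    def test_zero_se_collapses_ci(self):
        eff = to_effect_with_ci(0.3, 0.0, 0.95)
        assert eff.ci_low == eff.or_value == eff.ci_high == pytest.approx(math.exp(0.3))

    def test_nonpositive_or_is_domain_error(self):
        with pytest.raises(ParameterError):
            ci_to_se(0.0, 1.2, 0.95)

    @given(beta=st.floats(-2, 2), se=st.floats(1e-6, 5),
           level=st.floats(0.5, 0.99))
    def test_se_ci_roundtrip(self, beta, se, level):
        eff = to_effect_with_ci(beta, se, level)
        assert ci_to_se(eff.ci_low, eff.ci_high, level) == pytest.approx(se, abs=1e-10, rel=1e-10)


class TestInvariants:
    def test_se_must_be_positive(self):
        with pytest.raises(ValidationError):
            snp(se=-0.01)

    def test_alleles_must_differ(self):
        with pytest.raises(ValidationError):
            snp(ea="A", oa="A")

    def test_instrument_rejects_nonpositive_se(self):
        with pytest.raises(ValidationError):
            HarmonisedInstrument(["rs1"], [0.1], [0.0], [0.1], [0.1])

    def test_wide_tsv_roundtrip(self, tmp_path, random_instrument_factory):
        instr = random_instrument_factory(3, j=6, m=2)
        path = tmp_path / "h.tsv"
        instr.write_tsv(path)
        got = HarmonisedInstrument.read_tsv(path)
        assert got.snp_ids == instr.snp_ids
        assert got.covariate_labels == instr.covariate_labels
        np.testing.assert_allclose(got.bc, instr.bc, rtol=1e-10)
        np.testing.assert_allclose(got.by, instr.by, rtol=1e-10)
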