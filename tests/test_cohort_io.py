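"""PED / VCF / TSV readers, writers and round trips."""

import pytest

from retprio import io as cohort_io
from retprio.model import (
    Affection,
    Genotype,
    PedigreeError,
    StageCode,
    VariantKey,
)
from retprio.prediction import Call
from retprio.synthetic import SimulationConfig, simulate_cohort

TRIO_PED = """\
FAM1 dad 0 0 1 1
FAM1 mom 0 0 2 1
FAM1 kid dad mom 1 2
"""


@pytest.fixture
def trio_ped_path(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text(TRIO_PED)
    return p


class TestPed:
    def test_trio_field_mapping(self, trio_ped_path):
        peds = cohort_io.read_ped(trio_ped_path)
        assert len(peds) == 1
        fam = peds["FAM1"]
        assert len(fam.affected) == 1
        assert fam["kid"].father_id == "dad"
        assert fam["dad"].is_founder
        assert fam["dad"].affection is Affection.UNAFFECTED

    def test_unknown_affection_codes(self, tmp_path):
        p = tmp_path / "x.ped"
        p.write_text("F a 0 0 0 0\nF b 0 0 1 -9\nF c 0 0 2 2\n")
        peds = cohort_io.read_ped(p)
        fam = peds["F"]
        assert fam["a"].affection is Affection.UNKNOWN
        assert fam["b"].affection is Affection.UNKNOWN

    def test_missing_parent_is_structural_error(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text("FAM1 kid ghost 0 1 2\n")
        with pytest.raises(PedigreeError):
            cohort_io.read_ped(p)

    def test_duplicate_individual_is_structural_error(self, tmp_path):
        p = tmp_path / "dup.ped"
        p.write_text("F a 0 0 1 2\nF a 0 0 1 2\n")
        with pytest.raises(PedigreeError):
            cohort_io.read_ped(p)

    def test_short_row_names_line_number(self, tmp_path):
        p = tmp_path / "short.ped"
        p.write_text("F a 0 0 1 2\nF b 0 0\n")
        with pytest.raises(cohort_io.ParseError, match=":2"):
            cohort_io.read_ped(p)

    def test_extra_columns_ignored(self, tmp_path):
        p = tmp_path / "extra.ped"
        p.write_text("F a 0 0 1 2 0.5 extra\n")
        assert len(cohort_io.read_ped(p)["F"].members) == 1

    def test_roundtrip_on_13_family_cohort(self, tmp_path):
        cohort = simulate_cohort(
            SimulationConfig(n_families=13, n_background_variants=0, seed=5,
                             causal={"n_causal_families": 4})
        )
        p1 = tmp_path / "a.ped"
        p1.write_text(cohort.ped_text)
        peds = cohort_io.read_ped(p1)
        p2 = tmp_path / "b.ped"
        cohort_io.write_ped(peds, p2)
        assert p2.read_text() == cohort.ped_text


class TestVcf:
    def _write(self, tmp_path, body, samples=("dad", "mom", "kid")):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n" + body
        )
        return vcf

    def test_gt_semantics(self, tmp_path, trio_ped_path):
        peds = cohort_io.read_ped(trio_ped_path)
        vcf = self._write(tmp_path, "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t./.\n")
        table = cohort_io.read_vcf(vcf, peds)
        rec = table.records[0]
        assert rec.genotype("dad") is Genotype.HET
        assert rec.genotype("mom") is Genotype.HOM_ALT
        assert rec.genotype("kid") is Genotype.MISSING

    def test_phase_separator_ignored(self, tmp_path, trio_ped_path):
        peds = cohort_io.read_ped(trio_ped_path)
        vcf = self._write(tmp_path, "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n")
        rec = cohort_io.read_vcf(vcf, peds).records[0]
        assert rec.genotype("dad") is Genotype.HET

    def test_multiallelic_decomposition(self, tmp_path, trio_ped_path):
        peds = cohort_io.read_ped(trio_ped_path)
        vcf = self._write(
            tmp_path, "1\t100\t.\tG\tA,T\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\n"
        )
        table = cohort_io.read_vcf(vcf, peds)
        assert len(table) == 2
        recs = table.by_key()
        a = recs[VariantKey("1", 100, "G", "A")]
        t = recs[VariantKey("1", 100, "G", "T")]
        assert a.genotype("dad") is Genotype.HET
        assert a.genotype("mom") is Genotype.HOM_REF  # other alt -> ref here
        assert t.genotype("mom") is Genotype.HET
        assert t.genotype("dad") is Genotype.HOM_REF
        # decomposition conserves the total number of alt-carrier calls
        pre_split_carriers = 2
        assert len(a.carriers()) + len(t.carriers()) == pre_split_carriers

    def test_unknown_sample_warned_and_ignored(self, tmp_path, trio_ped_path, caplog):
        peds = cohort_io.read_ped(trio_ped_path)
        vcf = self._write(
            tmp_path,
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/1\n",
            samples=("dad", "mom", "kid", "stranger"),
        )
        with caplog.at_level("WARNING"):
            table = cohort_io.read_vcf(vcf, peds)
        assert "stranger" not in table.records[0].genotypes
        assert any("stranger" in r.message for r in caplog.records)

    def test_members_absent_from_vcf_marked_unsequenced(self, tmp_path, trio_ped_path):
        peds = cohort_io.read_ped(trio_ped_path)
        vcf = self._write(
            tmp_path, "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\n",
            samples=("dad", "mom"),
        )
        cohort_io.read_vcf(vcf, peds)
        assert not peds["FAM1"]["kid"].sequenced
        assert peds["FAM1"]["dad"].sequenced

    def test_generator_vcf_matches_truth_genotype_matrix(self, tmp_path):
        cohort = simulate_cohort(
            SimulationConfig(n_families=6, n_background_variants=25, seed=11,
                             causal={"n_causal_families": 2})
        )
        paths = cohort.write(tmp_path)
        peds = cohort_io.read_ped(paths["cohort.ped"])
        table = cohort_io.read_vcf(paths["cohort.vcf"], peds)
        samples = [m.individual_id for ped in peds for m in ped.members]
        truth = cohort.truth.genotypes
        assert len(table) == 26
        for rec in table:
            expected_nonref = truth[str(rec.key)]
            for s in samples:
                exp = expected_nonref.get(s, "hom_ref")
                assert rec.genotype(s).value == exp, (rec.key, s)


class TestTables:
    def test_annotation_missing_ac_preserved_as_absent(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tgene\tac_gnomad\tac_exac\t"
            "provean_score\tsift_score\tpolyphen2_score_or_label\tmutationtaster_label\n"
            "1\t100\tA\tT\tRP1L1\t\t5\t-3.0\t0.01\tbenign\tdisease_causing\n"
        )
        ann = cohort_io.read_annotations(p)
        va = ann[VariantKey("1", 100, "A", "T")]
        assert va.allele_counts == {"gnomad": None, "exac": 5}
        assert va.gene_symbol == "RP1L1"
        calls = va.predictions.resolve()
        assert calls["polyphen2"] is Call.TOLERATED
        assert calls["mutationtaster"] is Call.DAMAGING

    def test_annotation_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("chrom\tpos\tref\talt\n1\t100\tA\tT\n")
        with pytest.raises(cohort_io.SchemaError):
            cohort_io.read_annotations(p)

    def test_expression_row_parsing(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tntpm\nRP1L1\t12.3\n")
        assert cohort_io.read_expression(p) == {"RP1L1": 12.3}

    def test_expression_non_numeric_is_parse_error(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tntpm\nRP1L1\thigh\n")
        with pytest.raises(cohort_io.ParseError):
            cohort_io.read_expression(p)

    def test_clinical_stage_parsing(self, tmp_path):
        p = tmp_path / "clin.tsv"
        p.write_text(
            "patient_id\tfamily_id\tonset_age\texam_age\tstage\n"
            "P1\tF1\t25\t40\tIIb\nP2\tF1\t30\t\t\n"
        )
        table = cohort_io.read_clinical(p)
        assert table.records[0].stage is StageCode.IIb
        assert table.records[0].duration == 15.0
        assert table.records[1].stage is None
        assert table.records[1].duration is None

    def test_gzip_inputs_accepted(self, tmp_path):
        import gzip

        p = tmp_path / "trio.ped.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(TRIO_PED)
        assert len(cohort_io.read_ped(p)) == 1

    def test_generator_outputs_parse_cleanly(self, tmp_path):
        cohort = simulate_cohort(
            SimulationConfig(n_families=5, n_background_variants=10, seed=2,
                             causal={"n_causal_families": 2})
        )
        paths = cohort.write(tmp_path)
        peds = cohort_io.read_ped(paths["cohort.ped"])
        table = cohort_io.read_vcf(paths["cohort.vcf"], peds)
        ann = cohort_io.read_annotations(paths["annotations.tsv"])
        expr = cohort_io.read_expression(paths["expression.tsv"])
        clin = cohort_io.read_clinical(paths["clinical.tsv"])
        assert len(ann) == len(table) == 11
        assert all(v >= 0 for v in expr.values())
        assert all(r.stage is not None for r in clin)
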