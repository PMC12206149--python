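"""Dominant and recessive within-family co-segregation tests."""

import numpy as np
import pytest

from conftest import make_individual, random_genotypes, random_pedigree, vkey
from retprio.model import (
    Affection,
    DataError,
    Genotype,
    Pedigree,
    PedigreeSet,
    Sex,
    VariantKey,
    VariantRecord,
    VariantTable,
)
from retprio.segregation import (
    DOMINANT,
    RECESSIVE,
    SegregationConfig,
    UsageError,
    apply_segregation,
    segregates_dominant,
    segregates_recessive,
)

HR, HET, HA, MISS = (
    Genotype.HOM_REF,
    Genotype.HET,
    Genotype.HOM_ALT,
    Genotype.MISSING,
)


def oracle_dominant(genotypes, pedigree, max_unaffected_carriers=0):
    """Literal restatement of the genotype conditions, member by member."""
    informative = []
    for m in pedigree.members:
        g = genotypes.get(m.individual_id, MISS)
        if not m.sequenced or g is MISS or m.affection is Affection.UNKNOWN:
            continue
        informative.append((m.affection, g))
    affected = [g for a, g in informative if a is Affection.AFFECTED]
    unaffected = [g for a, g in informative if a is Affection.UNAFFECTED]
    if not affected:
        return False
    if any(g is HR for g in affected):
        return False
    carriers = sum(1 for g in unaffected if g in (HET, HA))
    return carriers <= max_unaffected_carriers


class TestDominant:
    def test_textbook_trio_pattern(self, trio):
        assert segregates_dominant({"dad": HR, "mom": HR, "kid": HET}, trio)

    def test_affected_non_carrier_fails(self, trio):
        assert not segregates_dominant({"dad": HR, "mom": HR, "kid": HR}, trio)

    def test_unaffected_carrier_fails(self, quartet):
        assert not segregates_dominant(
            {"dad": HR, "mom": HR, "kid": HET, "sib": HET}, quartet
        )

    def test_missing_genotype_excludes_the_member(self):
        ped = Pedigree(
            "FAM1",
            [
                make_individual("a1", affection=Affection.AFFECTED),
                make_individual("a2", affection=Affection.AFFECTED),
                make_individual("u1", affection=Affection.UNAFFECTED),
            ],
        )
        assert segregates_dominant({"a1": HET, "a2": MISS, "u1": HR}, ped)

    def test_no_informative_affected_fails(self, trio):
        assert not segregates_dominant({"dad": HR, "mom": HR, "kid": MISS}, trio)

    def test_hom_alt_affected_configurable(self, trio):
        genos = {"dad": HR, "mom": HR, "kid": HA}
        assert segregates_dominant(genos, trio)
        assert not segregates_dominant(
            genos, trio, SegregationConfig(allow_hom_alt_affected=False)
        )

    def test_relaxed_unaffected_carrier_budget(self, quartet):
        genos = {"dad": HR, "mom": HR, "kid": HET, "sib": HET}
        assert segregates_dominant(
            genos, quartet, SegregationConfig(max_unaffected_carriers=1)
        )

    def test_foreign_individual_is_a_data_error(self, trio):
        with pytest.raises(DataError):
            segregates_dominant({"stranger": HET, "kid": HET}, trio)

    def test_unknown_affection_members_are_ignored(self, trio):
        base = {"dad": HR, "mom": HR, "kid": HET}
        extended = Pedigree(
            "FAM1",
            list(trio.members)
            + [make_individual("gp", affection=Affection.UNKNOWN)],
        )
        assert segregates_dominant({**base, "gp": HET}, extended) == \
            segregates_dominant(base, trio)

    def test_matches_bruteforce_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            peds = [random_pedigree(f"F{i}", rng) for i in range(10)]
            for ped in peds:
                for _ in range(50):
                    genos = random_genotypes(ped, rng)
                    assert segregates_dominant(genos, ped) == oracle_dominant(
                        genos, ped
                    )


class TestRecessive:
    @pytest.fixture
    def rec_quartet(self):
        return Pedigree(
            "FAM1",
            [
                make_individual("dad", sex=Sex.MALE, affection=Affection.UNAFFECTED),
                make_individual("mom", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
                make_individual(
                    "kid", father="dad", mother="mom", affection=Affection.AFFECTED
                ),
                make_individual(
                    "sib", father="dad", mother="mom", affection=Affection.UNAFFECTED
                ),
            ],
        )

    def test_classic_homozygous_trio(self, rec_quartet):
        v = (vkey(1), {"dad": HET, "mom": HET, "kid": HA, "sib": HET})
        assert segregates_recessive([v], rec_quartet)

    def test_unaffected_homozygote_fails(self, rec_quartet):
        v = (vkey(1), {"dad": HET, "mom": HET, "kid": HA, "sib": HA})
        assert not segregates_recessive([v], rec_quartet)

    def test_trans_compound_het_passes(self, rec_quartet):
        v1 = (vkey(1), {"dad": HET, "mom": HR, "kid": HET, "sib": HR})
        v2 = (vkey(2), {"dad": HR, "mom": HET, "kid": HET, "sib": HR})
        assert segregates_recessive([v1, v2], rec_quartet)

    def test_cis_pair_from_one_parent_fails(self, rec_quartet):
        v1 = (vkey(1), {"dad": HET, "mom": HR, "kid": HET, "sib": HR})
        v2 = (vkey(2), {"dad": HET, "mom": HR, "kid": HET, "sib": HR})
        assert not segregates_recessive([v1, v2], rec_quartet)

    def test_parental_transmission_configurations_enumerated(self, rec_quartet):
        """Of the four single-donor parental configurations for a het pair,
        only those offering opposite-side transmission pass."""
        for dad_carries, mom_carries, expected in [
            ((True, False), (False, True), True),   # trans
            ((False, True), (True, False), True),   # trans, mirrored
            ((True, True), (False, False), False),  # both from dad: cis
            ((False, False), (True, True), False),  # both from mom: cis
        ]:
            v1 = (
                vkey(1),
                {
                    "dad": HET if dad_carries[0] else HR,
                    "mom": HET if mom_carries[0] else HR,
                    "kid": HET,
                    "sib": HR,
                },
            )
            v2 = (
                vkey(2),
                {
                    "dad": HET if dad_carries[1] else HR,
                    "mom": HET if mom_carries[1] else HR,
                    "kid": HET,
                    "sib": HR,
                },
            )
            assert segregates_recessive([v1, v2], rec_quartet) is expected

    def test_unphaseable_pair_gets_benefit_of_the_doubt(self):
        # no parents in the pedigree: phase cannot be resolved
        ped = Pedigree(
            "FAM1",
            [
                make_individual("kid", affection=Affection.AFFECTED),
                make_individual("sib", affection=Affection.UNAFFECTED),
            ],
        )
        v1 = (vkey(1), {"kid": HET, "sib": HR})
        v2 = (vkey(2), {"kid": HET, "sib": HR})
        assert segregates_recessive([v1, v2], ped)

    def test_unaffected_carrying_both_fails(self, rec_quartet):
        v1 = (vkey(1), {"dad": HET, "mom": HR, "kid": HET, "sib": HET})
        v2 = (vkey(2), {"dad": HR, "mom": HET, "kid": HET, "sib": HET})
        assert not segregates_recessive([v1, v2], rec_quartet)

    def test_multi_gene_input_is_a_usage_error(self, rec_quartet):
        v1 = (vkey(1), {"kid": HET})
        v2 = (vkey(2), {"kid": HET})
        with pytest.raises(UsageError):
            segregates_recessive([v1, v2], rec_quartet, gene_symbols=["A", "B"])


class TestApplySegregation:
    def _cohort(self):
        rng = np.random.default_rng(7)
        peds = PedigreeSet.from_pedigrees(
            [random_pedigree(f"F{i}", rng) for i in range(8)]
        )
        records = []
        for i in range(40):
            genos = {}
            for ped in peds:
                genos.update(random_genotypes(ped, rng))
            records.append(VariantRecord(key=vkey(i), genotypes=genos, gene_symbol="G1"))
        return peds, VariantTable(records=records)

    def test_output_is_subset_of_input(self):
        peds, table = self._cohort()
        out = apply_segregation(table, peds, DOMINANT)
        keys = {r.key for r in table}
        for fam, cands in out.items():
            assert set(cands) <= keys

    def test_agrees_with_per_variant_oracle(self):
        peds, table = self._cohort()
        out = apply_segregation(table, peds, DOMINANT)
        for ped in peds:
            expected = [
                rec.key
                for rec in table
                if oracle_dominant(
                    {m.individual_id: rec.genotype(m.individual_id)
                     for m in ped.sequenced_members},
                    ped,
                )
            ]
            assert out[ped.family_id] == expected

    def test_recessive_on_dominant_only_cohort_is_empty(self, rec_ped=None):
        peds = PedigreeSet.from_pedigrees(
            [
                Pedigree(
                    "F1",
                    [
                        make_individual("a", fam="F1", affection=Affection.AFFECTED),
                        make_individual("u", fam="F1", affection=Affection.UNAFFECTED),
                    ],
                )
            ]
        )
        table = VariantTable(
            records=[
                VariantRecord(vkey(1), {"a": HET, "u": HR}, gene_symbol="G1"),
            ]
        )
        out = apply_segregation(table, peds, RECESSIVE)
        assert out["F1"] == []

    def test_empty_pedigree_set_is_a_usage_error(self):
        with pytest.raises(UsageError):
            apply_segregation(
                VariantTable(records=[]), PedigreeSet(families={}), DOMINANT
            )
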