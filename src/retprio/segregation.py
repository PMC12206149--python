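"""Within-family co-segregation filtering under dominant and recessive models.

The dominant test is the strict full-penetrance comparison of affected
members against unaffected in-family controls: every sequenced affected
member must carry the alternate allele and no sequenced unaffected member
may carry it.  Members with a missing genotype or unknown affection are
uninformative and are excluded from both sides of the comparison rather
than failing the variant.

The recessive test operates per gene: either a single variant homozygous in
all affecteds (and non-homozygous in all unaffecteds), or a compound
heterozygote — two distinct variants each heterozygous in all affecteds
with no unaffected member carrying both.  Exome genotypes are unphased, so
the trans requirement for compound heterozygotes is enforced only when both
parents of an affected are sequenced and resolve the phase; otherwise trans
is assumed possible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import (
    Affection,
    DataError,
    Genotype,
    Pedigree,
    PedigreeSet,
    VariantKey,
    VariantRecord,
    VariantTable,
)

log = logging.getLogger(__name__)


class UsageError(ValueError):
    pass


@dataclass(frozen=True)
class InheritanceModel:
    mode: str  # "dominant" | "recessive"

    def __post_init__(self) -> None:
        if self.mode not in ("dominant", "recessive"):
            raise UsageError(f"unknown inheritance mode {self.mode!r}")


DOMINANT = InheritanceModel("dominant")
RECESSIVE = InheritanceModel("recessive")


@dataclass
class SegregationConfig:
    """Knobs for relaxing the strict full-penetrance test.

    max_unaffected_carriers: how many unaffected carriers a variant may
        show before failing (0 = full penetrance, no phenocopies).
    allow_hom_alt_affected: accept homozygous-alternate affecteds under the
        dominant model (carrier status is what matters, not strict
        heterozygosity).
    """

    max_unaffected_carriers: int = 0
    allow_hom_alt_affected: bool = True


def _carries(g: Genotype) -> Optional[bool]:
    """None for missing calls, else whether the genotype carries the alt."""
    if g is Genotype.MISSING:
        return None
    return g in (Genotype.HET, Genotype.HOM_ALT)


def _validate_members(genotypes: Mapping[str, Genotype], pedigree: Pedigree) -> None:
    unknown = [iid for iid in genotypes if iid not in pedigree]
    if unknown:
        raise DataError(
            f"genotypes reference individual(s) {unknown} not in family "
            f"{pedigree.family_id!r}"
        )


def segregates_dominant(
    genotypes: Mapping[str, Genotype],
    pedigree: Pedigree,
    config: Optional[SegregationConfig] = None,
) -> bool:
    """Full-penetrance dominant co-segregation within one pedigree.

    True iff at least one informative (sequenced, genotyped) affected
    member exists, every such affected carries >= 1 alternate allele, and
    at most ``max_unaffected_carriers`` informative unaffected members
    carry it.
    """
    cfg = config or SegregationConfig()
    _validate_members(genotypes, pedigree)

    informative_affected = 0
    for m in pedigree.sequenced_members:
        g = genotypes.get(m.individual_id, Genotype.MISSING)
        carrier = _carries(g)
        if carrier is None or m.affection is Affection.UNKNOWN:
            continue
        if m.affection is Affection.AFFECTED:
            if not carrier:
                return False
            if g is Genotype.HOM_ALT and not cfg.allow_hom_alt_affected:
                return False
            informative_affected += 1
    if informative_affected == 0:
        return False

    unaffected_carriers = sum(
        1
        for m in pedigree.sequenced_members
        if m.affection is Affection.UNAFFECTED
        and _carries(genotypes.get(m.individual_id, Genotype.MISSING)) is True
    )
    return unaffected_carriers <= cfg.max_unaffected_carriers


def _trans_resolvable_and_cis(
    v1: Mapping[str, Genotype],
    v2: Mapping[str, Genotype],
    affected_id: str,
    pedigree: Pedigree,
) -> bool:
    """True when parental genotypes resolve the pair's phase as cis.

    Phase is resolvable only when both parents are sequenced with calls at
    both sites.  The pair is trans-compatible when one parent can have
    transmitted the first variant and the *other* parent the second.
    """
    member = pedigree[affected_id]
    if member.father_id is None or member.mother_id is None:
        return False
    parents = [pedigree[member.father_id], pedigree[member.mother_id]]
    if not all(p.sequenced for p in parents):
        return False
    calls = [
        (_carries(v1.get(p.individual_id, Genotype.MISSING)),
         _carries(v2.get(p.individual_id, Genotype.MISSING)))
        for p in parents
    ]
    if any(c1 is None or c2 is None for c1, c2 in calls):
        return False
    for i, j in ((0, 1), (1, 0)):
        donor1_ok = calls[i][0]  # parent i carries v1
        donor2_ok = calls[j][1]  # parent j carries v2
        if donor1_ok and donor2_ok:
            return False  # a trans configuration exists
    # phase resolved, no trans assignment possible -> cis (or de novo on one side)
    de_novo = not any(c1 for c1, _ in calls) or not any(c2 for _, c2 in calls)
    if de_novo:
        return False  # unphaseable de novo allele: give the benefit of the doubt
    return True


def segregates_recessive(
    gene_variants: Sequence[tuple[VariantKey, Mapping[str, Genotype]]],
    pedigree: Pedigree,
    gene_symbols: Optional[Sequence[Optional[str]]] = None,
) -> bool:
    """Recessive co-segregation for the variants of one gene in one pedigree.

    Passes when a single variant is homozygous-alternate in all informative
    affecteds and not homozygous in any informative unaffected, or when a
    trans-compatible compound-heterozygous pair exists.
    """
    if gene_symbols is not None:
        symbols = {s for s in gene_symbols if s is not None}
        if len(symbols) > 1:
            raise UsageError(f"variants from multiple genes: {sorted(symbols)}")
    for _, genos in gene_variants:
        _validate_members(genos, pedigree)

    def informative(m, genos) -> bool:
        return (
            m.sequenced
            and m.affection is not Affection.UNKNOWN
            and genos.get(m.individual_id, Genotype.MISSING) is not Genotype.MISSING
        )

    affecteds = [m for m in pedigree.affected if m.sequenced]
    unaffecteds = [m for m in pedigree.unaffected if m.sequenced]

    # single homozygous variant
    for _, genos in gene_variants:
        inf_aff = [m for m in affecteds if informative(m, genos)]
        if not inf_aff:
            continue
        if all(
            genos[m.individual_id] is Genotype.HOM_ALT for m in inf_aff
        ) and not any(
            genos.get(m.individual_id, Genotype.MISSING) is Genotype.HOM_ALT
            for m in unaffecteds
        ):
            return True

    # compound heterozygote
    for (k1, g1), (k2, g2) in itertools.combinations(gene_variants, 2):
        inf_aff = [m for m in affecteds if informative(m, g1) and informative(m, g2)]
        if not inf_aff:
            continue
        if not all(
            g1[m.individual_id] is Genotype.HET and g2[m.individual_id] is Genotype.HET
            for m in inf_aff
        ):
            continue
        if any(
            _carries(g1.get(m.individual_id, Genotype.MISSING)) is True
            and _carries(g2.get(m.individual_id, Genotype.MISSING)) is True
            for m in unaffecteds
        ):
            continue
        if any(
            _trans_resolvable_and_cis(g1, g2, m.individual_id, pedigree)
            for m in inf_aff
        ):
            continue
        return True
    return False


@dataclass(frozen=True)
class RecessiveCandidate:
    """A gene-level recessive candidate: one homozygous variant or a het pair."""

    gene_symbol: Optional[str]
    variants: tuple[VariantKey, ...]


def _family_genotypes(
    record: VariantRecord, pedigree: Pedigree
) -> dict[str, Genotype]:
    return {
        m.individual_id: record.genotype(m.individual_id)
        for m in pedigree.sequenced_members
    }


def apply_segregation(
    table: VariantTable,
    pedigrees: PedigreeSet,
    model: InheritanceModel = DOMINANT,
    config: Optional[SegregationConfig] = None,
):
    """Run the per-family segregation test over a whole variant table.

    Dominant: returns ``{family_id: [VariantKey, ...]}``.
    Recessive: returns ``{family_id: [RecessiveCandidate, ...]}`` where each
    candidate is a homozygous single variant or a compound-het pair within
    one gene.
    """
    if len(pedigrees) == 0:
        raise UsageError("empty pedigree set")

    if model.mode == "dominant":
        out: dict[str, list[VariantKey]] = {ped.family_id: [] for ped in pedigrees}
        for rec in table:
            for ped in pedigrees:
                genos = _family_genotypes(rec, ped)
                if segregates_dominant(genos, ped, config):
                    out[ped.family_id].append(rec.key)
        return out

    by_gene: dict[Optional[str], list[VariantRecord]] = {}
    for rec in table:
        by_gene.setdefault(rec.gene_symbol, []).append(rec)
    out_r: dict[str, list[RecessiveCandidate]] = {
        ped.family_id: [] for ped in pedigrees
    }
    for gene, recs in by_gene.items():
        for ped in pedigrees:
            gvs = [(r.key, _family_genotypes(r, ped)) for r in recs]
            # report minimal passing units: singles first, then pairs
            for key, genos in gvs:
                if segregates_recessive([(key, genos)], ped):
                    out_r[ped.family_id].append(RecessiveCandidate(gene, (key,)))
            for pair in itertools.combinations(gvs, 2):
                keys = tuple(sorted(k for k, _ in pair))
                if any(
                    segregates_recessive([(k, g)], ped) for k, g in pair
                ):
                    continue  # already reported as a single
                if segregates_recessive(list(pair), ped):
                    out_r[ped.family_id].append(RecessiveCandidate(gene, keys))
    return out_r
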