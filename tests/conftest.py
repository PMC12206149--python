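import numpy as np
import pytest

from retprio.model import (
    Affection,
    Genotype,
    Individual,
    Pedigree,
    PedigreeSet,
    Sex,
    VariantKey,
)


def make_individual(
    iid,
    fam="FAM1",
    father=None,
    mother=None,
    sex=Sex.UNKNOWN,
    affection=Affection.UNKNOWN,
    sequenced=True,
):
    return Individual(
        individual_id=iid,
        family_id=fam,
        father_id=father,
        mother_id=mother,
        sex=sex,
        affection=affection,
        sequenced=sequenced,
    )


@pytest.fixture
def trio():
    """Father + mother (unaffected) and an affected child."""
    return Pedigree(
        family_id="FAM1",
        members=[
            make_individual("dad", sex=Sex.MALE, affection=Affection.UNAFFECTED),
            make_individual("mom", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
            make_individual(
                "kid", father="dad", mother="mom", affection=Affection.AFFECTED
            ),
        ],
    )


@pytest.fixture
def quartet():
    """Trio plus an unaffected sibling."""
    return Pedigree(
        family_id="FAM1",
        members=[
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


def random_pedigree(fam_id, rng):
    """Nuclear family with 2-4 children, random affection everywhere."""
    affs = [Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN]

    def aff():
        return affs[rng.integers(0, 3)]

    members = [
        make_individual(f"{fam_id}_d", fam=fam_id, sex=Sex.MALE, affection=aff()),
        make_individual(f"{fam_id}_m", fam=fam_id, sex=Sex.FEMALE, affection=aff()),
    ]
    for c in range(int(rng.integers(2, 5))):
        members.append(
            make_individual(
                f"{fam_id}_c{c}",
                fam=fam_id,
                father=f"{fam_id}_d",
                mother=f"{fam_id}_m",
                affection=aff(),
            )
        )
    return Pedigree(family_id=fam_id, members=members)


def random_genotypes(pedigree, rng, p_missing=0.1):
    gts = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT]
    out = {}
    for m in pedigree.members:
        if rng.random() < p_missing:
            out[m.individual_id] = Genotype.MISSING
        else:
            out[m.individual_id] = gts[rng.integers(0, 3)]
    return out


def vkey(i):
    return VariantKey("1", 1000 + i, "A", "T")
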