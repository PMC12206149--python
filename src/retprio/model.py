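"""Core data model for pedigree-based variant prioritization.

The cohort is represented as three loosely coupled pieces: the pedigree
structure (who is related to whom, and who is affected), the genotype
matrix (variant x individual calls), and per-variant/per-gene annotation
tables.  Segregation analysis only ever sees the first two; the frequency,
prediction and expression filters only see annotations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Genotype(enum.Enum):
    """Diploid genotype call relative to a single alternate allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def alt_count(self) -> Optional[int]:
        """Number of alternate alleles carried; None when the call is missing."""
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": None}[self.value]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (dangling parents, duplicates, cycles)."""


class DataError(ValueError):
    """Inconsistency between data tables (e.g. genotype for an unknown individual)."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Sex
    affection: Affection
    sequenced: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: members with parent links and affection status.

    The pedigree is the unit of segregation testing: a candidate variant is
    compared between affected members and unaffected in-family controls.
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.individual_id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            raise PedigreeError(
                f"duplicate individual id in family {self.family_id!r}"
            )
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"family {self.family_id!r}: individual {m.individual_id!r} "
                        f"references parent {pid!r} absent from the family"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS over parent links; an individual reachable from itself is a cycle.
        state: dict[str, int] = {}  # 0 = in progress, 1 = done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(
                    f"family {self.family_id!r}: individual {iid!r} is its own ancestor"
                )
            state[iid] = 0
            m = self._by_id[iid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 1

        for iid in self._by_id:
            visit(iid)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members)

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.affection is Affection.AFFECTED]

    @property
    def unaffected(self) -> list[Individual]:
        return [m for m in self.members if m.affection is Affection.UNAFFECTED]

    @property
    def sequenced_members(self) -> list[Individual]:
        return [m for m in self.members if m.sequenced]


@dataclass
class PedigreeSet:
    families: dict[str, Pedigree]

    @classmethod
    def from_pedigrees(cls, pedigrees: list[Pedigree]) -> "PedigreeSet":
        fams: dict[str, Pedigree] = {}
        for ped in pedigrees:
            if ped.family_id in fams:
                raise PedigreeError(f"duplicate family id {ped.family_id!r}")
            fams[ped.family_id] = ped
        return cls(families=fams)

    def __iter__(self) -> Iterator[Pedigree]:
        return iter(self.families.values())

    def __len__(self) -> int:
        return len(self.families)

    def __getitem__(self, family_id: str) -> Pedigree:
        return self.families[family_id]

    def family_of(self, individual_id: str) -> Optional[Pedigree]:
        for ped in self.families.values():
            if individual_id in ped:
                return ped
        return None

    @property
    def individuals(self) -> list[Individual]:
        return [m for ped in self for m in ped.members]


@dataclass(frozen=True, order=True)
class VariantKey:
    """Biallelic variant coordinate (1-based, VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @classmethod
    def parse(cls, s: str) -> "VariantKey":
        chrom, pos, ref, alt = s.rsplit("-", 3)
        return cls(chrom, int(pos), ref, alt)


@dataclass
class VariantRecord:
    """One biallelic variant with per-individual genotype calls.

    Multiallelic sites are decomposed before entry: each alternate allele
    becomes its own record, and genotypes referring to another alternate
    collapse to HOM_REF for this record.
    """

    key: VariantKey
    genotypes: dict[str, Genotype]
    gene_symbol: Optional[str] = None

    def genotype(self, individual_id: str) -> Genotype:
        return self.genotypes.get(individual_id, Genotype.MISSING)

    def carriers(self) -> set[str]:
        return {
            iid
            for iid, g in self.genotypes.items()
            if g in (Genotype.HET, Genotype.HOM_ALT)
        }


@dataclass
class VariantTable:
    records: list[VariantRecord]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise DataError("duplicate variant keys in table")

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_key(self) -> dict[VariantKey, VariantRecord]:
        return {r.key: r for r in self.records}


class StageCode(enum.Enum):
    """SD-OCT disease stage for occult macular dystrophy.

    Six ordered grades track the deterioration of the outer-retinal OCT
    bands (interdigitation and ellipsoid zones), from minimal foveal change
    (Ia) to a disrupted ellipsoid zone at the fovea (IIIb).  The fixed
    ordinal encoding 1..6 is what the correlation battery consumes.
    """

    Ia = 1
    Ib = 2
    IIa = 3
    IIb = 4
    IIIa = 5
    IIIb = 6

    @property
    def ordinal(self) -> int:
        return self.value

    @classmethod
    def parse(cls, s: str) -> "StageCode":
        try:
            return cls[s.strip()]
        except KeyError:
            raise ValueError(f"unknown stage code {s!r}") from None


@dataclass
class ClinicalRecord:
    patient_id: str
    family_id: str
    onset_age: float
    exam_age: Optional[float] = None
    stage: Optional[StageCode] = None

    def __post_init__(self) -> None:
        if self.onset_age < 0:
            raise ValueError(f"onset_age < 0 for patient {self.patient_id!r}")
        if self.duration is not None and self.duration < 0:
            raise ValueError(f"negative disease duration for {self.patient_id!r}")

    @property
    def duration(self) -> Optional[float]:
        """Disease duration in years (exam age minus onset age)."""
        if self.exam_age is None:
            return None
        return self.exam_age - self.onset_age


@dataclass
class ClinicalTable:
    records: list[ClinicalRecord]

    def __iter__(self) -> Iterator[ClinicalRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


ExpressionMap = Mapping[str, float]
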