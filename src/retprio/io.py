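"""Readers/writers for the formats the prioritization cascade touches.

PED (6-column), multi-sample VCF v4.2 (via cyvcf2), and tab-separated
annotation / expression / clinical tables (via pandas).  All readers accept
gzip-compressed input transparently.  I/O preserves missingness: an absent
panel allele count is recorded as absent, not zero — its interpretation is
the frequency filter's business.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, TextIO, Union

import pandas as pd
from cyvcf2 import VCF

from .model import (
    Affection,
    ClinicalRecord,
    ClinicalTable,
    DataError,
    Genotype,
    Individual,
    Pedigree,
    PedigreeError,
    PedigreeSet,
    Sex,
    StageCode,
    VariantKey,
    VariantRecord,
    VariantTable,
)
from .prediction import PredictionSet

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


class SchemaError(ValueError):
    """A mandatory column is missing from a tabular input."""


def _open_text(path: PathLike) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# PED

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFFECTION_CODES = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}


def read_ped(path: PathLike) -> PedigreeSet:
    """Read a 6-column whitespace-delimited PED file into a PedigreeSet.

    Affection codes: 1 -> unaffected, 2 -> affected, 0/-9 -> unknown.
    Parent id "0" -> none (founder).  Columns beyond the sixth are ignored.
    """
    rows: list[tuple[str, str, Optional[str], Optional[str], Sex, Affection]] = []
    seen: set[tuple[str, str]] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            fam, iid, fid, mid, sex, aff = fields[:6]
            if (fam, iid) in seen:
                raise PedigreeError(
                    f"{path}:{lineno}: duplicate individual {iid!r} in family {fam!r}"
                )
            seen.add((fam, iid))
            rows.append(
                (
                    fam,
                    iid,
                    None if fid == "0" else fid,
                    None if mid == "0" else mid,
                    _SEX_CODES.get(sex, Sex.UNKNOWN),
                    _AFFECTION_CODES.get(aff, Affection.UNKNOWN),
                )
            )
    by_family: dict[str, list[Individual]] = {}
    for fam, iid, fid, mid, sex, aff in rows:
        by_family.setdefault(fam, []).append(
            Individual(
                individual_id=iid,
                family_id=fam,
                father_id=fid,
                mother_id=mid,
                sex=sex,
                affection=aff,
            )
        )
    return PedigreeSet.from_pedigrees(
        [Pedigree(family_id=fam, members=members) for fam, members in by_family.items()]
    )


def write_ped(pedigrees: PedigreeSet, path: PathLike) -> None:
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_out = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}
    with open(path, "wt") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            m.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_out[m.sex],
                            aff_out[m.affection],
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# VCF

_PLOIDY_CALLS = {
    (0, 0): Genotype.HOM_REF,
}


def read_vcf(path: PathLike, pedigrees: PedigreeSet) -> VariantTable:
    """Read a multi-sample VCF into a VariantTable.

    Multiallelic records are decomposed into one biallelic record per
    alternate allele; genotype alleles referring to a different alternate
    count as reference for the current record.  Phase separators are
    ignored.  Samples present in the VCF but absent from the pedigree set
    are skipped with a warning; pedigree members absent from the VCF are
    marked ``sequenced=False`` in the returned PedigreeSet (updated in
    place).
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)

    known: set[str] = {m.individual_id for ped in pedigrees for m in ped.members}
    keep_idx: list[int] = []
    for i, s in enumerate(samples):
        if s in known:
            keep_idx.append(i)
        else:
            log.warning("VCF sample %r not in pedigree set; ignored", s)
    vcf_ids = {samples[i] for i in keep_idx}

    # flag unsequenced members in place
    for ped in pedigrees:
        new_members = []
        for m in ped.members:
            seq = m.individual_id in vcf_ids
            if m.sequenced != seq:
                m = Individual(
                    m.individual_id, m.family_id, m.father_id, m.mother_id,
                    m.sex, m.affection, sequenced=seq,
                )
            new_members.append(m)
        ped.members = new_members
        ped._by_id = {m.individual_id: m for m in new_members}

    records: list[VariantRecord] = []
    for v in vcf:
        alts = v.ALT
        gts = v.genotypes  # [[a1, a2, phased], ...]
        for ai, alt in enumerate(alts, start=1):
            if alt in (".", "*", None):
                continue
            genos: dict[str, Genotype] = {}
            for i in keep_idx:
                g = gts[i]
                alleles = [a for a in g[:-1]]
                if any(a is None or a < 0 for a in alleles):
                    call = Genotype.MISSING
                else:
                    n_alt = sum(1 for a in alleles if a == ai)
                    if len(alts) > 1 and any(a not in (0, ai) for a in alleles):
                        log.debug(
                            "sample %s at %s:%d carries another alternate; "
                            "counted as reference for allele %s",
                            samples[i], v.CHROM, v.POS, alt,
                        )
                    call = (
                        Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT
                    )[min(n_alt, 2)]
                genos[samples[i]] = call
            records.append(
                VariantRecord(
                    key=VariantKey(str(v.CHROM), int(v.POS), str(v.REF), str(alt)),
                    genotypes=genos,
                )
            )
    return VariantTable(records=records)


# ---------------------------------------------------------------------------
# Annotation / expression / clinical tables

VARIANT_KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]
ANNOTATION_FIXED_COLUMNS = VARIANT_KEY_COLUMNS + [
    "gene",
    "provean_score",
    "sift_score",
    "polyphen2_score_or_label",
    "mutationtaster_label",
]


@dataclass
class VariantAnnotation:
    gene_symbol: str
    allele_counts: dict[str, Optional[int]] = field(default_factory=dict)
    predictions: PredictionSet = field(default_factory=PredictionSet)


@dataclass
class AnnotationBundle:
    """Per-variant annotations: gene symbol, panel allele counts, tool calls."""

    variants: dict[VariantKey, VariantAnnotation]

    def __getitem__(self, key: VariantKey) -> VariantAnnotation:
        return self.variants[key]

    def get(self, key: VariantKey) -> Optional[VariantAnnotation]:
        return self.variants.get(key)

    def __len__(self) -> int:
        return len(self.variants)


def read_annotations(path: PathLike) -> AnnotationBundle:
    """Read the per-variant annotation TSV.

    Required columns: chrom, pos, ref, alt, gene, provean_score, sift_score,
    polyphen2_score_or_label, mutationtaster_label.  Every column named
    ``ac_<panel>`` is read as that panel's allele count; an empty cell means
    the variant was not observed in the panel and is stored as absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    ac_cols = [c for c in df.columns if c.startswith("ac_")]

    variants: dict[VariantKey, VariantAnnotation] = {}
    for idx, row in df.iterrows():
        try:
            key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        except ValueError as e:
            raise ParseError(f"{path}: row {idx + 2}: {e}") from e
        acs: dict[str, Optional[int]] = {}
        for c in ac_cols:
            raw = row[c].strip()
            if raw in ("", ".", "NA"):
                acs[c[3:]] = None
            else:
                try:
                    acs[c[3:]] = int(raw)
                except ValueError:
                    raise ParseError(
                        f"{path}: row {idx + 2}: non-integer allele count {raw!r} in {c}"
                    ) from None
        preds = PredictionSet(
            provean=row["provean_score"].strip() or None,
            sift=row["sift_score"].strip() or None,
            polyphen2=row["polyphen2_score_or_label"].strip() or None,
            mutationtaster=row["mutationtaster_label"].strip() or None,
        )
        variants[key] = VariantAnnotation(
            gene_symbol=row["gene"].strip(), allele_counts=acs, predictions=preds
        )
    return AnnotationBundle(variants=variants)


def read_expression(path: PathLike) -> dict[str, float]:
    """Read a two-column ``gene<TAB>ntpm`` expression table."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    for col in ("gene", "ntpm"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    out: dict[str, float] = {}
    for idx, row in df.iterrows():
        try:
            ntpm = float(row["ntpm"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: row {idx + 2}: non-numeric nTPM {row['ntpm']!r}"
            ) from None
        if ntpm < 0:
            raise ParseError(f"{path}: row {idx + 2}: negative nTPM {ntpm}")
        out[str(row["gene"]).strip()] = ntpm
    return out


CLINICAL_COLUMNS = ["patient_id", "family_id", "onset_age", "exam_age", "stage"]


def read_clinical(path: PathLike) -> ClinicalTable:
    """Read the per-patient clinical TSV (onset age, exam age, stage code)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    records: list[ClinicalRecord] = []
    for idx, row in df.iterrows():
        try:
            onset = float(row["onset_age"])
            exam = float(row["exam_age"]) if row["exam_age"].strip() else None
            stage = StageCode.parse(row["stage"]) if row["stage"].strip() else None
            records.append(
                ClinicalRecord(
                    patient_id=row["patient_id"].strip(),
                    family_id=row["family_id"].strip(),
                    onset_age=onset,
                    exam_age=exam,
                    stage=stage,
                )
            )
        except ValueError as e:
            raise ParseError(f"{path}: row {idx + 2}: {e}") from e
    return ClinicalTable(records=records)


def check_genotypes_known(table: VariantTable, pedigrees: PedigreeSet) -> None:
    """Raise DataError if any genotype references an unknown individual."""
    known = {m.individual_id for ped in pedigrees for m in ped.members}
    for rec in table:
        unknown = set(rec.genotypes) - known
        if unknown:
            raise DataError(
                f"genotypes at {rec.key} reference unknown individual(s) {sorted(unknown)}"
            )
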