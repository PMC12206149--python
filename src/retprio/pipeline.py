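"""End-to-end prioritization cascade with per-family provenance.

Order of application follows the discovery workflow: panel allele
frequency -> within-family segregation -> deleteriousness consensus ->
retinal expression, then cross-family recurrence tallying.  Each filter is
a pure per-(variant, family) predicate, so the surviving candidate set is
the same under any filter order; the order only determines which filter a
removed variant's exclusion is attributed to (first cause).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from . import io as cohort_io
from .expression import DEFAULT_MIN_NTPM, retina_expressed
from .frequency import DEFAULT_MAF_CUTOFF, FrequencyPanel, passes_frequency_counts
from .model import Genotype, Pedigree, PedigreeSet, VariantKey, VariantTable
from .prediction import PredictionSet, PredictionThresholds, damaging_consensus
from .recurrence import (
    RecurrenceRow,
    VariantRecurrenceRow,
    families_without_candidates,
    tally_genes,
    tally_variants,
)
from .segregation import (
    InheritanceModel,
    RecessiveCandidate,
    SegregationConfig,
    apply_segregation,
    segregates_dominant,
)

log = logging.getLogger(__name__)

FILTER_ORDER = ("frequency", "segregation", "consensus", "expression")


class PipelineConfigError(ValueError):
    pass


class PanelConfig(BaseModel):
    name: str
    n_individuals: int
    maf_cutoff: float = DEFAULT_MAF_CUTOFF


class ThresholdConfig(BaseModel):
    provean_max: float = -2.5
    sift_max: float = 0.05
    polyphen2_min: float = 0.446
    min_damaging: int = 3
    strict: bool = False


class PipelineConfig(BaseModel):
    """Everything one cascade run needs; round-trips through YAML/JSON."""

    ped: str
    vcf: str
    annotations: str
    expression: str
    clinical: Optional[str] = None
    panels: list[PanelConfig] = Field(
        default_factory=lambda: [
            PanelConfig(name="exac", n_individuals=60707),
            PanelConfig(name="gnomad", n_individuals=141456),
            PanelConfig(name="hgvd", n_individuals=1208),
            PanelConfig(name="tommo54k", n_individuals=54000),
            PanelConfig(name="inhouse", n_individuals=2076),
        ]
    )
    prediction_thresholds: ThresholdConfig = ThresholdConfig()
    expression_min_ntpm: float = DEFAULT_MIN_NTPM
    keep_unannotated_genes: bool = False
    model: str = "dominant"
    max_unaffected_carriers: int = 0
    output_dir: Optional[str] = None

    def frequency_panels(self) -> list[FrequencyPanel]:
        return [
            FrequencyPanel(p.name, p.n_individuals, p.maf_cutoff) for p in self.panels
        ]

    def check_paths(self) -> None:
        for label in ("ped", "vcf", "annotations", "expression", "clinical"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                raise PipelineConfigError(f"{label} input not found: {value}")


@dataclass
class FamilyResult:
    family_id: str
    funnel: dict[str, int]
    candidates: list[tuple[VariantKey, Optional[str]]]
    exclusions: dict[VariantKey, str]  # first-cause filter name
    single_informative_affected: bool = False


@dataclass
class CandidateReport:
    model: str
    total_families: int
    families: dict[str, FamilyResult]
    gene_table: list[RecurrenceRow]
    variant_table: list[VariantRecurrenceRow]
    n_families_without_candidates: int
    families_without_candidates: list[str]
    union_gene_count: int

    def to_json(self) -> dict:
        return {
            "model": self.model,
            "total_families": self.total_families,
            "union_gene_count": self.union_gene_count,
            "families_without_candidates": self.families_without_candidates,
            "families": {
                fam: {
                    "funnel": fr.funnel,
                    "candidates": [
                        {"variant": str(k), "gene": g} for k, g in fr.candidates
                    ],
                    "exclusions": {str(k): v for k, v in fr.exclusions.items()},
                    "single_informative_affected": fr.single_informative_affected,
                }
                for fam, fr in self.families.items()
            },
            "gene_recurrence": [
                {
                    "gene": r.gene_symbol,
                    "n_pedigrees": r.n_pedigrees,
                    "pct": r.pct,
                    "variants": {str(k): c for k, c in r.variants.items()},
                }
                for r in self.gene_table
            ],
            "variant_recurrence": [
                {
                    "variant": str(r.variant),
                    "gene": r.gene_symbol,
                    "n_pedigrees": r.n_pedigrees,
                    "pct": r.pct,
                }
                for r in self.variant_table
            ],
        }

    def write(self, outdir: Path | str) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        p = outdir / "funnel.tsv"
        lines = ["family\t" + "\t".join(("input",) + FILTER_ORDER)]
        for fam, fr in sorted(self.families.items()):
            lines.append(
                fam + "\t" + "\t".join(
                    str(fr.funnel[s]) for s in ("input",) + FILTER_ORDER
                )
            )
        p.write_text("\n".join(lines) + "\n")
        paths["funnel.tsv"] = p

        p = outdir / "gene_recurrence.tsv"
        lines = ["gene\tn_pedigrees\tpct"]
        lines += [
            f"{r.gene_symbol}\t{r.n_pedigrees}\t{r.pct:.2f}" for r in self.gene_table
        ]
        p.write_text("\n".join(lines) + "\n")
        paths["gene_recurrence.tsv"] = p

        p = outdir / "variant_recurrence.tsv"
        lines = ["variant\tgene\tn_pedigrees\tpct"]
        lines += [
            f"{r.variant}\t{r.gene_symbol or ''}\t{r.n_pedigrees}\t{r.pct:.2f}"
            for r in self.variant_table
        ]
        p.write_text("\n".join(lines) + "\n")
        paths["variant_recurrence.tsv"] = p

        p = outdir / "report.json"
        p.write_text(json.dumps(self.to_json(), indent=1, sort_keys=True))
        paths["report.json"] = p
        return paths


def _family_variants(table: VariantTable, pedigree: Pedigree):
    """Variants carried by at least one sequenced member of the family."""
    seq = [m.individual_id for m in pedigree.sequenced_members]
    for rec in table:
        for iid in seq:
            if rec.genotype(iid) in (Genotype.HET, Genotype.HOM_ALT):
                yield rec
                break


def run_cascade(
    table: VariantTable,
    pedigrees: PedigreeSet,
    annotations: cohort_io.AnnotationBundle,
    expression: dict[str, float],
    panels: Sequence[FrequencyPanel],
    thresholds: Optional[PredictionThresholds] = None,
    min_damaging: int = 3,
    strict_consensus: bool = False,
    expression_min_ntpm: float = DEFAULT_MIN_NTPM,
    keep_unannotated_genes: bool = False,
    seg_config: Optional[SegregationConfig] = None,
    model: InheritanceModel = InheritanceModel("dominant"),
    filter_order: Sequence[str] = FILTER_ORDER,
) -> CandidateReport:
    """Apply the four-filter cascade and tally recurrence.

    ``filter_order`` changes only exclusion-reason attribution and the
    funnel shape; the surviving set is order-invariant because every filter
    is a pure predicate.
    """
    if sorted(filter_order) != sorted(FILTER_ORDER):
        raise PipelineConfigError(f"filter_order must permute {FILTER_ORDER}")
    if len(pedigrees) == 0:
        raise PipelineConfigError("empty cohort")
    cohort_io.check_genotypes_known(table, pedigrees)
    seg_config = seg_config or SegregationConfig()

    if model.mode == "recessive":
        return _run_recessive(
            table, pedigrees, annotations, expression, panels, thresholds,
            min_damaging, strict_consensus, expression_min_ntpm,
            keep_unannotated_genes, seg_config,
        )

    families: dict[str, FamilyResult] = {}
    for ped in pedigrees:
        fam_recs = list(_family_variants(table, ped))
        funnel = {"input": len(fam_recs)}
        exclusions: dict[VariantKey, str] = {}
        survivors = []
        current = fam_recs
        genes: dict[VariantKey, Optional[str]] = {}
        predicate_cache: dict[VariantKey, dict[str, bool]] = {}
        for rec in fam_recs:
            ann = annotations.get(rec.key)
            gene = ann.gene_symbol if ann else rec.gene_symbol
            genes[rec.key] = gene
            genos = {
                m.individual_id: rec.genotype(m.individual_id)
                for m in ped.sequenced_members
            }
            predicate_cache[rec.key] = {
                "frequency": passes_frequency_counts(
                    ann.allele_counts if ann else {}, panels, rec.key
                ),
                "segregation": segregates_dominant(genos, ped, seg_config),
                "consensus": (
                    damaging_consensus(
                        ann.predictions, thresholds, min_damaging, strict_consensus
                    )
                    if ann
                    else damaging_consensus(
                        PredictionSet(), thresholds, min_damaging, strict_consensus
                    )
                ),
                "expression": retina_expressed(
                    gene or "", expression, expression_min_ntpm,
                    keep_unannotated_genes,
                ),
            }
        for stage in filter_order:
            kept = []
            for rec in current:
                if predicate_cache[rec.key][stage]:
                    kept.append(rec)
                else:
                    exclusions[rec.key] = stage
            current = kept
            funnel[stage] = len(current)
        survivors = [(rec.key, genes[rec.key]) for rec in current]

        informative_affected = sum(
            1
            for m in ped.sequenced_members
            if m.affection.value == "affected"
        )
        families[ped.family_id] = FamilyResult(
            family_id=ped.family_id,
            funnel=funnel,
            candidates=survivors,
            exclusions=exclusions,
            single_informative_affected=(informative_affected == 1),
        )

    per_family = {fam: fr.candidates for fam, fr in families.items()}
    total = len(pedigrees)
    gene_table = tally_genes(per_family, total)
    variant_table = tally_variants(per_family, total)
    n_empty, empty_ids = families_without_candidates(per_family)
    union_genes = {g for fr in families.values() for _, g in fr.candidates}
    return CandidateReport(
        model=model.mode,
        total_families=total,
        families=families,
        gene_table=gene_table,
        variant_table=variant_table,
        n_families_without_candidates=n_empty,
        families_without_candidates=empty_ids,
        union_gene_count=len(union_genes),
    )


def _run_recessive(
    table, pedigrees, annotations, expression, panels, thresholds,
    min_damaging, strict_consensus, expression_min_ntpm,
    keep_unannotated_genes, seg_config,
) -> CandidateReport:
    # frequency first (per-variant), then gene-level segregation units,
    # then consensus on every unit member, then gene expression
    def ann_of(key):
        return annotations.get(key)

    freq_pass = [
        rec
        for rec in table
        if passes_frequency_counts(
            (ann_of(rec.key).allele_counts if ann_of(rec.key) else {}), panels, rec.key
        )
    ]
    for rec in freq_pass:
        ann = ann_of(rec.key)
        if ann and rec.gene_symbol is None:
            rec.gene_symbol = ann.gene_symbol
    sub = VariantTable(records=freq_pass)
    units = apply_segregation(sub, pedigrees, InheritanceModel("recessive"), seg_config)

    families: dict[str, FamilyResult] = {}
    for ped in pedigrees:
        fam_units: list[RecessiveCandidate] = units[ped.family_id]
        survivors: list[tuple[VariantKey, Optional[str]]] = []
        exclusions: dict[VariantKey, str] = {}
        kept_units = []
        for unit in fam_units:
            ok_cons = all(
                (ann_of(k) is not None)
                and damaging_consensus(
                    ann_of(k).predictions, thresholds, min_damaging, strict_consensus
                )
                for k in unit.variants
            )
            if not ok_cons:
                for k in unit.variants:
                    exclusions.setdefault(k, "consensus")
                continue
            if not retina_expressed(
                unit.gene_symbol or "", expression, expression_min_ntpm,
                keep_unannotated_genes,
            ):
                for k in unit.variants:
                    exclusions.setdefault(k, "expression")
                continue
            kept_units.append(unit)
        for unit in kept_units:
            for k in unit.variants:
                if (k, unit.gene_symbol) not in survivors:
                    survivors.append((k, unit.gene_symbol))
        families[ped.family_id] = FamilyResult(
            family_id=ped.family_id,
            funnel={
                "input": len(table),
                "frequency": len(sub),
                "segregation": len(fam_units),
                "consensus": len(kept_units),
                "expression": len(kept_units),
            },
            candidates=survivors,
            exclusions=exclusions,
        )
    per_family = {fam: fr.candidates for fam, fr in families.items()}
    total = len(pedigrees)
    n_empty, empty_ids = families_without_candidates(per_family)
    union_genes = {g for fr in families.values() for _, g in fr.candidates}
    return CandidateReport(
        model="recessive",
        total_families=total,
        families=families,
        gene_table=tally_genes(per_family, total),
        variant_table=tally_variants(per_family, total),
        n_families_without_candidates=n_empty,
        families_without_candidates=empty_ids,
        union_gene_count=len(union_genes),
    )


def run_pipeline(config: PipelineConfig) -> CandidateReport:
    """Load the configured inputs, run the cascade, optionally write reports."""
    config.check_paths()
    pedigrees = cohort_io.read_ped(config.ped)
    table = cohort_io.read_vcf(config.vcf, pedigrees)
    annotations = cohort_io.read_annotations(config.annotations)
    expression = cohort_io.read_expression(config.expression)
    th = PredictionThresholds(
        provean_max=config.prediction_thresholds.provean_max,
        sift_max=config.prediction_thresholds.sift_max,
        polyphen2_min=config.prediction_thresholds.polyphen2_min,
    )
    report = run_cascade(
        table,
        pedigrees,
        annotations,
        expression,
        panels=config.frequency_panels(),
        thresholds=th,
        min_damaging=config.prediction_thresholds.min_damaging,
        strict_consensus=config.prediction_thresholds.strict,
        expression_min_ntpm=config.expression_min_ntpm,
        keep_unannotated_genes=config.keep_unannotated_genes,
        seg_config=SegregationConfig(
            max_unaffected_carriers=config.max_unaffected_carriers
        ),
        model=InheritanceModel(config.model),
    )
    for fam, fr in report.families.items():
        log.info(
            "family %s: funnel %s", fam,
            " -> ".join(str(fr.funnel[s]) for s in ("input",) + FILTER_ORDER),
        )
    if config.output_dir:
        report.write(config.output_dir)
    return report
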