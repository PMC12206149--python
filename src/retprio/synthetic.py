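"""Synthetic cohort generator with a ground-truth ledger.

The real study cohort (whole-exome genotypes for ~78 dominant macular
dystrophy pedigrees) is not publicly deposited, so every stage of the
cascade is exercised against simulated data with the same statistical
structure: multi-generation pedigrees with Mendelian transmission of a
dominant causal allele in a configurable subset of families, background
variants constructed to pass or fail each filter with configurable
probabilities, per-panel allele counts, four-tool prediction columns, a
retinal expression table and an ordinal-staged clinical table.

Every random draw is taken from one of a small number of named RNG streams
spawned from the master seed (pedigrees, genotypes/background annotation,
clinical), so adding an output table never perturbs the others, and the
same config + seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .frequency import FrequencyPanel, default_panels
from .model import (
    Affection,
    ClinicalRecord,
    ClinicalTable,
    Genotype,
    Individual,
    Pedigree,
    PedigreeSet,
    Sex,
    StageCode,
    VariantKey,
)

FILTER_STAGES = ("frequency", "segregation", "consensus", "expression")


class ConfigError(ValueError):
    pass


class CausalSpec(BaseModel):
    """The injected dominant causal variant and where it lives."""

    gene_symbol: str = "RP1L1"
    chrom: str = "8"
    pos: int = 10467694
    ref: str = "C"
    alt: str = "T"
    n_causal_families: int = 13
    penetrance: float = Field(default=1.0, ge=0.0, le=1.0)

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


class PassProbabilities(BaseModel):
    """Per-filter probability that a background variant is built to pass."""

    frequency: float = Field(default=0.1, ge=0.0, le=1.0)
    segregation: float = Field(default=0.2, ge=0.0, le=1.0)
    consensus: float = Field(default=0.4, ge=0.0, le=1.0)
    expression: float = Field(default=0.7, ge=0.0, le=1.0)


class SimulationConfig(BaseModel):
    n_families: int = Field(default=78, ge=1)
    family_size_range: tuple[int, int] = (4, 7)
    causal: CausalSpec = CausalSpec()
    n_background_variants: int = Field(default=1000, ge=0)
    background_pass: PassProbabilities = PassProbabilities()
    maf_cutoff: float = 0.00025
    stage_onset_rho: float = -0.447
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        lo, hi = self.family_size_range
        if lo < 3 or hi < lo:
            raise ConfigError(
                f"family_size_range must satisfy 3 <= lo <= hi, got {(lo, hi)}"
            )
        if self.causal.n_causal_families > self.n_families:
            raise ConfigError(
                f"n_causal_families={self.causal.n_causal_families} exceeds "
                f"n_families={self.n_families}"
            )
        if not -1.0 <= self.stage_onset_rho <= 1.0:
            raise ConfigError("stage_onset_rho must be in [-1, 1]")
        return self

    def panels(self) -> list[FrequencyPanel]:
        return default_panels(self.maf_cutoff)


@dataclass
class BackgroundTruth:
    variant: VariantKey
    gene_symbol: str
    host_family: str
    built_to_pass: dict[str, bool]  # per filter stage


@dataclass
class TruthSet:
    causal_variant: VariantKey
    causal_gene: str
    causal_families: list[str]
    background: list[BackgroundTruth]
    genotypes: dict[str, dict[str, str]]  # variant str -> {sample: call != hom_ref}

    def to_json(self) -> dict:
        return {
            "causal_variant": str(self.causal_variant),
            "causal_gene": self.causal_gene,
            "causal_families": self.causal_families,
            "background": [
                {
                    "variant": str(b.variant),
                    "gene": b.gene_symbol,
                    "host_family": b.host_family,
                    "built_to_pass": b.built_to_pass,
                }
                for b in self.background
            ],
            "non_ref_genotypes": self.genotypes,
        }


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    pedigrees: PedigreeSet
    truth: TruthSet
    clinical: ClinicalTable
    ped_text: str
    vcf_text: str
    annotations_text: str
    expression_text: str
    clinical_text: str

    def write(self, outdir: Path | str) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in [
            ("cohort.ped", self.ped_text),
            ("cohort.vcf", self.vcf_text),
            ("annotations.tsv", self.annotations_text),
            ("expression.tsv", self.expression_text),
            ("clinical.tsv", self.clinical_text),
        ]:
            p = outdir / name
            p.write_text(text)
            paths[name] = p
        tp = outdir / "truth.json"
        tp.write_text(json.dumps(self.truth.to_json(), indent=1, sort_keys=True))
        paths["truth.json"] = tp
        manifest = {
            "files": sorted(paths),
            "seed": self.config.seed,
            "n_families": self.config.n_families,
            "n_background_variants": self.config.n_background_variants,
        }
        mp = outdir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        paths["manifest.json"] = mp
        return paths


# ---------------------------------------------------------------------------
# pedigree construction

def _build_family(
    fam_id: str, total: int, causal: bool, penetrance: float, rng: np.random.Generator
) -> tuple[Pedigree, set[str]]:
    """Grow a 2-3 generation family; return (pedigree, carrier ids).

    A founder couple has children; when the requested size allows, the
    first child takes a founder spouse and has children of their own.  In a
    causal family one founder carries the dominant allele, which drops
    Mendelianly (p=1/2 per meiosis); carriers are affected with probability
    ``penetrance``.  Non-causal families get one phenocopy affected (their
    disease has some other, unmodelled cause), so every pedigree has at
    least one affected and — via the non-carrier founder — at least one
    unaffected member.
    """
    ids: list[str] = []
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    sexes: dict[str, Sex] = {}

    def add(iid: str, sex: Sex, father=None, mother=None) -> None:
        ids.append(iid)
        sexes[iid] = sex
        parents[iid] = (father, mother)

    father, mother = f"{fam_id}_1", f"{fam_id}_2"
    add(father, Sex.MALE)
    add(mother, Sex.FEMALE)
    remaining = total - 2
    if remaining > 4:
        n_children = int(rng.integers(2, 4))
    else:
        n_children = remaining
    leftover = remaining - n_children
    if leftover == 1:  # a lone in-law without descendants is pointless
        n_children += 1
        leftover = 0
    child_ids = []
    for c in range(n_children):
        iid = f"{fam_id}_{3 + c}"
        add(iid, Sex.MALE if rng.random() < 0.5 else Sex.FEMALE, father, mother)
        child_ids.append(iid)
    next_no = 3 + n_children
    spouse = None
    grandchildren: list[str] = []
    if leftover >= 2:
        spouse = f"{fam_id}_{next_no}"
        sp_sex = Sex.FEMALE if sexes[child_ids[0]] is Sex.MALE else Sex.MALE
        add(spouse, sp_sex)
        next_no += 1
        for g in range(leftover - 1):
            gid = f"{fam_id}_{next_no}"
            dad, mom = (
                (child_ids[0], spouse)
                if sexes[child_ids[0]] is Sex.MALE
                else (spouse, child_ids[0])
            )
            add(gid, Sex.MALE if rng.random() < 0.5 else Sex.FEMALE, dad, mom)
            grandchildren.append(gid)
            next_no += 1

    carriers: set[str] = set()
    if causal:
        founder_carrier = father if rng.random() < 0.5 else mother
        carriers.add(founder_carrier)
        for cid in child_ids:
            if rng.random() < 0.5:
                carriers.add(cid)
        if child_ids and child_ids[0] in carriers:
            for gid in grandchildren:
                if rng.random() < 0.5:
                    carriers.add(gid)

    affection: dict[str, Affection] = {}
    for iid in ids:
        if iid in carriers:
            affection[iid] = (
                Affection.AFFECTED
                if rng.random() < penetrance
                else Affection.UNAFFECTED
            )
        else:
            affection[iid] = Affection.UNAFFECTED
    if causal and not any(a is Affection.AFFECTED for a in affection.values()):
        affection[sorted(carriers)[0]] = Affection.AFFECTED
    if not causal:
        affection[ids[int(rng.integers(0, len(ids)))]] = Affection.AFFECTED

    members = [
        Individual(
            individual_id=iid,
            family_id=fam_id,
            father_id=parents[iid][0],
            mother_id=parents[iid][1],
            sex=sexes[iid],
            affection=affection[iid],
            sequenced=True,
        )
        for iid in ids
    ]
    return Pedigree(family_id=fam_id, members=members), carriers


# ---------------------------------------------------------------------------
# serialization helpers

_GT_STR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}

_BASES = np.array(list("ACGT"))


def _ped_text(pedigrees: PedigreeSet) -> str:
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_out = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2",
               Affection.UNKNOWN: "0"}
    lines = []
    for ped in pedigrees:
        for m in ped.members:
            lines.append(
                "\t".join(
                    [m.family_id, m.individual_id, m.father_id or "0",
                     m.mother_id or "0", sex_out[m.sex], aff_out[m.affection]]
                )
            )
    return "\n".join(lines) + "\n"


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (100, chrom)


def _vcf_text(
    samples: list[str], records: list[tuple[VariantKey, dict[str, Genotype]]]
) -> str:
    records = sorted(records, key=lambda r: (_chrom_sort_key(r[0].chrom), r[0].pos))
    chroms = []
    for key, _ in records:
        if key.chrom not in chroms:
            chroms.append(key.chrom)
    head = ["##fileformat=VCFv4.2"]
    head += [f"##contig=<ID={c}>" for c in sorted(chroms, key=_chrom_sort_key)]
    head.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    head.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    lines = head
    for key, genos in records:
        gts = "\t".join(_GT_STR[genos.get(s, Genotype.HOM_REF)] for s in samples)
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# clinical simulation

def simulate_clinical(
    n: int,
    stage_onset_rho_target: float,
    seed: int,
    stage_probs: Optional[dict[StageCode, float]] = None,
    patient_ids: Optional[list[tuple[str, str]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ClinicalTable, dict]:
    """Generate ordinal stages and onset ages with a target rank correlation.

    Stages and onsets are drawn through a Gaussian copula whose latent
    Pearson correlation ``2*sin(pi*rho_s/6)`` targets the requested
    Spearman coefficient; stages are then quantile-binned (equal bins by
    default), which attenuates the realized coefficient somewhat.  At
    target +-1 the copula is replaced by a comonotone construction where
    onset is a strictly monotone function of the stage ordinal, so the
    realized coefficient is exactly +-1 even with stage ties.
    """
    if n < 5:
        raise ConfigError(f"need n >= 5 clinical records, got {n}")
    if not -1.0 <= stage_onset_rho_target <= 1.0:
        raise ConfigError("stage_onset_rho_target must be in [-1, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    stages_all = list(StageCode)
    if stage_probs is None:
        probs = np.full(6, 1 / 6)
    else:
        probs = np.array([stage_probs.get(s, 0.0) for s in stages_all], dtype=float)
        probs = probs / probs.sum()

    if abs(stage_onset_rho_target) == 1.0:
        stage_idx = rng.choice(6, size=n, p=probs)
        sign = 1.0 if stage_onset_rho_target > 0 else -1.0
        # onset strictly monotone in the ordinal: tie structure matches exactly
        onset = 35.0 + sign * 8.0 * (stage_idx + 1 - 3.5)
    else:
        r_latent = 2.0 * np.sin(np.pi * stage_onset_rho_target / 6.0)
        cov = np.array([[1.0, r_latent], [r_latent, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        from scipy.stats import norm

        u_stage, u_onset = norm.cdf(z[:, 0]), norm.cdf(z[:, 1])
        edges = np.cumsum(probs)[:-1]
        stage_idx = np.searchsorted(edges, u_stage, side="right")
        onset = np.round(3.0 + 57.0 * u_onset, 1)  # years, onset range 3-60

    duration = np.round(rng.uniform(1.0, 30.0, size=n), 1)
    records = []
    for i in range(n):
        pid, fam = (
            patient_ids[i] if patient_ids is not None else (f"P{i + 1:03d}", f"F{i + 1:03d}")
        )
        records.append(
            ClinicalRecord(
                patient_id=pid,
                family_id=fam,
                onset_age=float(onset[i]),
                exam_age=float(onset[i] + duration[i]),
                stage=stages_all[int(stage_idx[i])],
            )
        )
    truth = {"rho_target": stage_onset_rho_target, "n": n}
    return ClinicalTable(records=records), truth


def clinical_text(table: ClinicalTable) -> str:
    lines = ["patient_id\tfamily_id\tonset_age\texam_age\tstage"]
    for r in table:
        lines.append(
            f"{r.patient_id}\t{r.family_id}\t{r.onset_age:g}\t"
            f"{'' if r.exam_age is None else f'{r.exam_age:g}'}\t"
            f"{'' if r.stage is None else r.stage.name}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# main generator

def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full cohort: PED, VCF, annotation/expression/clinical
    tables and the truth ledger, all as in-memory text plus typed objects."""
    ss = np.random.SeedSequence(config.seed)
    rng_ped, rng_bg, rng_clin = (np.random.default_rng(s) for s in ss.spawn(3))

    panels = config.panels()
    causal = config.causal
    lo, hi = config.family_size_range

    causal_fams = [f"F{i + 1:03d}" for i in range(causal.n_causal_families)]
    pedigrees: list[Pedigree] = []
    carriers_by_family: dict[str, set[str]] = {}
    for i in range(config.n_families):
        fam_id = f"F{i + 1:03d}"
        total = int(rng_ped.integers(lo, hi + 1))
        ped, carriers = _build_family(
            fam_id, total, fam_id in causal_fams, causal.penetrance, rng_ped
        )
        pedigrees.append(ped)
        carriers_by_family[fam_id] = carriers
    ped_set = PedigreeSet.from_pedigrees(pedigrees)
    samples = [m.individual_id for ped in ped_set for m in ped.members]

    # --- causal variant genotypes: het carriers, everyone else hom_ref
    records: list[tuple[VariantKey, dict[str, Genotype]]] = []
    causal_genos = {
        iid: Genotype.HET
        for fam, carr in carriers_by_family.items()
        for iid in carr
    }
    records.append((causal.key, causal_genos))

    # --- annotation rows
    damaging_values = {
        "provean": "-4.1", "sift": "0.001", "polyphen2": "0.982",
        "mutationtaster": "disease_causing",
    }
    tolerated_values = {
        "provean": "1.2", "sift": "0.44", "polyphen2": "0.021",
        "mutationtaster": "polymorphism",
    }
    tools = ("provean", "sift", "polyphen2", "mutationtaster")

    ann_rows: list[dict] = []
    expression_rows: dict[str, float] = {}

    causal_acs = {p.name: min(2, p.ac_cap) for p in panels}
    ann_rows.append(
        {
            "key": causal.key, "gene": causal.gene_symbol,
            "acs": {n: str(c) for n, c in causal_acs.items()},
            "preds": dict(damaging_values),
        }
    )
    expression_rows[causal.gene_symbol] = 44.5  # retina-expressed, HPA-like scale

    background: list[BackgroundTruth] = []
    fam_ids = [p.family_id for p in ped_set]
    pp = config.background_pass
    for j in range(config.n_background_variants):
        chrom = str(1 + j % 22)
        pos = 1_000_000 + 137 * (j // 22 + 1)
        ref = str(_BASES[int(rng_bg.integers(0, 4))])
        alt = str(_BASES[(list(_BASES).index(ref) + 1 + int(rng_bg.integers(0, 3))) % 4])
        key = VariantKey(chrom, pos, ref, alt)
        gene = f"BG{j + 1:04d}"
        host = fam_ids[int(rng_bg.integers(0, len(fam_ids)))]
        built = {s: bool(rng_bg.random() < getattr(pp, s)) for s in FILTER_STAGES}

        # genotypes: carried by the host family's affecteds; a failing
        # variant is additionally carried by one unaffected host member
        ped = ped_set[host]
        genos: dict[str, Genotype] = {
            m.individual_id: Genotype.HET for m in ped.affected
        }
        if not built["segregation"]:
            unaff = ped.unaffected
            pick = unaff[int(rng_bg.integers(0, len(unaff)))]
            genos[pick.individual_id] = Genotype.HET
        records.append((key, genos))

        # panel allele counts
        acs: dict[str, str] = {}
        fail_panel = (
            panels[int(rng_bg.integers(0, len(panels)))].name
            if not built["frequency"]
            else None
        )
        for p in panels:
            if p.name == fail_panel:
                acs[p.name] = str(p.ac_cap + 1 + int(rng_bg.integers(0, 5)))
            else:
                within = int(rng_bg.integers(0, p.ac_cap + 1))
                # some unobserved panels: missingness is a fact of annotation
                acs[p.name] = "" if (within == 0 and rng_bg.random() < 0.3) else str(within)

        # prediction calls
        n_dmg = int(rng_bg.integers(3, 5)) if built["consensus"] else int(rng_bg.integers(0, 3))
        dmg_tools = list(rng_bg.permutation(4)[:n_dmg])
        preds = {
            t: (damaging_values[t] if i in dmg_tools else tolerated_values[t])
            for i, t in enumerate(tools)
        }

        # expression
        expression_rows[gene] = (
            round(float(rng_bg.uniform(1.0, 60.0)), 2)
            if built["expression"]
            else round(float(rng_bg.uniform(0.0, 0.99)), 2)
        )

        ann_rows.append({"key": key, "gene": gene, "acs": acs, "preds": preds})
        background.append(BackgroundTruth(key, gene, host, built))

    # --- clinical table: genotype-confirmed affected carriers
    patients = [
        (iid, fam)
        for fam in causal_fams
        for iid in sorted(carriers_by_family[fam])
        if ped_set[fam][iid].affection is Affection.AFFECTED
    ]
    stage_probs = {StageCode.IIb: 17 / 22, StageCode.IIIa: 4 / 22, StageCode.IIIb: 1 / 22}
    if len(patients) >= 5:
        clin_table, _ = simulate_clinical(
            n=len(patients),
            stage_onset_rho_target=config.stage_onset_rho,
            seed=0,
            stage_probs=stage_probs,
            patient_ids=patients,
            rng=rng_clin,
        )
    else:
        clin_table = ClinicalTable(records=[])

    # --- serialize
    ped_text = _ped_text(ped_set)
    vcf_text = _vcf_text(samples, records)
    panel_names = [p.name for p in panels]
    ann_lines = [
        "\t".join(
            ["chrom", "pos", "ref", "alt", "gene"]
            + [f"ac_{n}" for n in panel_names]
            + ["provean_score", "sift_score", "polyphen2_score_or_label",
               "mutationtaster_label"]
        )
    ]
    ann_rows.sort(key=lambda r: (_chrom_sort_key(r["key"].chrom), r["key"].pos))
    for row in ann_rows:
        k = row["key"]
        ann_lines.append(
            "\t".join(
                [k.chrom, str(k.pos), k.ref, k.alt, row["gene"]]
                + [row["acs"].get(n, "") for n in panel_names]
                + [row["preds"][t] for t in tools]
            )
        )
    expr_lines = ["gene\tntpm"] + [
        f"{g}\t{v:g}" for g, v in sorted(expression_rows.items())
    ]

    truth = TruthSet(
        causal_variant=causal.key,
        causal_gene=causal.gene_symbol,
        causal_families=causal_fams,
        background=background,
        genotypes={
            str(key): {iid: g.value for iid, g in sorted(genos.items())}
            for key, genos in records
        },
    )
    return SimulatedCohort(
        config=config,
        pedigrees=ped_set,
        truth=truth,
        clinical=clin_table,
        ped_text=ped_text,
        vcf_text=vcf_text,
        annotations_text="\n".join(ann_lines) + "\n",
        expression_text="\n".join(expr_lines) + "\n",
        clinical_text=clinical_text(clin_table),
    )
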