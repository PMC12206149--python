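"""Cross-family recurrence tallies of surviving candidates.

After the per-family cascade, candidate genes and variants are tallied
across pedigrees: a gene's recurrence is the number of pedigrees in which
at least one of its variants survived (a pedigree contributes at most once
per gene, however many of its variants remain), expressed as a percentage
of all analyzed pedigrees — including those whose candidate list came out
empty.  Percentages are rounded half-up to two decimals, so 26 of 78
pedigrees prints as 33.33 and 13 of 78 as 16.67.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

from .model import VariantKey


class DomainError(ValueError):
    pass


def percent(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to 2 decimals."""
    if total <= 0:
        raise DomainError(f"total must be positive, got {total}")
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class RecurrenceRow:
    gene_symbol: str
    n_pedigrees: int
    pct: float
    variants: dict[VariantKey, int] = field(default_factory=dict)


@dataclass
class VariantRecurrenceRow:
    variant: VariantKey
    gene_symbol: Optional[str]
    n_pedigrees: int
    pct: float


Candidates = Mapping[str, Iterable[tuple[VariantKey, Optional[str]]]]
"""Per-family surviving candidates: family id -> (variant, gene symbol) pairs."""


def tally_genes(per_family: Candidates, total_pedigrees: int) -> list[RecurrenceRow]:
    """Rank genes by the number of pedigrees carrying a surviving variant.

    Rows are ordered by descending pedigree count, ties broken
    lexicographically by gene symbol.  ``total_pedigrees`` is the analysis
    denominator (all pedigrees that entered the cascade).
    """
    if total_pedigrees <= 0:
        raise DomainError("total_pedigrees must be positive")
    if len(per_family) > total_pedigrees:
        raise DomainError(
            f"{len(per_family)} families with candidates exceeds "
            f"total_pedigrees={total_pedigrees}"
        )
    gene_fams: dict[str, set[str]] = {}
    gene_variant_fams: dict[str, dict[VariantKey, set[str]]] = {}
    for fam, cands in per_family.items():
        for key, gene in cands:
            sym = gene if gene is not None else "?"
            gene_fams.setdefault(sym, set()).add(fam)
            gene_variant_fams.setdefault(sym, {}).setdefault(key, set()).add(fam)
    rows = [
        RecurrenceRow(
            gene_symbol=sym,
            n_pedigrees=len(fams),
            pct=percent(len(fams), total_pedigrees),
            variants={
                k: len(f) for k, f in sorted(gene_variant_fams[sym].items())
            },
        )
        for sym, fams in gene_fams.items()
    ]
    rows.sort(key=lambda r: (-r.n_pedigrees, r.gene_symbol))
    return rows


def tally_variants(
    per_family: Candidates, total_pedigrees: int
) -> list[VariantRecurrenceRow]:
    """As :func:`tally_genes` but at variant granularity."""
    if total_pedigrees <= 0:
        raise DomainError("total_pedigrees must be positive")
    var_fams: dict[VariantKey, set[str]] = {}
    var_gene: dict[VariantKey, Optional[str]] = {}
    for fam, cands in per_family.items():
        for key, gene in cands:
            var_fams.setdefault(key, set()).add(fam)
            var_gene.setdefault(key, gene)
    rows = [
        VariantRecurrenceRow(
            variant=key,
            gene_symbol=var_gene[key],
            n_pedigrees=len(fams),
            pct=percent(len(fams), total_pedigrees),
        )
        for key, fams in var_fams.items()
    ]
    rows.sort(key=lambda r: (-r.n_pedigrees, str(r.variant)))
    return rows


def families_without_candidates(per_family: Candidates) -> tuple[int, list[str]]:
    """Families whose post-cascade candidate list is empty."""
    ids = sorted(fam for fam, cands in per_family.items() if not list(cands))
    return len(ids), ids
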