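"""Retinal-expression filtering of candidate genes.

A candidate gene must be expressed in the target tissue: genes with
normalized transcripts-per-million (nTPM) below 1 in retina are excluded.
A gene absent from the expression table is treated as not expressed — the
restrictive reading, since the candidate set should be defensible — unless
``keep_unannotated`` is set.  Symbols are matched case-insensitively after
whitespace stripping; no alias resolution is attempted (unmatched symbols
are simply not found).
"""

from __future__ import annotations

import logging
from typing import Mapping

log = logging.getLogger(__name__)

DEFAULT_MIN_NTPM = 1.0


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


def normalize_expression_table(table: Mapping[str, float]) -> dict[str, float]:
    return {_normalize(g): float(v) for g, v in table.items()}


def retina_expressed(
    gene_symbol: str,
    table: Mapping[str, float],
    min_ntpm: float = DEFAULT_MIN_NTPM,
    keep_unannotated: bool = False,
) -> bool:
    """True iff the gene's retinal nTPM is at or above the threshold.

    ``table`` maps (normalized) gene symbol to nTPM.  Genes missing from
    the table count as not expressed unless ``keep_unannotated``.
    """
    norm = normalize_expression_table(table)
    sym = _normalize(gene_symbol)
    if sym not in norm:
        log.debug("gene %r not in expression table", gene_symbol)
        return keep_unannotated
    return norm[sym] >= min_ntpm


def filter_expressed(
    genes: list[str],
    table: Mapping[str, float],
    min_ntpm: float = DEFAULT_MIN_NTPM,
    keep_unannotated: bool = False,
) -> list[str]:
    """Subset of ``genes`` passing the expression requirement (order kept)."""
    norm = normalize_expression_table(table)
    out = []
    for g in genes:
        sym = _normalize(g)
        if sym in norm:
            if norm[sym] >= min_ntpm:
                out.append(g)
        elif keep_unannotated:
            out.append(g)
    return out
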