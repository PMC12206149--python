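"""Panel allele-frequency filtering for rare dominant candidates.

A minor-allele-frequency cutoff c applied to a reference panel of N diploid
individuals translates to an allele-count cap of floor(2*N*c): the largest
allele count whose frequency does not exceed c.  The comparison at the cap
is inclusive — a variant observed exactly at the implied frequency still
passes — and a variant must clear the cap in every configured panel.

The default panel set covers the catalogs typically consulted for East
Asian rare-disease cohorts (ExAC, gnomAD, HGVD, 54KJPN and an in-house
control panel) at a dominant-model cutoff of 2.5e-4; at that cutoff the
caps work out to 30, 70, 0, 27 and 1 alternate alleles respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .model import DataError, VariantKey


class DomainError(ValueError):
    pass


DEFAULT_MAF_CUTOFF = 0.00025


@dataclass(frozen=True)
class FrequencyPanel:
    """A reference panel: name, diploid sample size, MAF cutoff."""

    name: str
    n_individuals: int
    maf_cutoff: float = DEFAULT_MAF_CUTOFF

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise DomainError(f"panel {self.name!r}: n_individuals must be >= 1")
        if not (0 < self.maf_cutoff < 1):
            raise DomainError(f"panel {self.name!r}: maf_cutoff must be in (0, 1)")

    @property
    def ac_cap(self) -> int:
        return ac_threshold(self.n_individuals, self.maf_cutoff)


@dataclass(frozen=True)
class PanelObservation:
    """Observed allele count for one variant in one panel (None = unobserved)."""

    variant: VariantKey
    panel_name: str
    allele_count: Optional[int]


def default_panels(maf_cutoff: float = DEFAULT_MAF_CUTOFF) -> list[FrequencyPanel]:
    return [
        FrequencyPanel("exac", 60707, maf_cutoff),
        FrequencyPanel("gnomad", 141456, maf_cutoff),
        FrequencyPanel("hgvd", 1208, maf_cutoff),
        FrequencyPanel("tommo54k", 54000, maf_cutoff),
        FrequencyPanel("inhouse", 2076, maf_cutoff),
    ]


def ac_threshold(n_individuals: int, maf_cutoff: float) -> int:
    """Maximum allele count a passing variant may show in a panel.

    floor(2 * N * c): the largest integer a with a / (2N) <= c.  Allosomes
    are treated as diploid (panel sex composition is unknown).
    """
    if n_individuals < 1:
        raise DomainError(f"n_individuals must be positive, got {n_individuals}")
    if not (0 < maf_cutoff < 1):
        raise DomainError(f"maf_cutoff must be in (0, 1), got {maf_cutoff}")
    return math.floor(2 * n_individuals * maf_cutoff)


def passes_frequency(
    variant: VariantKey,
    observations: Iterable[PanelObservation],
    panels: Iterable[FrequencyPanel],
) -> bool:
    """True iff the variant's allele count is within the cap in every panel.

    An absent observation (or allele_count None) means the variant was not
    seen in that panel and counts as zero.
    """
    panels = list(panels)
    by_name = {p.name: p for p in panels}
    ac: dict[str, int] = {}
    for obs in observations:
        panel = by_name.get(obs.panel_name)
        if panel is None:
            raise DataError(
                f"{variant}: observation for unconfigured panel {obs.panel_name!r}"
            )
        count = obs.allele_count if obs.allele_count is not None else 0
        if count < 0:
            raise DataError(f"{variant}: negative allele count in {obs.panel_name!r}")
        if count > 2 * panel.n_individuals:
            raise DataError(
                f"{variant}: allele count {count} exceeds 2N={2 * panel.n_individuals} "
                f"in panel {obs.panel_name!r}"
            )
        ac[obs.panel_name] = count
    return all(ac.get(p.name, 0) <= p.ac_cap for p in panels)


def passes_frequency_counts(
    allele_counts: dict[str, Optional[int]],
    panels: Iterable[FrequencyPanel],
    variant: Optional[VariantKey] = None,
) -> bool:
    """Convenience form taking the ``panel -> allele count`` mapping that the
    annotation table stores directly."""
    key = variant or VariantKey("0", 1, "N", "A")
    obs = [
        PanelObservation(key, name, count)
        for name, count in allele_counts.items()
    ]
    return passes_frequency(key, obs, panels)
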