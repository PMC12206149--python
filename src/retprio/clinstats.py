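"""Clinical staging statistics for the macular dystrophy cohort.

The six SD-OCT stages (Ia..IIIb) carry a fixed ordinal encoding 1..6, which
lets rank statistics relate disease severity to onset age and duration.
The battery mirrors common ophthalmic-genetics practice: Spearman rank
correlation for severity vs. onset/duration, Welch's t for group mean
differences without equal-variance assumptions, Mann-Whitney U as the
distribution-free alternative, Shapiro-Wilk for normality and Levene for
variance homogeneity.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .model import ClinicalRecord, ClinicalTable, StageCode


class DegenerateInputError(ValueError):
    """The statistic is undefined on this input (e.g. a constant vector)."""


class UsageError(ValueError):
    pass


def stage_to_ordinal(stage: StageCode) -> int:
    return stage.ordinal


@dataclass
class StageDistribution:
    counts: dict[StageCode, int]
    percentages: dict[StageCode, float]
    n_staged: int
    unstaged: list[str]


def stage_distribution(records: Iterable[ClinicalRecord]) -> StageDistribution:
    """Per-stage counts and percentages (half-up, 2 decimals) over staged patients.

    Unstaged records are listed separately and excluded from the
    denominator.
    """
    counts: dict[StageCode, int] = {}
    unstaged: list[str] = []
    for r in records:
        if r.stage is None:
            unstaged.append(r.patient_id)
        else:
            counts[r.stage] = counts.get(r.stage, 0) + 1
    n = sum(counts.values())
    pct = {
        s: float(
            (Decimal(100 * c) / Decimal(n)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
        for s, c in counts.items()
    }
    return StageDistribution(
        counts=dict(sorted(counts.items(), key=lambda kv: kv[0].ordinal)),
        percentages=dict(sorted(pct.items(), key=lambda kv: kv[0].ordinal)),
        n_staged=n,
        unstaged=unstaged,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties; two-sided t-based p.

    Equivalent to the Pearson correlation of the two midrank vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UsageError("x and y must have equal length")
    if x.size < 3:
        raise UsageError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("spearman undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UsageError("each group needs >= 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical degenerate groups: no evidence of difference
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DegenerateInputError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U for the first group, normal approximation with tie
    correction; two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UsageError("each group needs >= 2 observations")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise UsageError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("shapiro-wilk undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def levene(
    groups: Sequence[Sequence[float]],
    center: Literal["mean", "median"] = "mean",
) -> tuple[float, float]:
    """Levene's test for variance homogeneity on absolute deviations from the
    group center (mean by default; median gives the Brown-Forsythe variant)."""
    if len(groups) < 2:
        raise UsageError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise UsageError("each group needs >= 2 observations")
    res = stats.levene(*arrays, center=center)
    return float(res.statistic), float(res.pvalue)


def correlate_stage(
    records: Iterable[ClinicalRecord],
    against: Literal["onset_age", "duration"],
) -> tuple[float, float]:
    """Spearman correlation of ordinal stage vs. onset age or disease duration.

    Only records with both the stage and the chosen covariate present are
    used; fewer than 3 such records is a usage error.
    """
    if against not in ("onset_age", "duration"):
        raise UsageError(f"unknown covariate {against!r}")
    xs: list[float] = []
    ys: list[float] = []
    for r in records:
        if r.stage is None:
            continue
        cov = r.onset_age if against == "onset_age" else r.duration
        if cov is None:
            continue
        xs.append(float(r.stage.ordinal))
        ys.append(float(cov))
    if len(xs) < 3:
        raise UsageError(f"need >= 3 complete records, got {len(xs)}")
    return spearman(xs, ys)


def summarize(table: ClinicalTable) -> dict:
    """Descriptive summary: median, mean, SEM and range of onset age and
    duration, plus the stage distribution."""
    onsets = np.array([r.onset_age for r in table], dtype=float)
    durations = np.array(
        [r.duration for r in table if r.duration is not None], dtype=float
    )

    def block(x: np.ndarray) -> Optional[dict]:
        if x.size == 0:
            return None
        return {
            "n": int(x.size),
            "median": float(np.median(x)),
            "mean": float(np.mean(x)),
            "sem": float(stats.sem(x)) if x.size > 1 else None,
            "range": [float(np.min(x)), float(np.max(x))],
        }

    dist = stage_distribution(table)
    return {
        "n_patients": len(table),
        "onset_age": block(onsets),
        "duration": block(durations),
        "stage_counts": {s.name: c for s, c in dist.counts.items()},
        "stage_percentages": {s.name: p for s, p in dist.percentages.items()},
        "n_unstaged": len(dist.unstaged),
    }
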