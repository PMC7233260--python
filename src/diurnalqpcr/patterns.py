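"""Rule-based diurnal pattern classification and cross-region concordance.

A gene in a region is called *diurnal* when at least one of three criteria
holds:

1. the one-way ANOVA time-point effect is significant (p <= alpha),
2. any of the three pairwise t-tests (ZT3 vs ZT5, ZT5 vs ZT9, ZT3 vs ZT9)
   is significant (p <= alpha), or
3. the mean -ddCT at any time point exceeds the magnitude threshold
   (|mean| > 0.25 by default, roughly a 20% change in relative expression
   under doubling efficiency).

Diurnal genes get a direction pair (d_ZT3, d_ZT9) with each element in
{up, down, flat} relative to the ZT5 reference — 3^2 - 1 = 8 possible
non-flat patterns. Support is *statistics-based* when criterion 1 or 2
fires and *threshold-based* when only criterion 3 does.

Direction rule (deterministic formalization): time point t is "up" when
mean -ddCT(t) > threshold, or when the t-vs-ZT5 t-test is significant and
mean -ddCT(t) > 0; "down" symmetrically; otherwise "flat". If a gene is
diurnal but both directions resolve flat (e.g. only the ZT3-vs-ZT9 test
fired), the time point with the larger |mean -ddCT| lends its sign,
flagged ``DIRECTION_FALLBACK``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffstats import GeneRegionStats, OK, PAIRS
from .synthetic import PATTERN_CODES

DEFAULT_ALPHA = 0.05
DEFAULT_THRESHOLD = 0.25

#: Row/column order of the concordance matrix: 8 patterns then "none".
CONCORDANCE_LEVELS = PATTERN_CODES + ("none",)


@dataclass
class PatternCall:
    gene_id: str
    region: str
    diurnal: bool
    direction: tuple[str, str]  # (d_ZT3, d_ZT9)
    support: str  # statistics | threshold | none
    criteria_met: frozenset[str]  # subset of {C1_anova, C2_ttest, C3_threshold}
    flags: frozenset[str] = frozenset()

    @property
    def pattern(self) -> str:
        return "none" if self.direction == ("flat", "flat") else f"{self.direction[0]}/{self.direction[1]}"


@dataclass
class ConcordanceMatrix:
    """9x9 cross-tabulation of DVC patterns (rows) vs CeA patterns (columns)."""

    counts: pd.DataFrame  # index/columns = CONCORDANCE_LEVELS
    not_quantifiable: dict[str, int] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_same_pattern(self) -> int:
        """Genes sharing the same non-flat pattern in both regions (diagonal)."""
        return int(sum(self.counts.loc[p, p] for p in PATTERN_CODES))

    @property
    def n_diurnal_both(self) -> int:
        return int(self.counts.loc[list(PATTERN_CODES), list(PATTERN_CODES)].to_numpy().sum())

    @property
    def n_diurnal_either(self) -> int:
        return self.n_genes - int(self.counts.loc["none", "none"])


def _sig(p: float, status: str, alpha: float) -> bool:
    # untestable / missing statistics never satisfy a criterion
    return status == OK and math.isfinite(p) and p <= alpha


def _direction_for(
    mean: float, p_vs_ref: float, status: str, alpha: float, threshold: float
) -> str:
    if math.isfinite(mean):
        if mean > threshold:
            return "up"
        if mean < -threshold:
            return "down"
        if _sig(p_vs_ref, status, alpha):
            if mean > 0:
                return "up"
            if mean < 0:
                return "down"
    return "flat"


def classify_diurnal(
    stats: GeneRegionStats,
    alpha: float = DEFAULT_ALPHA,
    threshold: float = DEFAULT_THRESHOLD,
) -> PatternCall:
    """Apply the three diurnal criteria and the direction rule to one gene."""
    means = stats.mean_neg_ddct
    c1 = _sig(stats.p_oneway, stats.oneway_status, alpha)
    c2 = any(_sig(stats.p_ttest[p], stats.ttest_status[p], alpha) for p in PAIRS)
    c3 = any(
        math.isfinite(means[zt]) and abs(means[zt]) > threshold for zt in ("ZT3", "ZT9")
    )
    criteria = frozenset(
        name for name, met in (("C1_anova", c1), ("C2_ttest", c2), ("C3_threshold", c3)) if met
    )
    diurnal = bool(criteria)

    flags: set[str] = set()
    if not diurnal:
        return PatternCall(stats.gene_id, stats.region, False, ("flat", "flat"), "none", criteria)

    d3 = _direction_for(
        means["ZT3"], stats.p_ttest[("ZT3", "ZT5")], stats.ttest_status[("ZT3", "ZT5")], alpha, threshold
    )
    d9 = _direction_for(
        means["ZT9"], stats.p_ttest[("ZT5", "ZT9")], stats.ttest_status[("ZT5", "ZT9")], alpha, threshold
    )
    if (d3, d9) == ("flat", "flat"):
        # diurnal call without a per-timepoint signal (e.g. only ZT3-vs-ZT9
        # fired): larger-|mean| time point lends its sign
        m3 = means["ZT3"] if math.isfinite(means["ZT3"]) else 0.0
        m9 = means["ZT9"] if math.isfinite(means["ZT9"]) else 0.0
        if abs(m3) >= abs(m9):
            d3 = "up" if m3 > 0 else "down"
        else:
            d9 = "up" if m9 > 0 else "down"
        flags.add("DIRECTION_FALLBACK")

    support = "statistics" if (c1 or c2) else "threshold"
    return PatternCall(
        stats.gene_id, stats.region, True, (d3, d9), support, criteria, frozenset(flags)
    )


def classify_region(
    stats: Sequence[GeneRegionStats],
    alpha: float = DEFAULT_ALPHA,
    threshold: float = DEFAULT_THRESHOLD,
    not_quantifiable: Iterable[tuple[str, str]] = (),
) -> list[PatternCall]:
    """Classify every quantifiable gene of one region."""
    nq = set(not_quantifiable)
    return [
        classify_diurnal(s, alpha, threshold)
        for s in stats
        if (s.gene_id, s.region) not in nq
    ]


def calls_frame(calls: Sequence[PatternCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "region": [c.region for c in calls],
            "diurnal": [c.diurnal for c in calls],
            "pattern": [c.pattern for c in calls],
            "support": [c.support for c in calls],
            "criteria_met": ["|".join(sorted(c.criteria_met)) for c in calls],
            "flags": ["|".join(sorted(c.flags)) for c in calls],
        }
    )


def concordance(
    calls_dvc: Sequence[PatternCall], calls_cea: Sequence[PatternCall]
) -> ConcordanceMatrix:
    """Cross-tabulate pattern calls of genes quantifiable in both regions.

    Genes present in only one region's call set (not quantifiable in the
    other) are excluded from the 9x9 counts and tallied separately.
    """
    dvc = {c.gene_id: c for c in calls_dvc}
    cea = {c.gene_id: c for c in calls_cea}
    if len(dvc) != len(calls_dvc) or len(cea) != len(calls_cea):
        raise ValueError("duplicate gene in a call set")
    shared = set(dvc) & set(cea)
    only_dvc = set(dvc) - shared
    only_cea = set(cea) - shared

    counts = pd.DataFrame(
        0, index=list(CONCORDANCE_LEVELS), columns=list(CONCORDANCE_LEVELS), dtype=int
    )
    for g in shared:
        counts.loc[dvc[g].pattern, cea[g].pattern] += 1
    return ConcordanceMatrix(
        counts,
        not_quantifiable={"CeA_only_in_DVC": len(only_dvc), "DVC_only_in_CeA": len(only_cea)},
    )
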