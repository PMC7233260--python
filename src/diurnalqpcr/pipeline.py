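"""End-to-end pipeline: normalize -> stats -> MDS -> patterns -> alignment.

Every analysis constant lives in :class:`RunConfig` (alpha, the -ddCT
magnitude threshold, the reference time point, MDS settings, alignment
cutoffs); the stages themselves only receive what the config provides,
so identical config and inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import alignment as align_mod
from . import diffstats, ordination, patterns
from .data_io import (
    CtMatrix,
    SampleAnnotation,
    write_gene_stats_table,
)
from .normalization import (
    NormalizedMatrix,
    compute_relative_expression,
    quantile_normalize,
)

logger = logging.getLogger("diurnalqpcr")


@dataclass
class RunConfig:
    """All tunable analysis parameters, serializable to/from YAML."""

    alpha: float = 0.05
    threshold: float = 0.25
    reference_zt: str = "ZT5"
    normalize_per_region: bool = False
    mds_gene_policy: str = "complete_genes"
    mds_k: int = 3
    alignment_cutoffs: dict[str, float] = field(
        default_factory=lambda: dict(align_mod.CATEGORY_CUTOFFS)
    )
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SummaryCounts:
    """Descriptive counts over the full analysis, per region and combined."""

    n_genes: int
    per_region: dict[str, dict[str, int]]
    n_sig_both_oneway: int
    n_diurnal_either: int
    n_diurnal_both: int
    n_same_pattern: int
    n_twofactor_time: int
    n_twofactor_region: int
    alignment_bands: dict[str, int]

    def validate(self) -> None:
        for region, c in self.per_region.items():
            if c["n_diurnal"] != c["n_statistics_based"] + c["n_threshold_only"]:
                raise ValueError(
                    f"{region}: n_diurnal != statistics-based + threshold-only"
                )
        min_diurnal = min(
            (c["n_diurnal"] for c in self.per_region.values()), default=0
        )
        if self.n_diurnal_both > min_diurnal:
            raise ValueError("n_diurnal_both exceeds a region's diurnal count")
        if self.n_same_pattern > self.n_diurnal_both:
            raise ValueError("n_same_pattern exceeds n_diurnal_both")
        region_counts = [c["n_diurnal"] for c in self.per_region.values()]
        if len(region_counts) == 2:
            expected = sum(region_counts) - self.n_diurnal_both
            if self.n_diurnal_either != expected:
                raise ValueError("inclusion-exclusion identity violated")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize(
    calls_by_region: dict[str, list[patterns.PatternCall]],
    oneway_by_region: dict[str, pd.DataFrame],
    twofactor: list[diffstats.TwoFactorStats],
    alignment_records: Sequence[align_mod.AlignmentRecord],
    conc: patterns.ConcordanceMatrix,
    alpha: float = 0.05,
) -> SummaryCounts:
    """Tally the headline counts and enforce their consistency identities."""
    regions = sorted(calls_by_region)
    per_region: dict[str, dict[str, int]] = {}
    diurnal_sets: dict[str, set[str]] = {}
    gene_universe: set[str] = set()
    for region in regions:
        calls = calls_by_region[region]
        gene_universe |= {c.gene_id for c in calls}
        ow = oneway_by_region[region]
        sig_oneway = {
            g
            for g in ow.index
            if ow.loc[g, "status"] == diffstats.OK and ow.loc[g, "p"] <= alpha
        }
        stats_based = {c.gene_id for c in calls if c.support == "statistics"}
        thresh_only = {c.gene_id for c in calls if c.support == "threshold"}
        diurnal = {c.gene_id for c in calls if c.diurnal}
        diurnal_sets[region] = diurnal
        per_region[region] = {
            "n_sig_oneway": len(sig_oneway),
            "n_sig_ttest_only": len(stats_based - sig_oneway),
            "n_statistics_based": len(stats_based),
            "n_threshold_only": len(thresh_only),
            "n_diurnal": len(diurnal),
        }

    oneway_sig_sets = [
        {
            g
            for g in oneway_by_region[r].index
            if oneway_by_region[r].loc[g, "status"] == diffstats.OK
            and oneway_by_region[r].loc[g, "p"] <= alpha
        }
        for r in regions
    ]
    n_sig_both = len(set.intersection(*oneway_sig_sets)) if oneway_sig_sets else 0

    all_diurnal = set().union(*diurnal_sets.values()) if diurnal_sets else set()
    both_diurnal = (
        set.intersection(*diurnal_sets.values()) if len(diurnal_sets) > 1 else set()
    )

    bands = {cat: 0 for cat in align_mod.CATEGORIES}
    for r in alignment_records:
        bands[r.category] += 1

    counts = SummaryCounts(
        n_genes=len(gene_universe),
        per_region=per_region,
        n_sig_both_oneway=n_sig_both,
        n_diurnal_either=len(all_diurnal),
        n_diurnal_both=len(both_diurnal),
        n_same_pattern=conc.n_same_pattern,
        n_twofactor_time=sum(
            1 for s in twofactor if s.status == diffstats.OK and s.p_time <= alpha
        ),
        n_twofactor_region=sum(
            1 for s in twofactor if s.status == diffstats.OK and s.p_region <= alpha
        ),
        alignment_bands=bands,
    )
    counts.validate()
    return counts


def run_pipeline(
    ct: CtMatrix,
    annotations: Sequence[SampleAnnotation],
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[SummaryCounts, dict[str, object]]:
    """Run every analysis stage on one CT matrix.

    Returns the summary counts and a dict of all intermediate artifacts
    (normalized matrix, relative expression, per-region stats and calls,
    MDS results, alignment records, concordance). When ``out_dir`` is given,
    each artifact is also written as a CSV table.
    """
    config = config or RunConfig()
    regions = sorted({a.region for a in annotations})

    logger.info("normalizing %d genes x %d samples", len(ct.gene_ids), len(ct.sample_ids))
    if config.normalize_per_region:
        norm = _normalize_per_region(ct, annotations)
    else:
        norm = quantile_normalize(ct)
    relexpr = compute_relative_expression(
        norm, annotations, reference_zt=config.reference_zt
    )

    twofactor = diffstats.two_factor_anova(norm, annotations)

    stats_by_region: dict[str, list[diffstats.GeneRegionStats]] = {}
    oneway_by_region: dict[str, pd.DataFrame] = {}
    calls_by_region: dict[str, list[patterns.PatternCall]] = {}
    for region in regions:
        stats = diffstats.region_gene_stats(
            norm, annotations, region, relexpr.timepoint_means
        )
        stats_by_region[region] = stats
        oneway_by_region[region] = diffstats.one_way_anova_time(norm, annotations, region)
        calls_by_region[region] = patterns.classify_region(
            stats,
            alpha=config.alpha,
            threshold=config.threshold,
            not_quantifiable=relexpr.not_quantifiable,
        )

    D, sample_ids = ordination.sample_distances(norm, config.mds_gene_policy)
    mds_all = ordination.classical_mds(D, config.mds_k, sample_ids)
    mds_by_region: dict[str, ordination.MdsResult] = {}
    for region in regions:
        keep = [
            j
            for j, s in enumerate(sample_ids)
            if next(a for a in annotations if a.sample_id == s).region == region
        ]
        Dr = D[np.ix_(keep, keep)]
        mds_by_region[region] = ordination.classical_mds(
            Dr, config.mds_k, [sample_ids[j] for j in keep]
        )

    records = align_mod.alignment_table(norm, annotations)
    if set(regions) == {"DVC", "CeA"}:
        conc = patterns.concordance(calls_by_region["DVC"], calls_by_region["CeA"])
    else:
        conc = patterns.ConcordanceMatrix(
            pd.DataFrame(
                0,
                index=list(patterns.CONCORDANCE_LEVELS),
                columns=list(patterns.CONCORDANCE_LEVELS),
                dtype=int,
            )
        )

    counts = summarize(
        calls_by_region, oneway_by_region, twofactor, records, conc, config.alpha
    )

    artifacts: dict[str, object] = {
        "normalized": norm,
        "relative_expression": relexpr,
        "two_factor": twofactor,
        "stats_by_region": stats_by_region,
        "oneway_by_region": oneway_by_region,
        "calls_by_region": calls_by_region,
        "mds_all": mds_all,
        "mds_by_region": mds_by_region,
        "alignment": records,
        "concordance": conc,
    }

    if out_dir is not None:
        _write_artifacts(Path(out_dir), config, counts, artifacts)
    return counts, artifacts


def _normalize_per_region(
    ct: CtMatrix, annotations: Sequence[SampleAnnotation]
) -> NormalizedMatrix:
    """Quantile-normalize each region's samples separately, then re-join."""
    by_id = {a.sample_id: a for a in annotations}
    out = np.full_like(ct.values, np.nan)
    for region in sorted({a.region for a in annotations}):
        idx = [j for j, s in enumerate(ct.sample_ids) if by_id[s].region == region]
        sub = CtMatrix(
            list(ct.gene_ids),
            [ct.sample_ids[j] for j in idx],
            ct.values[:, idx],
            ct.max_cycles,
        )
        out[:, idx] = quantile_normalize(sub).delta_ct
    return NormalizedMatrix(list(ct.gene_ids), list(ct.sample_ids), out)


def _write_artifacts(
    out_dir: Path, config: RunConfig, counts: SummaryCounts, artifacts: dict
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")

    norm: NormalizedMatrix = artifacts["normalized"]
    df = norm.to_frame()
    df.index.name = "gene"
    df.to_csv(out_dir / "normalized.csv", na_rep="NA", float_format="%.12g")

    relexpr = artifacts["relative_expression"]
    rdf = relexpr.to_frame()
    rdf.index.name = "gene"
    rdf.to_csv(out_dir / "neg_ddct.csv", na_rep="NA", float_format="%.12g")

    for region, stats in artifacts["stats_by_region"].items():
        sdf = diffstats.stats_frame(stats)
        cdf = patterns.calls_frame(artifacts["calls_by_region"][region])
        quantifiable = set(cdf["gene_id"])
        sdf = sdf[sdf["gene_id"].isin(quantifiable)]
        write_gene_stats_table(sdf, cdf, out_dir / f"gene_stats_{region}.csv")

    artifacts["mds_all"].to_frame().to_csv(out_dir / "mds_all.csv", index_label="sample_id")
    for region, res in artifacts["mds_by_region"].items():
        res.to_frame().to_csv(out_dir / f"mds_{region}.csv", index_label="sample_id")

    align_mod.alignment_frame(artifacts["alignment"]).to_csv(
        out_dir / "alignment.csv", index=False, float_format="%.12g"
    )
    artifacts["concordance"].counts.to_csv(out_dir / "concordance.csv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(counts.to_dict(), fh, indent=2, sort_keys=True)
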