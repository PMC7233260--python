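"""Per-gene differential statistics on deltaCT values.

All tests are fixed-effects, uncorrected, evaluated at alpha = 0.05:

* an additive two-factor ANOVA (region + time, no interaction) with
  Type II sums of squares for the unbalanced design,
* a per-region one-way ANOVA on time point,
* the three pairwise pooled-variance (Student) two-tailed t-tests,
* Tukey HSD comparisons using the studentized-range distribution with
  Tukey-Kramer standard errors for unequal group sizes.

No multiple-testing correction is applied anywhere; downstream counts are
descriptive and accept the implied false-positive rate.

Degenerate inputs never raise: a gene whose groups are too small or have
zero variance is flagged (``NOT_TESTABLE`` / ``DEGENERATE``) so that
whole-plate loops always complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import SampleAnnotation, ZT_LEVELS
from .normalization import NormalizedMatrix, _region_zt_columns

ALPHA = 0.05

#: The three time-point contrasts, in reporting order.
PAIRS = (("ZT3", "ZT5"), ("ZT5", "ZT9"), ("ZT3", "ZT9"))

# status flags
OK = "OK"
NOT_TESTABLE = "NOT_TESTABLE"
DEGENERATE = "DEGENERATE"


@dataclass
class TwoFactorStats:
    """Region and time main effects of the additive two-factor ANOVA."""

    gene_id: str
    f_time: float
    p_time: float
    f_region: float
    p_region: float
    df: tuple[int, int, int]  # (df_region, df_time, df_residual)
    status: str = OK


@dataclass
class GeneRegionStats:
    """All per-gene, per-region statistics feeding the pattern classifier."""

    gene_id: str
    region: str
    p_oneway: float
    oneway_status: str
    p_ttest: dict[tuple[str, str], float]
    ttest_status: dict[tuple[str, str], str]
    p_tukey: dict[tuple[str, str], float]
    tukey_status: dict[tuple[str, str], str]
    group_means: dict[str, float]  # mean deltaCT per zt
    group_sizes: dict[str, int]
    mean_neg_ddct: dict[str, float]  # mean -ddCT per zt


def _groups_for_gene(
    dct_row: np.ndarray, cols: dict[tuple[str, str], np.ndarray], region: str
) -> dict[str, np.ndarray]:
    out = {}
    for zt in ZT_LEVELS:
        idx = cols.get((region, zt), np.array([], dtype=int))
        vals = dct_row[idx]
        out[zt] = vals[np.isfinite(vals)]
    return out


def _anova_f(groups: Sequence[np.ndarray]) -> tuple[float, float, int, int, str]:
    """One-way fixed-effects F test with explicit degenerate handling."""
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        return np.nan, np.nan, 0, 0, NOT_TESTABLE
    all_vals = np.concatenate(groups)
    k = len(groups)
    n = all_vals.size
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within <= 1e-30:
        if ss_between <= 1e-30:
            return np.nan, np.nan, df_b, df_w, NOT_TESTABLE  # all values equal
        return np.inf, 0.0, df_b, df_w, DEGENERATE  # exact separation
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, float(sps.f.sf(f, df_b, df_w)), df_b, df_w, OK


def two_factor_anova(
    norm: NormalizedMatrix, annotations: Sequence[SampleAnnotation]
) -> list[TwoFactorStats]:
    """Additive two-factor ANOVA (deltaCT ~ region + time), Type II SS.

    Type II tests each main effect against the model containing the other
    factor, which for the additive model reduces to the nested-model F
    comparing residual sums of squares; this keeps the unbalanced-design
    main-effect tests invariant to factor order.
    """
    ann_by_id = {a.sample_id: a for a in annotations}
    regions = sorted({a.region for a in annotations})
    zts = [z for z in ZT_LEVELS if any(a.zt == z for a in annotations)]
    region_idx = {r: i for i, r in enumerate(regions)}
    zt_idx = {z: i for i, z in enumerate(zts)}

    n_samples = len(norm.sample_ids)
    # full-rank treatment-coded design columns (intercept + dummies)
    X_full = np.zeros((n_samples, 1 + (len(regions) - 1) + (len(zts) - 1)))
    X_full[:, 0] = 1.0
    for j, s in enumerate(norm.sample_ids):
        a = ann_by_id[s]
        if region_idx[a.region] > 0:
            X_full[j, region_idx[a.region]] = 1.0
        if zt_idx[a.zt] > 0:
            X_full[j, len(regions) - 1 + zt_idx[a.zt]] = 1.0
    region_cols = list(range(1, len(regions)))
    time_cols = list(range(len(regions), len(regions) - 1 + len(zts)))

    def rss(X: np.ndarray, y: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    results = []
    df_region, df_time = len(regions) - 1, len(zts) - 1
    for gi, gene in enumerate(norm.gene_ids):
        y = norm.delta_ct[gi]
        obs = np.isfinite(y)
        # every region and time level needs >= 2 observations
        counts_r = {r: 0 for r in regions}
        counts_t = {z: 0 for z in zts}
        for j in np.flatnonzero(obs):
            a = ann_by_id[norm.sample_ids[j]]
            counts_r[a.region] += 1
            counts_t[a.zt] += 1
        if min(counts_r.values(), default=0) < 2 or min(counts_t.values(), default=0) < 2:
            results.append(TwoFactorStats(gene, np.nan, np.nan, np.nan, np.nan, (df_region, df_time, 0), NOT_TESTABLE))
            continue
        Xo, yo = X_full[obs], y[obs]
        df_resid = yo.size - Xo.shape[1]
        total_ss = float(((yo - yo.mean()) ** 2).sum())
        if total_ss <= 1e-24:  # all observations equal
            results.append(TwoFactorStats(gene, np.nan, np.nan, np.nan, np.nan, (df_region, df_time, df_resid), NOT_TESTABLE))
            continue
        rss_full = rss(Xo, yo)
        rss_no_time = rss(Xo[:, [c for c in range(Xo.shape[1]) if c not in time_cols]], yo)
        rss_no_region = rss(Xo[:, [c for c in range(Xo.shape[1]) if c not in region_cols]], yo)
        tol = 1e-12 * total_ss
        if rss_full <= tol:  # the factors fit exactly: zero residual variance
            f_t = np.inf if rss_no_time > tol else 0.0
            f_r = np.inf if rss_no_region > tol else 0.0
            results.append(TwoFactorStats(gene, f_t, 0.0 if f_t == np.inf else 1.0, f_r, 0.0 if f_r == np.inf else 1.0, (df_region, df_time, df_resid), DEGENERATE))
            continue
        mse = rss_full / df_resid
        f_time = max(rss_no_time - rss_full, 0.0) / df_time / mse
        f_region = max(rss_no_region - rss_full, 0.0) / df_region / mse
        results.append(
            TwoFactorStats(
                gene,
                f_time,
                float(sps.f.sf(f_time, df_time, df_resid)),
                f_region,
                float(sps.f.sf(f_region, df_region, df_resid)),
                (df_region, df_time, df_resid),
            )
        )
    return results


def one_way_anova_time(
    norm: NormalizedMatrix, annotations: Sequence[SampleAnnotation], region: str
) -> pd.DataFrame:
    """One-way ANOVA of deltaCT across time points within one region.

    Returns a DataFrame indexed by gene with columns ``F``, ``p``, ``status``.
    """
    cols = _region_zt_columns(norm.sample_ids, annotations)
    rows = []
    for gi, gene in enumerate(norm.gene_ids):
        groups = _groups_for_gene(norm.delta_ct[gi], cols, region)
        f, p, _, _, status = _anova_f(list(groups.values()))
        rows.append({"gene_id": gene, "F": f, "p": p, "status": status})
    return pd.DataFrame(rows).set_index("gene_id")


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    if a.size < 2 or b.size < 2:
        return np.nan, np.nan, NOT_TESTABLE
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * var_a + (b.size - 1) * var_b) / df
    diff = a.mean() - b.mean()
    if sp2 <= 1e-30:
        if abs(diff) <= 1e-30:
            return 0.0, 1.0, OK
        return np.inf if diff > 0 else -np.inf, 0.0, DEGENERATE
    t = diff / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    return float(t), float(2 * sps.t.sf(abs(t), df)), OK


def pairwise_t_tests(
    norm: NormalizedMatrix, annotations: Sequence[SampleAnnotation], region: str
) -> pd.DataFrame:
    """Classical pooled-variance two-tailed t-tests for the three ZT pairs.

    Columns: ``p_{a}_{b}`` and ``status_{a}_{b}`` for each pair.
    """
    cols = _region_zt_columns(norm.sample_ids, annotations)
    rows = []
    for gi, gene in enumerate(norm.gene_ids):
        groups = _groups_for_gene(norm.delta_ct[gi], cols, region)
        row: dict[str, object] = {"gene_id": gene}
        for a, b in PAIRS:
            _, p, status = _pooled_t(groups[a], groups[b])
            row[f"p_{a}_{b}"] = p
            row[f"status_{a}_{b}"] = status
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def tukey_hsd(
    norm: NormalizedMatrix, annotations: Sequence[SampleAnnotation], region: str
) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for the three ZT pairs within a region.

    Uses the studentized-range distribution with the one-way ANOVA's pooled
    MSE and Tukey-Kramer standard errors for unequal group sizes.
    """
    cols = _region_zt_columns(norm.sample_ids, annotations)
    rows = []
    for gi, gene in enumerate(norm.gene_ids):
        groups = _groups_for_gene(norm.delta_ct[gi], cols, region)
        row: dict[str, object] = {"gene_id": gene}
        usable = {zt: g for zt, g in groups.items() if g.size >= 2}
        if len(usable) < 2:
            for a, b in PAIRS:
                row[f"p_{a}_{b}"] = np.nan
                row[f"status_{a}_{b}"] = NOT_TESTABLE
            rows.append(row)
            continue
        k = len(usable)
        n = sum(g.size for g in usable.values())
        mse = sum(((g - g.mean()) ** 2).sum() for g in usable.values()) / (n - k)
        df = n - k
        for a, b in PAIRS:
            if a not in usable or b not in usable:
                row[f"p_{a}_{b}"] = np.nan
                row[f"status_{a}_{b}"] = NOT_TESTABLE
                continue
            ga, gb = usable[a], usable[b]
            diff = abs(ga.mean() - gb.mean())
            if mse <= 1e-30:
                row[f"p_{a}_{b}"] = 1.0 if diff <= 1e-30 else 0.0
                row[f"status_{a}_{b}"] = DEGENERATE if diff > 1e-30 else OK
                continue
            se = np.sqrt(mse / 2 * (1 / ga.size + 1 / gb.size))
            q = diff / se
            row[f"p_{a}_{b}"] = float(sps.studentized_range.sf(q, k, df))
            row[f"status_{a}_{b}"] = OK
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def region_gene_stats(
    norm: NormalizedMatrix,
    annotations: Sequence[SampleAnnotation],
    region: str,
    mean_neg_ddct: pd.DataFrame | None = None,
) -> list[GeneRegionStats]:
    """Bundle all per-region statistics per gene into :class:`GeneRegionStats`.

    ``mean_neg_ddct``: the relative-expression per-timepoint means indexed by
    (gene_id, region); NaN means are recorded as-is when absent.
    """
    oneway = one_way_anova_time(norm, annotations, region)
    ttests = pairwise_t_tests(norm, annotations, region)
    tukey = tukey_hsd(norm, annotations, region)
    cols = _region_zt_columns(norm.sample_ids, annotations)

    out = []
    for gi, gene in enumerate(norm.gene_ids):
        groups = _groups_for_gene(norm.delta_ct[gi], cols, region)
        means = {zt: (float(g.mean()) if g.size else np.nan) for zt, g in groups.items()}
        sizes = {zt: int(g.size) for zt, g in groups.items()}
        if mean_neg_ddct is not None and (gene, region) in mean_neg_ddct.index:
            nd = {zt: float(mean_neg_ddct.loc[(gene, region), zt]) for zt in ZT_LEVELS}
        else:
            nd = {zt: np.nan for zt in ZT_LEVELS}
        out.append(
            GeneRegionStats(
                gene_id=gene,
                region=region,
                p_oneway=float(oneway.loc[gene, "p"]),
                oneway_status=str(oneway.loc[gene, "status"]),
                p_ttest={pair: float(ttests.loc[gene, f"p_{pair[0]}_{pair[1]}"]) for pair in PAIRS},
                ttest_status={pair: str(ttests.loc[gene, f"status_{pair[0]}_{pair[1]}"]) for pair in PAIRS},
                p_tukey={pair: float(tukey.loc[gene, f"p_{pair[0]}_{pair[1]}"]) for pair in PAIRS},
                tukey_status={pair: str(tukey.loc[gene, f"status_{pair[0]}_{pair[1]}"]) for pair in PAIRS},
                group_means=means,
                group_sizes=sizes,
                mean_neg_ddct=nd,
            )
        )
    return out


def stats_frame(stats: Sequence[GeneRegionStats]) -> pd.DataFrame:
    """Flatten :class:`GeneRegionStats` records into the result-table layout."""
    rows = []
    for s in stats:
        row = {
            "gene_id": s.gene_id,
            "region": s.region,
            "mean_neg_ddct_ZT3": s.mean_neg_ddct["ZT3"],
            "mean_neg_ddct_ZT5": s.mean_neg_ddct["ZT5"],
            "mean_neg_ddct_ZT9": s.mean_neg_ddct["ZT9"],
            "p_oneway": s.p_oneway,
        }
        for a, b in PAIRS:
            row[f"p_t_{a}_{b}"] = s.p_ttest[(a, b)]
            row[f"p_tukey_{a}_{b}"] = s.p_tukey[(a, b)]
        rows.append(row)
    return pd.DataFrame(rows)
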