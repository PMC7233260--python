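"""Quantile normalization of CT to deltaCT and relative expression (-ddCT).

Quantile normalization forces every sample's value distribution onto a
common reference (the mean of the samples' sorted value vectors) while
preserving within-sample ranks. It replaces housekeeping-gene referencing:
per-sample loading or efficiency offsets shift every value in a column by
(roughly) a constant and are removed because only ranks survive.

Relative expression is then computed per brain region against the ZT5
reference time point: ddCT(gene, sample) = dCT - mean dCT over that
region's ZT5 samples, and -ddCT is its negation so that positive values
mean higher expression than the ZT5 reference (lower CT = more transcript).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import CtMatrix, SampleAnnotation, ZT_LEVELS

REFERENCE_ZT = "ZT5"


class NormalizationError(ValueError):
    """Raised when a sample cannot be quantile-normalized."""


@dataclass
class NormalizedMatrix:
    """Quantile-normalized CT (deltaCT), same shape/missingness as the input."""

    gene_ids: list[str]
    sample_ids: list[str]
    delta_ct: np.ndarray  # NaN where input was missing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.delta_ct, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class RelativeExpression:
    """Per-sample -ddCT and per-timepoint means, per gene x region.

    ``not_quantifiable`` lists (gene, region) pairs with no usable ZT5
    reference observation; their values are NaN rather than silently dropped.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    neg_ddct: np.ndarray  # genes x samples, NaN for missing or unquantifiable
    timepoint_means: pd.DataFrame  # index (gene_id, region), columns ZT3/ZT5/ZT9
    not_quantifiable: set[tuple[str, str]] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.neg_ddct, index=self.gene_ids, columns=self.sample_ids)


def _reference_distribution(values: np.ndarray) -> np.ndarray:
    """Mean across samples of their sorted values, on a common grid.

    Each column's non-missing sorted values are linearly interpolated onto a
    grid of ``n_genes`` quantile positions; the reference is the grid-wise
    mean over columns. For complete matrices this is exactly the mean of the
    sorted columns.
    """
    n_genes, n_samples = values.shape
    grid = np.linspace(0.0, 1.0, n_genes)
    interpolated = np.empty((n_genes, n_samples))
    for j in range(n_samples):
        col = np.sort(values[~np.isnan(values[:, j]), j])
        if col.size < 2:
            raise NormalizationError(
                f"sample at column {j} has fewer than 2 non-missing values"
            )
        positions = np.linspace(0.0, 1.0, col.size)
        interpolated[:, j] = np.interp(grid, positions, col)
    return interpolated.mean(axis=1)


def quantile_normalize(ct: CtMatrix) -> NormalizedMatrix:
    """Rank-map every sample onto the mean-of-sorted-columns reference.

    Missing entries are excluded from rank computation and stay missing.
    Samples with missing entries map their ranks onto the reference by
    linear interpolation of quantile positions; tied values within a sample
    receive the mean of the reference values their ranks span.
    """
    values = ct.values
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise NormalizationError("quantile normalization requires >= 2 samples")
    reference = _reference_distribution(values)
    grid = np.linspace(0.0, 1.0, n_genes)

    out = np.full_like(values, np.nan)
    for j in range(n_samples):
        obs_idx = np.flatnonzero(~np.isnan(values[:, j]))
        col = values[obs_idx, j]
        order = np.argsort(col, kind="stable")
        n = col.size
        positions = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        mapped_sorted = np.interp(positions, grid, reference)
        # ties: average the mapped values across each tied run
        sorted_vals = col[order]
        mapped = np.empty(n)
        start = 0
        while start < n:
            stop = start
            while stop + 1 < n and sorted_vals[stop + 1] == sorted_vals[start]:
                stop += 1
            mapped[start : stop + 1] = mapped_sorted[start : stop + 1].mean()
            start = stop + 1
        col_out = np.empty(n)
        col_out[order] = mapped
        out[obs_idx, j] = col_out
    return NormalizedMatrix(list(ct.gene_ids), list(ct.sample_ids), out)


def _nanmean_rows(block: np.ndarray) -> np.ndarray:
    """Row-wise mean of finite entries; NaN for rows with none (no warning)."""
    finite = np.isfinite(block)
    counts = finite.sum(axis=1)
    sums = np.where(finite, block, 0.0).sum(axis=1)
    return np.divide(sums, counts, out=np.full(block.shape[0], np.nan), where=counts > 0)


def _region_zt_columns(
    sample_ids: Sequence[str], annotations: Sequence[SampleAnnotation]
) -> dict[tuple[str, str], np.ndarray]:
    """Column indices per (region, zt), in matrix order."""
    ann_by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in sample_ids if s not in ann_by_id]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    groups: dict[tuple[str, str], list[int]] = {}
    for j, s in enumerate(sample_ids):
        a = ann_by_id[s]
        groups.setdefault((a.region, a.zt), []).append(j)
    return {k: np.array(v, dtype=int) for k, v in groups.items()}


def compute_relative_expression(
    norm: NormalizedMatrix,
    annotations: Sequence[SampleAnnotation],
    *,
    reference_zt: str = REFERENCE_ZT,
) -> RelativeExpression:
    """Compute -ddCT per sample and its per-timepoint means per gene x region.

    The reference level is the mean deltaCT over the *same region's*
    ``reference_zt`` samples (missing excluded). A gene with no non-missing
    reference observation in a region is flagged not-quantifiable there;
    by construction the mean -ddCT at the reference time point is zero for
    every quantifiable gene x region.
    """
    if reference_zt not in ZT_LEVELS:
        raise ValueError(f"reference_zt must be one of {ZT_LEVELS}")
    dct = norm.delta_ct
    cols = _region_zt_columns(norm.sample_ids, annotations)
    regions = sorted({r for r, _ in cols})

    neg_ddct = np.full_like(dct, np.nan)
    not_quantifiable: set[tuple[str, str]] = set()
    mean_rows = []
    for region in regions:
        ref_cols = cols.get((region, reference_zt), np.array([], dtype=int))
        region_cols = np.concatenate(
            [cols[(r, z)] for (r, z) in cols if r == region]
        )
        ref_mean = _nanmean_rows(dct[:, ref_cols]) if ref_cols.size else np.full(dct.shape[0], np.nan)
        ddct = dct[:, region_cols] - ref_mean[:, None]
        neg_ddct[:, region_cols] = -ddct
        for gi, gene in enumerate(norm.gene_ids):
            if not np.isfinite(ref_mean[gi]):
                not_quantifiable.add((gene, region))
        for gi, gene in enumerate(norm.gene_ids):
            row = {"gene_id": gene, "region": region}
            for zt in ZT_LEVELS:
                zt_cols = cols.get((region, zt), np.array([], dtype=int))
                vals = neg_ddct[gi, zt_cols] if zt_cols.size else np.array([np.nan])
                finite = vals[np.isfinite(vals)]
                row[zt] = float(finite.mean()) if finite.size else np.nan
            mean_rows.append(row)

    means = pd.DataFrame(mean_rows).set_index(["gene_id", "region"])
    return RelativeExpression(
        list(norm.gene_ids), list(norm.sample_ids), neg_ddct, means, not_quantifiable
    )
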