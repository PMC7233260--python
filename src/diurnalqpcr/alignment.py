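"""Cross-region alignment score between temporal expression profiles.

For each gene and region, the mean deltaCT at the three time points forms a
3-vector x = (ZT3, ZT5, ZT9). The alignment between the two regions is the
cosine of the angle between their vectors,

    AS* = <x_dvc, x_cea> / (||x_dvc|| ||x_cea||) = cos(theta),

log-transformed to expand the compressed high-similarity range:

    AS = -log10(1 - AS*).

A large AS means similar temporal patterns across regions; a small AS means
divergent patterns. Because the cosine is scale-invariant, multiplicative
region-wide differences do not affect the score (additive CT offsets do;
the score is computed exactly as defined).

Genes are binned by fixed cutoffs: high (AS > 5.5), moderately high
(5.0 < AS <= 5.5), mid (4.1 < AS <= 5.0), moderately low (3.7 < AS <= 4.1),
low (AS <= 3.7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import SampleAnnotation, ZT_LEVELS
from .normalization import NormalizedMatrix, _region_zt_columns

#: 1 - AS* is clamped below at EPS so perfect alignment yields the finite cap.
EPS = 1e-12
AS_CAP = 12.0

CATEGORY_CUTOFFS = {"low": 3.7, "mod_low": 4.1, "mid": 5.0, "mod_high": 5.5}
CATEGORIES = ("low", "mod_low", "mid", "mod_high", "high", "undefined")


@dataclass
class AlignmentRecord:
    gene_id: str
    x_dvc: np.ndarray  # mean deltaCT at (ZT3, ZT5, ZT9)
    x_cea: np.ndarray
    as_star: float  # cos(theta), NaN when undefined
    as_score: float
    category: str
    flags: frozenset[str] = frozenset()


def mean_timepoint_vector(
    norm: NormalizedMatrix,
    annotations: Sequence[SampleAnnotation],
    gene: str,
    region: str,
) -> np.ndarray:
    """Mean deltaCT per time point for one gene in one region (3-vector).

    Any time point with no non-missing observation yields NaN in that slot.
    """
    cols = _region_zt_columns(norm.sample_ids, annotations)
    gi = norm.gene_ids.index(gene)
    vec = np.empty(3)
    for t, zt in enumerate(ZT_LEVELS):
        idx = cols.get((region, zt), np.array([], dtype=int))
        vals = norm.delta_ct[gi, idx]
        vals = vals[np.isfinite(vals)]
        vec[t] = vals.mean() if vals.size else np.nan
    return vec


def alignment_score(x_dvc: np.ndarray, x_cea: np.ndarray) -> tuple[float, float, frozenset[str]]:
    """Cosine alignment AS* and transformed score AS for two 3-vectors.

    Returns ``(as_star, as_score, flags)``. Undefined (NaN components or a
    zero vector) yields NaNs with the ``UNDEFINED`` flag; perfect alignment
    is clamped to the cap with the ``CAPPED`` flag.
    """
    x, y = np.asarray(x_dvc, float), np.asarray(x_cea, float)
    if x.shape != (3,) or y.shape != (3,):
        raise ValueError("expected 3-vectors of per-time-point means")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        return np.nan, np.nan, frozenset({"UNDEFINED"})
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return np.nan, np.nan, frozenset({"UNDEFINED"})
    as_star = float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))
    gap = 1.0 - as_star
    flags: frozenset[str] = frozenset()
    if gap < EPS:
        gap = EPS
        flags = frozenset({"CAPPED"})
    return as_star, float(-math.log10(gap)), flags


def categorize_alignment(as_score: float, flags: frozenset[str] = frozenset()) -> str:
    """Bin an alignment score into its similarity band.

    Boundary values fall into the lower band (bands are half-open on the
    right); capped scores are ``high``.
    """
    if "UNDEFINED" in flags or not math.isfinite(as_score):
        return "undefined"
    if as_score <= CATEGORY_CUTOFFS["low"]:
        return "low"
    if as_score <= CATEGORY_CUTOFFS["mod_low"]:
        return "mod_low"
    if as_score <= CATEGORY_CUTOFFS["mid"]:
        return "mid"
    if as_score <= CATEGORY_CUTOFFS["mod_high"]:
        return "mod_high"
    return "high"


def alignment_table(
    norm: NormalizedMatrix,
    annotations: Sequence[SampleAnnotation],
    *,
    region_a: str = "DVC",
    region_b: str = "CeA",
) -> list[AlignmentRecord]:
    """Compute an :class:`AlignmentRecord` for every gene."""
    cols = _region_zt_columns(norm.sample_ids, annotations)
    records = []
    for gi, gene in enumerate(norm.gene_ids):
        vecs = {}
        for region in (region_a, region_b):
            vec = np.empty(3)
            for t, zt in enumerate(ZT_LEVELS):
                idx = cols.get((region, zt), np.array([], dtype=int))
                vals = norm.delta_ct[gi, idx]
                vals = vals[np.isfinite(vals)]
                vec[t] = vals.mean() if vals.size else np.nan
            vecs[region] = vec
        as_star, score, flags = alignment_score(vecs[region_a], vecs[region_b])
        records.append(
            AlignmentRecord(
                gene, vecs[region_a], vecs[region_b], as_star, score,
                categorize_alignment(score, flags), flags,
            )
        )
    return records


def alignment_frame(records: Sequence[AlignmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id}
        for t, zt in enumerate(ZT_LEVELS):
            row[f"x_dvc_{zt}"] = r.x_dvc[t]
            row[f"x_cea_{zt}"] = r.x_cea[t]
        row.update(
            as_star=r.as_star,
            as_score=r.as_score,
            category=r.category,
            flags="|".join(sorted(r.flags)),
        )
        rows.append(row)
    return pd.DataFrame(rows)
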