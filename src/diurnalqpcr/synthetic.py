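"""Synthetic CT matrices with planted diurnal structure and ground truth.

The generator emulates the study design this pipeline analyzes: two brain
regions (DVC, CeA) sampled at three Zeitgeber times with unbalanced group
sizes (ZT3: 7, ZT5: 18, ZT9: 15 animals), 145 assayed genes, additive
region and time effects on the CT (cycle) scale, i.i.d. Gaussian
animal-level noise, per-sample column shifts (loading differences that
quantile normalization must remove), and missing-completely-at-random
reaction failures.

CT is log2-scale in transcript abundance and *lower* CT means *more*
transcript, so an "up" pattern plants a negative CT shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CtMatrix, SampleAnnotation, REGIONS, ZT_LEVELS

DIRECTIONS = ("up", "down", "flat")

#: The 8 non-flat direction pairs (d_ZT3, d_ZT9); (flat, flat) means no pattern.
PATTERN_CODES = tuple(
    f"{d3}/{d9}" for d3 in DIRECTIONS for d9 in DIRECTIONS if (d3, d9) != ("flat", "flat")
)


class DesignError(ValueError):
    """A simulation design parameter violates its constraint."""


@dataclass
class SimulationDesign:
    """Parameters of the synthetic study; defaults mirror the emulated design.

    All effect sizes and noise scales are in PCR cycles (CT units).
    """

    n_genes: int = 145
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"ZT3": 7, "ZT5": 18, "ZT9": 15}
    )
    regions: tuple[str, ...] = REGIONS
    baseline_ct_range: tuple[float, float] = (14.0, 30.0)
    region_effect_sd: float = 1.0
    time_effect_magnitudes: tuple[float, ...] = (0.25, 0.5, 1.0)
    fraction_diurnal: float = 0.5
    noise_sd: float = 0.5
    failure_rate: float = 0.02
    column_shift_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise DesignError("n_genes must be >= 1")
        if set(self.group_sizes) != set(ZT_LEVELS):
            raise DesignError(f"group_sizes must cover {ZT_LEVELS}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise DesignError("every time-point group needs >= 2 animals")
        if not 0 <= self.failure_rate < 1:
            raise DesignError("failure_rate must lie in [0, 1)")
        if not 0 <= self.fraction_diurnal <= 1:
            raise DesignError("fraction_diurnal must lie in [0, 1]")
        for name in ("region_effect_sd", "noise_sd", "column_shift_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if any(m <= 0 for m in self.time_effect_magnitudes):
            raise DesignError("time effect magnitudes must be positive")
        lo, hi = self.baseline_ct_range
        if not 0 < lo <= hi:
            raise DesignError("baseline_ct_range must satisfy 0 < low <= high")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per gene x region direction pair and CT shifts.

    ``delta`` holds the planted CT shift at (ZT3, ZT9) — note the sign flip:
    an "up" direction is a negative CT shift. ``region_offset`` is the
    per-gene additive CT offset of each region.
    """

    gene_ids: list[str]
    direction: dict[tuple[str, str], tuple[str, str]]  # (gene, region) -> (d3, d9)
    delta: dict[tuple[str, str], tuple[float, float]]  # (gene, region) -> CT shifts
    region_offset: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (g, r), (d3, d9) in self.direction.items():
            dd3, dd9 = self.delta[(g, r)]
            rows.append(
                {
                    "gene_id": g,
                    "region": r,
                    "direction_ZT3": d3,
                    "direction_ZT9": d9,
                    "delta_ct_ZT3": dd3,
                    "delta_ct_ZT9": dd9,
                    "region_offset": self.region_offset[(g, r)],
                }
            )
        return pd.DataFrame(rows)


def _ct_shift(direction: str, magnitude: float) -> float:
    # up-regulation = more transcript = fewer cycles to threshold
    if direction == "up":
        return -magnitude
    if direction == "down":
        return magnitude
    return 0.0


def generate_dataset(
    design: SimulationDesign,
) -> tuple[CtMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Simulate a CT matrix, its sample annotations, and the planted truth.

    The CT value of gene g in sample s (region r, time t) is

        baseline(g) + region_offset(g, r) + delta(g, r, t)
        + noise(g, s) + column_shift(s)

    with delta(g, r, ZT5) = 0, and each entry independently failed
    (set missing) with probability ``failure_rate``. Identical seeds give
    byte-identical output.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = [f"gene{i + 1:04d}" for i in range(design.n_genes)]

    # samples: each animal contributes one sample per region
    annotations: list[SampleAnnotation] = []
    animal_counter = 0
    animals_by_zt: dict[str, list[str]] = {}
    for zt in ZT_LEVELS:
        animals = []
        for _ in range(design.group_sizes[zt]):
            animal_counter += 1
            animals.append(f"animal{animal_counter:03d}")
        animals_by_zt[zt] = animals
    for region in design.regions:
        for zt in ZT_LEVELS:
            for animal in animals_by_zt[zt]:
                annotations.append(
                    SampleAnnotation(f"{animal}_{region}", animal, region, zt)
                )
    sample_ids = [a.sample_id for a in annotations]
    n_samples = len(sample_ids)

    lo, hi = design.baseline_ct_range
    baseline = rng.uniform(lo, hi, size=design.n_genes)

    direction: dict[tuple[str, str], tuple[str, str]] = {}
    delta: dict[tuple[str, str], tuple[float, float]] = {}
    region_offset: dict[tuple[str, str], float] = {}
    nonflat = [p.split("/") for p in PATTERN_CODES]
    for region in design.regions:
        offsets = rng.normal(0.0, design.region_effect_sd, size=design.n_genes)
        is_diurnal = rng.random(design.n_genes) < design.fraction_diurnal
        pair_idx = rng.integers(0, len(nonflat), size=design.n_genes)
        mags = rng.choice(design.time_effect_magnitudes, size=(design.n_genes, 2))
        for gi, gene in enumerate(genes):
            region_offset[(gene, region)] = float(offsets[gi])
            if is_diurnal[gi]:
                d3, d9 = nonflat[pair_idx[gi]]
            else:
                d3, d9 = "flat", "flat"
            direction[(gene, region)] = (d3, d9)
            delta[(gene, region)] = (
                _ct_shift(d3, float(mags[gi, 0])),
                _ct_shift(d9, float(mags[gi, 1])),
            )

    column_shift = rng.normal(0.0, design.column_shift_sd, size=n_samples)
    values = np.empty((design.n_genes, n_samples))
    zt_index = {"ZT3": 0, "ZT5": None, "ZT9": 1}
    for sj, ann in enumerate(annotations):
        shift_idx = zt_index[ann.zt]
        for gi, gene in enumerate(genes):
            d = delta[(gene, ann.region)]
            time_shift = 0.0 if shift_idx is None else d[shift_idx]
            values[gi, sj] = (
                baseline[gi]
                + region_offset[(gene, ann.region)]
                + time_shift
                + column_shift[sj]
            )
    values += rng.normal(0.0, design.noise_sd, size=values.shape)
    failed = rng.random(values.shape) < design.failure_rate
    values[failed] = np.nan
    # clip into the valid CT range without disturbing rank structure much;
    # baselines sit well inside (0, 40] so clipping is a no-op in practice
    values = np.clip(values, 1e-6, 40.0)

    ct = CtMatrix(genes, sample_ids, values)
    truth = SyntheticTruth(genes, direction, delta, region_offset)
    return ct, annotations, truth


def truth_pattern_labels(truth: SyntheticTruth) -> dict[tuple[str, str], str]:
    """Map each (gene, region) to its true pattern code or ``"none"``."""
    return {
        key: ("none" if pair == ("flat", "flat") else f"{pair[0]}/{pair[1]}")
        for key, pair in truth.direction.items()
    }
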