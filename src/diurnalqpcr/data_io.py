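"""Readers and writers for CT matrices, sample annotations, and result tables.

All on-disk formats are plain delimited text (comma or tab, auto-detected).
CT matrices may be *wide* (genes as rows, samples as columns) or *long*
(``gene,sample,ct`` triples). Missing reactions are encoded as empty cells,
``NA``/``NaN``, or a numeric sentinel at or above the cycle cap (Fluidigm
exports commonly use 999 for failed reactions).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REGIONS = ("DVC", "CeA")
ZT_LEVELS = ("ZT3", "ZT5", "ZT9")

#: Default PCR cycle cap; CT values at or above a sentinel >= this are failures.
DEFAULT_MAX_CYCLES = 40.0

#: Numeric precision used when writing result tables (round-trip safe).
TABLE_FLOAT_FORMAT = "%.12g"


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicates, bad enum token...)."""


class ParseError(ValueError):
    """A cell could not be interpreted as a number or missing-value token."""


@dataclass
class CtMatrix:
    """Raw cycle-threshold values, genes x samples, NaN marks failed reactions.

    Invariants: gene and sample ids unique; every finite entry satisfies
    ``0 < CT <= max_cycles``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float, NaN = missing
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValidationError(f"duplicate {name} id: {dup!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() <= 0 or finite.max() > self.max_cycles):
            bad = finite[(finite <= 0) | (finite > self.max_cycles)][0]
            raise ValidationError(
                f"CT value {bad} outside (0, {self.max_cycles}]"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CtMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass(frozen=True)
class SampleAnnotation:
    """Maps a sample to its animal, brain region, and Zeitgeber time.

    One animal contributes at most one sample per region (bilateral punches
    are pooled into a single sample).
    """

    sample_id: str
    animal_id: str
    region: str
    zt: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region token {self.region!r}; expected one of {REGIONS}")
        if self.zt not in ZT_LEVELS:
            raise ValidationError(f"unknown zt token {self.zt!r}; expected one of {ZT_LEVELS}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Free-text functional grouping and cellular localization for a gene."""

    gene_id: str
    functional_group: str = ""
    cellular_localization: str = ""


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override is not None:
        return override
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def _parse_ct_cell(
    raw: str, *, max_cycles: float, sentinel: float | None, row: int, col: int
) -> float:
    token = raw.strip()
    if token == "" or token.upper() in {"NA", "NAN"}:
        return np.nan
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"non-numeric CT cell {raw!r} at row {row}, column {col}"
        ) from None
    if sentinel is not None and value >= sentinel:
        return np.nan
    if not 0 < value <= max_cycles:
        raise ValidationError(
            f"CT value {value} at row {row}, column {col} outside (0, {max_cycles}]"
        )
    return value


def read_ct_table(
    path: str | Path,
    dialect: str = "wide",
    *,
    delimiter: str | None = None,
    max_cycles: float = DEFAULT_MAX_CYCLES,
    sentinel: float | None = DEFAULT_MAX_CYCLES,
) -> CtMatrix:
    """Read a CT matrix from a wide or long delimited file.

    Parameters
    ----------
    dialect
        ``"wide"``: first column gene ids, remaining columns one sample each.
        ``"long"``: header ``gene,sample,ct``, one reaction per row.
    sentinel
        Numeric failure sentinel: any CT >= ``sentinel`` becomes missing
        before range validation. ``None`` disables sentinel handling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("wide", "long"):
        raise ValueError(f"dialect must be 'wide' or 'long', got {dialect!r}")
    sep = _sniff_delimiter(path, delimiter)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise ParseError(f"{path}: empty file")

    if dialect == "wide":
        header = rows[0]
        sample_ids = [c.strip() for c in header[1:]]
        gene_ids: list[str] = []
        data: list[list[float]] = []
        for i, row in enumerate(rows[1:], start=2):
            gene_ids.append(row[0].strip())
            if len(row) != len(sample_ids) + 1:
                raise ParseError(f"row {i} has {len(row)} fields, expected {len(sample_ids) + 1}")
            data.append(
                [
                    _parse_ct_cell(cell, max_cycles=max_cycles, sentinel=sentinel, row=i, col=j)
                    for j, cell in enumerate(row[1:], start=2)
                ]
            )
        return CtMatrix(gene_ids, sample_ids, np.array(data, dtype=float).reshape(len(gene_ids), len(sample_ids)), max_cycles)

    # long: accumulate (gene, sample) -> value, preserving first-seen order
    header = [c.strip().lower() for c in rows[0]]
    required = ["gene", "sample", "ct"]
    if header[:3] != required:
        raise ParseError(f"long dialect requires header {required}, got {rows[0]}")
    gene_order: list[str] = []
    sample_order: list[str] = []
    cells: dict[tuple[str, str], float] = {}
    for i, row in enumerate(rows[1:], start=2):
        g, s = row[0].strip(), row[1].strip()
        if g not in gene_order:
            gene_order.append(g)
        if s not in sample_order:
            sample_order.append(s)
        key = (g, s)
        if key in cells:
            raise ValidationError(f"duplicate record for gene {g!r}, sample {s!r} at row {i}")
        cells[key] = _parse_ct_cell(row[2], max_cycles=max_cycles, sentinel=sentinel, row=i, col=3)
    values = np.full((len(gene_order), len(sample_order)), np.nan)
    for (g, s), v in cells.items():
        values[gene_order.index(g), sample_order.index(s)] = v
    return CtMatrix(gene_order, sample_order, values, max_cycles)


def write_ct_table(ct: CtMatrix, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a CT matrix in the wide dialect; missing entries become ``NA``.

    Uses 17 significant digits so float64 CT values round-trip exactly.
    """
    df = ct.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep=delimiter, na_rep="NA", float_format="%.17g")


def read_annotations(path: str | Path, *, delimiter: str | None = None) -> list[SampleAnnotation]:
    """Read sample annotations; enforces the one-sample-per-animal-per-region rule."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "animal_id", "region", "zt"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValidationError(f"annotation file missing column(s): {sorted(missing_cols)}")
    anns = [
        SampleAnnotation(r.sample_id, r.animal_id, r.region, r.zt)
        for r in df.itertuples(index=False)
    ]
    validate_annotations(anns)
    return anns


def validate_annotations(anns: Sequence[SampleAnnotation]) -> None:
    dup_sample = _first_duplicate([a.sample_id for a in anns])
    if dup_sample is not None:
        raise ValidationError(f"duplicate sample id: {dup_sample!r}")
    seen: set[tuple[str, str]] = set()
    for a in anns:
        key = (a.animal_id, a.region)
        if key in seen:
            raise ValidationError(
                f"animal {a.animal_id!r} has more than one {a.region} sample"
            )
        seen.add(key)


def write_annotations(anns: Iterable[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame([vars(a) for a in anns]).to_csv(path, index=False)


def read_gene_annotations(path: str | Path, *, delimiter: str | None = None) -> list[GeneAnnotation]:
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "gene_id" not in df.columns:
        raise ValidationError("gene annotation file missing column 'gene_id'")
    dup = _first_duplicate(list(df["gene_id"]))
    if dup is not None:
        raise ValidationError(f"duplicate gene id: {dup!r}")
    return [
        GeneAnnotation(
            r["gene_id"],
            r.get("functional_group", ""),
            r.get("cellular_localization", ""),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Per-region gene-statistics result table (supplementary-table style layout:
# one gene per row with time-point means, all p-values, and the pattern call).

GENE_STATS_COLUMNS = [
    "gene_id",
    "region",
    "mean_neg_ddct_ZT3",
    "mean_neg_ddct_ZT5",
    "mean_neg_ddct_ZT9",
    "p_oneway",
    "p_t_ZT3_ZT5",
    "p_t_ZT5_ZT9",
    "p_t_ZT3_ZT9",
    "p_tukey_ZT3_ZT5",
    "p_tukey_ZT5_ZT9",
    "p_tukey_ZT3_ZT9",
    "diurnal",
    "pattern",
    "support",
]


def write_gene_stats_table(
    stats: pd.DataFrame, pattern_calls: pd.DataFrame, path: str | Path
) -> None:
    """Join per-gene statistics with pattern calls and write one row per gene.

    ``stats`` carries the numeric columns of :data:`GENE_STATS_COLUMNS`,
    ``pattern_calls`` the ``diurnal``/``pattern``/``support`` columns; both
    must be indexed by (or contain) ``gene_id`` over the same gene set.
    """
    stats = stats.reset_index() if "gene_id" not in stats.columns else stats.copy()
    calls = (
        pattern_calls.reset_index()
        if "gene_id" not in pattern_calls.columns
        else pattern_calls.copy()
    )
    missing = set(stats["gene_id"]) - set(calls["gene_id"])
    if missing:
        raise ValidationError(
            f"gene(s) present in stats but absent from pattern calls: {sorted(missing)[:5]}"
        )
    merged = stats.merge(calls[["gene_id", "diurnal", "pattern", "support"]], on="gene_id")
    merged = merged[[c for c in GENE_STATS_COLUMNS if c in merged.columns]]
    merged.to_csv(path, index=False, float_format=TABLE_FLOAT_FORMAT)


def read_gene_stats_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
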