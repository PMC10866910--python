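"""TCR repertoire summaries from per-sample clonotype read counts:
sample read filter, relative-proportion size classes, Hill diversity.

Size classes: "rare" (a single supporting read, taking precedence),
then by relative proportion R: infrequent R < 1%, frequent 1% <= R <= 10%,
hyper-frequent R > 10%.  "True diversity" is interpreted as Hill numbers;
the default order is q = 1 (exponential Shannon entropy) — the source
analysis names no order, so q is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RARE = "rare"
INFREQUENT = "infrequent"
FREQUENT = "frequent"
HYPER_FREQUENT = "hyper-frequent"
SIZE_CLASSES = (RARE, INFREQUENT, FREQUENT, HYPER_FREQUENT)

#: Samples need strictly more than this many total reads to be analyzed.
DEFAULT_MIN_READS = 100

#: Column-name mapping for AIRR-style rearrangement tables.
AIRR_COLUMN_MAP = {"sequence_id": "clonotype_id", "duplicate_count": "reads"}


@dataclass
class ClonotypeTable:
    """Clonotype read counts for one sample."""

    sample_id: str
    clonotype_ids: list[str]
    reads: np.ndarray

    def __post_init__(self) -> None:
        self.reads = np.asarray(self.reads, dtype=int)
        if len(self.clonotype_ids) != len(self.reads):
            raise ValueError("clonotype ids and reads must be aligned")
        if len(set(self.clonotype_ids)) != len(self.clonotype_ids):
            raise ValueError(f"{self.sample_id}: duplicate clonotype ids")
        if self.reads.size and self.reads.min() < 1:
            raise ValueError(f"{self.sample_id}: reads must be >= 1")

    @property
    def total_reads(self) -> int:
        return int(self.reads.sum())

    def __len__(self) -> int:
        return len(self.clonotype_ids)


def read_clonotype_table(
    path: str | Path,
    sample_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ClonotypeTable:
    """Read a per-sample clonotype TSV (columns clonotype_id, reads).

    AIRR-style column names can be supplied via ``column_map``
    (e.g. :data:`AIRR_COLUMN_MAP`).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = {"clonotype_id", "reads"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return ClonotypeTable(
        sample_id=sample_id or path.stem,
        clonotype_ids=frame["clonotype_id"].astype(str).tolist(),
        reads=frame["reads"].to_numpy(),
    )


def filter_samples(
    tables: Iterable[ClonotypeTable],
    min_reads: int = DEFAULT_MIN_READS,
) -> list[ClonotypeTable]:
    """Retain samples whose total reads are strictly greater than ``min_reads``."""
    return [t for t in tables if t.total_reads > min_reads]


def proportions(table: ClonotypeTable) -> np.ndarray:
    """Relative proportion R per clonotype (reads / total reads; sums to 1)."""
    total = table.total_reads
    if total <= 0:
        raise ValueError(f"{table.sample_id}: zero total reads")
    return table.reads / total


def classify_clonotype(reads: int, R: float) -> str:
    """Size class of one clonotype from its read count and proportion R."""
    if reads < 1:
        raise ValueError("reads must be >= 1")
    if not 0 < R <= 1:
        raise ValueError("R must lie in (0, 1]")
    if reads == 1:
        return RARE
    if R < 0.01:
        return INFREQUENT
    if R <= 0.10:
        return FREQUENT
    return HYPER_FREQUENT


def diversity(reads: Sequence[int], q: float = 1.0) -> float:
    """Hill diversity of order q: effective number of clonotypes.

    D_q = (sum p_i^q)^(1/(1-q)); the q = 1 limit is exp(Shannon entropy).
    Satisfies 1 <= D_q <= number of clonotypes and is non-increasing in q.
    """
    reads = np.asarray(reads, dtype=float)
    if reads.size == 0:
        raise ValueError("empty read vector")
    if reads.min() <= 0:
        raise ValueError("reads must be positive")
    if q < 0:
        raise ValueError("order q must be >= 0")
    p = reads / reads.sum()
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def class_abundance(table: ClonotypeTable, min_reads: int = DEFAULT_MIN_READS) -> pd.Series:
    """Fraction of total reads held by each size class (sums to 1).

    The sample must pass the read filter; unfiltered samples are rejected.
    """
    if table.total_reads <= min_reads:
        raise ValueError(
            f"{table.sample_id}: {table.total_reads} reads <= filter threshold {min_reads}"
        )
    R = proportions(table)
    out = {cls: 0.0 for cls in SIZE_CLASSES}
    for reads, r in zip(table.reads, R):
        out[classify_clonotype(int(reads), float(r))] += float(r)
    return pd.Series(out)


def repertoire_summary(
    tables: Iterable[ClonotypeTable],
    q: float = 1.0,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Per-sample diversity and size-class abundances for filtered samples."""
    rows = []
    for table in filter_samples(tables, min_reads=min_reads):
        abundances = class_abundance(table, min_reads=min_reads)
        rows.append(
            {
                "sample": table.sample_id,
                "total_reads": table.total_reads,
                "n_clonotypes": len(table),
                "diversity": diversity(table.reads, q=q),
                **{f"frac_{cls}": abundances[cls] for cls in SIZE_CLASSES},
            }
        )
    return pd.DataFrame(rows).set_index("sample") if rows else pd.DataFrame()
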