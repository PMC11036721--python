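"""Core in-memory containers.

Tabular data is held in pandas objects; these thin dataclasses add the
metadata the pipeline needs (chronological sample order, gene lengths, RNA
class, normalization unit) and validate invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")


@dataclass
class CountMatrix:
    """Integer gene x sample counts with chronologically ordered samples.

    Parameters
    ----------
    counts
        DataFrame, genes in rows, samples in columns. Column order is taken
        as the chronological sample order. Values must be non-negative
        integers.
    lengths
        Optional mapping gene id -> exonic length in bp (> 0), required by
        TPM/FPKM.
    rna_class
        One of mRNA / lncRNA / circRNA / miRNA, or None for untyped input.
    """

    counts: pd.DataFrame
    lengths: Optional[Mapping[str, float]] = None
    rna_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")
        if self.rna_class is not None and self.rna_class not in RNA_CLASSES:
            raise ValueError(f"rna_class must be one of {RNA_CLASSES}, got {self.rna_class!r}")
        if self.lengths is not None:
            bad = [g for g, L in self.lengths.items() if not L > 0]
            if bad:
                raise ValueError(f"non-positive gene lengths: {bad[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_intervals(self) -> int:
        """Number of adjacent timepoint intervals (samples - 1)."""
        return max(len(self.counts.columns) - 1, 0)

    def interval_label(self, t: int) -> str:
        """Label of adjacent interval t, e.g. '3w-4w' for columns '3w','4w'."""
        if not 0 <= t < self.n_intervals:
            raise IndexError(f"interval index {t} out of range [0, {self.n_intervals})")
        return f"{self.samples[t]}-{self.samples[t + 1]}"

    def length_vector(self) -> pd.Series:
        """Per-gene lengths aligned to the count index; raises if any missing."""
        if self.lengths is None:
            raise ValueError("gene lengths required but not provided")
        lengths = pd.Series(self.lengths).reindex(self.genes)
        missing = lengths.index[lengths.isna()].tolist()
        if missing:
            raise ValueError(f"missing gene lengths for: {missing[:10]}")
        return lengths.astype(float)


NORM_UNITS = ("CPM", "TPM", "FPKM", "size-factor-normalized")


@dataclass
class NormalizedMatrix:
    """Normalized expression values with the unit recorded."""

    values: pd.DataFrame
    unit: str
    rna_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.unit not in NORM_UNITS:
            raise ValueError(f"unit must be one of {NORM_UNITS}, got {self.unit!r}")
        arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("normalized values must be non-negative")


@dataclass
class LibrarySummary:
    """Raw/clean/mapped read totals for a sequencing library (or a pool)."""

    raw_reads: int
    clean_reads: int
    mapped_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if self.raw_reads < 0:
            raise ValueError("raw_reads must be >= 0")
        if not 0 <= self.clean_reads <= self.raw_reads:
            raise ValueError("need 0 <= clean_reads <= raw_reads")
        if self.mapped_reads is not None and not 0 <= self.mapped_reads <= self.clean_reads:
            raise ValueError("need 0 <= mapped_reads <= clean_reads")


class DERecord(NamedTuple):
    """One gene's differential-expression result for one adjacent interval.

    status is 'U' (log2fc > 1 and p < 0.05), 'D' (log2fc < -1 and p < 0.05),
    or 'M' (maintained) otherwise.
    """

    gene: str
    interval: str
    log2fc: float
    p_value: float
    status: str


DE_COLUMNS = ["gene", "interval", "log2fc", "p_value", "status"]


def de_frame(records: list[DERecord]) -> pd.DataFrame:
    """Pack DERecords into the canonical DE result frame."""
    if not records:
        return pd.DataFrame(columns=DE_COLUMNS)
    return pd.DataFrame(records, columns=DE_COLUMNS)
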