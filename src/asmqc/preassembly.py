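"""Pre-assembly read-quality statistics.

Each read is summarized by its MinimalQ (minimum base Phred score) and its
high-quality base fraction %HighQ(q) = #{bases with score >= q} / #bases,
and categorized:

* HIGH   — every base scored Q20 or above (MinimalQ >= 20);
* POOR   — more than 10% of bases scored Q14 or less;
* MEDIUM — neither.

Reads with low MinimalQ correlate with mis-assembly, which motivates the
read-level (rather than position-averaged) criterion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import PHRED_MAX, ReadRecord

#: Every base at or above this score makes a read high-quality.
HIGHQ_MIN_SCORE = 20
#: Bases at or below this score count toward the poor-quality fraction
#: ("less than Q15" on integer scores).
LOWQ_MAX_SCORE = 14
#: Strictly more than this fraction of low bases makes a read poor-quality.
POOR_FRACTION = 0.10

DEFAULT_Q_GRID = (10, 15, 20, 25, 30, 35, 40)


class QualityCategory(str, Enum):
    HIGH = "HIGH"
    MEDIUM = "MEDIUM"
    POOR = "POOR"


def percent_high_q(read: ReadRecord, q: int) -> float:
    """Fraction of the read's bases with Phred score >= q.

    %HighQ(0) is 1 for any read; %HighQ(q) == 1 iff MinimalQ >= q.
    """
    if len(read) == 0:
        raise ValueError("percent_high_q undefined for an empty read")
    return int(np.count_nonzero(read.qual_array >= q)) / len(read)


def minimal_q(read: ReadRecord) -> int:
    """Minimum Phred score over the read's bases (MinimalQ)."""
    if len(read) == 0:
        raise ValueError("minimal_q undefined for an empty read")
    return int(read.qual_array.min())


def categorize_read(read: ReadRecord) -> QualityCategory:
    if len(read) == 0:
        raise ValueError("cannot categorize an empty read")
    quals = read.qual_array
    if quals.min() >= HIGHQ_MIN_SCORE:
        return QualityCategory.HIGH
    low = int(np.count_nonzero(quals <= LOWQ_MAX_SCORE))
    if low / len(read) > POOR_FRACTION:
        return QualityCategory.POOR
    return QualityCategory.MEDIUM


@dataclass(frozen=True)
class ReadQualityStats:
    """Per-read quality digest."""

    read_id: str
    length: int
    minimal_q: int
    gc_fraction: float  # over non-N bases; 0.0 if the read is all N
    n_count: int
    category: QualityCategory


def read_quality_stats(read: ReadRecord) -> ReadQualityStats:
    bases = read.bases
    n_count = bases.count("N")
    acgt = len(bases) - n_count
    gc = bases.count("G") + bases.count("C")
    return ReadQualityStats(
        read_id=read.read_id,
        length=len(read),
        minimal_q=minimal_q(read),
        gc_fraction=gc / acgt if acgt else 0.0,
        n_count=n_count,
        category=categorize_read(read),
    )


@dataclass
class PreAssemblySummary:
    """Aggregate pre-assembly statistics over a read set."""

    n_reads: int
    n_bases: int
    min_length: int
    max_length: int
    mean_length: float
    base_composition: dict[str, int]          # counts of A, C, G, T, N
    gc_distribution: list[int]                # per-read GC%, 5%-wide bins [0,100]
    base_quality_distribution: list[int]      # counts per Phred score 0..93
    minimalq_distribution: list[int]          # per-read MinimalQ, scores 0..93
    highq_cdf: dict[int, list[float]]         # q -> P(%HighQ(q)*100 >= p), p = 0,5,...,100
    category_fractions: dict[str, float]
    pct_bases_ge_q30: float

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_bases": self.n_bases,
            "min_length": self.min_length,
            "max_length": self.max_length,
            "mean_length": round(self.mean_length, 1),
            "base_composition": self.base_composition,
            "gc_distribution": self.gc_distribution,
            "base_quality_distribution": self.base_quality_distribution,
            "minimalq_distribution": self.minimalq_distribution,
            "highq_cdf": {str(q): v for q, v in self.highq_cdf.items()},
            "category_fractions": self.category_fractions,
            "pct_bases_ge_q30": self.pct_bases_ge_q30,
        }


def summarize_preassembly(
    reads: Sequence[ReadRecord],
    q_grid: Sequence[int] = DEFAULT_Q_GRID,
) -> PreAssemblySummary:
    """Aggregate composition, base-quality and categorization statistics.

    ``highq_cdf[q][k]`` is the fraction of reads whose %HighQ(q), expressed
    as a percentage, is at least ``5*k`` — the complementary cumulative
    distribution of high-quality portions sampled every 5 points.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("summarize_preassembly requires at least one read")

    lengths = np.array([len(r) for r in reads])
    composition: Counter[str] = Counter()
    qual_hist = np.zeros(PHRED_MAX + 1, dtype=np.int64)
    minq_hist = np.zeros(PHRED_MAX + 1, dtype=np.int64)
    gc_hist = np.zeros(21, dtype=np.int64)
    cat_counts = Counter({c: 0 for c in QualityCategory})
    p_grid = np.arange(0, 101, 5)
    highq_ge = {q: np.zeros(len(p_grid), dtype=np.int64) for q in q_grid}

    for read in reads:
        composition.update(read.bases)
        quals = read.qual_array
        np.add.at(qual_hist, quals, 1)
        minq_hist[quals.min()] += 1
        stats = read_quality_stats(read)
        cat_counts[stats.category] += 1
        gc_hist[min(int(stats.gc_fraction * 100) // 5, 20)] += 1
        for q in q_grid:
            pct = 100.0 * int(np.count_nonzero(quals >= q)) / len(read)
            highq_ge[q] += pct >= p_grid

    n_reads = len(reads)
    n_bases = int(lengths.sum())
    base_composition = {b: int(composition.get(b, 0)) for b in "ACGTN"}
    other = n_bases - sum(base_composition.values())
    if other:
        base_composition["N"] += other  # non-IUPAC treated as ambiguous

    return PreAssemblySummary(
        n_reads=n_reads,
        n_bases=n_bases,
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        mean_length=float(lengths.mean()),
        base_composition=base_composition,
        gc_distribution=gc_hist.tolist(),
        base_quality_distribution=qual_hist.tolist(),
        minimalq_distribution=minq_hist.tolist(),
        highq_cdf={int(q): (highq_ge[q] / n_reads).tolist() for q in q_grid},
        category_fractions={c.value: cat_counts[c] / n_reads for c in QualityCategory},
        pct_bases_ge_q30=100.0 * float(qual_hist[30:].sum()) / n_bases,
    )
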