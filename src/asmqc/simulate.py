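"""Synthetic fixtures: reads, genomes and SAM alignments with known truth.

Every generator plants structure by construction — a read assigned the
POOR category really has >10% of its bases at Q14 or below; a read assigned
label C really carries a soft-clip of the planted clip ratio, with MD/NM/AS
tags consistent with the planted errors — so the analysis modules can be
tested against exact ground truth with no external aligner or download.

Category and label mixes are assigned by deterministic counts (largest
remainder), not Bernoulli draws, so recovered fractions are exact; a
stochastic mode exists for property tests. No attempt is made to model
platform error spectra or quality-by-cycle decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preassembly import HIGHQ_MIN_SCORE, LOWQ_MAX_SCORE, POOR_FRACTION, QualityCategory
from .seqio import ReadRecord, ScaffoldRecord

#: Uniform ranges for the governing error-density ratio planted per label.
DEFAULT_RATIO_RANGES: dict[str, tuple[float, float]] = {
    "S": (0.01, 0.15),   # mismatch ratio
    "C": (0.05, 0.60),   # clip ratio
    "N": (0.01, 0.30),   # N ratio
    "O": (0.01, 0.10),   # indel density
}

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Parameters of a synthetic read/alignment fixture."""

    n_reads: int = 1000
    read_length: int = 100
    category_mix: dict[str, float] = field(
        default_factory=lambda: {"HIGH": 0.5, "MEDIUM": 0.3, "POOR": 0.2})
    label_mix: dict[str, float] = field(
        default_factory=lambda: {"P": 0.5, "S": 0.2, "C": 0.1, "O": 0.05,
                                 "M": 0.05, "F": 0.05, "N": 0.05})
    ratio_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATIO_RANGES))
    seed: int = 0
    assignment: str = "exact"  # "exact" (count-based) or "bernoulli"

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")
        for name, mix in (("category_mix", self.category_mix),
                          ("label_mix", self.label_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.assignment not in ("exact", "bernoulli"):
            raise ValueError("assignment must be 'exact' or 'bernoulli'")


def exact_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items to the mix's fractions."""
    keys = list(mix)
    raw = np.array([mix[k] * n for k in keys])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(keys, (int(c) for c in counts)))


def _assign(mix: Mapping[str, float], n: int, rng: np.random.Generator,
            mode: str) -> list[str]:
    if mode == "exact":
        assigned = [k for k, c in exact_counts(mix, n).items() for _ in range(c)]
    else:
        keys = list(mix)
        assigned = list(rng.choice(keys, size=n, p=[mix[k] for k in keys]))
    rng.shuffle(assigned)
    return assigned


def random_genome(length: int, gc: float = 0.5, seed: int = 0,
                  scaffold_id: str = "ref1") -> ScaffoldRecord:
    """Seeded random scaffold of the given length and GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return ScaffoldRecord(scaffold_id, seq)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------- quality

def make_quality_reads(spec: FixtureSpec) -> tuple[list[ReadRecord], dict[str, str]]:
    """Reads whose quality strings satisfy their assigned category.

    HIGH: every score >= 20. POOR: floor(0.10*L)+1 bases at <= 14.
    MEDIUM: exactly one base in [15, 19], the rest >= 20. Returns the reads
    and the ground-truth category per read id.
    """
    L = spec.read_length
    n_low_poor = int(POOR_FRACTION * L) + 1
    if n_low_poor > L:
        raise ValueError(f"read_length {L} too short to plant a poor-quality read")
    rng = np.random.default_rng(spec.seed)
    categories = _assign(spec.category_mix, spec.n_reads, rng, spec.assignment)

    reads: list[ReadRecord] = []
    truth: dict[str, str] = {}
    for i, cat in enumerate(categories):
        quals = rng.integers(HIGHQ_MIN_SCORE, 41, size=L)
        if cat == QualityCategory.POOR.value:
            pos = rng.choice(L, size=n_low_poor, replace=False)
            quals[pos] = rng.integers(2, LOWQ_MAX_SCORE + 1, size=n_low_poor)
        elif cat == QualityCategory.MEDIUM.value:
            quals[rng.integers(L)] = rng.integers(LOWQ_MAX_SCORE + 1, HIGHQ_MIN_SCORE)
        read_id = f"read{i:06d}"
        reads.append(ReadRecord(read_id, _random_seq(rng, L), tuple(int(q) for q in quals)))
        truth[read_id] = cat
    return reads, truth


# ---------------------------------------------------------------- alignment

def _planted_count(rng: np.random.Generator, lo: float, hi: float, L: int,
                   max_count: int) -> int:
    ratio = rng.uniform(lo, hi)
    return min(max(1, round(ratio * L)), max_count)


def _md_for_substitutions(L: int, positions: Sequence[int], ref_bases: Sequence[str]) -> str:
    md = []
    prev = 0
    for pos, base in zip(positions, ref_bases):
        md.append(str(pos - prev))
        md.append(base)
        prev = pos + 1
    md.append(str(L - prev))
    return "".join(md)


def _substitute(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[rng.integers(3)]


def make_labeled_sam(
    spec: FixtureSpec,
    reference: ScaffoldRecord,
    sam_path: str | Path,
    mapq: int = 60,
) -> tuple[dict[str, str], list[ReadRecord]]:
    """Write a SAM file whose records force known classifier labels.

    Each read is drawn from the reference and its FLAG/CIGAR/MD/NM/AS/XA
    fields are constructed so that classification from the SAM evidence
    must reproduce the assigned label. Alignment scores follow
    match-minus-penalty arithmetic (AS = L for perfect matches, -5 per
    substitution, -2 per clipped base, -6-d for a length-d insertion) so P
    scores stochastically dominate S, which dominate C. Multi-mapped reads
    alternate between XA-tag evidence and an explicit secondary record.

    Returns (ground-truth label per read id, the reads as ReadRecords).
    The reads carry flat Q40 qualities: quality categories are the quality
    generator's concern, not this one's.
    """
    L = spec.read_length
    ref = reference.sequence
    if len(ref) < L + 2:
        raise ValueError("reference too short to place reads")
    rng = np.random.default_rng(spec.seed)
    labels = _assign(spec.label_mix, spec.n_reads, rng, spec.assignment)

    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{reference.scaffold_id}\tLN:{len(ref)}",
        "@PG\tID:synthetic\tPN:synthetic",
    ]
    truth: dict[str, str] = {}
    reads: list[ReadRecord] = []
    qual_str = "I" * L

    def emit(read_id: str, flag: int, pos: int, cigar: str, seq: str,
             tags: Sequence[str] = ()) -> None:
        rname = "*" if flag & 0x4 else reference.scaffold_id
        p = 0 if flag & 0x4 else pos + 1
        mq = 0 if flag & 0x4 else mapq
        fields = [read_id, str(flag), rname, str(p), str(mq),
                  "*" if flag & 0x4 else cigar, "*", "0", "0", seq,
                  "*" if seq == "*" else qual_str]
        fields.extend(tags)
        lines.append("\t".join(fields))

    for i, lab in enumerate(labels):
        read_id = f"read{i:06d}"
        truth[read_id] = lab
        pos = int(rng.integers(0, len(ref) - L + 1))
        seq = ref[pos:pos + L]

        if lab == "P":
            emit(read_id, 0, pos, f"{L}M", seq,
                 ["NM:i:0", f"MD:Z:{L}", f"AS:i:{L}"])
        elif lab == "S":
            lo, hi = spec.ratio_ranges["S"]
            nsub = _planted_count(rng, lo, hi, L, L)
            sub_pos = sorted(int(p) for p in rng.choice(L, size=nsub, replace=False))
            ref_bases = [seq[p] for p in sub_pos]
            s = list(seq)
            for p in sub_pos:
                s[p] = _substitute(rng, seq[p])
            emit(read_id, 0, pos, f"{L}M", "".join(s),
                 [f"NM:i:{nsub}", f"MD:Z:{_md_for_substitutions(L, sub_pos, ref_bases)}",
                  f"AS:i:{max(L - 5 * nsub, 0)}"])
        elif lab == "C":
            lo, hi = spec.ratio_ranges["C"]
            c = _planted_count(rng, lo, hi, L, L - 1)
            aligned = L - c
            s = ref[pos:pos + aligned] + _random_seq(rng, c)
            emit(read_id, 0, pos, f"{aligned}M{c}S", s,
                 [f"NM:i:0", f"MD:Z:{aligned}", f"AS:i:{max(L - 2 * c, 0)}"])
        elif lab == "O":
            lo, hi = spec.ratio_ranges["O"]
            d = _planted_count(rng, lo, hi, L, L - 2)
            a = (L - d) // 2
            b = L - d - a
            s = ref[pos:pos + a] + _random_seq(rng, d) + ref[pos + a:pos + a + b]
            emit(read_id, 0, pos, f"{a}M{d}I{b}M", s,
                 [f"NM:i:{d}", f"MD:Z:{a + b}", f"AS:i:{max(L - 6 - d, 0)}"])
        elif lab == "M":
            alt_pos = int(rng.integers(0, len(ref) - L + 1))
            if i % 2 == 0:
                emit(read_id, 0, pos, f"{L}M", seq,
                     ["NM:i:0", f"MD:Z:{L}", f"AS:i:{L}",
                      f"XA:Z:{reference.scaffold_id},+{alt_pos + 1},{L}M,0;"])
            else:
                emit(read_id, 0, pos, f"{L}M", seq,
                     ["NM:i:0", f"MD:Z:{L}", f"AS:i:{L}"])
                emit(read_id, 0x100, alt_pos, f"{L}M", "*",
                     ["NM:i:0", f"AS:i:{L}"])
        elif lab == "F":
            emit(read_id, 0x4, 0, "*", _random_seq(rng, L))
        elif lab == "N":
            lo, hi = spec.ratio_ranges["N"]
            k = _planted_count(rng, lo, hi, L, L)
            n_pos = sorted(int(p) for p in rng.choice(L, size=k, replace=False))
            ref_bases = [seq[p] for p in n_pos]
            s = list(seq)
            for p in n_pos:
                s[p] = "N"
            emit(read_id, 0, pos, f"{L}M", "".join(s),
                 [f"NM:i:{k}", f"MD:Z:{_md_for_substitutions(L, n_pos, ref_bases)}",
                  f"AS:i:{max(L - 5 * k, 0)}"])
        else:
            raise ValueError(f"unknown label {lab!r} in label_mix")

        # reconstruct the read's bases from the primary record just emitted
        primary = lines[-2] if lab == "M" and i % 2 == 1 else lines[-1]
        bases = primary.split("\t")[9]
        reads.append(ReadRecord(read_id, bases, (40,) * L))

    Path(sam_path).write_text("\n".join(lines) + "\n")
    return truth, reads


def write_truth(truth: Mapping[str, str], path: str | Path) -> None:
    """Ground-truth read_id -> label as a two-column TSV."""
    with open(path, "w") as fh:
        for read_id, label in truth.items():
            fh.write(f"{read_id}\t{label}\n")
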