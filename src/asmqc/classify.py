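"""Post-assembly read-mapping classification and the PM% statistic.

Each sampled read, after alignment of the sample back to its own assembly,
is assigned exactly one of seven labels from the SAM evidence:

======  =======================================================
label   meaning
======  =======================================================
N       read contains an ambiguous base (N), decided pre-mapping
F       failed to map
M       multi-mapped (more than one reported location)
P       uniquely mapped, perfect match (no errors)
S       uniquely mapped, at least one substitution
C       uniquely mapped, contains clips (soft or hard)
O       uniquely mapped, other errors (indels only)
======  =======================================================

P and M reads count as highly mapped, F as poorly mapped; S, C, N (and
optionally O) reads are split by an error-density ratio against a threshold
(default 0.3) — e.g. clip ratio = total clipped length / read length. The
poorly-mapped percentage PM% is the sum of the poorly-mapped contributions;
when two alignment strategies are run (local and end-to-end) the two PM%
values are averaged. An assembly passes the assessment if PM% < 20 (strict).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .seqio import ReadRecord

logger = logging.getLogger(__name__)

LABELS = ("P", "S", "C", "O", "M", "F", "N")

#: Label priority: N screens out reads before mapping outcome is considered,
#: then F, M; among unique mapped reads substitutions take precedence over
#: clips, clips over indels. Configurable via ``label_read(order=...)``.
DEFAULT_ERROR_ORDER = ("S", "C", "O")


@dataclass(frozen=True)
class Thresholds:
    """Error-density cutoffs partitioning S/C/N/O reads, and the pass bar.

    A read of the given label is poorly mapped when its ratio exceeds the
    threshold (strict). ``other_threshold=None`` means O reads are never
    poorly mapped. ``pm_pass_threshold`` is a percentage: the assessment
    passes iff final PM% is strictly below it.
    """

    clip_threshold: float = 0.3
    mismatch_threshold: float = 0.3
    n_threshold: float = 0.3
    other_threshold: float | None = 0.3
    pm_pass_threshold: float = 20.0

    def __post_init__(self) -> None:
        for name in ("clip_threshold", "mismatch_threshold", "n_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.other_threshold is not None and not 0 < self.other_threshold <= 1:
            raise ValueError(f"other_threshold must be in (0, 1] or None")
        if not 0 < self.pm_pass_threshold <= 100:
            raise ValueError("pm_pass_threshold must be in (0, 100]")


@dataclass
class AlignmentObservation:
    """Digested SAM evidence for one read."""

    read_id: str
    read_length: int
    has_n: bool
    mapped: bool
    multiplicity: int = 0
    substitutions: int = 0
    insertion_bases: int = 0
    deletion_bases: int = 0
    clip_bases: int = 0
    alignment_score: int | None = None
    n_count: int = 0

    @property
    def mismatch_ratio(self) -> float:
        return self.substitutions / self.read_length

    @property
    def clip_ratio(self) -> float:
        return self.clip_bases / self.read_length

    @property
    def n_ratio(self) -> float:
        return self.n_count / self.read_length

    @property
    def indel_ratio(self) -> float:
        return (self.insertion_bases + self.deletion_bases) / self.read_length

    @property
    def indel_bases(self) -> int:
        return self.insertion_bases + self.deletion_bases


_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def count_md_substitutions(md: str) -> int:
    """Number of substituted bases encoded in an MD tag.

    Single reference letters are substitutions; letters after ``^`` are
    deleted reference bases and do not count.
    """
    subs = 0
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise ValueError(f"unparsable MD tag: {md!r}")
        if m.group(3):
            subs += 1
        pos = m.end()
    if pos != len(md):
        raise ValueError(f"unparsable MD tag: {md!r}")
    return subs


def _xa_hits(xa: str) -> int:
    return sum(1 for part in xa.split(";") if part)


def digest_sam(
    sam_path: str | Path,
    reads: Mapping[str, ReadRecord] | None = None,
) -> dict[str, AlignmentObservation]:
    """Digest a SAM file into one :class:`AlignmentObservation` per read.

    Multiplicity counts the primary record plus secondary (0x100) and
    supplementary (0x800) records plus XA-tag alternative hits. Substitution
    counts come from the MD tag when present, else NM minus indel bases.
    Clip bases sum soft (S) and hard (H) CIGAR operations on both ends;
    hard-clipped bases are added back to the read length.

    When ``reads`` (the sampled read set) is given, SAM records for reads
    outside it are skipped with a warning and N content is taken from the
    read sequences; otherwise N content comes from the SAM SEQ field.
    """
    obs: dict[str, AlignmentObservation] = {}
    extra_counts: dict[str, int] = {}

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            qname = rec.query_name
            if reads is not None and qname not in reads:
                logger.warning("SAM read %s not in sample; skipped", qname)
                continue
            if rec.is_secondary or rec.is_supplementary:
                extra_counts[qname] = extra_counts.get(qname, 0) + 1
                continue
            obs[qname] = _digest_primary(rec, reads[qname] if reads is not None else None)

    for qname, extra in extra_counts.items():
        if qname in obs and obs[qname].mapped:
            obs[qname].multiplicity += extra
    return obs


def _digest_primary(rec: pysam.AlignedSegment,
                    read: ReadRecord | None) -> AlignmentObservation:
    if read is not None:
        seq = read.bases
        length = len(read)
    else:
        seq = rec.query_sequence or ""
        length = len(seq)
    n_count = seq.count("N")

    if rec.is_unmapped:
        return AlignmentObservation(
            read_id=rec.query_name, read_length=max(length, 1),
            has_n=n_count > 0, mapped=False, n_count=n_count,
        )

    ins = dels = soft = hard = 0
    for op, ln in rec.cigartuples or ():
        if op == pysam.CINS:
            ins += ln
        elif op == pysam.CDEL:
            dels += ln
        elif op == pysam.CSOFT_CLIP:
            soft += ln
        elif op == pysam.CHARD_CLIP:
            hard += ln
    if read is None:
        length = len(seq) + hard  # hard-clipped bases are part of the read

    if rec.has_tag("MD"):
        subs = count_md_substitutions(str(rec.get_tag("MD")))
    elif rec.has_tag("NM"):
        subs = max(int(rec.get_tag("NM")) - ins - dels, 0)
    else:
        logger.warning("read %s: mapped record lacks MD and NM; "
                       "assuming 0 substitutions", rec.query_name)
        subs = 0

    multiplicity = 1
    if rec.has_tag("XA"):
        multiplicity += _xa_hits(str(rec.get_tag("XA")))

    return AlignmentObservation(
        read_id=rec.query_name,
        read_length=max(length, 1),
        has_n=n_count > 0,
        mapped=True,
        multiplicity=multiplicity,
        substitutions=subs,
        insertion_bases=ins,
        deletion_bases=dels,
        clip_bases=soft + hard,
        alignment_score=int(rec.get_tag("AS")) if rec.has_tag("AS") else None,
        n_count=n_count,
    )


def label_read(obs: AlignmentObservation,
               order: Sequence[str] = DEFAULT_ERROR_ORDER) -> str:
    """Assign one of the seven labels to a digested read.

    Decision sequence: N (read contains an N, regardless of mapping) ->
    F (unmapped) -> M (multiplicity > 1) -> P (unique, error-free) -> then
    the first matching error label in ``order`` (default S before C before
    O; the alternative clips-before-substitutions reading is supported by
    passing ``order=("C", "S", "O")``).
    """
    if obs.has_n:
        return "N"
    if not obs.mapped:
        return "F"
    if obs.multiplicity > 1:
        return "M"
    if obs.substitutions == 0 and obs.clip_bases == 0 and obs.indel_bases == 0:
        return "P"
    present = {
        "S": obs.substitutions > 0,
        "C": obs.clip_bases > 0,
        "O": True,  # fallthrough: indels only
    }
    for label in order:
        if present.get(label, False):
            return label
    return "O"


@dataclass
class LabelProfile:
    """Per-aligner label fractions with per-label ratio and score lists."""

    aligner_name: str
    n_reads: int
    counts: dict[str, int]
    fractions: dict[str, float]
    ratios: dict[str, list[float]]          # the label's governing error ratio
    alignment_scores: dict[str, list[int]]

    def to_dict(self) -> dict:
        return {
            "aligner_name": self.aligner_name,
            "n_reads": self.n_reads,
            "counts": self.counts,
            "fractions": self.fractions,
        }


_RATIO_OF = {
    "S": lambda o: o.mismatch_ratio,
    "C": lambda o: o.clip_ratio,
    "N": lambda o: o.n_ratio,
    "O": lambda o: o.indel_ratio,
}


def profile_labels(
    labels: Mapping[str, str],
    observations: Mapping[str, AlignmentObservation],
    aligner_name: str = "aligner",
) -> LabelProfile:
    """Tabulate label fractions and attach per-label ratios and AS scores."""
    if not labels:
        raise ValueError("profile_labels requires at least one labeled read")
    counts = {lab: 0 for lab in LABELS}
    ratios: dict[str, list[float]] = {lab: [] for lab in LABELS}
    scores: dict[str, list[int]] = {lab: [] for lab in LABELS}
    for read_id, lab in labels.items():
        counts[lab] += 1
        obs = observations[read_id]
        if lab in _RATIO_OF:
            ratios[lab].append(_RATIO_OF[lab](obs))
        if obs.alignment_score is not None:
            scores[lab].append(obs.alignment_score)
    total = len(labels)
    return LabelProfile(
        aligner_name=aligner_name,
        n_reads=total,
        counts=counts,
        fractions={lab: counts[lab] / total for lab in LABELS},
        ratios=ratios,
        alignment_scores=scores,
    )


@dataclass
class PMBreakdown:
    """Highly/poorly-mapped decomposition of a label profile.

    ``poorly_mapped_pct[label]`` is the percentage of all reads of that
    label that are poorly mapped (the negative bars of the label chart);
    ``pm_pct`` is their sum.
    """

    aligner_name: str
    highly_mapped_pct: dict[str, float]
    poorly_mapped_pct: dict[str, float]
    pm_pct: float

    def to_dict(self) -> dict:
        return {
            "aligner_name": self.aligner_name,
            "highly_mapped_pct": self.highly_mapped_pct,
            "poorly_mapped_pct": self.poorly_mapped_pct,
            "pm_pct": self.pm_pct,
        }


def compute_pm(
    profile: LabelProfile,
    observations: Mapping[str, AlignmentObservation],
    thresholds: Thresholds = Thresholds(),
    labels: Mapping[str, str] | None = None,
) -> PMBreakdown:
    """Split each label's share into highly/poorly-mapped and sum PM%.

    All P and M reads are highly mapped; all F reads are poorly mapped.
    An S, C, N or O read is poorly mapped when its governing ratio
    (mismatch, clip, N or indel density) strictly exceeds its threshold.
    """
    total = profile.n_reads
    thr = {
        "S": thresholds.mismatch_threshold,
        "C": thresholds.clip_threshold,
        "N": thresholds.n_threshold,
        "O": thresholds.other_threshold,
    }
    highly: dict[str, float] = {}
    poorly: dict[str, float] = {}
    for lab in LABELS:
        frac_pct = 100.0 * profile.fractions[lab]
        if lab in ("P", "M"):
            highly[lab], poorly[lab] = frac_pct, 0.0
        elif lab == "F":
            highly[lab], poorly[lab] = 0.0, frac_pct
        else:
            t = thr[lab]
            if t is None:
                n_poor = 0
            else:
                n_poor = sum(1 for r in profile.ratios[lab] if r > t)
            poorly[lab] = 100.0 * n_poor / total
            highly[lab] = frac_pct - poorly[lab]
    return PMBreakdown(
        aligner_name=profile.aligner_name,
        highly_mapped_pct=highly,
        poorly_mapped_pct=poorly,
        pm_pct=sum(poorly.values()),
    )


def average_pm(*breakdowns: PMBreakdown | float) -> float:
    """Final PM%: arithmetic mean of the per-aligner PM% values."""
    if not breakdowns:
        raise ValueError("average_pm requires at least one PM% value")
    values = [b.pm_pct if isinstance(b, PMBreakdown) else float(b) for b in breakdowns]
    return sum(values) / len(values)


def pass_assessment(final_pm: float, thresholds: Thresholds = Thresholds()) -> bool:
    """True iff the final PM% is strictly below the pass threshold."""
    if not 0 <= final_pm <= 100:
        raise ValueError(f"PM% must be in [0, 100], got {final_pm}")
    return final_pm < thresholds.pm_pass_threshold


def display_pm(final_pm: float) -> str:
    """PM% rendered to one decimal.

    Values are carried at full precision internally; display rounds ties
    downward after clearing binary-float noise, so a mean of 12.55 shows
    as 12.5.
    """
    from decimal import ROUND_HALF_DOWN, Decimal
    cleaned = Decimal(repr(round(final_pm, 6)))
    return str(cleaned.quantize(Decimal("0.1"), rounding=ROUND_HALF_DOWN))


def alignment_score_stats(profile: LabelProfile,
                          labels: Sequence[str] = ("P", "S", "C")) -> dict[str, dict]:
    """Median/quartiles/histogram of alignment scores per label.

    A label with no scored reads yields an empty summary, not an error.
    """
    out: dict[str, dict] = {}
    for lab in labels:
        scores = profile.alignment_scores.get(lab, [])
        if not scores:
            out[lab] = {}
            continue
        arr = np.asarray(scores)
        q1, med, q3 = (float(v) for v in np.percentile(arr, [25, 50, 75]))
        hist, edges = np.histogram(arr, bins=min(20, max(1, len(set(scores)))))
        out[lab] = {
            "n": len(scores),
            "median": med,
            "q1": q1,
            "q3": q3,
            "min": int(arr.min()),
            "max": int(arr.max()),
            "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
        }
    return out
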