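# Methods

## Scope and model

`asmqc` assesses a sequencing dataset and its de novo assembly from two
sides. The pre-assembly side treats each read's base-quality vector as the
object of interest and summarizes it by MinimalQ (the minimum Phred score)
and %HighQ(q), the fraction of bases at or above q. The rationale for a
minimum-based rather than mean-based read statistic is that a single very
low-quality base can seed a mis-assembly even in an otherwise good read.
The post-assembly side treats the assembly as a putative reference and asks
how well the reads it was built from map back onto it: reads that cannot be
placed, or place only with dense errors, are evidence against the assembly.

## Read categorization (pre-assembly)

* HIGH iff MinimalQ >= 20 (equivalently %HighQ(20) = 100%).
* POOR iff the fraction of bases with score <= 14 strictly exceeds 0.10.
  "Score <= 14" and "score < 15" are the same criterion on integer Phred
  scores; the strict ">10%" boundary means a 100-base read with exactly 10
  low bases is MEDIUM.
* MEDIUM otherwise. The three groups partition any read set.

N bases keep their (typically low) quality scores in all quality
statistics; per-read GC fraction is computed over non-N bases only, which
matches common QC practice. The cumulative %HighQ distribution is reported
on a fixed grid q in {10,15,20,25,30,35,40} (configurable) rather than all
94 scores, sampled at 5-percentage-point steps, to keep reports small.

## Sampling

Reads are sampled uniformly without replacement by single-pass reservoir
sampling (Algorithm R) with an explicit seed, so a FASTQ of any size
streams in one pass and the same (input, n, seed) reproduces the same
sample byte-for-byte. Default sample size is 1,000,000 reads; sampling can
be bypassed. Sample order is the reservoir's order; no order guarantee is
made. The sampled reads are written to `sampled.fastq` so external aligners
and the pre-assembly analysis consume the identical sample. The Phred
offset is fixed at 33 (configurable, never auto-detected — auto-detection
is error-prone and modern Illumina data is uniformly Phred+33). Paired
files are treated as independent single-end inputs.

## Label assignment (post-assembly)

SAM digestion produces one observation per read: mapped flag, multiplicity
(primary record + secondary 0x100 and supplementary 0x800 records + XA-tag
alternative hits; MAPQ is deliberately not used, since reported extra
locations are the explicit SAM evidence of repeats), substitution count
(MD tag preferred because NM conflates indels with substitutions; fallback
NM − indel bases; if both are absent, zero with a logged warning), clip
bases (soft + hard, both ends; hard-clipped bases are added back to the
read length so ratios are over the full read), indel bases, and the AS
alignment score.

Labels are assigned in priority order N → F → M → P → S → C → O. N is
decided on the raw read sequence before the mapping outcome, so a mapped
read containing an N is still N. A uniquely mapped read with both
substitutions and clips is S under the default order; the alternative
clips-first reading is available via `label_read(order=("C","S","O"))`.
A read that is multi-mapped and error-containing is M.

## PM%

Per aligner, each label's share of reads splits into highly and poorly
mapped. P and M are wholly highly mapped, F wholly poorly mapped. An
S/C/N/O read is poorly mapped iff its governing error-density ratio
(mismatch, clip, N, indel density — each count divided by read length)
strictly exceeds its threshold. All four thresholds default to 0.3; only
the clip threshold has an established default in the field, so the other
three adopt the same value for uniformity and are CLI-configurable. The
contribution of O reads is genuinely open; the default applies the same
threshold mechanism to indel density, and `other_threshold=None` gives the
stricter reading in which only F/S/C/N can be poorly mapped. PM% is the
sum of the poorly-mapped shares, so PM% >= F% always, PM% <=
100 − P% − M%, and raising any threshold can never raise PM%.

With two aligners (a local and an end-to-end strategy; the tool is
aligner-agnostic and only consumes SAM) the final PM% is the arithmetic
mean of the two values; with one SAM it is that value, noted in the report.
The verdict is pass iff final PM% < 20 strictly. PM% is carried at full
precision; display rounds to one decimal with ties broken downward after
clearing binary-float noise, so a mean of 12.55 displays as 12.5.

## Contiguity metrics

Nx is the length of the scaffold at which the cumulative length of
descending-sorted scaffolds first reaches x% of the assembly size (the
">= threshold" convention, ties resolved at the scaffold that crosses the
threshold); Lx is the count of scaffolds in that prefix. GC% excludes N
and other ambiguous characters from the denominator. Ns per 100 kbp is
N count / assembly size × 100,000. NGx/LGx substitute an explicitly
supplied reference length for the assembly size and are omitted otherwise;
reference-based correctness metrics (indels, inversions, relocations) are
out of scope.

## Synthetic data generator

The generator exists so every stage is testable with no download and no
aligner, by planting structure that satisfies the definitions exactly:

* quality reads — HIGH reads draw all scores from [20, 40]; POOR reads get
  exactly floor(0.10·L)+1 bases in [2, 14]; MEDIUM reads get exactly one
  base in [15, 19]. Category and label mixes are apportioned by largest
  remainder ("exact" mode), so recovered fractions are equalities in tests;
  a Bernoulli mode exists for property tests.
* alignments — reads are substrings of a seeded random reference genome
  (default 50% GC) with per-label CIGAR/MD/NM/AS/XA fields constructed to
  force the label: S reads carry planted substitutions with a consistent
  MD tag and NM = substitutions + indel bases (keeping both substitution
  derivation paths testable), C reads carry a soft clip of the planted
  ratio, O reads an insertion, M reads either an XA hit or an explicit
  secondary record (alternating, so both multiplicity paths are
  exercised), F reads an unmapped flag, N reads planted N bases.
  Alignment scores follow match-minus-penalty arithmetic (L for perfect,
  −5 per substitution, −2 per clipped base, −6−d for a d-base insertion),
  which makes P scores stochastically dominate S and S dominate C under
  the default ratio ranges (mismatch U(0.01,0.15), clip U(0.05,0.60),
  N U(0.01,0.30), indel U(0.01,0.10)).

What the generator does **not** emulate: platform error spectra,
quality-by-cycle decay, duplicated or adapter-contaminated reads, genuine
repeat structure in the reference, or aligner-specific scoring quirks.
Passing tests therefore demonstrate that the statistics are computed
correctly from SAM/FASTQ evidence, not that any particular aligner's
output distribution is reproduced.

## Problem sizes and numerics

The test suite and the acceptance script run fixtures of 200–2000 reads on
references of 4–10 kbp, and 500 random assemblies of up to 25 scaffolds
for the contiguity oracle — sizes chosen so the planted mixes are exact
and every suite completes in seconds while exercising all code paths.
Degenerate inputs (empty reads, empty assemblies, non-positive sample
sizes, infeasible generator specs) raise `ValueError` rather than
returning sentinel values. Determinism is end-to-end: every random draw
flows from an explicit seed.

## Known limitations

Single-end analysis only: paired-end flags and mate information in SAM are
ignored, and 10X barcode structure is not interpreted. One observation per
read is derived from its primary record; chimeric alignments beyond one
supplementary record only contribute to multiplicity. The HTML report is a
static view (tables and inline bars) rather than an interactive interface.
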