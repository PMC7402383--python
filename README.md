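# asmqc

Two-way sequencing-quality assessment for de novo genome assemblies: are the
reads good enough, and does the assembly explain the reads? `asmqc` is aimed
at people running (or inheriting) de novo assembly projects for non-model
organisms, where no reference genome exists and correctness can only be
judged by mapping the reads back onto their own assembly.

## What it computes

**Pre-assembly** (reads only). For each read the minimum base Phred score
(MinimalQ) and the high-quality base fraction

    %HighQ(q) = #{bases with Phred score >= q} / #bases

are computed, and every read is categorized:

* **HIGH** — every base scored Q20 or above (equivalently MinimalQ >= 20);
* **POOR** — more than 10% of bases scored Q14 or less;
* **MEDIUM** — neither.

Aggregates include base composition, base-quality and MinimalQ histograms,
cumulative %HighQ distributions, and the percentage of bases at Q30+.

**Post-assembly** (reads + assembly + one or two SAM files of the reads
aligned back to the assembly, e.g. from a local and an end-to-end aligner).
Every read gets exactly one label from the SAM evidence:

| label | meaning |
|-------|---------|
| N | read contains an ambiguous base (decided before mapping) |
| F | failed to map |
| M | multi-mapped (secondary/supplementary records or XA hits) |
| P | uniquely mapped, perfect match |
| S | uniquely mapped, >= 1 substitution (from the MD tag, or NM minus indels) |
| C | uniquely mapped, contains soft/hard clips |
| O | uniquely mapped, other errors (indels) |

P and M reads are *highly mapped* and F reads *poorly mapped* outright; an
S, C, N or O read is poorly mapped when its error-density ratio — e.g.
clip ratio = total clipped length / read length — exceeds a threshold
(0.3 by default). The **poorly-mapped percentage**

    PM% = F% + S%(mismatch ratio > t) + C%(clip ratio > t) + N%(N ratio > t) + O%(indel ratio > t)

is computed per aligner and averaged across the two alignment strategies;
the assembly **passes** the assessment iff PM% < 20 (strict). Assembly
contiguity (N25/N50/N75, L80/L90/L99, GC%, Ns per 100 kbp, optional
NGx/LGx against a reference length) is computed natively.

Large FASTQ inputs are reduced by seeded single-pass reservoir sampling
(default one million reads) so the whole assessment stays desk-scale.

## Worked example

```sh
python examples/02_read_labeling_pm.py
```

builds a synthetic 1400-read SAM with a planted label mix and prints:

```
label distribution (% of reads):
  P:  50.0
  S:  20.0
  C:  10.0
  O:   5.0
  M:   5.0
  F:   5.0
  N:   5.0
poorly-mapped share per label (the negative bars):
  C:  5.36
  F:  5.00
PM% = 10.4 -> PASS (bar: PM% < 20)
alignment-score medians: {'P': 100.0, 'S': 60.0, 'C': 35.0}
```

The label fractions recover the planted mix exactly; PM% is the 5.0% of
unmapped reads plus the 5.36% of reads whose clip ratio exceeds 0.3; the
verdict passes because 10.4 < 20. Alignment-score medians decline from
perfect matches (P) through substitutions (S) to clips (C), as expected
when errors cost score. The other scripts in `examples/` cover read
quality, contiguity metrics, and the full pipeline with JSON/HTML reports.

## Command line

```sh
asmqc pre  reads.fastq -o outdir [--sample-size N] [--no-sample] [--seed S]
asmqc post reads.fastq assembly.fa -o outdir --sam mem=mem.sam --sam bt=bt.sam \
       [--clip-threshold F] [--mismatch-threshold F] [--n-threshold F] \
       [--other-threshold F] [--pm-threshold F]
asmqc all  reads.fastq assembly.fa -o outdir --sam ... # both stages
```

`--align` shells out to bwa (mem + aln/samse) instead of `--sam` when bwa
is on PATH. Exit codes: 0 pass, 1 FAIL verdict, 2 configuration/runtime
error — usable as a CI gate. All numbers land in JSON
(`preassembly.json`, `postassembly_<aligner>.json`, `pm_summary.json`,
`assembly_stats.json`); the HTML reports are views over them.

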