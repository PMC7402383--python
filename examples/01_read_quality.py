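"""Pre-assembly read quality: MinimalQ, %HighQ and HIGH/MEDIUM/POOR groups.

Builds a small synthetic FASTQ with a planted 50/30/20 quality mix, then
recovers the mix and prints the aggregate quality statistics.
"""

from asmqc import minimal_q, percent_high_q, summarize_preassembly
from asmqc.simulate import FixtureSpec, make_quality_reads

spec = FixtureSpec(n_reads=1000, read_length=100,
                   category_mix={"HIGH": 0.5, "MEDIUM": 0.3, "POOR": 0.2}, seed=1)
reads, truth = make_quality_reads(spec)

first = reads[0]
print(f"read {first.read_id}: MinimalQ={minimal_q(first)}, "
      f"%HighQ(20)={percent_high_q(first, 20):.2f}, "
      f"%HighQ(30)={percent_high_q(first, 30):.2f}")

summary = summarize_preassembly(reads)
print(f"{summary.n_reads} reads, {summary.n_bases} bases, "
      f"mean length {summary.mean_length:.1f}")
print(f"% of bases with Q30 & above: {summary.pct_bases_ge_q30:.1f}")
for cat, frac in summary.category_fractions.items():
    print(f"  {cat:6s} {100 * frac:5.1f}%")
# The three fractions recover the planted 50/30/20 mix exactly: a read is
# HIGH iff every base is Q20+, POOR iff >10% of bases are Q14 or below.
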