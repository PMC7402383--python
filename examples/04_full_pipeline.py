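"""The whole assessment in one go: sample -> pre-assembly QC ->
post-assembly classification -> contiguity -> JSON + HTML reports.

Equivalent to the command line:
    asmqc all reads.fastq assembly.fa --sam mem=mem.sam --sam bt=bt.sam \
        --no-sample -o outdir
"""

import tempfile
from pathlib import Path

from asmqc import RunConfig, run_post, run_pre
from asmqc.seqio import write_fasta, write_fastq
from asmqc.simulate import FixtureSpec, make_labeled_sam, random_genome

tmp = Path(tempfile.mkdtemp())
ref = random_genome(8000, seed=5)
spec = FixtureSpec(n_reads=1000, read_length=100, seed=6)
truth, reads = make_labeled_sam(spec, ref, tmp / "mem.sam")
make_labeled_sam(spec, ref, tmp / "backtrack.sam")
write_fastq(reads, tmp / "reads.fastq")
write_fasta([ref], tmp / "assembly.fa")

config = RunConfig(
    fastq_path=tmp / "reads.fastq",
    assembly_path=tmp / "assembly.fa",
    sam_paths={"mem": tmp / "mem.sam", "backtrack": tmp / "backtrack.sam"},
    output_dir=tmp / "report",
    bypass_sampling=True,
    seed=0,
)
pre = run_pre(config)
post = run_post(config)

cf = pre["summary"]["category_fractions"]
print("pre : read quality " + ", ".join(f"{k}={100 * v:.1f}%" for k, v in cf.items()))
pm = post["pm_summary"]
print(f"post: final PM% = {pm['final_pm_display']} "
      f"({'PASS' if pm['pass'] else 'FAIL'}, bar PM% < {pm['pm_pass_threshold']})")
print(f"post: N50 = {post['assembly_stats']['nx']['N50']} bp")
print("reports written to", tmp / "report")
# preassembly.json / postassembly_*.json / pm_summary.json hold every
# number; pre_report.html and post_report.html are views over them.
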