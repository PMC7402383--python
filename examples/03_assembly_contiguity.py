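"""Assembly contiguity metrics: Nx, Lx, GC% and Ns per 100 kbp.

Uses the five-scaffold worked case (lengths 5,4,3,2,1; total 15): the
descending cumulative sums 5, 9, 12, 14, 15 first reach 50% of 15 (=7.5)
at the second scaffold, so N50 = 4; they reach 80% (=12) at the third,
so L80 = 3.
"""

from asmqc import ScaffoldRecord, contiguity_stats

scaffolds = [ScaffoldRecord(f"s{i}", "ACGTACGT"[:n])
             for i, n in enumerate([5, 4, 3, 2, 1])]
stats = contiguity_stats(scaffolds)
print(f"{stats.n_scaffolds} scaffolds, {stats.assembly_size} bp total, "
      f"max {stats.max_scaffold} bp")
print("Nx:", {f"N{x}": v for x, v in stats.nx.items()})
print("Lx:", {f"L{x}": v for x, v in stats.lx.items()})
print(f"GC% = {stats.gc_pct:.2f}, Ns per 100 kbp = {stats.ns_per_100kbp:.2f}")

# With a reference genome length the NGx/LGx variants use the reference
# size as the denominator instead of the assembly size:
with_ref = contiguity_stats(scaffolds, reference_length=30)
print("NG50 vs N50:", with_ref.ngx[50], "vs", with_ref.nx[50])
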