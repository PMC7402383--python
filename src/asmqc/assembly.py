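"""Assembly contiguity and composition metrics (native Nx/Lx/GC/Ns).

Nx is the length of the scaffold at which the cumulative length of
descending-sorted scaffolds first reaches x% of the assembly size; Lx is
the number of scaffolds in that cumulative prefix (the ">= threshold"
convention). GC% is computed over unambiguous A/C/G/T bases only.
NGx/LGx use a supplied reference genome length as the denominator and are
reported only when that length is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import ScaffoldRecord

DEFAULT_NX = (25, 50, 75)
DEFAULT_LX = (80, 90, 99)


@dataclass
class AssemblyContiguityStats:
    n_scaffolds: int
    assembly_size: int
    max_scaffold: int
    nx: dict[int, int]
    lx: dict[int, int]
    gc_pct: float
    ns_per_100kbp: float
    ngx: dict[int, int] = field(default_factory=dict)
    lgx: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_scaffolds": self.n_scaffolds,
            "assembly_size": self.assembly_size,
            "max_scaffold": self.max_scaffold,
            "nx": {f"N{x}": v for x, v in self.nx.items()},
            "lx": {f"L{x}": v for x, v in self.lx.items()},
            "gc_pct": self.gc_pct,
            "ns_per_100kbp": self.ns_per_100kbp,
        }
        if self.ngx:
            d["ngx"] = {f"NG{x}": v for x, v in self.ngx.items()}
            d["lgx"] = {f"LG{x}": v for x, v in self.lgx.items()}
        return d


def nx_lx(lengths: Sequence[int], x: float, total: int | None = None) -> tuple[int, int]:
    """(Nx, Lx) for one x: scaffold length and count where the cumulative
    sum of descending-sorted lengths first reaches x% of ``total``
    (assembly size by default; a reference size for NGx/LGx)."""
    lengths = sorted(lengths, reverse=True)
    if total is None:
        total = sum(lengths)
    threshold = x / 100.0 * total
    cum = 0
    for i, ln in enumerate(lengths, start=1):
        cum += ln
        if cum >= threshold:
            return ln, i
    return lengths[-1], len(lengths)  # reference larger than assembly


def contiguity_stats(
    scaffolds: Iterable[ScaffoldRecord],
    nx_grid: Sequence[int] = DEFAULT_NX,
    lx_grid: Sequence[int] = DEFAULT_LX,
    reference_length: int | None = None,
) -> AssemblyContiguityStats:
    scaffolds = list(scaffolds)
    if not scaffolds:
        raise ValueError("contiguity_stats requires at least one scaffold")
    lengths = [len(s) for s in scaffolds]
    total = sum(lengths)

    gc = at = ns = 0
    for s in scaffolds:
        seq = s.sequence
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        ns += len(seq) - (seq.count("A") + seq.count("C")
                          + seq.count("G") + seq.count("T"))

    stats = AssemblyContiguityStats(
        n_scaffolds=len(scaffolds),
        assembly_size=total,
        max_scaffold=max(lengths),
        nx={x: nx_lx(lengths, x)[0] for x in nx_grid},
        lx={x: nx_lx(lengths, x)[1] for x in lx_grid},
        gc_pct=100.0 * gc / (gc + at) if gc + at else 0.0,
        ns_per_100kbp=100_000.0 * ns / total,
    )
    if reference_length is not None:
        stats.ngx = {x: nx_lx(lengths, x, reference_length)[0] for x in nx_grid}
        stats.lgx = {x: nx_lx(lengths, x, reference_length)[1] for x in lx_grid}
    return stats
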