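"""Pipeline orchestration and report rendering.

``run_pre`` samples reads and writes the pre-assembly quality bundle;
``run_post`` digests one or two SAM files, labels reads, computes PM% with
a pass/fail verdict and assembly contiguity, and writes the post-assembly
bundle. All numeric results live in JSON files; the HTML reports are pure
views over those bundles (content parity with the original tool's report:
summary statistic, label descriptions and thresholds sidebar, tables and
distributions — not pixel parity).
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
from dataclasses import asdict, dataclass, field
from pathlib import Path
from string import Template

from . import assembly as asm
from . import classify, preassembly, seqio

logger = logging.getLogger(__name__)

LABEL_DESCRIPTIONS = {
    "P": "uniquely mapped, perfect match",
    "S": "uniquely mapped, with substitution errors",
    "C": "uniquely mapped, contains clips",
    "O": "uniquely mapped, other errors (indels)",
    "M": "multi-mapped (repeats)",
    "F": "failed to map",
    "N": "contains ambiguous base N",
}


@dataclass
class RunConfig:
    """Configuration of one assessment run."""

    fastq_path: str | Path | None = None
    assembly_path: str | Path | None = None
    sam_paths: dict[str, str | Path] = field(default_factory=dict)  # aligner name -> SAM
    output_dir: str | Path = "asmqc_out"
    sample_size: int = seqio.DEFAULT_SAMPLE_SIZE
    bypass_sampling: bool = False
    seed: int = 0
    thresholds: classify.Thresholds = field(default_factory=classify.Thresholds)
    thread_count: int = 1

    def outdir(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_sample(config: RunConfig) -> list[seqio.ReadRecord]:
    if config.fastq_path is None:
        raise ValueError("a FASTQ path is required")
    stream = seqio.read_fastq(config.fastq_path)
    n = None if config.bypass_sampling else config.sample_size
    sample = seqio.sample_reads(stream, n, seed=config.seed)
    seqio.write_fastq(sample, config.outdir() / "sampled.fastq")
    return sample


def run_pre(config: RunConfig) -> dict:
    """Sample reads, compute pre-assembly quality statistics, write reports.

    Writes ``sampled.fastq``, ``preassembly.json`` and ``pre_report.html``
    into the output directory; returns the JSON bundle.
    """
    out = config.outdir()
    sample = _load_sample(config)
    summary = preassembly.summarize_preassembly(sample)
    bundle = {
        "input": str(config.fastq_path),
        "sample_size": len(sample),
        "sampling_bypassed": config.bypass_sampling,
        "seed": config.seed,
        "summary": summary.to_dict(),
    }
    _write_json(bundle, out / "preassembly.json")
    (out / "pre_report.html").write_text(render_pre_html(bundle))
    return bundle


def run_post(config: RunConfig) -> dict:
    """Classify mapped reads, compute PM% and contiguity, write reports.

    Requires the assembly FASTA and one or two SAM files of the sampled
    reads aligned to it. Writes ``postassembly_<aligner>.json`` per SAM,
    ``assembly_stats.json``, ``pm_summary.json`` and ``post_report.html``;
    returns the combined bundle whose headline is the final PM%.
    """
    if config.assembly_path is None:
        raise ValueError("an assembly FASTA path is required")
    if not config.sam_paths:
        raise ValueError("at least one SAM file (or an aligner) is required")
    if len(config.sam_paths) > 2:
        raise ValueError("at most two SAM files (one per aligner strategy)")
    out = config.outdir()

    sample = _load_sample(config)
    read_map = {r.read_id: r for r in sample}

    per_aligner: dict[str, dict] = {}
    breakdowns: list[classify.PMBreakdown] = []
    for name, sam_path in config.sam_paths.items():
        observations = classify.digest_sam(sam_path, read_map)
        labels = {rid: classify.label_read(o) for rid, o in observations.items()}
        profile = classify.profile_labels(labels, observations, aligner_name=name)
        breakdown = classify.compute_pm(profile, observations, config.thresholds)
        breakdowns.append(breakdown)
        aligner_bundle = {
            "profile": profile.to_dict(),
            "pm": breakdown.to_dict(),
            "alignment_scores": classify.alignment_score_stats(profile),
            "ratio_histograms": _ratio_histograms(profile),
        }
        per_aligner[name] = aligner_bundle
        _write_json(aligner_bundle, out / f"postassembly_{name}.json")

    final_pm = classify.average_pm(*breakdowns)
    verdict = classify.pass_assessment(final_pm, config.thresholds)
    pm_summary = {
        "per_aligner_pm_pct": {b.aligner_name: b.pm_pct for b in breakdowns},
        "final_pm_pct": final_pm,
        "final_pm_display": classify.display_pm(final_pm),
        "pass": verdict,
        "pm_pass_threshold": config.thresholds.pm_pass_threshold,
        "single_aligner_mode": len(breakdowns) == 1,
    }
    _write_json(pm_summary, out / "pm_summary.json")

    stats = asm.contiguity_stats(seqio.read_fasta(config.assembly_path))
    _write_json(stats.to_dict(), out / "assembly_stats.json")

    bundle = {
        "input_fastq": str(config.fastq_path),
        "input_assembly": str(config.assembly_path),
        "sample_size": len(sample),
        "seed": config.seed,
        "thresholds": {
            "clip": config.thresholds.clip_threshold,
            "mismatch": config.thresholds.mismatch_threshold,
            "n": config.thresholds.n_threshold,
            "other": config.thresholds.other_threshold,
            "pm_pass": config.thresholds.pm_pass_threshold,
        },
        "pm_summary": pm_summary,
        "aligners": per_aligner,
        "assembly_stats": stats.to_dict(),
    }
    (out / "post_report.html").write_text(render_post_html(bundle))
    return bundle


def _ratio_histograms(profile: classify.LabelProfile, bins: int = 20) -> dict:
    import numpy as np
    out = {}
    for lab, ratios in profile.ratios.items():
        if not ratios:
            continue
        counts, edges = np.histogram(ratios, bins=bins, range=(0.0, 1.0))
        out[lab] = {"counts": counts.tolist(), "edges": edges.tolist()}
    return out


# ------------------------------------------------------------------ HTML

_PAGE = Template("""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>$title</title>
<style>
body{font-family:sans-serif;margin:2em;max-width:70em}
table{border-collapse:collapse;margin:1em 0}
td,th{border:1px solid #999;padding:0.3em 0.7em;text-align:right}
th{background:#eee}
.headline{font-size:1.6em;margin:0.5em 0}
.pass{color:#070}.fail{color:#a00}
.sidebar{background:#f7f7f7;border:1px solid #ccc;padding:0.5em 1em;margin:1em 0}
.bar{background:#48a;display:inline-block;height:0.8em}
</style></head><body>
<h1>$title</h1>
$body
</body></html>
""")

_PLACEHOLDER = "<p><em>not computed</em></p>"


def _table(headers: list[str], rows: list[list]) -> str:
    head = "".join(f"<th>{h}</th>" for h in headers)
    body = "".join(
        "<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>" for row in rows)
    return f"<table><tr>{head}</tr>{body}</table>"


def _hist_rows(counts: list, labels: list, limit: int = 100) -> list[list]:
    maxc = max(counts) if counts else 1
    rows = []
    for lab, c in zip(labels, counts):
        if c:
            width = max(1, int(200 * c / max(maxc, 1)))
            rows.append([lab, c, f'<span class="bar" style="width:{width}px"></span>'])
    return rows[:limit]


def render_pre_html(bundle: dict) -> str:
    """Pre-assembly HTML: category proportions, basic and quality statistics."""
    s = bundle.get("summary")
    if not s:
        return _PAGE.substitute(title="Pre-assembly quality report", body=_PLACEHOLDER)
    cf = s["category_fractions"]
    parts = [
        '<p class="headline">Read quality: '
        + ", ".join(f"{k} {100 * v:.1f}%" for k, v in cf.items()) + "</p>",
        "<h2>Basic statistics</h2>",
        _table(["measure", "value"], [
            ["input", bundle.get("input", "?")],
            ["reads analyzed", s["n_reads"]],
            ["bases", s["n_bases"]],
            ["read length min/mean/max",
             f'{s["min_length"]} / {s["mean_length"]} / {s["max_length"]}'],
            ["% of bases with Q30 &amp; above", f'{s["pct_bases_ge_q30"]:.1f}'],
        ]),
        "<h2>Base composition</h2>",
        _table(list(s["base_composition"]), [list(s["base_composition"].values())]),
        "<h2>Base quality score distribution</h2>",
        _table(["Q", "count", ""], _hist_rows(
            s["base_quality_distribution"],
            list(range(len(s["base_quality_distribution"]))))),
        "<h2>MinimalQ distribution</h2>",
        _table(["MinimalQ", "count", ""], _hist_rows(
            s["minimalq_distribution"],
            list(range(len(s["minimalq_distribution"]))))),
        "<h2>Cumulative %HighQ distributions</h2>",
        _table(["q"] + [f"&ge;{p}%" for p in range(0, 101, 5)],
               [[q] + [f"{v:.3f}" for v in vals]
                for q, vals in s["highq_cdf"].items()]),
    ]
    return _PAGE.substitute(title="Pre-assembly quality report", body="\n".join(parts))


def render_post_html(bundle: dict) -> str:
    """Post-assembly HTML headed by the final PM% with pass/fail verdict."""
    pm = bundle.get("pm_summary")
    parts = []
    if pm:
        cls = "pass" if pm["pass"] else "fail"
        verdict = "PASS" if pm["pass"] else "FAIL"
        parts.append(
            f'<p class="headline">Final PM% = <b>{pm["final_pm_display"]}</b> '
            f'<span class="{cls}">{verdict}</span> '
            f'(threshold: PM% &lt; {pm["pm_pass_threshold"]})</p>')
        if pm.get("single_aligner_mode"):
            parts.append("<p><em>Single-aligner mode: final PM% is from one "
                         "alignment strategy, not an average of two.</em></p>")
    else:
        parts.append(_PLACEHOLDER)

    thr = bundle.get("thresholds", {})
    parts.append('<div class="sidebar"><h3>Read labels</h3>'
                 + _table(["label", "description"],
                          [[k, v] for k, v in LABEL_DESCRIPTIONS.items()])
                 + "<h3>Thresholds</h3>"
                 + (_table(["ratio", "poorly-mapped above"],
                           [[k, v] for k, v in thr.items()]) if thr else _PLACEHOLDER)
                 + "</div>")

    aligners = bundle.get("aligners", {})
    if aligners:
        labels = list(LABEL_DESCRIPTIONS)
        parts.append("<h2>Label distribution (%)</h2>")
        rows = []
        for name, ab in aligners.items():
            fr = ab["profile"]["fractions"]
            rows.append([name] + [f"{100 * fr[lab]:.1f}" for lab in labels])
        parts.append(_table(["aligner"] + labels, rows))
        for name, ab in aligners.items():
            pmb = ab["pm"]
            parts.append(f"<h3>{name}: highly / poorly mapped (%)</h3>")
            parts.append(_table(
                ["label", "highly", "poorly"],
                [[lab, f'{pmb["highly_mapped_pct"][lab]:.2f}',
                  f'{pmb["poorly_mapped_pct"][lab]:.2f}'] for lab in labels]
                + [["PM%", "", f'{pmb["pm_pct"]:.2f}']]))
            scores = ab.get("alignment_scores") or {}
            srows = [[lab, st.get("n", ""), st.get("median", ""),
                      st.get("q1", ""), st.get("q3", "")]
                     for lab, st in scores.items() if st]
            parts.append("<h3>%s: alignment scores</h3>" % name)
            parts.append(_table(["label", "n", "median", "Q1", "Q3"], srows)
                         if srows else _PLACEHOLDER)
    else:
        parts.append(_PLACEHOLDER)

    st = bundle.get("assembly_stats")
    parts.append("<h2>Assembly statistics</h2>")
    if st:
        rows = [["# scaffolds", st["n_scaffolds"]],
                ["assembly size (bp)", st["assembly_size"]],
                ["max scaffold (bp)", st["max_scaffold"]]]
        rows += [[k, v] for k, v in st["nx"].items()]
        rows += [[k, v] for k, v in st["lx"].items()]
        rows += [["GC%", f'{st["gc_pct"]:.2f}'],
                 ["N's per 100 kbp", f'{st["ns_per_100kbp"]:.2f}']]
        parts.append(_table(["metric", "value"], rows))
    else:
        parts.append(_PLACEHOLDER)

    return _PAGE.substitute(title="Post-assembly mapping report", body="\n".join(parts))


# -------------------------------------------------------- aligner plumbing

def run_bwa_aligners(fastq: Path, assembly: Path, outdir: Path,
                     threads: int = 1) -> dict[str, Path]:
    """Produce the two SAM files with bwa (local ``mem`` + end-to-end
    ``aln``/``samse``) when the executable is on PATH. Command lines are
    logged for provenance. Raises ``RuntimeError`` if bwa is unavailable."""
    if shutil.which("bwa") is None:
        raise RuntimeError("bwa executable not found on PATH; supply SAM files instead")
    outdir.mkdir(parents=True, exist_ok=True)
    idx = outdir / "ref.fa"
    shutil.copy(assembly, idx)
    sams: dict[str, Path] = {}

    def run(cmd: list[str], stdout=None) -> None:
        logger.info("running: %s", " ".join(map(str, cmd)))
        subprocess.run(list(map(str, cmd)), check=True, stdout=stdout,
                       stderr=subprocess.DEVNULL)

    run(["bwa", "index", idx])
    mem_sam = outdir / "mem.sam"
    with open(mem_sam, "w") as fh:
        run(["bwa", "mem", "-t", threads, idx, fastq], stdout=fh)
    sams["bwa-mem"] = mem_sam
    sai = outdir / "backtrack.sai"
    with open(sai, "w") as fh:
        run(["bwa", "aln", "-t", threads, idx, fastq], stdout=fh)
    bt_sam = outdir / "backtrack.sam"
    with open(bt_sam, "w") as fh:
        run(["bwa", "samse", idx, sai, fastq], stdout=fh)
    sams["bwa-backtrack"] = bt_sam
    return sams
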