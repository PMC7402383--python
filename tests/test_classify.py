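"""SAM digestion, seven-way read labeling and the PM% statistic."""

import re

import numpy as np
import pytest

from asmqc.classify import (
    AlignmentObservation,
    Thresholds,
    alignment_score_stats,
    average_pm,
    compute_pm,
    count_md_substitutions,
    digest_sam,
    display_pm,
    label_read,
    pass_assessment,
    profile_labels,
)
from asmqc.simulate import FixtureSpec, make_labeled_sam, random_genome

HEADER = "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:100000\n"


def sam_file(tmp_path, records, name="t.sam"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(r + "\n" for r in records))
    return path


def rec(qname, flag, cigar, seq, *tags, pos=1000):
    if flag & 0x4:
        return f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*"
    qual = "*" if seq == "*" else "I" * len(seq)
    return "\t".join([qname, str(flag), "ref", str(pos), "60", cigar, "*", "0", "0",
                      seq, qual] + list(tags))


A100 = "A" * 100


class TestMdTag:
    @pytest.mark.parametrize("md,expected", [
        ("100", 0),
        ("40A59", 1),
        ("0A0C98", 2),
        ("10^AC88", 0),        # deletion letters are not substitutions
        ("5^ACG2T40", 1),
        ("0T0", 1),
    ])
    def test_substitution_count(self, md, expected):
        assert count_md_substitutions(md) == expected

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            count_md_substitutions("12+3")


class TestDigestSam:
    def test_unmapped_flag(self, tmp_path):
        obs = digest_sam(sam_file(tmp_path, [rec("r1", 4, "*", A100)]))
        assert obs["r1"].mapped is False
        assert obs["r1"].multiplicity == 0
        assert obs["r1"].substitutions == obs["r1"].clip_bases == 0

    def test_soft_clip_ratio(self, tmp_path):
        obs = digest_sam(sam_file(
            tmp_path, [rec("r1", 0, "70M30S", A100, "NM:i:0", "MD:Z:70")]))
        assert obs["r1"].clip_bases == 30
        assert obs["r1"].clip_ratio == pytest.approx(0.3)

    def test_md_substitutions(self, tmp_path):
        obs = digest_sam(sam_file(
            tmp_path, [rec("r1", 0, "100M", A100, "NM:i:1", "MD:Z:40C59")]))
        assert obs["r1"].substitutions == 1
        assert obs["r1"].mismatch_ratio == pytest.approx(0.01)

    def test_nm_fallback_subtracts_indels(self, tmp_path):
        # NM=3 with a 2-base insertion leaves 1 substitution
        obs = digest_sam(sam_file(
            tmp_path, [rec("r1", 0, "50M2I48M", A100, "NM:i:3")]))
        assert obs["r1"].substitutions == 1
        assert obs["r1"].insertion_bases == 2

    def test_missing_md_and_nm_warns_zero(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            obs = digest_sam(sam_file(tmp_path, [rec("r1", 0, "100M", A100)]))
        assert obs["r1"].substitutions == 0
        assert any("MD" in m for m in caplog.messages)

    def test_hard_clips_extend_read_length(self, tmp_path):
        # 80 bp SEQ + 20 bp hard clip: ratio over the full 100 bp read
        obs = digest_sam(sam_file(
            tmp_path, [rec("r1", 0, "80M20H", "A" * 80, "NM:i:0", "MD:Z:80")]))
        assert obs["r1"].read_length == 100
        assert obs["r1"].clip_bases == 20
        assert obs["r1"].clip_ratio == pytest.approx(0.2)

    def test_multiplicity_from_xa_and_secondary(self, tmp_path):
        obs = digest_sam(sam_file(tmp_path, [
            rec("r1", 0, "100M", A100, "NM:i:0", "MD:Z:100",
                "XA:Z:ref,+500,100M,0;ref,-900,100M,1;"),
            rec("r2", 0, "100M", A100, "NM:i:0", "MD:Z:100"),
            rec("r2", 256, "100M", "*", "NM:i:0"),
        ]))
        assert obs["r1"].multiplicity == 3
        assert obs["r2"].multiplicity == 2

    def test_read_not_in_sample_skipped(self, tmp_path, caplog):
        from asmqc.seqio import ReadRecord
        reads = {"r1": ReadRecord("r1", A100, (40,) * 100)}
        with caplog.at_level("WARNING"):
            obs = digest_sam(sam_file(tmp_path, [
                rec("r1", 0, "100M", A100, "NM:i:0", "MD:Z:100"),
                rec("stranger", 0, "100M", A100, "NM:i:0", "MD:Z:100"),
            ]), reads)
        assert set(obs) == {"r1"}


def make_obs(**kw):
    base = dict(read_id="r", read_length=100, has_n=False, mapped=True,
                multiplicity=1)
    base.update(kw)
    return AlignmentObservation(**base)


class TestLabelRead:
    @pytest.mark.parametrize("obs,expected", [
        (make_obs(), "P"),
        (make_obs(substitutions=2), "S"),
        (make_obs(clip_bases=10), "C"),
        (make_obs(insertion_bases=1), "O"),
        (make_obs(deletion_bases=3), "O"),
        (make_obs(multiplicity=2), "M"),
        (make_obs(mapped=False, multiplicity=0), "F"),
        (make_obs(has_n=True, n_count=1), "N"),
    ])
    def test_canonical_cases(self, obs, expected):
        assert label_read(obs) == expected

    def test_n_screens_before_mapping_outcome(self):
        # even a perfectly mapped read with an N is type N
        assert label_read(make_obs(has_n=True, n_count=1)) == "N"
        assert label_read(make_obs(has_n=True, mapped=False, multiplicity=0,
                                   n_count=1)) == "N"

    def test_multi_mapped_beats_errors(self):
        assert label_read(make_obs(multiplicity=3, substitutions=5)) == "M"

    def test_substitutions_take_precedence_over_clips(self):
        obs = make_obs(substitutions=1, clip_bases=10)
        assert label_read(obs) == "S"
        assert label_read(obs, order=("C", "S", "O")) == "C"


def brute_force_labels(sam_path):
    """Independent label re-derivation from raw SAM text fields."""
    primaries, n_extra = {}, {}
    for line in open(sam_path):
        if line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        qname, flag = f[0], int(f[1])
        if flag & (0x100 | 0x800):
            n_extra[qname] = n_extra.get(qname, 0) + 1
        else:
            primaries[qname] = f
    labels = {}
    for qname, f in primaries.items():
        flag, cigar, seq = int(f[1]), f[5], f[9]
        tags = {t.split(":", 1)[0]: t.split(":", 2)[2] for t in f[11:]}
        if "N" in seq:
            labels[qname] = "N"
        elif flag & 0x4:
            labels[qname] = "F"
        else:
            hits = 1 + n_extra.get(qname, 0)
            if "XA" in tags:
                hits += tags["XA"].count(";")
            md_subs = len(re.findall(r"[A-Z]", re.sub(r"\^[A-Z]+", "", tags["MD"]))) \
                if "MD" in tags else 0
            clips = sum(int(n) for n, op in re.findall(r"(\d+)([SH])", cigar))
            indels = sum(int(n) for n, op in re.findall(r"(\d+)([ID])", cigar))
            if hits > 1:
                labels[qname] = "M"
            elif md_subs == 0 and clips == 0 and indels == 0:
                labels[qname] = "P"
            elif md_subs > 0:
                labels[qname] = "S"
            elif clips > 0:
                labels[qname] = "C"
            else:
                labels[qname] = "O"
    return labels


class TestClassifierOracle:
    def test_agrees_with_brute_force_on_random_fixture(self, tmp_path):
        ref = random_genome(4000, seed=5)
        spec = FixtureSpec(n_reads=200, read_length=100, seed=13)
        sam = tmp_path / "oracle.sam"
        truth, reads = make_labeled_sam(spec, ref, sam)
        obs = digest_sam(sam, {r.read_id: r for r in reads})
        ours = {rid: label_read(o) for rid, o in obs.items()}
        assert ours == truth
        assert ours == brute_force_labels(sam)


class TestProfileAndPM:
    def test_all_perfect(self):
        obs = {f"r{i}": make_obs(read_id=f"r{i}") for i in range(10)}
        labels = {k: "P" for k in obs}
        prof = profile_labels(labels, obs)
        assert prof.fractions["P"] == 1.0
        assert compute_pm(prof, obs).pm_pct == 0.0

    def test_unmapped_only_contribution(self):
        obs = {f"p{i}": make_obs(read_id=f"p{i}") for i in range(90)}
        obs.update({f"f{i}": make_obs(read_id=f"f{i}", mapped=False, multiplicity=0)
                    for i in range(10)})
        labels = {k: ("F" if k.startswith("f") else "P") for k in obs}
        prof = profile_labels(labels, obs)
        assert prof.fractions == pytest.approx({"P": 0.9, "F": 0.1, "S": 0, "C": 0,
                                                "O": 0, "M": 0, "N": 0})
        assert compute_pm(prof, obs).pm_pct == pytest.approx(10.0)

    def test_clip_threshold_partition(self):
        # 50 P + 50 C; 20 clipped at ratio 0.5 (> 0.3) and 30 at 0.1
        obs = {f"p{i}": make_obs(read_id=f"p{i}") for i in range(50)}
        obs.update({f"c{i}": make_obs(read_id=f"c{i}", clip_bases=50)
                    for i in range(20)})
        obs.update({f"d{i}": make_obs(read_id=f"d{i}", clip_bases=10)
                    for i in range(30)})
        labels = {k: ("P" if k.startswith("p") else "C") for k in obs}
        breakdown = compute_pm(profile_labels(labels, obs), obs)
        assert breakdown.pm_pct == pytest.approx(20.0)
        assert breakdown.poorly_mapped_pct["C"] == pytest.approx(20.0)
        assert breakdown.highly_mapped_pct["C"] == pytest.approx(30.0)

    def test_other_threshold_none_never_poor(self):
        obs = {"o1": make_obs(read_id="o1", insertion_bases=90)}
        labels = {"o1": "O"}
        thr = Thresholds(other_threshold=None)
        assert compute_pm(profile_labels(labels, obs), obs, thr).pm_pct == 0.0

    def test_totals_and_bounds_on_fixture(self, labeled_fixture):
        obs = digest_sam(labeled_fixture["sam"],
                         {r.read_id: r for r in labeled_fixture["reads"]})
        labels = {rid: label_read(o) for rid, o in obs.items()}
        prof = profile_labels(labels, obs)
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        b = compute_pm(prof, obs)
        assert b.pm_pct == pytest.approx(sum(b.poorly_mapped_pct.values()))
        assert b.pm_pct >= 100 * prof.fractions["F"] - 1e-9
        assert b.pm_pct <= 100 * (1 - prof.fractions["P"] - prof.fractions["M"]) + 1e-9
        total = sum(b.poorly_mapped_pct.values()) + sum(b.highly_mapped_pct.values())
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_pm_monotone_in_each_threshold(self, labeled_fixture):
        obs = digest_sam(labeled_fixture["sam"],
                         {r.read_id: r for r in labeled_fixture["reads"]})
        labels = {rid: label_read(o) for rid, o in obs.items()}
        prof = profile_labels(labels, obs)
        grid = [0.05, 0.1, 0.3, 0.6, 1.0]
        for field in ("clip_threshold", "mismatch_threshold", "n_threshold",
                      "other_threshold"):
            pms = [compute_pm(prof, obs, Thresholds(**{field: t})).pm_pct
                   for t in grid]
            assert all(a >= b for a, b in zip(pms, pms[1:])), field


class TestFinalPM:
    def test_mean_of_two_aligners(self):
        assert average_pm(8.8, 16.3) == pytest.approx(12.55)
        assert display_pm(average_pm(8.8, 16.3)) == "12.5"

    @pytest.mark.parametrize("a,b,expected", [(7.0, 7.0, 7.0), (0.0, 100.0, 50.0)])
    def test_mean_properties(self, a, b, expected):
        assert average_pm(a, b) == pytest.approx(expected)

    def test_single_aligner_is_identity(self):
        assert average_pm(9.9) == pytest.approx(9.9)

    @pytest.mark.parametrize("pm,expected", [
        (12.5, True),    # below the default 20% bar
        (19.999, True),
        (20.0, False),   # strict inequality
        (59.0, False),
    ])
    def test_pass_verdict_strict(self, pm, expected):
        assert pass_assessment(pm) is expected

    def test_verdict_flips_exactly_at_threshold(self):
        thr = Thresholds(pm_pass_threshold=35.0)
        assert pass_assessment(34.999999, thr)
        assert not pass_assessment(35.0, thr)


class TestAlignmentScores:
    def test_constant_scores(self):
        obs = {f"r{i}": make_obs(read_id=f"r{i}", alignment_score=77) for i in range(5)}
        stats = alignment_score_stats(profile_labels({k: "P" for k in obs}, obs))
        assert stats["P"]["median"] == 77
        assert stats["S"] == {} and stats["C"] == {}

    def test_median_ordering_on_fixture(self, labeled_fixture):
        obs = digest_sam(labeled_fixture["sam"],
                         {r.read_id: r for r in labeled_fixture["reads"]})
        labels = {rid: label_read(o) for rid, o in obs.items()}
        stats = alignment_score_stats(profile_labels(labels, obs))
        assert stats["P"]["median"] >= stats["S"]["median"] >= stats["C"]["median"]
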