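"""Contig-based correction, dual-caller read correction, pileup calling."""

import numpy as np
import pytest

from replifin.align import (TargetIndex, VariantCandidate, align_pair,
                            classify_context, left_normalize)
from replifin.polish import (ContigPolicy, CorrectionReport, apply_edits,
                             correct_with_contigs, correct_with_read_calls,
                             merge_candidates, pileup_calls,
                             sam_to_alignments, write_vcf)
from replifin.seqmodel import ParamSet, Replicon
from replifin.simulate import (corrupt_longread_style, make_contigs,
                               simulate_long_reads, coding_like_sequence,
                               SimConfig, build_truth)

from conftest import random_seq


@pytest.fixture(scope="module")
def planted_scenario():
    """100 kb truth, 30 planted homopolymer deletions + 2 substitutions,
    5 error-free contig tiles."""
    cfg = SimConfig(chromosome_length=100_000, tir_len=3_000,
                    n_hp_del=30, n_subst=2,
                    plasmid1_circle_len=20_000, plasmid1_dup_len=2_000,
                    plasmid2_len=30_000, plasmid2_gap=(18_000, 20_000),
                    n_contigs=5, seed=7)
    fs, _ = build_truth(cfg)
    truth = fs.get("chrom")
    draft, ledger = corrupt_longread_style(truth, 30, 2, 100, seed=3)
    contigs = make_contigs(truth, 5, seed=4)
    return truth, draft, ledger, contigs


class TestContigCorrection:
    def test_planted_truth_recovery(self, planted_scenario):
        truth, draft, ledger, contigs = planted_scenario
        corrected, rep = correct_with_contigs(draft, contigs)
        assert rep.total_corrections == 32
        assert rep.inserted_bases == 30
        assert rep.substituted_bases == 2
        assert rep.by_context.get("gc_homopolymer") == 30
        assert corrected.seq == truth.seq
        rep.validate()

    def test_fixed_point_on_identical_contigs(self, planted_scenario):
        _, draft, _, _ = planted_scenario
        corrected, rep = correct_with_contigs(draft, [Replicon("c", draft.seq)])
        assert rep.total_corrections == 0
        assert corrected.seq == draft.seq

    def test_idempotence(self, planted_scenario):
        truth, draft, _, contigs = planted_scenario
        once, rep1 = correct_with_contigs(draft, contigs)
        twice, rep2 = correct_with_contigs(once, contigs)
        assert rep2.total_corrections == 0
        assert twice.seq == once.seq

    def test_unaligned_contig_passed_through(self, planted_scenario, rng):
        _, draft, _, _ = planted_scenario
        alien = Replicon("alien", random_seq(np.random.default_rng(0), 5_000))
        corrected, rep = correct_with_contigs(draft, [alien])
        assert corrected.seq == draft.seq
        assert any(r.reason == "unaligned-contig" for r in rep.rejected)

    def test_conflicting_contigs_reject_without_exception(self, rng):
        """Two overlapping contigs disagreeing on a substitution: rejected."""
        t = random_seq(rng, 20_000)
        draft = Replicon("d", t)
        pos = 10_000
        alt1 = "A" if t[pos] != "A" else "G"
        alt2 = "T" if t[pos] not in "T" else "C"
        c1 = Replicon("c1", t[:pos] + alt1 + t[pos + 1:])
        c2 = Replicon("c2", t[:pos] + alt2 + t[pos + 1:])
        corrected, rep = correct_with_contigs(draft, [c1, c2])
        assert corrected.seq == draft.seq
        assert any(r.reason in ("conflict",) for r in rep.rejected)

    def test_substitution_unanimity_applied(self, rng):
        t = random_seq(rng, 20_000)
        pos = 9_000
        alt = "A" if t[pos] != "A" else "G"
        fixed = t[:pos] + alt + t[pos + 1:]
        draft = Replicon("d", t)
        tiles = [Replicon("c1", fixed[:12_000]), Replicon("c2", fixed[7_000:])]
        corrected, rep = correct_with_contigs(draft, tiles)
        assert corrected.seq == fixed
        assert rep.substituted_bases == 1


class TestApplyEdits:
    def test_order_independence(self, planted_scenario):
        truth, draft, _, contigs = planted_scenario
        _, rep = correct_with_contigs(draft, contigs)
        a = apply_edits(draft.seq, rep.applied, "right_to_left")
        b = apply_edits(draft.seq, rep.applied, "left_to_right_shifted")
        assert a == b == truth.seq

    def test_length_bookkeeping(self, planted_scenario):
        _, draft, _, contigs = planted_scenario
        corrected, rep = correct_with_contigs(draft, contigs)
        assert rep.after_len == rep.before_len + rep.inserted_bases - rep.deleted_bases
        assert rep.total_corrections == (
            rep.inserted_bases + rep.deleted_bases + rep.substituted_bases)


def _ins_call(seq, pos, base, who):
    p = left_normalize(seq, pos, "insertion", base)
    return VariantCandidate(
        tid="chr", tpos=p, ref="", alt=base, kind="insertion",
        context=classify_context(seq, p, "insertion", base), support={who})


class TestReadCallCorrection:
    def test_dual_supported_homopolymer_insertions_applied(self, rng):
        """Worked micro-edits: a sixth C after G in a run of five Cs, a C in
        acccaa and in aacccca, a G in cggg — all dual-caller supported."""
        pre, post = random_seq(rng, 300), random_seq(rng, 300)
        draft = pre + "GCCCCC" + "TT" + "ACCCAA" + "TT" + "AACCCCA" + "TT" + "CGGG" + post
        truth = pre + "GCCCCCC" + "TT" + "ACCCCAA" + "TT" + "AACCCCCA" + "TT" + "CGGGG" + post
        d = Replicon("chr", draft)
        positions = [301, 309, 318, 326]
        a = [_ins_call(draft, p, b, "bwa") for p, b in
             zip(positions, "CCCG")]
        b = [_ins_call(draft, p, b_, "bowtie2") for p, b_ in
             zip(positions, "CCCG")]
        corrected, rep = correct_with_read_calls(d, a, b)
        assert rep.total_corrections == 4
        assert corrected.seq == truth
        assert all(c.context == "gc_homopolymer" for c in rep.applied)

    def test_single_caller_deletion_with_frame_repair_applied(self):
        """A spurious extra base in a gene (GTGGA-style) reported by one
        caller only is applied because removing it repairs the frame."""
        seq, genes = coding_like_sequence(4, 3_000, 0.9, seed=11)
        a, b = genes[1]
        pos = (a + b) // 2
        corrupted = seq[:pos] + "G" + seq[pos:]   # erroneous addition
        d = Replicon("chr", corrupted)
        p = left_normalize(corrupted, pos, "deletion", "G")
        cand = VariantCandidate(tid="chr", tpos=p, ref=corrupted[p], alt="",
                                kind="deletion", support={"bwa"})
        corrected, rep = correct_with_read_calls(d, [cand], [])
        assert rep.total_corrections == 1
        assert corrected.seq == seq

    def test_substitutions_never_applied(self, rng):
        s = random_seq(rng, 2_000)
        d = Replicon("chr", s)
        alt = "A" if s[500] != "A" else "G"
        cand = VariantCandidate(tid="chr", tpos=500, ref=s[500], alt=alt,
                                kind="substitution", support={"bwa"})
        cand2 = VariantCandidate(tid="chr", tpos=500, ref=s[500], alt=alt,
                                 kind="substitution", support={"bowtie2"})
        corrected, rep = correct_with_read_calls(d, [cand], [cand2])
        assert rep.total_corrections == 0
        assert corrected.seq == s
        assert rep.rejected[0].reason == "policy:no-substitutions"

    def test_out_of_range_rejected(self, rng):
        s = random_seq(rng, 1_000)
        d = Replicon("chr", s)
        cand = VariantCandidate(tid="chr", tpos=5_000, ref="A", alt="",
                                kind="deletion", support={"bwa"})
        corrected, rep = correct_with_read_calls(d, [cand], [cand])
        assert corrected.seq == s
        assert rep.rejected[0].reason == "out-of-range"

    def test_empty_call_sets(self, rng):
        s = random_seq(rng, 1_000)
        corrected, rep = correct_with_read_calls(Replicon("chr", s), [], [])
        assert rep.total_corrections == 0
        assert corrected.seq == s


class TestPileup:
    def _align_reads(self, reads, draft):
        idx = TargetIndex(draft.seq, 21)
        out = []
        for r in reads:
            b = align_pair(r.seq, draft.seq, index=idx, min_anchor=100,
                           qid=r.id, tid=draft.id)
            if b is not None:
                out.append((r, b))
        return out

    def test_planted_insertion_called(self, rng):
        truth = random_seq(rng, 20_000)
        draft = Replicon("d", truth[:10_000] + truth[10_001:])
        reads, _ = simulate_long_reads(Replicon("t", truth), 2_000, 15, 0.0,
                                       seed=5)
        calls = pileup_calls(draft, self._align_reads(reads, draft),
                             min_depth=10, min_fraction=0.8)
        assert len(calls) == 1
        assert calls[0].kind == "insertion"
        assert calls[0].alt == truth[10_000] or calls[0].alt in "ACGT"

    def test_no_reads_no_calls(self, rng):
        draft = Replicon("d", random_seq(rng, 1_000))
        assert pileup_calls(draft, []) == []

    def test_split_column_below_fraction_not_called(self, rng):
        truth = random_seq(rng, 6_000)
        pos = 3_000
        alt = "A" if truth[pos] != "A" else "G"
        variant = truth[:pos] + alt + truth[pos + 1:]
        draft = Replicon("d", truth)
        reads = ([Replicon(f"r{i}", truth[1_000:5_000]) for i in range(15)]
                 + [Replicon(f"v{i}", variant[1_000:5_000]) for i in range(15)])
        calls = pileup_calls(draft, self._align_reads(reads, draft),
                             min_depth=10, min_fraction=0.8)
        assert calls == []   # 15/30 = 0.5 < 0.8


class TestSamInput:
    SAM = (
        "@HD\tVN:1.6\tSO:unknown\n"
        "@SQ\tSN:d\tLN:{ln}\n"
        "{body}"
    )

    def test_sam_round_trip_pileup(self, rng, tmp_path):
        truth = random_seq(rng, 4_000)
        draft = Replicon("d", truth[:2_000] + truth[2_001:])  # deletion at 2000
        body = ""
        for i in range(12):
            read = truth[1_000:3_000]
            # read has one base (truth[2000]) absent from draft: 1000M 1I 999M
            body += (f"r{i}\t0\td\t1001\t60\t1000M1I999M\t*\t0\t0\t{read}\t*\n")
        p = tmp_path / "reads.sam"
        p.write_text(self.SAM.format(ln=len(draft.seq), body=body))
        pairs = sam_to_alignments(p, draft)
        assert len(pairs) == 12
        for _, block in pairs:
            block.validate()
        calls = pileup_calls(draft, pairs, min_depth=10, min_fraction=0.8)
        assert len(calls) == 1
        assert calls[0].kind == "insertion"


class TestVcf:
    def test_vcf_refs_match_draft(self, planted_scenario, tmp_path):
        _, draft, _, contigs = planted_scenario
        _, rep = correct_with_contigs(draft, contigs)
        out = tmp_path / "edits.vcf"
        write_vcf(rep, draft, out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == rep.total_corrections
        for line in lines:
            chrom, pos, _, ref, alt, *_ = line.split("\t")
            pos = int(pos)
            assert draft.seq[pos - 1 : pos - 1 + len(ref)] == ref
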