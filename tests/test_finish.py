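"""Artifact flagging, terminus extension, bridging, pipeline orchestration."""

import numpy as np
import pytest

from replifin.finish import (FinishError, bridge_contigs, extend_terminus,
                             flag_artifact_contigs, run_pipeline)
from replifin.seqmodel import ParamSet, Replicon, revcomp
from replifin.simulate import (SimConfig, build_truth, corrupt_longread_style,
                               linearize_with_duplication, make_contigs,
                               simulate_long_reads, tiling_reads)

from conftest import random_seq


def mutate_to_identity(seq: str, identity: float, rng) -> str:
    out = list(seq)
    n = int(round((1 - identity) * len(seq)))
    for p in rng.choice(len(seq), size=n, replace=False):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


class TestArtifactFlagging:
    def test_partition(self, rng):
        asm = Replicon("asm", random_seq(rng, 60_000))
        artifact = Replicon("artifact",
                            mutate_to_identity(asm.seq[20_000:29_613], 0.92, rng))
        genuine = Replicon("genuine", asm.seq[5_000:14_000])
        unplaced = Replicon("unplaced",
                            random_seq(np.random.default_rng(77), 9_000))
        parts = flag_artifact_contigs([artifact, genuine, unplaced], asm)
        assert [c.id for c in parts["artifact"]] == ["artifact"]
        assert [c.id for c in parts["genuine"]] == ["genuine"]
        assert [c.id for c in parts["unplaced"]] == ["unplaced"]

    def test_reverse_complement_artifact_found(self, rng):
        asm = Replicon("asm", random_seq(rng, 40_000))
        art = Replicon("rc_art",
                       revcomp(mutate_to_identity(asm.seq[10_000:19_613],
                                                  0.92, rng)))
        parts = flag_artifact_contigs([art], asm)
        assert [c.id for c in parts["artifact"]] == ["rc_art"]


class TestExtendTerminus:
    def test_planted_overhang_5prime(self, rng):
        truth = random_seq(rng, 120_000)
        draft = Replicon("d", truth[5_121:])
        contig = Replicon("end_contig", truth[:29_048])
        extended, added = extend_terminus(draft, [contig], "5prime")
        assert added == 5_121
        assert extended.seq == truth

    def test_planted_overhang_3prime(self, rng):
        truth = random_seq(rng, 120_000)
        draft = Replicon("d", truth[:-4_000])
        contig = Replicon("c", truth[-20_000:])
        extended, added = extend_terminus(draft, [contig], "3prime")
        assert added == 4_000
        assert extended.seq == truth

    def test_contained_contig_adds_nothing(self, rng):
        truth = random_seq(rng, 50_000)
        draft = Replicon("d", truth)
        contig = Replicon("c", truth[0:20_000])
        extended, added = extend_terminus(draft, [contig], "5prime")
        assert added == 0
        assert extended.seq == truth

    def test_toy_micro_case(self, rng):
        draft = Replicon("d", random_seq(rng, 60))
        contig = Replicon("c", "AAAA" + draft.seq[:30])
        params = ParamSet(anchor_k=11, min_anchor=11)
        extended, added = extend_terminus(draft, [contig], "5prime",
                                          min_overlap=20, min_ident=0.99,
                                          params=params)
        assert added == 4
        assert extended.seq == "AAAA" + draft.seq

    def test_conflicting_overhangs_error(self, rng):
        truth = random_seq(rng, 50_000)
        draft = Replicon("d", truth[3_000:])
        good = Replicon("good", truth[:10_000])
        bad = Replicon("bad", random_seq(np.random.default_rng(5), 3_000)
                       + truth[3_000:10_000])
        with pytest.raises(FinishError, match="good.*bad|bad.*good"):
            extend_terminus(draft, [good, bad], "5prime")

    def test_reverse_complement_contig_used(self, rng):
        truth = random_seq(rng, 60_000)
        draft = Replicon("d", truth[2_000:])
        contig = Replicon("c", revcomp(truth[:15_000]))
        extended, added = extend_terminus(draft, [contig], "5prime")
        assert added == 2_000
        assert extended.seq == truth


@pytest.fixture(scope="module")
def gap_scenario():
    rng = np.random.default_rng(31)
    truth = Replicon("P", random_seq(rng, 60_000))
    a = Replicon("A", truth.seq[:40_000])
    b = Replicon("B", truth.seq[42_500:])
    return truth, a, b


class TestBridging:
    def test_planted_gap_filled(self, gap_scenario):
        truth, a, b = gap_scenario
        reads = tiling_reads(truth, 10_000, 30)
        merged, gap = bridge_contigs(a, b, reads, min_anchor=500,
                                     min_span_reads=3)
        assert merged.seq == truth.seq
        assert gap == 2_500

    def test_adjacent_contigs_concatenate(self, rng):
        truth = Replicon("P", random_seq(rng, 50_000))
        a = Replicon("A", truth.seq[:30_000])
        b = Replicon("B", truth.seq[30_000:])
        reads = tiling_reads(truth, 8_000, 30)
        merged, gap = bridge_contigs(a, b, reads, min_span_reads=3)
        assert gap == 0
        assert merged.seq == truth.seq

    def test_unbridged_error(self, gap_scenario):
        truth, a, b = gap_scenario
        reads = [Replicon("r", truth.seq[:10_000])]  # nowhere near the gap
        with pytest.raises(FinishError, match="unbridged"):
            bridge_contigs(a, b, reads)

    def test_ambiguous_gap_error(self, gap_scenario):
        truth, a, b = gap_scenario
        # two read populations implying gap lengths differing by 40 bases
        alt = truth.seq[:41_000] + truth.seq[41_040:]
        reads = (tiling_reads(truth, 10_000, 20)
                 + tiling_reads(Replicon("P2", alt), 10_000, 20))
        with pytest.raises(FinishError, match="ambiguous"):
            bridge_contigs(a, b, reads, min_span_reads=3)

    def test_overlapping_contigs_trimmed(self, rng):
        truth = Replicon("P", random_seq(rng, 50_000))
        a = Replicon("A", truth.seq[:30_000])
        b = Replicon("B", truth.seq[28_000:])   # 2 kb overlap
        merged, gap = bridge_contigs(a, b, tiling_reads(truth, 10_000, 20),
                                     min_span_reads=3)
        assert gap == 0
        assert merged.seq == truth.seq

    def test_noisy_reads_consensus(self, gap_scenario):
        """With 1% substitution errors and >= 10 spanning reads the bridged
        gap matches the truth in nearly all seeds."""
        truth, a, b = gap_scenario
        exact = 0
        trials = 10
        for seed in range(trials):
            reads, _ = simulate_long_reads(truth, 10_000, 25.0,
                                           error_rate=0.01, seed=seed)
            try:
                merged, _ = bridge_contigs(a, b, reads, min_span_reads=3)
            except FinishError:
                continue
            exact += merged.seq == truth.seq
        assert exact >= int(0.9 * trials)


@pytest.fixture(scope="module")
def scenario():
    cfg = SimConfig(chromosome_length=120_000, tir_len=3_000,
                    n_hp_del=25, n_subst=3,
                    plasmid1_circle_len=20_000, plasmid1_dup_len=2_000,
                    plasmid2_len=30_000, plasmid2_gap=(18_000, 20_000),
                    n_contigs=6, seed=42)
    fs, _ = build_truth(cfg)
    chrom = fs.get("chrom")
    draft, _ = corrupt_longread_style(chrom, cfg.n_hp_del, cfg.n_subst,
                                      100, seed=43)
    contigs = make_contigs(chrom, cfg.n_contigs, seed=44)
    contigs += make_contigs(fs.get("plin"), 2,
                            dropped_regions=[cfg.plasmid2_gap], seed=45)
    p1c = linearize_with_duplication(fs.get("pcirc"), cfg.plasmid1_dup_len)
    reads, _ = simulate_long_reads(fs.get("plin"), 10_000, 20.0, 0.0,
                                   seed=46)
    config = {"draft": [draft, p1c], "contigs": contigs, "reads": reads,
              "seed": 42}
    return cfg, fs, config


class TestPipeline:
    def test_end_to_end_recovery(self, scenario):
        cfg, truth_fs, config = scenario
        out = run_pipeline(config)
        assert out.get("chrom").seq == truth_fs.get("chrom").seq
        circ = out.get("pcirc_contig")
        assert circ.topology == "circular"
        assert len(circ.seq) == cfg.plasmid1_circle_len
        merged = [r for r in out.replicons if "+" in r.id]
        assert len(merged) == 1
        assert len(merged[0].seq) == cfg.plasmid2_len
        assert merged[0].seq == truth_fs.get("plin").seq

    def test_determinism(self, scenario):
        _, _, config = scenario
        out1 = run_pipeline(config)
        out2 = run_pipeline(config)
        assert [(r.id, r.seq, r.topology) for r in out1.replicons] == \
               [(r.id, r.seq, r.topology) for r in out2.replicons]

    def test_draft_only_topology_scan(self, rng):
        rep = Replicon("solo", random_seq(rng, 30_000))
        out = run_pipeline({"draft": [rep]})
        assert len(out.replicons) == 1
        assert out.replicons[0].seq == rep.seq
        assert out.replicons[0].topology == "linear"

    def test_rerun_applies_no_further_corrections(self, scenario):
        _, truth_fs, config = scenario
        out = run_pipeline(config)
        chrom = out.get("chrom")
        config2 = dict(config)
        config2["draft"] = [chrom]
        out2 = run_pipeline(config2)
        rep = out2.reports.get("polish:chrom")
        assert rep is not None and rep.total_corrections == 0
        assert out2.get("chrom").seq == chrom.seq
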