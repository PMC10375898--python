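import numpy as np
import pytest

from chemclipseq import (
    Annotation,
    CandidateRegion,
    CoverageTrack,
    SimulationConfig,
    SpikeSpec,
    Transcript,
    aggregate_transcripts,
    assign_regions,
    compare_conditions,
    generate_annotation,
    run_enrichment,
    run_transcript_hits,
    simulate_coverage,
)
from chemclipseq.transcripts import TranscriptHit


def region(contig, start, end):
    return CandidateRegion(contig=contig, start=start, end=end, auc=0.0, max_neglog10p=0.0)


class TestAssignRegions:
    def test_contained_region_assigned(self):
        ann = Annotation([Transcript("t1", "g1", "c", 0, 1000)])
        a = assign_regions([region("c", 100, 600)], ann)
        assert [r.start for r in a.by_transcript["t1"]] == [100]
        assert a.intergenic == [] and a.ambiguous_regions == []

    def test_region_over_two_transcripts_flagged_ambiguous(self):
        ann = Annotation([
            Transcript("t1", "g1", "c", 0, 500),
            Transcript("t2", "g2", "c", 400, 900),
        ])
        a = assign_regions([region("c", 450, 480)], ann)
        assert set(a.by_transcript) == {"t1", "t2"}
        assert len(a.ambiguous_regions) == 1

    def test_unoverlapped_region_is_intergenic(self):
        ann = Annotation([Transcript("t1", "g1", "c", 0, 100)])
        a = assign_regions([region("c", 200, 300), region("other", 0, 10)], ann)
        assert len(a.intergenic) == 2

    def test_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(17)
        transcripts = []
        for i in range(40):
            start = int(rng.integers(0, 10_000))
            transcripts.append(
                Transcript(f"t{i}", f"g{i}", f"chr{i % 4}", start,
                           start + int(rng.integers(50, 2000)))
            )
        ann = Annotation(transcripts)
        regions = []
        for _ in range(120):
            start = int(rng.integers(0, 11_000))
            regions.append(
                region(f"chr{int(rng.integers(0, 4))}", start, start + int(rng.integers(10, 800)))
            )
        a = assign_regions(regions, ann)
        # quadratic oracle: strict interval intersection on shared contigs
        expected: dict[str, set] = {}
        for r in regions:
            for t in transcripts:
                if t.contig == r.contig and r.start < t.end and t.start < r.end:
                    expected.setdefault(t.transcript_id, set()).add((r.start, r.end))
        got = {
            tid: {(r.start, r.end) for r in regs}
            for tid, regs in a.by_transcript.items()
        }
        assert got == expected


class TestAggregate:
    def hand_fixture(self):
        # two regions on one transcript; input sums 20+20, output 30+50,
        # library totals engineered equal (1000 reads each side)
        inp = np.full(500, 2, dtype=np.int64)
        out = np.full(500, 2, dtype=np.int64)
        out[0:10] = 3
        out[20:30] = 5
        out[30:70] = 1
        ann = Annotation([Transcript("t1", "g1", "c", 0, 500)])
        assignment = assign_regions([region("c", 0, 10), region("c", 20, 30)], ann)
        return (
            assignment,
            {"c": CoverageTrack("c", inp)},
            {"c": CoverageTrack("c", out)},
            ann,
        )

    def test_multi_region_sum_matches_hand_recomputation(self):
        assignment, pooled_in, pooled_out, ann = self.hand_fixture()
        assert pooled_in["c"].total == pooled_out["c"].total == 1000
        hits = aggregate_transcripts(
            assignment, pooled_in, pooled_out, ann, hit_threshold=0.8, pseudocount=0.5
        )
        (h,) = hits
        assert h.n_regions == 2
        assert h.reads_input_norm == pytest.approx(40 / 1000 * 1e6)
        assert h.reads_output_norm == pytest.approx(80 / 1000 * 1e6)
        expected = np.log2((80_000 + 0.5) / (40_000 + 0.5))
        assert h.log2_enrichment == pytest.approx(expected)
        assert h.log2_enrichment == pytest.approx(1.0, abs=1e-4)
        assert h.passing

    def test_equal_sides_give_zero_enrichment(self):
        inp = np.full(200, 4, dtype=np.int64)
        ann = Annotation([Transcript("t1", "g1", "c", 0, 200)])
        assignment = assign_regions([region("c", 50, 150)], ann)
        track = {"c": CoverageTrack("c", inp)}
        (h,) = aggregate_transcripts(assignment, track, track, ann)
        assert h.log2_enrichment == 0.0
        assert not h.passing

    def test_region_reads_conserved_in_transcript_sum(self):
        assignment, pooled_in, pooled_out, ann = self.hand_fixture()
        (h,) = aggregate_transcripts(assignment, pooled_in, pooled_out, ann)
        per_region_out = sum(
            pooled_out["c"].values[r.start : r.end].sum()
            for r in assignment.by_transcript["t1"]
        )
        assert h.reads_output_norm * pooled_out["c"].total / 1e6 == pytest.approx(
            per_region_out
        )

    def test_uniform_scaling_leaves_enrichment_unchanged(self):
        assignment, pooled_in, pooled_out, ann = self.hand_fixture()
        (h1,) = aggregate_transcripts(assignment, pooled_in, pooled_out, ann)
        scaled_in = {"c": CoverageTrack("c", pooled_in["c"].values * 7)}
        scaled_out = {"c": CoverageTrack("c", pooled_out["c"].values * 7)}
        (h2,) = aggregate_transcripts(assignment, scaled_in, scaled_out, ann)
        assert h2.log2_enrichment == pytest.approx(h1.log2_enrichment)

    def test_zero_library_total_rejected(self):
        ann = Annotation([Transcript("t1", "g1", "c", 0, 10)])
        assignment = assign_regions([region("c", 0, 5)], ann)
        empty = {"c": CoverageTrack("c", np.zeros(10, dtype=np.int64))}
        with pytest.raises(ValueError, match="library"):
            aggregate_transcripts(assignment, empty, empty, ann)


def hit(tid, log2, passing=True):
    return TranscriptHit(
        transcript_id=tid, gene_id=tid.replace("t", "g"), n_regions=1,
        reads_input_norm=1.0, reads_output_norm=1.0,
        log2_enrichment=log2, passing=passing,
    )


class TestCompareConditions:
    def test_identical_hit_lists_have_no_exclusives(self):
        hits = [hit("t1", 1.2), hit("t2", 0.9)]
        table = compare_conditions(hits, hits, "dm1", "wt")
        assert (table["membership"] == "shared").all()

    def test_set_difference_and_intersection(self):
        a = [hit("t1", 1.5), hit("t2", 0.91)]
        b = [hit("t2", 0.85), hit("t3", 0.2, passing=False)]
        table = compare_conditions(a, b, "dm1", "wt").set_index("transcript_id")
        assert table.loc["t1", "membership"] == "dm1_only"
        assert table.loc["t2", "membership"] == "shared"
        assert "t3" not in table.index
        assert table.loc["t2", "log2_dm1"] == pytest.approx(0.91)
        assert table.loc["t2", "log2_wt"] == pytest.approx(0.85)


def test_condition_specific_spikes_yield_exclusive_hits():
    """Two conditions spiked on disjoint transcripts: the exclusive hit
    sets recovered end-to-end equal the simulated ground truth."""
    base = SimulationConfig(
        n_transcripts=20, transcript_length_range=(2500, 3500), seed=21
    )
    ann = generate_annotation(base)

    def run(spiked_tids, seed):
        spikes = [SpikeSpec(tid, 800, 1500, fold=8.0) for tid in spiked_tids]
        cfg = SimulationConfig(
            n_transcripts=20, transcript_length_range=(2500, 3500),
            seed=base.seed, spikes=spikes,
        )
        cfg.seed = base.seed  # same annotation; coverage varies by spike set
        tracks = simulate_coverage(ann, cfg)
        pairs = [(tracks[(k, "input")], tracks[(k, "output")]) for k in range(3)]
        result = run_enrichment(pairs)
        hits, _ = run_transcript_hits(result, ann)
        return hits

    hits_a = run(["tx03", "tx11"], 21)
    hits_b = run(["tx11", "tx17"], 22)
    table = compare_conditions(hits_a, hits_b, "A", "B")
    by_membership = {
        m: set(g["transcript_id"]) for m, g in table.groupby("membership")
    }
    assert by_membership.get("A_only") == {"tx03"}
    assert by_membership.get("B_only") == {"tx17"}
    assert by_membership.get("shared") == {"tx11"}
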