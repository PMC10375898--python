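import numpy as np
import pytest

from chemclipseq import (
    CoverageTrack,
    EnrichmentProfile,
    FilterConfig,
    apply_filters,
    call_regions,
)

from _oracles import brute_force_auc, brute_force_regions
from conftest import random_neglog10p_track


def profile(nlp, contig="c"):
    nlp = np.asarray(nlp, dtype=float)
    return EnrichmentProfile(
        contig=contig, ratio=np.ones(len(nlp)),
        mask=~np.isnan(nlp), neglog10p=nlp,
    )


class TestCallRegions:
    def test_hand_computable_example(self):
        regs = call_regions(profile([0, 12, 12, 0]), FilterConfig(p_cutoff=10, max_gap=0))
        assert len(regs) == 1
        r = regs[0]
        assert (r.start, r.end, r.length) == (1, 3, 2)
        assert r.auc == pytest.approx(4.0)
        assert r.max_neglog10p == 12.0

    def test_raw_auc_mode_sums_whole_signal(self):
        regs = call_regions(
            profile([0, 12, 12, 0]), FilterConfig(p_cutoff=10, auc_mode="raw")
        )
        assert regs[0].auc == pytest.approx(24.0)

    def test_all_zero_track_yields_nothing(self):
        assert call_regions(profile(np.zeros(100))) == []

    def test_gap_merging(self):
        nlp = [12, 0, 12]
        assert len(call_regions(profile(nlp), FilterConfig(max_gap=0))) == 2
        merged = call_regions(profile(nlp), FilterConfig(max_gap=1))
        assert [(r.start, r.end) for r in merged] == [(0, 3)]

    def test_masked_nucleotide_shatters_unless_gap_allowed(self):
        nlp = [12, np.nan, 12]
        assert len(call_regions(profile(nlp), FilterConfig(max_gap=0))) == 2
        assert len(call_regions(profile(nlp), FilterConfig(max_gap=1))) == 1

    def test_cutoff_is_strict_inequality(self):
        regs = call_regions(profile([10.0, 10.0]), FilterConfig(p_cutoff=10))
        assert regs == []

    @pytest.mark.parametrize("max_gap", [0, 2])
    @pytest.mark.parametrize("auc_mode", ["above_cutoff", "raw"])
    def test_matches_brute_force_scanner(self, max_gap, auc_mode):
        rng = np.random.default_rng(123 + max_gap)
        cutoff = 10.0
        config = FilterConfig(p_cutoff=cutoff, max_gap=max_gap, auc_mode=auc_mode)
        for _ in range(60):
            length = int(rng.integers(50, 3000))
            nlp = random_neglog10p_track(rng, length)
            got = call_regions(profile(nlp), config)
            expected = brute_force_regions(nlp, cutoff, max_gap)
            assert [(r.start, r.end) for r in got] == expected
            for r, (s, e) in zip(got, expected):
                assert r.auc == pytest.approx(
                    brute_force_auc(nlp, s, e, cutoff, auc_mode)
                )


def two_region_fixture(folds_by_rep, length=500):
    """One contig, a single candidate region with chosen per-replicate folds."""
    L = 5000
    start = 1000
    nlp = np.zeros(L)
    nlp[start : start + length] = 15.0
    pairs = []
    for fold in folds_by_rep:
        inp = np.full(L, 10, dtype=np.int64)
        out = np.full(L, 10, dtype=np.int64)
        out[start : start + length] = int(round(10 * fold))
        pairs.append(
            ({"c": CoverageTrack("c", inp)}, {"c": CoverageTrack("c", out)})
        )
    return profile(nlp), pairs


class TestApplyFilters:
    def test_length_350_fails_length_filter(self):
        prof, pairs = two_region_fixture([3, 3, 3], length=350)
        regions = call_regions(prof, FilterConfig())
        passing, verdicts = apply_filters(regions, pairs, FilterConfig())
        assert passing == []
        assert not verdicts["pass_length"].iloc[0]
        assert verdicts["pass_auc"].iloc[0]
        assert verdicts["pass_replicates"].iloc[0]

    def test_inconsistent_replicate_fails_consistency_filter(self):
        # per-replicate log2 fold changes ~ [1.2, 1.1, 0.5]: one replicate
        # below the 0.8 minimum sinks the region
        prof, pairs = two_region_fixture([2.3, 2.15, 1.42])
        regions = call_regions(prof, FilterConfig())
        passing, verdicts = apply_filters(regions, pairs, FilterConfig())
        assert passing == []
        row = verdicts.iloc[0]
        assert row["log2fc_rep1"] > 0.8 and row["log2fc_rep2"] > 0.8
        assert row["log2fc_rep3"] < 0.8
        assert not row["pass_replicates"]
        assert row[["pass_auc", "pass_length", "pass_reads"]].all()

    def test_crafted_cascade_passes_exactly_the_known_subset(self, cascade_fixture):
        fx = cascade_fixture
        regions = call_regions(fx.profile, FilterConfig())
        assert {(r.start, r.end) for r in regions} == set(fx.regions.values())
        passing, verdicts = apply_filters(regions, fx.replicate_pairs, FilterConfig())
        got = {(r.start, r.end) for r in passing}
        expected = {fx.regions[name] for name in fx.expected_passing}
        assert got == expected
        assert len(passing) == 4

    def test_cascade_verdicts_match_independent_recomputation(self, cascade_fixture):
        fx = cascade_fixture
        config = FilterConfig()
        regions = call_regions(fx.profile, config)
        _, verdicts = apply_filters(regions, fx.replicate_pairs, config)
        nlp = fx.profile.neglog10p
        lib = [
            (float(inp["chrF"].values.sum()), float(out["chrF"].values.sum()))
            for inp, out in fx.replicate_pairs
        ]
        for _, row in verdicts.iterrows():
            s, e = int(row["start"]), int(row["end"])
            auc = brute_force_auc(nlp, s, e, config.p_cutoff, config.auc_mode)
            reads_out = sum(
                float(out["chrF"].values[s:e].sum()) for _, out in fx.replicate_pairs
            )
            fcs = []
            for (inp, out), (n_in, n_out) in zip(fx.replicate_pairs, lib):
                o = (float(out["chrF"].values[s:e].sum()) + 1.0) / n_out
                i = (float(inp["chrF"].values[s:e].sum()) + 1.0) / n_in
                fcs.append(np.log2(o / i))
            assert row["auc"] == pytest.approx(auc)
            assert row["pass_auc"] == (auc >= 200)
            assert row["pass_length"] == (400 <= e - s <= 1000)
            assert row["pass_reads"] == (reads_out >= 10)
            assert row["pass_replicates"] == all(fc >= 0.8 for fc in fcs)
            assert row["pass_all"] == (
                row["pass_auc"] and row["pass_length"]
                and row["pass_reads"] and row["pass_replicates"]
            )

    def test_relaxing_any_threshold_never_removes_a_passing_region(self, cascade_fixture):
        fx = cascade_fixture
        base = FilterConfig()
        regions = call_regions(fx.profile, base)
        baseline, _ = apply_filters(regions, fx.replicate_pairs, base)
        base_set = {(r.start, r.end) for r in baseline}
        relaxed_configs = [
            FilterConfig(min_auc=50),
            FilterConfig(length_min=100),
            FilterConfig(length_max=5000),
            FilterConfig(min_reads=0),
            FilterConfig(min_log2fc=0.0),
        ]
        for config in relaxed_configs:
            passing, _ = apply_filters(regions, fx.replicate_pairs, config)
            assert base_set <= {(r.start, r.end) for r in passing}

    def test_replicate_pair_required(self, cascade_fixture):
        regions = call_regions(cascade_fixture.profile, FilterConfig())
        with pytest.raises(ValueError, match="replicate"):
            apply_filters(regions, [], FilterConfig())
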