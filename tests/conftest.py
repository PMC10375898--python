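from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from chemclipseq import CoverageTrack, EnrichmentProfile


def make_track(values, contig="chrT", offset=0):
    return CoverageTrack(contig, np.asarray(values), offset=offset)


@dataclass
class CascadeFixture:
    """Hand-crafted contig with ten candidate regions of known properties.

    Regions are designed around the published operating point (cutoff
    10, AUC >= 200, length 400-1000, reads >= 10, log2FC >= 0.8 in all
    replicates): four satisfy every filter, the others each miss at
    least one in a predetermined way.
    """

    profile: EnrichmentProfile
    replicate_pairs: list  # [(input TrackSet, output TrackSet)] per replicate
    regions: dict[str, tuple[int, int]]  # name -> (start, end)
    expected_passing: set[str]
    contig_length: int = 50_000


@pytest.fixture(scope="session")
def cascade_fixture() -> CascadeFixture:
    L = 50_000
    contig = "chrF"
    # name: (start, length, nlp excess over the cutoff, per-replicate output/nt)
    spec = {
        "pass_basic": (1000, 500, 1.0, [30, 30, 30]),
        "fail_auc": (2000, 450, 0.4, [30, 30, 30]),
        "fail_short": (3000, 350, 1.0, [30, 30, 30]),
        "fail_long": (4000, 1200, 1.0, [30, 30, 30]),
        "fail_reads": (6000, 400, 1.0, None),  # input 0; 2 output reads/rep
        "fail_reps": (7000, 500, 1.0, [30, 30, 12]),
        "pass_auc_boundary": (8000, 400, 0.5, [30, 30, 30]),
        "pass_len_boundary": (9000, 1000, 0.3, [25, 25, 25]),
        "fail_multi": (11000, 300, 0.2, [10, 10, 10]),
        "pass_multi_fc": (12000, 700, 2.0, [30, 35, 40]),
    }
    expected_passing = {
        "pass_basic", "pass_auc_boundary", "pass_len_boundary", "pass_multi_fc",
    }

    nlp = np.zeros(L)
    inp = np.full(L, 10, dtype=np.int64)
    outs = [np.full(L, 10, dtype=np.int64) for _ in range(3)]
    for name, (start, length, excess, folds) in spec.items():
        end = start + length
        nlp[start:end] = 10.0 + excess
        if folds is None:  # the read-starved region
            inp[start:end] = 0
            for out in outs:
                out[start:end] = 0
                out[start] = 2
        else:
            for out, v in zip(outs, folds):
                out[start:end] = v

    profile = EnrichmentProfile(
        contig=contig,
        ratio=np.ones(L),
        mask=np.ones(L, dtype=bool),
        neglog10p=nlp,
    )
    pairs = [
        ({contig: CoverageTrack(contig, inp.copy())}, {contig: CoverageTrack(contig, out)})
        for out in outs
    ]
    return CascadeFixture(
        profile=profile,
        replicate_pairs=pairs,
        regions={n: (s, s + ln) for n, (s, ln, _, _) in spec.items()},
        expected_passing=expected_passing,
        contig_length=L,
    )


def random_neglog10p_track(rng, length, nan_fraction=0.05, scale=6.0):
    """A jagged -log10(p)-like track hovering around typical cutoffs."""
    vals = rng.exponential(scale, size=length)
    # smear in some long high stretches so multi-nucleotide regions occur
    n_blocks = max(1, length // 2000)
    for _ in range(rng.integers(0, n_blocks + 1)):
        start = int(rng.integers(0, max(1, length - 50)))
        width = int(rng.integers(5, 400))
        vals[start : start + width] += rng.uniform(5, 15)
    nan_idx = rng.random(length) < nan_fraction
    vals[nan_idx] = np.nan
    return vals
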